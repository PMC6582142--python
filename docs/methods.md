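# Methods

## Model

The intestinal wall is treated as a two-dimensional continuum of resistor
elements. Each wall element of size Δx·Δy couples three compartments in
series/parallel:

- **Transmural influx**: arteries perforating the muscle layer deliver
  flow density j_α = α(x,y)·(Δp₀ − p), where Δp₀ is the systemic arterial
  perfusion-pressure gradient and p(x,y) the local submucosal perfusion
  pressure. Wall stress (muscle contraction, traction) lowers α.
- **Terminal outflow**: the mucosal vascular bed plus the part of the
  muscle supplied retrogradely from the submucosa drains j_ω = ω(x,y)·p.
  Metabolic demand (acid secretion, acid exposure) raises ω.
- **Lateral collateral flow** in the submucosal arterial plane, with
  direction-dependent resistances λx (axial) and λy (circumferential):
  j_λx = −(1/λx)·∂p/∂x and analogously in y.

Stationarity (the wall stores no blood) gives the elliptic PDE

    α(Δp₀ − p) − ω p + ∂x[(1/λx) ∂x p] + ∂y[(1/λy) ∂y p] = 0 .

All quantities are dimensionless model units: h = 1 per cell edge and
Δp₀ = 1 by default. No physiological calibration (mmHg, ml·min⁻¹·100 g⁻¹)
is attempted; only relative spatial patterns are interpreted.

## Discretization and solvers

Finite volumes on an nx×ny grid (x = axial, oral→aboral; y =
circumferential). The face between cells (i,j) and (i+1,j) carries
conductance g = 1/(λx[i,j]·h²) under the default `lower_index` convention
(the lateral resistance is attributed to the lower-index cell, matching
the model's one-sided difference relation), or
g = 2/((λx[i,j]+λx[i+1,j])·h²) under `harmonic_mean`, the standard
finite-volume alternative. The cell balance is

    (α + ω + Σg)·p − Σ g·p_neighbour = α·Δp₀ ,

a diagonally dominant M-matrix system (strictly dominant wherever
α + ω > 0). Consequences asserted as test properties: the discrete maximum
principle 0 ≤ p ≤ Δp₀; global Kirchhoff conservation Σj_α = Σj_ω under
no-flux boundaries; and steal monotonicity — raising ω in any cell
strictly lowers p in every cell of its laterally connected component.

**Boundary conditions.** Default `no_flux` on all edges (an isolated
tissue patch). `periodic_y` closes the circumference; x edges stay
no-flux. The linear-ulcer scenario uses `periodic_y`, since its claim — a
trough ringing the whole circumference — concerns the closed organ; the
other built-in scenarios are self-contained patches.

**Iterative solver.** Plain Gauss–Seidel (SOR for relaxation in (1,2)),
fixed row-major ascending sweep order, initial guess p = α·Δp₀/(α+ω)
cellwise (exact in the homogeneous case). Stopping rule: maximum absolute
per-sweep update ≤ tolerance·Δp₀ (default 10⁻¹⁰), capped at 200 000
sweeps; the residual of the balance equation is audited separately
(`balance_residuals`). The sweep kernel is compiled with numba; a sweep of
the 50×50 scenarios costs microseconds and the published configurations
converge in tens to a few thousand sweeps.

**Direct oracle.** The same assembled system solved by sparse LU
(scipy.sparse). It is used as the independent ground truth in tests (50
seeded random instances up to 20×20 must agree with Gauss–Seidel to
10⁻⁶·Δp₀) and never as the production path. A laterally connected
component without any α > 0 is rejected as sourceless/singular.

**Mirror symmetry.** Under `harmonic_mean` the discretization is exactly
mirror-symmetric. Under `lower_index` the face attribution is
orientation-dependent, so mirroring the parameter grids mirrors the
solution exactly only when λ is constant along the mirrored axis — true
in every built-in scenario (the cardia scenario is the exact x-mirror of
the borderline scenario). This is an inherent property of the one-sided
convention, not a solver defect.

## Scenarios

Constants are recorded in each scenario's `metadata` and may be overridden
individually. Quoted index blocks are 1-based inclusive and tile the grid.

- **antrum-borderline** (50×50): α ≡ 0.1; ω = 5.0 on corpus columns 1–30,
  1.0 on antral columns 31–50; lesser-curvature rows 1–20 have λx =
  3.82·10⁻¹, λy = 3.82·10³ (axial arteries), parietal-wall rows 21–50 the
  transpose (circumferential arteries).
- **cardia**: the exact axial mirror of the above.
- **linear-ulcer**: as antrum-borderline but isotropic λx = λy = 3.82·10⁻¹
  everywhere (the star-shaped distal-antrum plexus), periodic in y.
- **watershed(ω)** (50×50): central 30×30 block (rows/cols 11–40) α =
  0.001, α = 1 outside; isotropic λ = 3.82·10⁻¹; uniform ω. The demand
  ramp is exercised at ω ∈ {1, 10, 100} as three separate solves.
- **necrosis(pre|post)** (50×50): circular watershed of diameter 18 cells
  (cell-centre distance ≤ 9 from the grid centre; ties inside) with α =
  0.05 inside, 0.1 outside; isotropic λ = 3.82·10⁻¹; ω = 10 in vital
  mucosa, and in the `post` stage ω = 0.05 on the inner disc of diameter
  15 (the necrotic core).
- **homogeneous**: uniform α = 0.1, ω = 1, λ = 3.82·10⁻¹ — the closed-form
  reference p = α·Δp₀/(α+ω).

`random_fixture(seed, nx, ny)` draws log-uniform fields (α ∈ [10⁻³, 1],
ω ∈ [10⁻², 10²], λ ∈ [10⁻¹, 10⁴]) for oracle testing. These ranges bracket
the scenario constants by about an order of magnitude on each side; the
fixtures exercise the solver across extreme conductance contrasts but do
not emulate anatomically structured fields, so passing the oracle tests
validates the numerics, not any physiological realism.

## Necrosis feedback

`run_necrosis_iteration` implements the viability feedback: solve; mark
every active, not-yet-necrotic cell with j_ω < θ; collapse those cells' ω
to ω_necrotic (default 0.05, the residual retrograde muscle-layer
conductance) synchronously; repeat. The necrotic set grows monotonically,
so the iteration terminates in at most nx·ny rounds; in practice the
published configuration reaches its fixed point in one collapse round,
because the redistributed collateral flow immediately lifts the surviving
rim above threshold. The viability threshold θ has no established
numerical value; it is an explicit argument, and
`find_self_limiting_theta` scans the observed j_ω range to exhibit the
self-limiting regime. Synchronous whole-set collapse was chosen over
one-cell-at-a-time sequential necrosis to match the two-state (vital/dead)
presentation of the scenario; a sequential variant would reach the same
kind of fixed point through more rounds. Rounds are logical, not temporal
— no healing or time constants are modelled.

## Pattern metrics

The morphological claims are verbal; the operational definitions here are
this package's own.

- **reibungsform_asymmetry**: locate the interior minimum of a row's j_ω
  profile; on each side take the median of the outermost 10 columns as
  that side's plateau, and measure the distance (linearly interpolated
  between cells) to the point recovering 50% of the way from the minimum
  to that plateau. Ratio = distal/proximal half-width; > 1 means steep
  corpus edge and shallow distal tail. The per-side plateau (rather than a
  single distal reference) makes the metric of a profile and of its mirror
  exact reciprocals even when the two plateaus differ, as they do at a
  borderline between unequal ω.
- **dip_depth** = 1 − min(j_ω over centre)/mean(j_ω over reference),
  clipped to [0,1]. In the watershed ramp the dip is nearly saturated at
  every ω (the 30-cell block is much wider than the collateral
  penetration depth √(1/(λω)) of a few cells), but it still increases
  strictly with ω.
- **circularity** = 4πA/P² of the largest 4-connected component of the
  sublevel set j_ω ≤ min + f·(reference − min), with the reference level
  taken as the median of j_ω over the search mask and P counted as
  boundary edges. Note the rasterization cap: with an edge-count
  perimeter, every digitally convex set has P equal to its bounding-box
  perimeter, so a square scores π/4 ≈ 0.785 and a staircase disc
  π²/16 ≈ 0.617 — the "rounding" of the watershed dip therefore shows up
  as the corner-cell deficit of the sublevel set against its bounding
  box, not as a circularity above π/4.
- **circumferential_extent**: fraction of rows whose profile has an
  interior minimum deeper than a given absolute threshold below that
  row's distal plateau (median of the last 10 columns) and below both row
  ends. The threshold is a caller choice; the tests use 20% of the
  deepest row trough of the anisotropic borderline solution, which cleanly
  separates the lesser-curvature band (extent 0.4) from the isotropic
  full ring (extent 1.0).
- **steal_index**: relative change of mean regional j_ω against a
  baseline solution.
- **contrast_enhancement**: post/pre ratio of the maximum central-
  difference gradient magnitude of j_ω over a set of margin cells.
- **net_lateral_inflow**: signed sum of face flows crossing a region
  boundary, positive inward.

All metrics except circumferential_extent are invariant under rescaling
Δp₀ (the PDE is linear); the extent is invariant when its absolute
threshold is scaled along.

## Numerical choices and degenerate inputs

- Tolerance 10⁻¹⁰·Δp₀ on the sweep update leaves the iterative solution
  within ~10⁻⁸ of the direct solve in the worst random instance, two
  orders below the 10⁻⁶ oracle tolerance.
- Cells with α = ω = 0 are permitted as pure lateral conductors; the
  system stays non-singular as long as each connected component has a
  source.
- 0/0 in the initial guess (α = ω = 0) is defined as 0.
- Disc rasterization uses Euclidean cell-centre distance with ties
  counted inside.
- Sublevel-set ties (j_ω exactly at threshold) are inside; connectivity
  is 4-neighbour throughout.
- Interior-minimum search takes the lowest interior value; with
  `boundary_x` given, ties resolve to the candidate nearest the boundary.

## Problem sizes

The test suite and the acceptance script use the native 50×50 scenario
grids throughout; solver cross-validation runs 50 random instances up to
20×20, where sparse LU factorisation is exact and cheap. The whole suite
runs in a few seconds.

## Known limitations

- The model is 2-D and stationary: no 3-D recurrent-artery topography, no
  storage/time dependence, no haematocrit or rheology, and no healing.
- The pressure–flow relations are linear; autoregulation and
  vasomotor response are outside scope.
- Scenario constants are stylized block patterns, not patient-specific
  vascular maps; conclusions are about pattern classes, not individuals.
- Iteration counts of the Gauss–Seidel solver depend on the documented
  sweep order; only the converged fields are order-independent.
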