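"""Built-in simulation scenarios and randomized test fixtures.

Each builder returns a fully parameterized :class:`Scenario`: grid,
parameter fields, named boolean region masks and a metadata record of the
constants used.  Constants follow the published figure settings of the
model (dimensionless units, ``delta_p0 = 1``).

Index convention: the figure settings are quoted 1-based and inclusive
("columns 1–30"); internally arrays are 0-based, so the corpus block
``x in [1, 30]`` is the slice ``[0:30]``.  The quoted open ranges are
resolved as inclusive blocks that tile the 50x50 grid exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GridSpec, InvalidArgumentError, ParameterFields

__all__ = [
    "Scenario",
    "LAMBDA_LOW",
    "LAMBDA_HIGH",
    "scenario_antrum_borderline",
    "scenario_cardia",
    "scenario_linear_ulcer",
    "scenario_watershed",
    "scenario_necrosis",
    "scenario_homogeneous",
    "random_fixture",
]

#: Submucosal lateral resistance along the prevailing artery direction.
LAMBDA_LOW = 3.82e-1
#: Lateral resistance perpendicular to the prevailing artery direction.
LAMBDA_HIGH = 3.82e3


@dataclass
class Scenario:
    """A named, fully parameterized model configuration.

    ``masks`` maps region names (corpus, antrum, lesser_curvature,
    parietal_wall, watershed_centre, necrotic_core, surround, ...) to
    boolean grids; ``metadata`` records the constants the builder used.
    """

    name: str
    grid: GridSpec
    fields: ParameterFields
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


def _apply_overrides(constants: dict, overrides: dict | None) -> dict:
    if not overrides:
        return dict(constants)
    unknown = set(overrides) - set(constants)
    if unknown:
        raise InvalidArgumentError(
            f"unknown scenario constant(s): {sorted(unknown)}; "
            f"known: {sorted(constants)}"
        )
    merged = dict(constants)
    merged.update(overrides)
    return merged


def scenario_antrum_borderline(overrides: dict | None = None) -> Scenario:
    """Borderline between acid-secreting corpus and antrum, 50x50 grid.

    Limited transmural influx everywhere (``alpha = 0.1``); terminal
    conductivity 5.0 in the corpus (columns 1–30) against 1.0 in the
    antrum (columns 31–50).  The lesser curvature (rows 1–20) carries
    axially running submucosal arteries (``lambda_x`` low, ``lambda_y``
    high); the parietal wall (rows 21–50) the circumferential pattern
    (``lambda_x`` high, ``lambda_y`` low).  The low axial resistance along
    the lesser curvature lets the corpus steal flow from the adjacent
    antral segments, producing the asymmetric borderline trough.
    """
    constants = {
        "nx": 50,
        "ny": 50,
        "alpha": 0.1,
        "omega_corpus": 5.0,
        "omega_antrum": 1.0,
        "corpus_cols": (1, 30),
        "lc_rows": (1, 20),
        "lambda_low": LAMBDA_LOW,
        "lambda_high": LAMBDA_HIGH,
        "delta_p0": 1.0,
    }
    c = _apply_overrides(constants, overrides)
    nx, ny = int(c["nx"]), int(c["ny"])
    grid = GridSpec(nx, ny)

    corpus_end = int(c["corpus_cols"][1])  # 1-based inclusive
    lc_end = int(c["lc_rows"][1])
    x = np.arange(1, nx + 1)[:, None]
    y = np.arange(1, ny + 1)[None, :]
    corpus = np.broadcast_to(x <= corpus_end, (nx, ny)).copy()
    lesser = np.broadcast_to(y <= lc_end, (nx, ny)).copy()

    alpha = np.full((nx, ny), float(c["alpha"]))
    omega = np.where(corpus, float(c["omega_corpus"]), float(c["omega_antrum"]))
    lambda_x = np.where(lesser, float(c["lambda_low"]), float(c["lambda_high"]))
    lambda_y = np.where(lesser, float(c["lambda_high"]), float(c["lambda_low"]))
    fields = ParameterFields(alpha, omega, lambda_x, lambda_y, float(c["delta_p0"]))
    masks = {
        "corpus": corpus,
        "antrum": ~corpus,
        "lesser_curvature": lesser,
        "parietal_wall": ~lesser,
    }
    return Scenario("antrum-borderline", grid, fields, masks, c)


def scenario_cardia(overrides: dict | None = None) -> Scenario:
    """The borderline scenario mirrored axially (corpus on the high-x side).

    Models the rare ulcer at the cranial edge of the corpus mucosa: the
    same steal mechanism with the laterally reversed orientation.
    """
    base = scenario_antrum_borderline(overrides)
    masks = {name: mask[::-1].copy() for name, mask in base.masks.items()}
    return Scenario("cardia", base.grid, base.fields.mirror_x(), masks, base.metadata)


def scenario_linear_ulcer(overrides: dict | None = None) -> Scenario:
    """Borderline with an isotropic submucosal plexus, periodic circumference.

    In the distal antrum the submucosal meshes are star-shaped, with no
    preferential direction: ``lambda_x = lambda_y`` (low) everywhere, so
    the borderline trough extends around the whole circumference — the
    predicted circular (linear) ulcer.
    """
    base = scenario_antrum_borderline(overrides)
    c = dict(base.metadata)
    grid = GridSpec(base.grid.nx, base.grid.ny, base.grid.h, "periodic_y")
    low = float(c["lambda_low"])
    fields = ParameterFields(
        base.fields.alpha,
        base.fields.omega,
        np.full(grid.shape, low),
        np.full(grid.shape, low),
        base.fields.delta_p0,
    )
    return Scenario("linear-ulcer", grid, fields, dict(base.masks), c)


def scenario_watershed(omega_level: float = 10.0, overrides: dict | None = None) -> Scenario:
    """Collaterally supplied central square under rising mucosal demand.

    The central 30x30 block (rows/columns 11–40) has essentially no
    transmural influx (``alpha = 0.001``) and is perfused by submucosal
    collaterals only — a watershed like the anterior duodenal bulb between
    the two mesenteric inflows.  Uniform isotropic plexus and uniform
    terminal conductivity ``omega_level``; the published demand ramp is
    exercised by calling with ``omega_level`` in {1, 10, 100}.
    """
    if not omega_level > 0:
        raise InvalidArgumentError(f"omega_level must be positive, got {omega_level}")
    constants = {
        "nx": 50,
        "ny": 50,
        "alpha_centre": 0.001,
        "alpha_surround": 1.0,
        "centre_block": (11, 40),
        "lambda_iso": LAMBDA_LOW,
        "delta_p0": 1.0,
    }
    c = _apply_overrides(constants, overrides)
    c["omega_level"] = float(omega_level)
    nx, ny = int(c["nx"]), int(c["ny"])
    grid = GridSpec(nx, ny)
    lo, hi = (int(v) for v in c["centre_block"])  # 1-based inclusive
    x = np.arange(1, nx + 1)[:, None]
    y = np.arange(1, ny + 1)[None, :]
    centre = (x >= lo) & (x <= hi) & (y >= lo) & (y <= hi)
    alpha = np.where(centre, float(c["alpha_centre"]), float(c["alpha_surround"]))
    omega = np.full((nx, ny), float(omega_level))
    lam = np.full((nx, ny), float(c["lambda_iso"]))
    fields = ParameterFields(alpha, omega, lam, lam.copy(), float(c["delta_p0"]))
    masks = {"watershed_centre": centre, "surround": ~centre}
    return Scenario("watershed", grid, fields, masks, c)


def _disc(nx: int, ny: int, diameter: float) -> np.ndarray:
    """Cells whose centre lies within diameter/2 of the grid centre (ties in)."""
    cx, cy = nx / 2.0, ny / 2.0
    x = np.arange(nx)[:, None] + 0.5
    y = np.arange(ny)[None, :] + 0.5
    return (x - cx) ** 2 + (y - cy) ** 2 <= (diameter / 2.0) ** 2


def scenario_necrosis(stage: str = "pre", overrides: dict | None = None) -> Scenario:
    """Circular watershed of the duodenal wall, before/after mucosal death.

    A disc of diameter 18 cells in the centre of the 50x50 grid has only
    limited transmural influx (``alpha = 0.05`` vs 0.1 outside); isotropic
    plexus.  ``stage="pre"``: the mucosa is vital everywhere
    (``omega = 10``), collateral flow feeds the watershed.  ``stage="post"``:
    the inner disc of diameter 15 is necrotic — its terminal conductivity
    collapses to the residual retrograde muscle-layer value 0.05 — and
    collateral flow reverses away from the dead centre.
    """
    if stage not in ("pre", "post"):
        raise InvalidArgumentError(f"stage must be 'pre' or 'post', got {stage!r}")
    constants = {
        "nx": 50,
        "ny": 50,
        "watershed_diameter": 18.0,
        "core_diameter": 15.0,
        "alpha_centre": 0.05,
        "alpha_surround": 0.1,
        "omega_vital": 10.0,
        "omega_necrotic": 0.05,
        "lambda_iso": LAMBDA_LOW,
        "delta_p0": 1.0,
    }
    c = _apply_overrides(constants, overrides)
    c["stage"] = stage
    nx, ny = int(c["nx"]), int(c["ny"])
    grid = GridSpec(nx, ny)
    watershed = _disc(nx, ny, float(c["watershed_diameter"]))
    core = _disc(nx, ny, float(c["core_diameter"]))
    alpha = np.where(watershed, float(c["alpha_centre"]), float(c["alpha_surround"]))
    omega = np.full((nx, ny), float(c["omega_vital"]))
    if stage == "post":
        omega[core] = float(c["omega_necrotic"])
    lam = np.full((nx, ny), float(c["lambda_iso"]))
    fields = ParameterFields(alpha, omega, lam, lam.copy(), float(c["delta_p0"]))
    masks = {
        "watershed_centre": watershed,
        "necrotic_core": core,
        "surround": ~watershed,
    }
    return Scenario(f"necrosis-{stage}", grid, fields, masks, c)


def scenario_homogeneous(overrides: dict | None = None) -> Scenario:
    """Uniform fields — the closed-form reference configuration."""
    constants = {
        "nx": 50,
        "ny": 50,
        "alpha": 0.1,
        "omega": 1.0,
        "lambda_iso": LAMBDA_LOW,
        "delta_p0": 1.0,
    }
    c = _apply_overrides(constants, overrides)
    nx, ny = int(c["nx"]), int(c["ny"])
    grid = GridSpec(nx, ny)
    fields = ParameterFields.uniform(
        grid, float(c["alpha"]), float(c["omega"]), float(c["lambda_iso"]),
        delta_p0=float(c["delta_p0"]),
    )
    masks = {"all": np.ones((nx, ny), dtype=bool)}
    return Scenario("homogeneous", grid, fields, masks, c)


def random_fixture(seed: int, nx: int, ny: int) -> Scenario:
    """Seeded log-uniform random fields for oracle testing.

    alpha in [1e-3, 1], omega in [1e-2, 1e2], lambda in [1e-1, 1e4],
    delta_p0 = 1.  Identical arguments yield bit-identical scenarios.
    """
    rng = np.random.default_rng(seed)

    def loguniform(lo: float, hi: float) -> np.ndarray:
        return 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), size=(nx, ny))

    fields = ParameterFields(
        loguniform(1e-3, 1.0),
        loguniform(1e-2, 1e2),
        loguniform(1e-1, 1e4),
        loguniform(1e-1, 1e4),
        1.0,
    )
    grid = GridSpec(nx, ny)
    masks = {"all": np.ones((nx, ny), dtype=bool)}
    meta = {"seed": int(seed), "nx": nx, "ny": ny}
    return Scenario(f"fixture-{seed}-{nx}x{ny}", grid, fields, masks, meta)
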