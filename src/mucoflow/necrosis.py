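"""Threshold-driven necrosis feedback.

Mucosal tissue whose terminal blood flow ``j_omega`` falls below a
viability threshold ``theta`` dies; dead tissue loses its terminal
vascular bed, so its conductivity collapses to the small residual
retrograde muscle-layer value ``omega_necrotic``.  The collapse
redistributes collateral flow toward the surviving rim, which raises the
rim's ``j_omega`` — so the lesion is self-limiting: the iteration

    solve -> mark j_omega < theta -> collapse omega -> re-solve

reaches a fixed point whose necrotic set is sharply demarcated from a
surround with nearly unaffected flow.  Rounds are logical, not temporal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import InvalidArgumentError, SolutionFields
from .scenarios import Scenario
from .solver import SolverOptions, solve_gauss_seidel

__all__ = ["NecrosisTrace", "run_necrosis_iteration", "find_self_limiting_theta"]


@dataclass
class NecrosisTrace:
    """Round-by-round history of the conductivity-collapse iteration.

    ``rounds[k]`` holds the cumulative necrotic mask in effect during the
    k-th solve together with that solve's :class:`SolutionFields`; masks
    are monotonically non-decreasing.  The final round either added no new
    necrosis (``fixed_point_reached``) or hit the ``nx*ny`` round cap.
    """

    rounds: list[tuple[np.ndarray, SolutionFields]] = field(default_factory=list)
    theta: float = 0.0
    omega_necrotic: float = 0.05
    terminated: bool = False
    fixed_point_reached: bool = False

    @property
    def final_mask(self) -> np.ndarray:
        return self.rounds[-1][0]

    @property
    def final_solution(self) -> SolutionFields:
        return self.rounds[-1][1]

    @property
    def baseline_solution(self) -> SolutionFields:
        """The pre-necrosis solve (round 0, all tissue vital)."""
        return self.rounds[0][1]


def run_necrosis_iteration(
    scenario: Scenario,
    theta: float,
    active_mask: np.ndarray | None = None,
    omega_necrotic: float = 0.05,
    opts: SolverOptions | None = None,
) -> NecrosisTrace:
    """Iterate solve/mark/collapse to a fixed point.

    Each round solves the current fields, marks every active, not yet
    necrotic cell with ``j_omega < theta`` as newly necrotic, and sets
    their ``omega`` to ``omega_necrotic`` synchronously (the whole set at
    once).  Stops when a round marks nothing new, or after ``nx*ny``
    rounds.  ``active_mask`` restricts which cells may die (default: the
    whole grid); ``omega_necrotic`` must lie below the smallest active
    ``omega`` so that collapse is a genuine loss of conductivity.
    """
    if not theta > 0:
        raise InvalidArgumentError(f"theta must be positive, got {theta}")
    grid = scenario.grid
    if active_mask is None:
        active_mask = np.ones(grid.shape, dtype=bool)
    active_mask = np.asarray(active_mask, dtype=bool)
    if active_mask.shape != grid.shape:
        raise InvalidArgumentError(
            f"active_mask shape {active_mask.shape} does not match grid {grid.shape}"
        )
    if not active_mask.any():
        raise InvalidArgumentError("active_mask selects no cells")
    min_active_omega = float(scenario.fields.omega[active_mask].min())
    if not omega_necrotic < min_active_omega:
        raise InvalidArgumentError(
            f"omega_necrotic ({omega_necrotic}) must lie below the smallest "
            f"active omega ({min_active_omega})"
        )

    fields = scenario.fields.copy()
    necrotic = np.zeros(grid.shape, dtype=bool)
    trace = NecrosisTrace(theta=float(theta), omega_necrotic=float(omega_necrotic))
    round_cap = grid.nx * grid.ny
    for _ in range(round_cap):
        sol = solve_gauss_seidel(fields, grid, opts)
        trace.rounds.append((necrotic.copy(), sol))
        new = active_mask & ~necrotic & (sol.j_omega < theta)
        if not new.any():
            trace.fixed_point_reached = True
            break
        necrotic |= new
        fields.omega[new] = omega_necrotic
    trace.terminated = True
    return trace


def find_self_limiting_theta(
    scenario: Scenario,
    active_mask: np.ndarray | None = None,
    omega_necrotic: float = 0.05,
    opts: SolverOptions | None = None,
    n_candidates: int = 12,
) -> tuple[float, NecrosisTrace]:
    """Scan thresholds for a self-limiting necrotic fixed point.

    Candidate thresholds are spaced over the observed ``j_omega`` range of
    the vital solve within ``active_mask`` (endpoints excluded).  Returns
    the first (smallest) theta whose fixed point is non-empty and strictly
    smaller than the active set; raises if none exists in the scan.
    """
    grid = scenario.grid
    if active_mask is None:
        active_mask = np.ones(grid.shape, dtype=bool)
    baseline = solve_gauss_seidel(scenario.fields, grid, opts)
    jw = baseline.j_omega[active_mask]
    lo, hi = float(jw.min()), float(jw.max())
    candidates = np.linspace(lo, hi, n_candidates + 2)[1:-1]
    n_active = int(np.count_nonzero(active_mask))
    for theta in candidates:
        if not theta > 0:
            continue
        trace = run_necrosis_iteration(scenario, float(theta), active_mask, omega_necrotic, opts)
        n_dead = int(np.count_nonzero(trace.final_mask))
        if trace.fixed_point_reached and 0 < n_dead < n_active:
            return float(theta), trace
    raise InvalidArgumentError(
        "no self-limiting threshold found in the scanned j_omega range"
    )
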