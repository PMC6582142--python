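"""Scalar pattern metrics for solved perfusion fields.

The model's morphological predictions are verbal — an asymmetric
borderline trough (Aschoff's Reibungsform), a central watershed dip that
rounds toward a circle, a circumferential band under an isotropic plexus,
steal between neighbouring mucosae, contrast enhancement at a necrotic
margin.  This module pins each claim to a number so it can be tested.
Exact constructions (50%-recovery half-widths, sublevel-set circularity,
plateau medians) are this package's own operational definitions.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import GridSpec, InvalidArgumentError, SolutionFields

__all__ = [
    "UndefinedMetricError",
    "axial_profile",
    "reibungsform_asymmetry",
    "steal_index",
    "dip_depth",
    "circularity",
    "region_circularity",
    "circumferential_extent",
    "contrast_enhancement",
    "net_lateral_inflow",
]

#: 4-neighbour connectivity for sublevel components and perimeters.
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


class UndefinedMetricError(ValueError):
    """The metric is not defined for this input (e.g. monotone profile)."""


def axial_profile(sol: SolutionFields, row: int) -> np.ndarray:
    """Terminal flow along one circumferential row, ascending x.

    Returns an ``(nx, 2)`` array of ``(x, j_omega)`` pairs (x is the
    0-based axial cell index).
    """
    ny = sol.j_omega.shape[1]
    if not 0 <= row < ny:
        raise InvalidArgumentError(f"row {row} outside grid with ny={ny}")
    nx = sol.j_omega.shape[0]
    return np.column_stack([np.arange(nx, dtype=float), sol.j_omega[:, row]])


def _interior_minimum(values: np.ndarray, near: float | None = None) -> int:
    """Index of the interior minimum; raises on monotone profiles."""
    n = len(values)
    if n < 3:
        raise UndefinedMetricError("profile too short for an interior minimum")
    interior = values[1:-1]
    vmin = interior.min()
    if vmin >= min(values[0], values[-1]):
        raise UndefinedMetricError("profile has no interior minimum")
    candidates = np.flatnonzero(interior == vmin) + 1
    if near is not None:
        return int(candidates[np.argmin(np.abs(candidates - near))])
    return int(candidates[0])


def _half_width(x: np.ndarray, v: np.ndarray, m: int, recovery: float, direction: int) -> float:
    """Distance from minimum m to the 50%-recovery crossing, interpolated."""
    i = m
    while 0 <= i + direction < len(v):
        j = i + direction
        if v[j] >= recovery:
            # linear interpolation between cells i and j
            if v[j] == v[i]:
                frac = 0.0
            else:
                frac = (recovery - v[i]) / (v[j] - v[i])
            return abs(x[i] + frac * (x[j] - x[i]) - x[m])
        i = j
    raise UndefinedMetricError(
        "profile never recovers to the 50% level on the "
        + ("distal" if direction > 0 else "proximal")
        + " side"
    )


def reibungsform_asymmetry(
    profile: np.ndarray,
    boundary_x: int | None = None,
    plateau_cols: int = 10,
) -> float:
    """Distal/proximal half-width ratio of a flow trough.

    Locates the interior minimum (nearest ``boundary_x`` on ties, if
    given).  On each side the reference plateau is the median of the
    outermost ``plateau_cols`` values on that side, and the half-width is
    the interpolated distance from the minimum to the point where the
    profile recovers 50% of the way from the minimum to that plateau.
    A ratio > 1 is the Reibungsform orientation: steep proximal (corpus)
    edge, shallow distal tail.  The per-side reference makes the metric of
    a profile and of its mirror exact reciprocals.
    """
    profile = np.asarray(profile, dtype=float)
    x, v = profile[:, 0], profile[:, 1]
    m = _interior_minimum(v, near=boundary_x)
    k = min(plateau_cols, len(v))
    proximal_ref = float(np.median(v[:k]))
    distal_ref = float(np.median(v[-k:]))
    if proximal_ref <= v[m] or distal_ref <= v[m]:
        raise UndefinedMetricError("plateau does not rise above the trough minimum")
    hw_prox = _half_width(x, v, m, v[m] + 0.5 * (proximal_ref - v[m]), -1)
    hw_dist = _half_width(x, v, m, v[m] + 0.5 * (distal_ref - v[m]), +1)
    if hw_prox == 0:
        raise UndefinedMetricError("degenerate proximal half-width")
    return hw_dist / hw_prox


def steal_index(
    sol_test: SolutionFields, sol_baseline: SolutionFields, region: np.ndarray
) -> float:
    """Relative change of mean regional terminal flow against a baseline.

    ``(mean j_omega in test - mean in baseline) / mean in baseline`` over
    ``region``; negative = the region's flow was stolen.
    """
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise InvalidArgumentError("region selects no cells")
    base = float(sol_baseline.j_omega[region].mean())
    if base == 0:
        raise UndefinedMetricError("zero baseline mean flow in region")
    return (float(sol_test.j_omega[region].mean()) - base) / base


def dip_depth(
    sol: SolutionFields, centre_mask: np.ndarray, reference_mask: np.ndarray
) -> float:
    """Relative depth of the central flow dip, in [0, 1].

    ``1 - min(j_omega over centre) / mean(j_omega over reference)``,
    clipped to [0, 1]; 0 = no dip, 1 = complete flow collapse.
    """
    centre_mask = np.asarray(centre_mask, dtype=bool)
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if not centre_mask.any() or not reference_mask.any():
        raise InvalidArgumentError("masks must be non-empty")
    if (centre_mask & reference_mask).any():
        raise InvalidArgumentError("centre and reference masks must be disjoint")
    ref = float(sol.j_omega[reference_mask].mean())
    if ref == 0:
        raise UndefinedMetricError("zero mean flow in reference region")
    depth = 1.0 - float(sol.j_omega[centre_mask].min()) / ref
    return float(np.clip(depth, 0.0, 1.0))


def region_circularity(mask: np.ndarray) -> float:
    """``4*pi*A/P**2`` of a cell region (A = cells, P = boundary edges).

    1 would be a perfect continuum disc; rasterized shapes score lower
    (a single cell gives ``4*pi/16 ~ 0.785``, a large square ``pi/4``).
    """
    mask = np.asarray(mask, dtype=bool)
    area = int(mask.sum())
    if area == 0:
        raise UndefinedMetricError("empty region has no circularity")
    padded = np.pad(mask, 1)
    perim = int(
        (padded[1:, :] != padded[:-1, :]).sum() + (padded[:, 1:] != padded[:, :-1]).sum()
    )
    return 4.0 * np.pi * area / perim**2


def circularity(
    sol: SolutionFields, level_fraction: float, search_mask: np.ndarray
) -> float:
    """Circularity of the low-flow sublevel set.

    The threshold is ``min + level_fraction * (reference - min)`` of
    ``j_omega`` within ``search_mask``, where the reference level is the
    mask's median flow (a robust periphery value).  The largest
    4-connected component of the sublevel set is scored by
    :func:`region_circularity`.
    """
    if not 0 < level_fraction < 1:
        raise InvalidArgumentError(f"level_fraction must be in (0,1), got {level_fraction}")
    search_mask = np.asarray(search_mask, dtype=bool)
    if not search_mask.any():
        raise InvalidArgumentError("search_mask selects no cells")
    jw = sol.j_omega
    mn = float(jw[search_mask].min())
    ref = float(np.median(jw[search_mask]))
    threshold = mn + level_fraction * (ref - mn)
    sub = search_mask & (jw <= threshold)
    if not sub.any():
        raise UndefinedMetricError("empty sublevel set")
    labels, n = ndimage.label(sub, structure=_CROSS)
    if n == 0:
        raise UndefinedMetricError("empty sublevel set")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = labels == (1 + int(np.argmax(sizes)))
    return region_circularity(largest)


def circumferential_extent(
    sol: SolutionFields, depth_threshold: float, plateau_cols: int = 10
) -> float:
    """Fraction of circumferential rows carrying a flow trough.

    A row counts when its axial profile has an interior minimum lying
    deeper than ``depth_threshold`` below that row's distal plateau
    (median of the last ``plateau_cols`` columns) and below both row ends.
    1.0 = the trough rings the whole circumference (the linear-ulcer
    pattern); 0 = no trough anywhere.
    """
    jw = sol.j_omega
    nx, ny = jw.shape
    if nx < 3:
        return 0.0
    k = min(plateau_cols, nx)
    count = 0
    for j in range(ny):
        v = jw[:, j]
        vmin = v[1:-1].min()
        if vmin >= min(v[0], v[-1]):
            continue
        plateau = float(np.median(v[-k:]))
        if plateau - vmin > depth_threshold:
            count += 1
    return count / ny


def contrast_enhancement(
    sol_pre: SolutionFields, sol_post: SolutionFields, boundary_cells: np.ndarray
) -> float:
    """Post/pre ratio of the steepest terminal-flow gradient at a margin.

    The gradient magnitude of ``j_omega`` (central differences) is
    maximised over ``boundary_cells`` in both solutions; the ratio > 1
    means the margin sharpened.  Invariant under rescaling ``delta_p0``.
    """
    boundary_cells = np.asarray(boundary_cells, dtype=bool)
    if not boundary_cells.any():
        raise InvalidArgumentError("boundary_cells selects no cells")

    def max_grad(sol: SolutionFields) -> float:
        gx, gy = np.gradient(sol.j_omega)
        return float(np.hypot(gx, gy)[boundary_cells].max())

    pre = max_grad(sol_pre)
    if pre == 0:
        raise UndefinedMetricError("zero pre-necrosis gradient at the boundary")
    return max_grad(sol_post) / pre


def net_lateral_inflow(sol: SolutionFields, mask: np.ndarray, grid: GridSpec) -> float:
    """Summed collateral face flow across the mask boundary, oriented inward.

    Positive = the submucosal plexus feeds the region (vital watershed);
    negative = collateral flow dissipates away from it (necrotic centre).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InvalidArgumentError("mask selects no cells")
    nx, ny = grid.shape
    jx, jy = sol.j_lambda_x, sol.j_lambda_y
    total = 0.0
    if nx > 1:
        upper, lower = mask[1:], mask[:-1]  # cells i and i-1 of interior face i
        crossing = upper != lower
        sign = np.where(upper, 1.0, -1.0)  # +x flow enters the region holding cell i
        total += float((jx[1:nx] * sign * crossing).sum())
    if ny > 1:
        upper, lower = mask[:, 1:], mask[:, :-1]
        crossing = upper != lower
        sign = np.where(upper, 1.0, -1.0)
        total += float((jy[:, 1:ny] * sign * crossing).sum())
        if grid.periodic_y:
            upper, lower = mask[:, 0], mask[:, -1]  # wrap face between ny-1 and 0
            crossing = upper != lower
            sign = np.where(upper, 1.0, -1.0)
            total += float((jy[:, 0] * sign * crossing).sum())
    return total
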