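"""Finite-volume discretisation and solvers for the perfusion equation.

The stationary balance in each wall element reads

    alpha*(delta_p0 - p) - omega*p + d/dx[(1/lambda_x) dp/dx]
                                   + d/dy[(1/lambda_y) dp/dy] = 0.

Integrating over a cell of edge ``h`` gives, per cell,

    (alpha + omega + sum_g) * p - sum_g g * p_neighbour = alpha * delta_p0

with one conductance ``g`` per open face.  Under the default
``lower_index`` convention the face between cells ``(i, j)`` and
``(i+1, j)`` takes ``g = 1/(lambda_x[i, j] * h**2)``, i.e. the lateral
resistance is attributed to the lower-index cell; ``harmonic_mean`` uses
``g = 2/((lambda_x[i, j] + lambda_x[i+1, j]) * h**2)`` instead.  The
resulting matrix is a symmetric-in-structure M-matrix, diagonally dominant
(strictly wherever ``alpha + omega > 0``), so plain Gauss–Seidel and SOR
with relaxation in (0, 2) converge and the discrete maximum principle
``0 <= p <= delta_p0`` holds.

Two solution paths are provided: ``solve_gauss_seidel`` (fixed row-major
sweeps, the production path) and ``solve_direct`` (sparse LU, the exact
oracle used in tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve

from .core import (
    GridSpec,
    InvalidArgumentError,
    ParameterFields,
    SolutionFields,
    validate_fields,
)

__all__ = [
    "SolverOptions",
    "LinearSystem",
    "SingularSystemError",
    "assemble_system",
    "solve_direct",
    "solve_gauss_seidel",
    "compute_flows",
    "balance_residuals",
]


class SingularSystemError(RuntimeError):
    """A laterally connected component has no transmural pressure source."""


@dataclass(frozen=True)
class SolverOptions:
    """Iterative-solver controls.

    ``tolerance`` is relative to ``delta_p0``: iteration stops when the
    largest absolute per-sweep pressure update falls below
    ``tolerance * delta_p0``.  ``relaxation`` = 1 is plain Gauss–Seidel;
    values in (1, 2) give SOR.  ``face_convention`` selects how a face
    conductance is built from the two adjacent lateral resistances.
    """

    tolerance: float = 1e-10
    max_iterations: int = 200_000
    relaxation: float = 1.0
    face_convention: str = "lower_index"

    def __post_init__(self) -> None:
        if not self.tolerance > 0:
            raise InvalidArgumentError(f"tolerance must be positive, got {self.tolerance}")
        if self.max_iterations < 1:
            raise InvalidArgumentError("max_iterations must be >= 1")
        if not 0.0 < self.relaxation < 2.0:
            raise InvalidArgumentError(
                f"relaxation must lie in (0, 2), got {self.relaxation}"
            )
        if self.face_convention not in ("lower_index", "harmonic_mean"):
            raise InvalidArgumentError(f"unknown face_convention {self.face_convention!r}")


@dataclass
class LinearSystem:
    """Assembled finite-volume system.

    ``face_conductance_x`` has shape ``(nx+1, ny)``: entry ``[i, j]`` is
    the conductance of the face between cells ``(i-1, j)`` and ``(i, j)``;
    boundary faces (i = 0 and i = nx) are zero.  ``face_conductance_y`` has
    shape ``(nx, ny+1)``; under ``periodic_y`` both ``[:, 0]`` and
    ``[:, ny]`` hold the wrap-around face conductance.  ``diagonal`` is
    ``alpha + omega + sum of incident face conductances`` and ``source`` is
    ``alpha * delta_p0``.
    """

    diagonal: np.ndarray
    face_conductance_x: np.ndarray
    face_conductance_y: np.ndarray
    source: np.ndarray
    grid: GridSpec


def _face_conductances(
    fields: ParameterFields, grid: GridSpec, opts: SolverOptions
) -> tuple[np.ndarray, np.ndarray]:
    nx, ny = grid.shape
    h2 = grid.h * grid.h
    gx = np.zeros((nx + 1, ny))
    gy = np.zeros((nx, ny + 1))
    lx, ly = fields.lambda_x, fields.lambda_y
    if opts.face_convention == "lower_index":
        gx[1:nx] = 1.0 / (lx[:-1] * h2)
        gy[:, 1:ny] = 1.0 / (ly[:, :-1] * h2)
        if grid.periodic_y and ny > 1:
            wrap = 1.0 / (ly[:, -1] * h2)
            gy[:, 0] = wrap
            gy[:, ny] = wrap
    else:  # harmonic_mean
        gx[1:nx] = 2.0 / ((lx[:-1] + lx[1:]) * h2)
        gy[:, 1:ny] = 2.0 / ((ly[:, :-1] + ly[:, 1:]) * h2)
        if grid.periodic_y and ny > 1:
            wrap = 2.0 / ((ly[:, -1] + ly[:, 0]) * h2)
            gy[:, 0] = wrap
            gy[:, ny] = wrap
    return gx, gy


def assemble_system(
    fields: ParameterFields, grid: GridSpec, opts: SolverOptions | None = None
) -> LinearSystem:
    """Build diagonal, face conductances and source for valid fields."""
    opts = opts or SolverOptions()
    if fields.alpha.shape != grid.shape:
        raise InvalidArgumentError(
            f"field shape {fields.alpha.shape} does not match grid {grid.shape}"
        )
    gx, gy = _face_conductances(fields, grid, opts)
    # Each cell sees its four incident faces; under periodic_y the wrap face
    # enters cell j=0 through gy[:, 0] and cell j=ny-1 through gy[:, ny].
    diag = fields.alpha + fields.omega + gx[:-1] + gx[1:] + gy[:, :-1] + gy[:, 1:]
    source = fields.alpha * fields.delta_p0
    return LinearSystem(diag, gx, gy, source, grid)


def _as_sparse(system: LinearSystem) -> csr_matrix:
    nx, ny = system.grid.shape
    idx = np.arange(nx * ny).reshape(nx, ny)
    rows, cols, vals = [], [], []

    rows.append(idx.ravel())
    cols.append(idx.ravel())
    vals.append(system.diagonal.ravel())

    gx, gy = system.face_conductance_x, system.face_conductance_y
    if nx > 1:
        g = gx[1:nx]  # faces between (i-1) and (i)
        rows.append(idx[1:].ravel()), cols.append(idx[:-1].ravel()), vals.append(-g.ravel())
        rows.append(idx[:-1].ravel()), cols.append(idx[1:].ravel()), vals.append(-g.ravel())
    if ny > 1:
        g = gy[:, 1:ny]
        rows.append(idx[:, 1:].ravel()), cols.append(idx[:, :-1].ravel()), vals.append(-g.ravel())
        rows.append(idx[:, :-1].ravel()), cols.append(idx[:, 1:].ravel()), vals.append(-g.ravel())
        if system.grid.periodic_y:
            g = gy[:, 0]
            rows.append(idx[:, 0]), cols.append(idx[:, -1]), vals.append(-g)
            rows.append(idx[:, -1]), cols.append(idx[:, 0]), vals.append(-g)
    return csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(nx * ny, nx * ny),
    )


def solve_direct(system: LinearSystem) -> np.ndarray:
    """Exact sparse solve of the assembled system (test oracle).

    Every laterally connected component must contain at least one cell with
    a transmural source (``alpha > 0``); a sourceless component is reported
    as :class:`SingularSystemError` naming one of its cells.
    """
    nx, ny = system.grid.shape
    matrix = _as_sparse(system)
    adjacency = matrix.copy()
    adjacency.setdiag(0)
    adjacency.eliminate_zeros()
    n_comp, labels = connected_components(np.abs(adjacency), directed=False)
    src = system.source.ravel() > 0
    for comp in range(n_comp):
        members = labels == comp
        if not src[members].any():
            cell = int(np.flatnonzero(members)[0])
            raise SingularSystemError(
                f"no transmural source (alpha > 0) in the component of cell "
                f"({cell // ny}, {cell % ny})"
            )
    p = spsolve(matrix.tocsc(), system.source.ravel())
    return np.asarray(p).reshape(nx, ny)


@njit(cache=True)
def _gs_iterate(p, diag, gx, gy, source, relax, tol, max_sweeps, periodic_y):
    nx, ny = p.shape
    sweeps = 0
    delta = 0.0
    while sweeps < max_sweeps:
        delta = 0.0
        for i in range(nx):
            for j in range(ny):
                acc = source[i, j]
                if i > 0:
                    acc += gx[i, j] * p[i - 1, j]
                if i < nx - 1:
                    acc += gx[i + 1, j] * p[i + 1, j]
                if j > 0:
                    acc += gy[i, j] * p[i, j - 1]
                elif periodic_y and ny > 1:
                    acc += gy[i, 0] * p[i, ny - 1]
                if j < ny - 1:
                    acc += gy[i, j + 1] * p[i, j + 1]
                elif periodic_y and ny > 1:
                    acc += gy[i, ny] * p[i, 0]
                new = (1.0 - relax) * p[i, j] + relax * acc / diag[i, j]
                d = abs(new - p[i, j])
                if d > delta:
                    delta = d
                p[i, j] = new
        sweeps += 1
        if delta <= tol:
            return sweeps, delta, True
    return sweeps, delta, False


def initial_guess(fields: ParameterFields) -> np.ndarray:
    """Cellwise closed form ``alpha*delta_p0/(alpha+omega)`` (0/0 -> 0).

    Exact for homogeneous fields with no-flux boundaries (zero lateral
    terms), and a maximum-principle-respecting start in general.
    """
    denom = fields.alpha + fields.omega
    with np.errstate(divide="ignore", invalid="ignore"):
        p0 = np.where(denom > 0, fields.alpha * fields.delta_p0 / denom, 0.0)
    return p0


def solve_gauss_seidel(
    fields: ParameterFields,
    grid: GridSpec,
    opts: SolverOptions | None = None,
    progress=None,
) -> SolutionFields:
    """Gauss–Seidel/SOR solution with derived flows and residual audit.

    Sweeps cells in fixed row-major ascending order (x outer, y inner),
    applying ``p <- (1-w)p + w*(source + sum_g g*p_nb)/diag``; stops when
    the largest absolute update of a sweep is at most
    ``tolerance * delta_p0`` or ``max_iterations`` sweeps have run (the
    ``converged`` flag records which).  ``progress``, if given, is called
    as ``progress(sweeps_done, max_update)`` every 100 sweeps.
    """
    opts = opts or SolverOptions()
    violations = validate_fields(fields, grid)
    if violations:
        raise InvalidArgumentError("invalid fields: " + "; ".join(violations))
    system = assemble_system(fields, grid, opts)
    p = initial_guess(fields)
    tol = opts.tolerance * fields.delta_p0
    block = 100 if progress is not None else opts.max_iterations
    total = 0
    converged = False
    delta = np.inf
    while total < opts.max_iterations and not converged:
        sweeps = min(block, opts.max_iterations - total)
        done, delta, converged = _gs_iterate(
            p,
            system.diagonal,
            system.face_conductance_x,
            system.face_conductance_y,
            system.source,
            opts.relaxation,
            tol,
            sweeps,
            grid.periodic_y,
        )
        total += done
        if progress is not None:
            progress(total, delta)
    j_alpha, j_omega, j_lx, j_ly = compute_flows(p, fields, grid, opts)
    sol = SolutionFields(p, j_alpha, j_omega, j_lx, j_ly, total, converged, 0.0)
    residuals, _ = balance_residuals(sol, fields, grid)
    sol.max_residual = float(np.abs(residuals).max())
    return sol


def compute_flows(
    p: np.ndarray,
    fields: ParameterFields,
    grid: GridSpec,
    opts: SolverOptions | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Transmural, terminal and face-centred lateral flow densities.

    ``j_alpha = alpha*(delta_p0 - p)``; ``j_omega = omega*p``; the lateral
    flow across a face is ``g*(p_lower - p_upper)``, positive in the +x
    (+y) direction.  No-flux boundary faces are exactly zero.
    """
    opts = opts or SolverOptions()
    if p.shape != grid.shape:
        raise InvalidArgumentError(f"pressure shape {p.shape} does not match grid {grid.shape}")
    gx, gy = _face_conductances(fields, grid, opts)
    j_alpha = fields.alpha * (fields.delta_p0 - p)
    j_omega = fields.omega * p
    j_lx = np.zeros_like(gx)
    j_ly = np.zeros_like(gy)
    nx, ny = grid.shape
    if nx > 1:
        j_lx[1:nx] = gx[1:nx] * (p[:-1] - p[1:])
    if ny > 1:
        j_ly[:, 1:ny] = gy[:, 1:ny] * (p[:, :-1] - p[:, 1:])
        if grid.periodic_y:
            wrap = gy[:, 0] * (p[:, -1] - p[:, 0])
            j_ly[:, 0] = wrap
            j_ly[:, ny] = wrap
    return j_alpha, j_omega, j_lx, j_ly


def balance_residuals(
    sol: SolutionFields, fields: ParameterFields, grid: GridSpec
) -> tuple[np.ndarray, float]:
    """Kirchhoff audit: per-cell flow imbalance and global conservation.

    Per cell: ``residual = j_alpha - j_omega - net lateral outflow`` (face
    flows carry the 1/h^2 metric, see module docstring); at a solution it
    vanishes.  The global imbalance ``|sum j_alpha - sum j_omega| * h^2``
    must vanish under no-flux boundaries, where face flows telescope.
    """
    j_lx, j_ly = sol.j_lambda_x, sol.j_lambda_y
    div = (j_lx[1:] - j_lx[:-1]) + (j_ly[:, 1:] - j_ly[:, :-1])
    residual = sol.j_alpha - sol.j_omega - div
    imbalance = abs(float(sol.j_alpha.sum() - sol.j_omega.sum())) * grid.h * grid.h
    return residual, imbalance
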