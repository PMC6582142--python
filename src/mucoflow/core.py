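"""Grid, parameter and solution containers for the submucosal perfusion model.

The intestinal wall is idealised as a two-dimensional resistor network: a
submucosal arterial plane lying between a transmural influx compartment
(arteries perforating the muscle layer, conductivity ``alpha`` per unit
area) and a terminal outflow compartment (mucosa plus the retrogradely
supplied part of the muscle layer, conductivity ``omega`` per unit area).
Lateral collateral flow within the submucosal plane is governed by
direction-dependent resistances ``lambda_x`` (axial, oral→aboral) and
``lambda_y`` (circumferential).  The systemic perfusion-pressure gradient
``delta_p0`` drives the whole network; the unknown is the local submucosal
perfusion pressure ``p(x, y)`` with ``0 <= p <= delta_p0``.

All quantities are dimensionless model units (cell edge ``h = 1`` and
``delta_p0 = 1`` by default); only relative flow patterns are meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GAS_CONSTANT",
    "BODY_TEMPERATURE_K",
    "GridSpec",
    "ParameterFields",
    "SolutionFields",
    "InvalidArgumentError",
    "validate_fields",
    "free_energy_of_secretion",
]

#: Molar gas constant, J mol^-1 K^-1.
GAS_CONSTANT = 8.314

#: Default temperature for the free-energy estimate (body temperature), K.
BODY_TEMPERATURE_K = 310.0


class InvalidArgumentError(ValueError):
    """Raised when an argument violates a documented precondition."""


@dataclass(frozen=True)
class GridSpec:
    """Rectangular cell grid covering a patch of intestinal wall.

    ``x`` (first array axis, ``nx`` cells) is the axial, oral→aboral
    direction; ``y`` (second axis, ``ny`` cells) is the circumferential
    direction.  ``boundary_mode`` is ``"no_flux"`` (isolated patch) or
    ``"periodic_y"`` (the circumference closes on itself; x edges stay
    no-flux).
    """

    nx: int
    ny: int
    h: float = 1.0
    boundary_mode: str = "no_flux"

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise InvalidArgumentError(f"grid must have nx, ny >= 1, got {self.nx}x{self.ny}")
        if not self.h > 0:
            raise InvalidArgumentError(f"cell edge h must be positive, got {self.h}")
        if self.boundary_mode not in ("no_flux", "periodic_y"):
            raise InvalidArgumentError(f"unknown boundary_mode {self.boundary_mode!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nx, self.ny)

    @property
    def periodic_y(self) -> bool:
        return self.boundary_mode == "periodic_y"


@dataclass
class ParameterFields:
    """Conductivity/resistance fields plus the systemic pressure gradient.

    alpha, omega, lambda_x, lambda_y are ``(nx, ny)`` arrays; ``delta_p0``
    is the scalar systemic arterial perfusion-pressure gradient.
    """

    alpha: np.ndarray
    omega: np.ndarray
    lambda_x: np.ndarray
    lambda_y: np.ndarray
    delta_p0: float = 1.0

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        self.lambda_x = np.asarray(self.lambda_x, dtype=float)
        self.lambda_y = np.asarray(self.lambda_y, dtype=float)
        self.delta_p0 = float(self.delta_p0)

    @classmethod
    def uniform(
        cls,
        grid: GridSpec,
        alpha: float,
        omega: float,
        lambda_x: float,
        lambda_y: float | None = None,
        delta_p0: float = 1.0,
    ) -> "ParameterFields":
        """Spatially homogeneous fields (``lambda_y`` defaults to ``lambda_x``)."""
        if lambda_y is None:
            lambda_y = lambda_x
        full = lambda v: np.full(grid.shape, float(v))
        return cls(full(alpha), full(omega), full(lambda_x), full(lambda_y), delta_p0)

    def copy(self) -> "ParameterFields":
        return ParameterFields(
            self.alpha.copy(),
            self.omega.copy(),
            self.lambda_x.copy(),
            self.lambda_y.copy(),
            self.delta_p0,
        )

    def mirror_x(self) -> "ParameterFields":
        """Fields mirrored along the axial direction."""
        return ParameterFields(
            self.alpha[::-1].copy(),
            self.omega[::-1].copy(),
            self.lambda_x[::-1].copy(),
            self.lambda_y[::-1].copy(),
            self.delta_p0,
        )


@dataclass
class SolutionFields:
    """Solved pressure field and the flow fields derived from it.

    ``p`` is cell-centred ``(nx, ny)``.  ``j_alpha = alpha*(delta_p0 - p)``
    and ``j_omega = omega*p`` are cell-centred flow densities.  Lateral
    flows are face-centred: ``j_lambda_x`` has shape ``(nx+1, ny)`` (face i
    sits between cells i-1 and i; positive = flow in +x), ``j_lambda_y``
    has shape ``(nx, ny+1)``; under ``periodic_y`` the first and last y
    faces both carry the wrap-around face flow.  No-flux boundary faces are
    exactly zero.
    """

    p: np.ndarray
    j_alpha: np.ndarray
    j_omega: np.ndarray
    j_lambda_x: np.ndarray
    j_lambda_y: np.ndarray
    iterations: int = 0
    converged: bool = True
    max_residual: float = 0.0


def validate_fields(fields: ParameterFields, grid: GridSpec) -> list[str]:
    """Check parameter-field invariants; return one descriptor per violation.

    Violations are data, not exceptions: an empty list means the fields are
    well formed.  Checks shapes, sign constraints (alpha, omega >= 0;
    lambda_x, lambda_y > 0; delta_p0 > 0) and that at least one cell has
    alpha > 0 (otherwise the network has no pressure source).
    """
    violations: list[str] = []
    shape = grid.shape
    for name in ("alpha", "omega", "lambda_x", "lambda_y"):
        arr = getattr(fields, name)
        if arr.shape != shape:
            violations.append(f"{name}: shape {arr.shape} does not match grid {shape}")
    if violations:
        return violations  # elementwise checks need matching shapes

    for name in ("alpha", "omega"):
        arr = getattr(fields, name)
        bad = np.argwhere(~(arr >= 0))
        if bad.size:
            i, j = bad[0]
            violations.append(f"{name}: negative conductivity at cell ({i}, {j})")
    for name in ("lambda_x", "lambda_y"):
        arr = getattr(fields, name)
        bad = np.argwhere(~(arr > 0))
        if bad.size:
            i, j = bad[0]
            violations.append(f"{name}: non-positive resistance at cell ({i}, {j})")
    if not fields.delta_p0 > 0:
        violations.append(f"delta_p0: must be positive, got {fields.delta_p0}")
    if not np.any(fields.alpha > 0):
        violations.append("alpha: no pressure source (alpha is zero everywhere)")
    return violations


def free_energy_of_secretion(
    ph_lumen: float,
    ph_plasma: float = 7.4,
    temperature: float = BODY_TEMPERATURE_K,
) -> float:
    """Free-energy change for secreting one mole of H+ against a pH gradient.

    Returns ``R*T*ln(10^-ph_lumen / 10^-ph_plasma) / 1000`` in kJ/mol,
    positive when the lumen is more acidic than plasma.  At pH 1 vs 7.4 and
    310 K this is ~38 kJ/mol — the energetic cost that makes the
    acid-secreting mucosa the metabolically demanding compartment of the
    model.
    """
    if not temperature > 0:
        raise InvalidArgumentError(f"temperature must be positive Kelvin, got {temperature}")
    return GAS_CONSTANT * temperature * math.log(10.0) * (ph_plasma - ph_lumen) / 1000.0
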