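"""Configuration files, solution writers and run manifests.

Formats: TOML configs, tab-separated numeric matrices (row = y index
ascending, column = x index ascending, so a printed file matches the
figures' orientation with x running left to right), JSON manifests.
Deterministic runs produce byte-identical matrix files.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from . import __version__
from .core import GridSpec, ParameterFields, SolutionFields, validate_fields
from .scenarios import (
    Scenario,
    scenario_antrum_borderline,
    scenario_cardia,
    scenario_homogeneous,
    scenario_linear_ulcer,
    scenario_necrosis,
    scenario_watershed,
)
from .solver import SolverOptions

__all__ = [
    "ConfigError",
    "RunManifest",
    "SCENARIO_BUILDERS",
    "build_scenario",
    "read_config",
    "write_solution",
    "read_solution",
]


class ConfigError(ValueError):
    """Malformed configuration: names the offending key or file."""


def _watershed_from_overrides(overrides: dict | None = None) -> Scenario:
    overrides = dict(overrides or {})
    omega_level = overrides.pop("omega_level", 10.0)
    return scenario_watershed(float(omega_level), overrides or None)


SCENARIO_BUILDERS = {
    "antrum-borderline": scenario_antrum_borderline,
    "cardia": scenario_cardia,
    "linear-ulcer": scenario_linear_ulcer,
    "watershed": _watershed_from_overrides,
    "necrosis-pre": lambda overrides=None: scenario_necrosis("pre", overrides),
    "necrosis-post": lambda overrides=None: scenario_necrosis("post", overrides),
    "homogeneous": scenario_homogeneous,
}


def build_scenario(name: str, overrides: dict | None = None) -> Scenario:
    """Build a named scenario, forwarding constant overrides."""
    try:
        builder = SCENARIO_BUILDERS[name]
    except KeyError:
        raise ConfigError(
            f"unknown scenario {name!r}; known: {sorted(SCENARIO_BUILDERS)}"
        ) from None
    return builder(overrides)


@dataclass
class RunManifest:
    """Machine-readable record of one solver run."""

    scenario: str
    constants: dict = field(default_factory=dict)
    solver: dict = field(default_factory=dict)
    iterations: int = 0
    converged: bool = True
    max_residual: float = 0.0
    global_imbalance: float = 0.0
    metrics: dict = field(default_factory=dict)
    version: str = __version__
    seed: int | None = None
    timestamp: str = ""

    @classmethod
    def for_run(
        cls,
        scenario: Scenario,
        sol: SolutionFields,
        opts: SolverOptions,
        global_imbalance: float,
        metrics: dict | None = None,
        seed: int | None = None,
    ) -> "RunManifest":
        constants = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in scenario.metadata.items()
        }
        return cls(
            scenario=scenario.name,
            constants=constants,
            solver=asdict(opts),
            iterations=sol.iterations,
            converged=sol.converged,
            max_residual=sol.max_residual,
            global_imbalance=global_imbalance,
            metrics=dict(metrics or {}),
            seed=seed,
            timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def read(cls, path: Path) -> "RunManifest":
        return cls(**json.loads(path.read_text()))


_SOLUTION_FILES = {
    "p": "p.tsv",
    "j_alpha": "j_alpha.tsv",
    "j_omega": "j_omega.tsv",
    "j_lambda_x": "j_lambda_x.tsv",
    "j_lambda_y": "j_lambda_y.tsv",
}


def _write_matrix(path: Path, grid_xy: np.ndarray) -> None:
    # stored row = y, column = x; %r-style repr keeps full double precision
    np.savetxt(path, np.asarray(grid_xy).T, fmt="%.17g", delimiter="\t")


def _read_matrix(path: Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter="\t")).T


def write_solution(
    sol: SolutionFields,
    fields: ParameterFields,
    outdir: str | Path,
    manifest: RunManifest | None = None,
) -> list[Path]:
    """Write the five flow matrices plus ``manifest.json`` to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for attr, fname in _SOLUTION_FILES.items():
        path = outdir / fname
        _write_matrix(path, getattr(sol, attr))
        written.append(path)
    if manifest is None:
        manifest = RunManifest(
            scenario="unnamed",
            iterations=sol.iterations,
            converged=sol.converged,
            max_residual=sol.max_residual,
            timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )
    mpath = outdir / "manifest.json"
    manifest.write(mpath)
    written.append(mpath)
    return written


def read_solution(outdir: str | Path) -> tuple[SolutionFields, RunManifest]:
    """Read back a solution directory written by :func:`write_solution`."""
    outdir = Path(outdir)
    arrays = {attr: _read_matrix(outdir / fname) for attr, fname in _SOLUTION_FILES.items()}
    manifest = RunManifest.read(outdir / "manifest.json")
    sol = SolutionFields(
        arrays["p"],
        arrays["j_alpha"],
        arrays["j_omega"],
        arrays["j_lambda_x"],
        arrays["j_lambda_y"],
        iterations=manifest.iterations,
        converged=manifest.converged,
        max_residual=manifest.max_residual,
    )
    return sol, manifest


_SOLVER_KEYS = {"tolerance", "max_iterations", "relaxation", "face_convention"}
_GRID_KEYS = {"nx", "ny", "h", "boundary_mode"}
_FIELD_KEYS = {"alpha", "omega", "lambda_x", "lambda_y", "delta_p0"}


def _solver_options(table: dict) -> SolverOptions:
    unknown = set(table) - _SOLVER_KEYS
    if unknown:
        raise ConfigError(f"unknown [solver] key(s): {sorted(unknown)}")
    return SolverOptions(**table)


def _load_field(value, grid: GridSpec, base: Path, key: str) -> np.ndarray:
    if isinstance(value, (int, float)):
        return np.full(grid.shape, float(value))
    if isinstance(value, str):
        path = base / value
        if not path.exists():
            raise ConfigError(f"[fields] {key}: matrix file {path} does not exist")
        arr = _read_matrix(path)
        if arr.shape != grid.shape:
            raise ConfigError(
                f"[fields] {key}: matrix shape {arr.shape} does not match grid {grid.shape}"
            )
        return arr
    raise ConfigError(f"[fields] {key}: expected a number or a TSV path, got {type(value).__name__}")


def read_config(path: str | Path) -> tuple[Scenario, SolverOptions]:
    """Parse a TOML run configuration.

    Two forms are accepted.  Named scenario::

        [scenario]
        name = "antrum-borderline"
        [scenario.overrides]
        omega_corpus = 1.0
        [solver]
        tolerance = 1e-12

    Custom fields (constants per field, or paths to TSV matrices relative
    to the config file)::

        [grid]
        nx = 20
        ny = 20
        [fields]
        alpha = 0.1
        omega = "omega.tsv"
        lambda_x = 0.382
        lambda_y = 0.382
        delta_p0 = 1.0

    Unknown keys are rejected; omitted solver keys take their defaults.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} does not exist")
    try:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"{path}: TOML parse error: {exc}") from exc

    unknown = set(data) - {"scenario", "solver", "grid", "fields"}
    if unknown:
        raise ConfigError(f"unknown top-level table(s): {sorted(unknown)}")
    opts = _solver_options(data.get("solver", {}))

    if "scenario" in data:
        if "grid" in data or "fields" in data:
            raise ConfigError("give either [scenario] or [grid]+[fields], not both")
        table = dict(data["scenario"])
        name = table.pop("name", None)
        if name is None:
            raise ConfigError("[scenario] requires a 'name' key")
        overrides = table.pop("overrides", None)
        if table:
            raise ConfigError(f"unknown [scenario] key(s): {sorted(table)}")
        scenario = build_scenario(name, overrides)
        return scenario, opts

    if "grid" not in data or "fields" not in data:
        raise ConfigError("config requires [scenario], or both [grid] and [fields]")
    gtable = dict(data["grid"])
    unknown = set(gtable) - _GRID_KEYS
    if unknown:
        raise ConfigError(f"unknown [grid] key(s): {sorted(unknown)}")
    grid = GridSpec(**gtable)
    ftable = dict(data["fields"])
    unknown = set(ftable) - _FIELD_KEYS
    if unknown:
        raise ConfigError(f"unknown [fields] key(s): {sorted(unknown)}")
    missing = _FIELD_KEYS - {"delta_p0"} - set(ftable)
    if missing:
        raise ConfigError(f"missing [fields] key(s): {sorted(missing)}")
    base = path.parent
    fields = ParameterFields(
        _load_field(ftable["alpha"], grid, base, "alpha"),
        _load_field(ftable["omega"], grid, base, "omega"),
        _load_field(ftable["lambda_x"], grid, base, "lambda_x"),
        _load_field(ftable["lambda_y"], grid, base, "lambda_y"),
        float(ftable.get("delta_p0", 1.0)),
    )
    violations = validate_fields(fields, grid)
    if violations:
        raise ConfigError(f"{path}: invalid fields: " + "; ".join(violations))
    masks = {"all": np.ones(grid.shape, dtype=bool)}
    scenario = Scenario(path.stem, grid, fields, masks, {"config": str(path)})
    return scenario, opts
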