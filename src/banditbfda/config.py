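"""Run configuration: schema, defaults, validation, and small test fixtures.

A run configuration is a plain YAML/JSON mapping.  Unknown keys are
rejected, every simulation command requires a root seed, and all defaults
(learning rate 0.1, population SD 0.02, tau grid [0.01, 3] step 0.01,
uniform priors, arm probabilities {0.1, 0.3, 0.9}) are resolved at load
time so the echoed config is self-contained and hashable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .bfda import BFDACondition
from .errors import ConfigurationError
from .likelihood import TauGrid
from .task import TaskSpec

__all__ = ["RunConfig", "load_config", "fixture_small_task", "config_hash"]

_TASK_KEYS = {"probabilities", "n_forced", "forced_allocation", "n_free", "include_equal_pairs"}
_TOP_KEYS = {
    "seed",
    "task",
    "alpha",
    "sigma",
    "grid",
    "delta_prior_bounds",
    "hpdi_level",
    "conditions",
    "sweep",
    "n_sims",
    "output_dir",
}
_GRID_KEYS = {"lo", "hi", "step"}
_CONDITION_KEYS = {"delta_mu", "n_per_group", "n_games", "n_sims", "seed"}
_SWEEP_KEYS = {"n_values", "delta_values", "n_games_values", "delta_mu", "n_games"}


@dataclass
class RunConfig:
    """Fully resolved configuration for a run."""

    seed: int
    task: TaskSpec = field(default_factory=TaskSpec)
    alpha: float = 0.1
    sigma: float = 0.02
    grid: dict = field(default_factory=lambda: {"lo": 0.01, "hi": 3.0, "step": 0.01})
    delta_prior_bounds: tuple[float, float] = (-3.0, 3.0)
    hpdi_level: float = 0.95
    n_sims: int = 250
    conditions: list[dict] = field(default_factory=list)
    sweep: dict | None = None
    output_dir: str = "."

    def tau_grid(self) -> TauGrid:
        return TauGrid.default(**self.grid)

    def build_conditions(self) -> list[BFDACondition]:
        """Materialize the listed conditions with all defaults applied."""
        out = []
        for i, c in enumerate(self.conditions):
            out.append(
                BFDACondition(
                    delta_mu=float(c["delta_mu"]),
                    n_per_group=int(c["n_per_group"]),
                    n_games=int(c["n_games"]),
                    n_sims=int(c.get("n_sims", self.n_sims)),
                    seed=int(c.get("seed", self.seed + i)),
                    task=self.task,
                    alpha=self.alpha,
                    sigma=self.sigma,
                    tau_grid=self.tau_grid(),
                    delta_prior_bounds=self.delta_prior_bounds,
                    hpdi_level=self.hpdi_level,
                )
            )
        return out

    def to_dict(self) -> dict:
        d = asdict(self)
        d["task"] = {
            "probabilities": list(self.task.probabilities),
            "n_forced": self.task.n_forced,
            "forced_allocation": list(self.task.forced_allocation),
            "n_free": self.task.n_free,
            "include_equal_pairs": self.task.include_equal_pairs,
        }
        d["delta_prior_bounds"] = list(self.delta_prior_bounds)
        return d


def _check_keys(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigurationError(f"unknown keys in {where}: {sorted(unknown)}")


def parse_config(raw: dict) -> RunConfig:
    """Validate a raw mapping and resolve all defaults."""
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")
    if "seed" not in raw:
        raise ConfigurationError("missing required key: seed")
    task_raw = raw.get("task", {})
    _check_keys(task_raw, _TASK_KEYS, "task")
    task_kwargs = dict(task_raw)
    for key in ("probabilities", "forced_allocation"):
        if key in task_kwargs:
            task_kwargs[key] = tuple(task_kwargs[key])
    grid = dict(raw.get("grid", {}))
    _check_keys(grid, _GRID_KEYS, "grid")
    grid = {"lo": 0.01, "hi": 3.0, "step": 0.01} | grid
    for i, c in enumerate(raw.get("conditions", [])):
        _check_keys(c, _CONDITION_KEYS, f"conditions[{i}]")
        missing = {"delta_mu", "n_per_group", "n_games"} - set(c)
        if missing:
            raise ConfigurationError(f"conditions[{i}] missing keys: {sorted(missing)}")
    if raw.get("sweep") is not None:
        _check_keys(raw["sweep"], _SWEEP_KEYS, "sweep")
    return RunConfig(
        seed=int(raw["seed"]),
        task=TaskSpec(**task_kwargs),
        alpha=float(raw.get("alpha", 0.1)),
        sigma=float(raw.get("sigma", 0.02)),
        grid=grid,
        delta_prior_bounds=tuple(raw.get("delta_prior_bounds", (-3.0, 3.0))),
        hpdi_level=float(raw.get("hpdi_level", 0.95)),
        n_sims=int(raw.get("n_sims", 250)),
        conditions=list(raw.get("conditions", [])),
        sweep=raw.get("sweep"),
        output_dir=str(raw.get("output_dir", ".")),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    text = path.read_text()
    try:
        raw = yaml.safe_load(text)  # YAML is a superset of JSON
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    return parse_config(raw)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the fully resolved configuration."""
    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def fixture_small_task() -> TaskSpec:
    """Reduced horizon task (2 forced + 2 free trials, 16 paths).

    Small enough that the exact PMF can be enumerated by hand, which makes
    it the reference fixture for oracle tests.
    """
    return TaskSpec(n_forced=2, forced_allocation=(1, 2), n_free=2)
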