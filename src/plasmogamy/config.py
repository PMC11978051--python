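"""Run configuration: YAML loading, fail-fast validation, serialization.

A run configuration fully determines an experiment: survival family,
ecological parameters (E, T, C), the environment schedule, mutation
parameters, initial traits, cycle budget and the mandatory random seed.
Unknown keys are rejected and every invalid field is reported (not just
the first), so a bad configuration fails before any computation starts.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .lifecycle import Genotype, ModelParams, PlasticGenotype
from .evosim import MutationParams
from .survival import Environment, EnvironmentSchedule, SurvivalModel

__all__ = ["RunConfig", "ConfigError", "load_config", "serialize_config"]

EXPERIMENT_KINDS = ("simulate", "gradient_field", "flow", "fixed_points",
                    "cbase", "separatrix", "regimes")


class ConfigError(ValueError):
    """Raised with a list of every offending configuration field."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(problems))


@dataclass(frozen=True)
class RunConfig:
    """Validated experiment description (see module docstring)."""

    experiment: str
    seed: int
    survival_family: str = "vance"
    m_min: float = 0.0
    E: float = 100.0
    T: float = 1.0
    C: float = 0.0
    schedule_mode: str = "fixed"
    harshness: tuple[float, ...] = (1.0,)
    switch_cycles: tuple[int, ...] = ()
    lambda_12: float = 0.0
    lambda_21: float = 0.0
    initial_m: float = 1.0
    initial_alpha: float = 0.0
    plastic: bool = False
    pin_alpha: bool = False
    n_cycles: int = 10_000
    record_every: int = 1
    mu: float = 0.01
    delta_m: float = 0.02
    delta_alpha: float = 0.02
    prune_threshold: float = 1e-6
    m_floor: float = 1e-3
    seed_frequency: float = 1e-3
    p1: float = 0.5
    out_prefix: str = "run"

    # ---- structured views -------------------------------------------------
    def model_params(self) -> ModelParams:
        return ModelParams(E=self.E, T=self.T, C=self.C)

    def survival_model(self) -> SurvivalModel:
        return SurvivalModel(family=self.survival_family, m_min=self.m_min)

    def mutation_params(self) -> MutationParams:
        return MutationParams(mu=self.mu, delta_m=self.delta_m,
                              delta_alpha=self.delta_alpha,
                              prune_threshold=self.prune_threshold,
                              m_floor=self.m_floor,
                              seed_frequency=self.seed_frequency)

    def environments(self) -> tuple[Environment, ...]:
        return tuple(Environment(h, label=f"env{i + 1}")
                     for i, h in enumerate(self.harshness))

    def schedule(self) -> EnvironmentSchedule:
        envs = self.environments()
        if self.schedule_mode == "fixed":
            return EnvironmentSchedule.fixed(envs[0])
        if self.schedule_mode == "scheduled":
            return EnvironmentSchedule.scheduled(envs[0], envs[1],
                                                 self.switch_cycles)
        return EnvironmentSchedule.telegraph(envs[0], envs[1],
                                             self.lambda_12, self.lambda_21)

    def initial_genotype(self):
        if self.plastic:
            return PlasticGenotype(m1=self.initial_m, alpha1=self.initial_alpha,
                                   m2=self.initial_m, alpha2=self.initial_alpha)
        return Genotype(m=self.initial_m, alpha=self.initial_alpha)


def _validate(raw: dict[str, Any]) -> RunConfig:
    problems: list[str] = []
    known = {f.name for f in fields(RunConfig)}
    for key in raw:
        if key not in known:
            problems.append(f"unknown key {key!r}")
    if "experiment" not in raw:
        problems.append("missing required key 'experiment'")
    elif raw["experiment"] not in EXPERIMENT_KINDS:
        problems.append(
            f"experiment must be one of {EXPERIMENT_KINDS}, got {raw['experiment']!r}")
    if "seed" not in raw:
        problems.append("missing required key 'seed' (seeds are mandatory, "
                        "never auto-generated)")
    elif not isinstance(raw["seed"], int):
        problems.append(f"seed must be an integer, got {raw['seed']!r}")

    def check(name, ok, msg):
        if name in raw and not ok(raw[name]):
            problems.append(f"{name}: {msg} (got {raw[name]!r})")

    num = (int, float)
    check("E", lambda v: isinstance(v, num) and v > 0, "must be > 0")
    check("T", lambda v: isinstance(v, num) and v >= 0, "must be >= 0")
    check("C", lambda v: isinstance(v, num) and 0 <= v <= 1, "must lie in [0, 1]")
    check("survival_family", lambda v: v in ("vance", "threshold_linear"),
          "must be 'vance' or 'threshold_linear'")
    check("m_min", lambda v: isinstance(v, num) and v >= 0, "must be >= 0")
    check("schedule_mode", lambda v: v in ("fixed", "scheduled", "telegraph"),
          "must be fixed|scheduled|telegraph")
    check("harshness", lambda v: isinstance(v, (list, tuple)) and
          all(isinstance(h, num) and h > 0 for h in v) and 1 <= len(v) <= 2,
          "must be a list of 1-2 positive numbers")
    check("switch_cycles", lambda v: isinstance(v, (list, tuple)) and
          all(isinstance(c, int) and c >= 0 for c in v) and
          all(b > a for a, b in zip(v, v[1:])),
          "must be strictly increasing non-negative integers")
    for lam in ("lambda_12", "lambda_21"):
        check(lam, lambda v: isinstance(v, num) and 0 <= v <= 1,
              "must lie in [0, 1]")
    check("initial_m", lambda v: isinstance(v, num) and v > 0, "must be > 0")
    check("initial_alpha", lambda v: isinstance(v, num) and v >= 0, "must be >= 0")
    check("n_cycles", lambda v: isinstance(v, int) and v >= 1, "must be >= 1")
    check("record_every", lambda v: isinstance(v, int) and v >= 1, "must be >= 1")
    check("mu", lambda v: isinstance(v, num) and v > 0, "must be > 0")
    check("delta_m", lambda v: isinstance(v, num) and v > 0, "must be > 0")
    check("delta_alpha", lambda v: isinstance(v, num) and v > 0, "must be > 0")
    check("prune_threshold", lambda v: isinstance(v, num) and 0 <= v <= 1e-3,
          "must lie in [0, 1e-3]")
    check("m_floor", lambda v: isinstance(v, num) and v > 0, "must be > 0")
    check("p1", lambda v: isinstance(v, num) and 0 < v < 1, "must lie in (0, 1)")
    for flag in ("plastic", "pin_alpha"):
        check(flag, lambda v: isinstance(v, bool), "must be a boolean")
    mode = raw.get("schedule_mode", "fixed")
    n_env = len(raw.get("harshness", (1.0,)))
    if mode != "fixed" and n_env != 2:
        problems.append(f"{mode} schedule requires exactly two harshness values")
    if mode == "scheduled" and not raw.get("switch_cycles"):
        problems.append("scheduled mode requires switch_cycles")
    if mode == "telegraph" and not (raw.get("lambda_12", 0) > 0
                                    and raw.get("lambda_21", 0) > 0):
        problems.append("telegraph mode requires positive lambda_12 and lambda_21")
    if problems:
        raise ConfigError(problems)
    cfg = dict(raw)
    for key in ("harshness", "switch_cycles"):
        if key in cfg:
            cfg[key] = tuple(cfg[key])
    return RunConfig(**cfg)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError(["configuration must be a YAML mapping"])
    return _validate(raw)


def serialize_config(config: RunConfig) -> str:
    """Canonical YAML serialization; ``load_config`` round-trips it."""
    d = asdict(config)
    d["harshness"] = list(d["harshness"])
    d["switch_cycles"] = list(d["switch_cycles"])
    return yaml.safe_dump(d, sort_keys=True)
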