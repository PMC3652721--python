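"""Run configuration: one YAML file drives the whole pipeline.

Every field is validated against the preconditions of the operation that
consumes it, at load time; unknown keys are rejected so typos fail fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .design import RANDOM_STRUCTURES


class ConfigError(ValueError):
    """A configuration field failed validation."""


_DEFAULTS: dict = {
    "seed": 1,
    "geography": {
        "n_states": 51,
        "counties_per_state": 4,
        "zips_per_county": 5,
        "bgs_per_county": 8,
        "bg_covariate_source": "independent",
    },
    "true_model": {
        "intercept": -3.4529,
        "sigma2_state": 0.0530,
        "sigma2_county": 0.0,
        "coefficients": "default",
        "reduced": False,
    },
    "survey": {
        "n_per_state": 400,
        "county_concentration": None,
        "state_child_population": 100000.0,
    },
    "population": {"mean_children_per_bg": 60.0},
    "models": ["state", "county", "state+county", "zip"],
    "n_draws": 1000,
    "reliability": {"min_n": 30, "max_rse": 0.3},
    "correlation_thresholds": [15, 30, 50, 100, 150, 200],
    "out_dir": "outputs",
}


@dataclass
class RunConfig:
    seed: int
    geography: dict
    true_model: dict
    survey: dict
    population: dict
    models: list
    n_draws: int
    reliability: dict
    correlation_thresholds: list
    out_dir: str = "outputs"

    def to_dict(self) -> dict:
        return asdict(self)

    def validate(self) -> None:
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ConfigError(f"seed: must be a non-negative integer, got {self.seed!r}")
        g = self.geography
        for k in ("n_states", "counties_per_state", "zips_per_county", "bgs_per_county"):
            if not isinstance(g.get(k), int) or g[k] < 1:
                raise ConfigError(f"geography.{k}: must be an integer >= 1, got {g.get(k)!r}")
        if g.get("bg_covariate_source") not in ("independent", "zip"):
            raise ConfigError("geography.bg_covariate_source: must be 'independent' or 'zip'")
        t = self.true_model
        for k in ("sigma2_state", "sigma2_county"):
            if not isinstance(t.get(k), (int, float)) or t[k] < 0:
                raise ConfigError(f"true_model.{k}: must be a non-negative number")
        if not isinstance(t.get("intercept"), (int, float)):
            raise ConfigError("true_model.intercept: must be a number")
        if not (t.get("coefficients") == "default" or isinstance(t.get("coefficients"), dict)):
            raise ConfigError("true_model.coefficients: 'default' or a term->level->value mapping")
        if not isinstance(t.get("reduced"), bool):
            raise ConfigError("true_model.reduced: must be a boolean")
        s = self.survey
        if not isinstance(s.get("n_per_state"), int) or s["n_per_state"] < 1:
            raise ConfigError("survey.n_per_state: must be an integer >= 1")
        cc = s.get("county_concentration")
        if cc is not None and (not isinstance(cc, (int, float)) or cc <= 0):
            raise ConfigError("survey.county_concentration: must be a positive number or null")
        if not isinstance(s.get("state_child_population"), (int, float)) or s[
            "state_child_population"
        ] <= 0:
            raise ConfigError("survey.state_child_population: must be a positive number")
        p = self.population
        if not isinstance(p.get("mean_children_per_bg"), (int, float)) or p[
            "mean_children_per_bg"
        ] <= 0:
            raise ConfigError("population.mean_children_per_bg: must be > 0")
        for m in self.models:
            if m not in RANDOM_STRUCTURES:
                raise ConfigError(
                    f"models: {m!r} is not one of {sorted(RANDOM_STRUCTURES)}"
                )
        if not isinstance(self.n_draws, int) or self.n_draws < 2:
            raise ConfigError("n_draws: must be an integer >= 2")
        r = self.reliability
        if not isinstance(r.get("min_n"), int) or r["min_n"] < 1:
            raise ConfigError("reliability.min_n: must be an integer >= 1")
        if not isinstance(r.get("max_rse"), (int, float)) or r["max_rse"] <= 0:
            raise ConfigError("reliability.max_rse: must be > 0")
        th = self.correlation_thresholds
        if not th or list(th) != sorted(th) or any(not isinstance(x, int) for x in th):
            raise ConfigError("correlation_thresholds: non-empty increasing integers")


def _merge(defaults: dict, user: dict, prefix: str = "") -> dict:
    out = {}
    unknown = set(user) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown config key(s): {[prefix + k for k in sorted(unknown)]}")
    for k, dv in defaults.items():
        uv = user.get(k, dv)
        if isinstance(dv, dict) and isinstance(uv, dict):
            out[k] = _merge(dv, uv, prefix=f"{prefix}{k}.")
        else:
            out[k] = uv
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load, default-fill and validate a YAML config; None = all defaults."""
    user: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must contain a YAML mapping")
        user = loaded
    merged = _merge(_DEFAULTS, user)
    if overrides:
        for k, v in overrides.items():
            if v is not None:
                merged[k] = v
    cfg = RunConfig(**merged)
    cfg.validate()
    return cfg
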