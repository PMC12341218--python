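"""Run configuration: schema, strict validation and canonical hashing.

The configuration is one JSON object with the blocks below; every block is
optional and falls back to package defaults, but unknown keys anywhere are
rejected so typos cannot silently revert a parameter to its default.

    {
      "baseline": {"alpha": 0.008, "beta": 0.5, "sigma": 1.67},
      "scenario": {"t_exo_up": 300.0, "lead": 60.0, "alpha_factor": 1.5,
                    "beta_change_value": 0.01,
                    "beta_change_mode": "multiplicative"},
      "observables": {"n_pool": 200.0, "gain": 1000.0, "baseline_f": 100.0},
      "synth": {"amplitude": {"log_mean": 3.0, "log_sd": 0.4, "floor_pa": 5.0},
                 "noise": {"additive_sd": 0.0, "multiplicative_sd": 0.0},
                 "seed": 0},
      "grid": {"t_end": 1080.0, "dt": 1.0}
    }
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from .kinetics import DEFAULT_HORIZON, DEFAULT_RATES, RateSet
from .scenario import ScenarioParams
from .synth import AmplitudeModel, NoiseModel

__all__ = ["ConfigError", "RunConfig"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


def _check_keys(block: Mapping[str, Any], allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}; allowed: {sorted(allowed)}")


def _number(block: Mapping[str, Any], key: str, default: float, where: str) -> float:
    v = block.get(key, default)
    if not isinstance(v, (int, float)) or isinstance(v, bool) or not np.isfinite(v):
        raise ConfigError(f"{where}.{key} must be a finite number, got {v!r}")
    return float(v)


@dataclass(frozen=True)
class RunConfig:
    """Validated parameters of a pipeline run."""

    baseline: RateSet = field(default_factory=lambda: DEFAULT_RATES)
    scenario: ScenarioParams = field(default_factory=ScenarioParams)
    n_pool: float = 200.0
    gain: float = 1000.0
    baseline_f: float = 100.0
    amplitude: AmplitudeModel = field(default_factory=AmplitudeModel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    t_end: float = DEFAULT_HORIZON
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.n_pool <= 0:
            raise ConfigError("observables.n_pool must be > 0")
        if self.gain < 0:
            raise ConfigError("observables.gain must be >= 0")
        if self.t_end <= 0 or self.dt <= 0 or self.dt > self.t_end:
            raise ConfigError("grid must satisfy 0 < dt <= t_end")
        if not isinstance(self.seed, int) or isinstance(self.seed, bool) or self.seed < 0:
            raise ConfigError("synth.seed must be a nonnegative integer")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        _check_keys(d, {"baseline", "scenario", "observables", "synth", "grid"}, "config")
        try:
            base_d = d.get("baseline", {})
            _check_keys(base_d, {"alpha", "beta", "sigma"}, "baseline")
            baseline = RateSet(
                alpha=_number(base_d, "alpha", DEFAULT_RATES.alpha, "baseline"),
                beta=_number(base_d, "beta", DEFAULT_RATES.beta, "baseline"),
                sigma=_number(base_d, "sigma", DEFAULT_RATES.sigma, "baseline"),
            )
            sc = d.get("scenario", {})
            _check_keys(
                sc,
                {"t_exo_up", "lead", "alpha_factor", "beta_change_value", "beta_change_mode"},
                "scenario",
            )
            mode = sc.get("beta_change_mode", "multiplicative")
            scenario = ScenarioParams(
                t_exo_up=_number(sc, "t_exo_up", 300.0, "scenario"),
                lead=_number(sc, "lead", 60.0, "scenario"),
                alpha_factor=_number(sc, "alpha_factor", 1.5, "scenario"),
                beta_change_value=_number(sc, "beta_change_value", 0.01, "scenario"),
                beta_change_mode=mode,
                baseline=baseline,
            )
            obs = d.get("observables", {})
            _check_keys(obs, {"n_pool", "gain", "baseline_f"}, "observables")
            syn = d.get("synth", {})
            _check_keys(syn, {"amplitude", "noise", "seed"}, "synth")
            amp_d = syn.get("amplitude", {})
            _check_keys(amp_d, {"log_mean", "log_sd", "floor_pa"}, "synth.amplitude")
            noise_d = syn.get("noise", {})
            _check_keys(noise_d, {"additive_sd", "multiplicative_sd"}, "synth.noise")
            grid = d.get("grid", {})
            _check_keys(grid, {"t_end", "dt"}, "grid")
            seed = syn.get("seed", 0)
            return cls(
                baseline=baseline,
                scenario=scenario,
                n_pool=_number(obs, "n_pool", 200.0, "observables"),
                gain=_number(obs, "gain", 1000.0, "observables"),
                baseline_f=_number(obs, "baseline_f", 100.0, "observables"),
                amplitude=AmplitudeModel(
                    log_mean=_number(amp_d, "log_mean", 3.0, "synth.amplitude"),
                    log_sd=_number(amp_d, "log_sd", 0.4, "synth.amplitude"),
                    floor_pa=_number(amp_d, "floor_pa", 5.0, "synth.amplitude"),
                ),
                noise=NoiseModel(
                    additive_sd=_number(noise_d, "additive_sd", 0.0, "synth.noise"),
                    multiplicative_sd=_number(noise_d, "multiplicative_sd", 0.0, "synth.noise"),
                ),
                seed=seed,
                t_end=_number(grid, "t_end", DEFAULT_HORIZON, "grid"),
                dt=_number(grid, "dt", 1.0, "grid"),
            )
        except ConfigError:
            raise
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        try:
            d = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{path}: not valid JSON: {exc}") from exc
        if not isinstance(d, dict):
            raise ConfigError(f"{path}: top-level config must be a JSON object")
        return cls.from_dict(d)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "baseline": {
                "alpha": self.baseline.alpha,
                "beta": self.baseline.beta,
                "sigma": self.baseline.sigma,
            },
            "scenario": {
                "t_exo_up": self.scenario.t_exo_up,
                "lead": self.scenario.lead,
                "alpha_factor": self.scenario.alpha_factor,
                "beta_change_value": self.scenario.beta_change_value,
                "beta_change_mode": self.scenario.beta_change_mode,
            },
            "observables": {"n_pool": self.n_pool, "gain": self.gain, "baseline_f": self.baseline_f},
            "synth": {
                "amplitude": {
                    "log_mean": self.amplitude.log_mean,
                    "log_sd": self.amplitude.log_sd,
                    "floor_pa": self.amplitude.floor_pa,
                },
                "noise": {
                    "additive_sd": self.noise.additive_sd,
                    "multiplicative_sd": self.noise.multiplicative_sd,
                },
                "seed": self.seed,
            },
            "grid": {"t_end": self.t_end, "dt": self.dt},
        }

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()

    def grid_times(self) -> np.ndarray:
        n = int(round(self.t_end / self.dt))
        return np.linspace(0.0, n * self.dt, n + 1)

    def with_seed(self, seed: int) -> "RunConfig":
        from dataclasses import replace

        return replace(self, seed=seed)
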