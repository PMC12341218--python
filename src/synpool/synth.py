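"""Seeded synthetic-data generators for every input the pipeline consumes.

Events, traces and dose-response tables are generated with the statistical
structure the analysis assumes:

* mEPSC trains are inhomogeneous Poisson processes driven by the model's
  release rate, sampled by Lewis-Shedler thinning under a piecewise
  envelope; amplitudes are i.i.d. and independent of the event times and of
  any drug condition (amplitude distributions are condition-invariant).
* Ca2+ traces are a flat baseline plus a difference-of-exponentials
  transient peaking ~75-85 s after the stimulus.
* SynaptopHluorin traces are the fused-fraction signal plus additive noise.
* Dose-response tables are Boltzmann-curve values with configurable noise.

Every generator is deterministic given its seed; independent random streams
are spawned from the seed so adding one draw never perturbs another stream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .kinetics import Trajectory
from .observables import CaTrace, DoseResponseData, EventTrain, PHluorinTrace, phluorin_signal

__all__ = [
    "AmplitudeModel",
    "NoiseModel",
    "sample_event_train",
    "synth_dose_response",
    "synth_ca_trace",
    "synth_phluorin_trace",
]


@dataclass(frozen=True)
class AmplitudeModel:
    """Log-normal mini amplitude distribution truncated at a detection floor.

    The log-location/scale are in log-pA.  Defaults (median ~20 pA, ~40%
    coefficient of variation, 5 pA floor) are plausible for hippocampal
    mEPSCs but arbitrary: only the condition-invariance of the distribution
    matters downstream, not its scale.
    """

    log_mean: float = 3.0    # log(pA); exp(3.0) ~ 20 pA median
    log_sd: float = 0.4
    floor_pa: float = 5.0    # minimum detectable amplitude

    def __post_init__(self) -> None:
        if self.log_sd <= 0:
            raise ValueError("log_sd must be > 0")
        if self.floor_pa < 0:
            raise ValueError("floor_pa must be >= 0")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        out = np.empty(0)
        while out.size < n:
            draw = rng.lognormal(self.log_mean, self.log_sd, size=max(n - out.size, 16))
            out = np.concatenate([out, draw[draw >= self.floor_pa]])
        return out[:n]


@dataclass(frozen=True)
class NoiseModel:
    """Additive and/or multiplicative Gaussian noise on a trace or table."""

    additive_sd: float = 0.0        # in trace units
    multiplicative_sd: float = 0.0  # fractional

    def __post_init__(self) -> None:
        if self.additive_sd < 0 or self.multiplicative_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")

    def apply(self, rng: np.random.Generator, values: np.ndarray) -> np.ndarray:
        out = np.asarray(values, dtype=float).copy()
        if self.multiplicative_sd > 0:
            out *= 1.0 + rng.normal(0.0, self.multiplicative_sd, size=out.shape)
        if self.additive_sd > 0:
            out += rng.normal(0.0, self.additive_sd, size=out.shape)
        return out


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def sample_event_train(
    rate_fn: Callable[[np.ndarray], np.ndarray],
    duration: float,
    amp_model: AmplitudeModel | None = None,
    seed: int = 0,
    max_rate: float | None = None,
) -> EventTrain:
    """Sample an inhomogeneous Poisson event train by thinning.

    ``rate_fn`` must be vectorised (array of times -> array of rates in Hz)
    and bounded.  The envelope is taken from ``rate_fn.envelope_pieces``
    (piecewise bounds, as provided by the model rate objects) when
    available, otherwise ``max_rate`` must be given.  Candidate events are
    drawn homogeneously at the envelope rate and accepted with probability
    rate/envelope (Lewis-Shedler).
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    pieces: Sequence[tuple[float, float, float]]
    env_fn = getattr(rate_fn, "envelope_pieces", None)
    if env_fn is not None:
        pieces = env_fn(duration)
    elif max_rate is not None:
        pieces = [(0.0, duration, float(max_rate))]
    else:
        raise ValueError("rate_fn has no envelope; pass max_rate explicitly")

    t_rng, a_rng = _streams(seed, 2)
    accepted: list[np.ndarray] = []
    for t0, t1, lam in pieces:
        if not np.isfinite(lam) or lam < 0:
            raise ValueError(f"invalid envelope rate {lam} on [{t0}, {t1}]")
        if lam == 0:
            continue
        n_cand = t_rng.poisson(lam * (t1 - t0))
        cand = np.sort(t_rng.uniform(t0, t1, size=n_cand))
        u = t_rng.uniform(0.0, 1.0, size=n_cand)
        rate = np.asarray(rate_fn(cand), dtype=float)
        if np.any(rate < 0):
            raise ValueError("rate_fn returned negative values")
        if np.any(rate > lam * (1.0 + 1e-9)):
            raise ValueError("rate_fn exceeds its envelope; thinning would be biased")
        accepted.append(cand[u * lam < rate])
    times = np.sort(np.concatenate(accepted)) if accepted else np.empty(0)
    amps = amp_model.sample(a_rng, times.size) if amp_model is not None else None
    return EventTrain(times=times, duration=float(duration), amplitudes=amps)


#: Default LPA concentration ladder (uM) spanning the tested 0.1-50 uM range.
DEFAULT_CONCENTRATIONS_UM = (0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 50.0)


def synth_dose_response(
    curve: Mapping[str, float],
    concentrations_um: Sequence[float] = DEFAULT_CONCENTRATIONS_UM,
    reps: int = 5,
    noise: NoiseModel = NoiseModel(multiplicative_sd=0.10),
    seed: int = 0,
) -> DoseResponseData:
    """Boltzmann-curve responses at the given concentrations, with noise.

    ``curve`` needs keys ``r_min``, ``r_max``, ``ec50_um`` and ``slope``
    (slope in decades on the log10-concentration axis).  Default curve
    parameters for the LPA Ca2+ response use an EC50 of 1.2 uM.
    """
    c = np.asarray(concentrations_um, dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentrations must be > 0")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    r_min, r_max = curve["r_min"], curve["r_max"]
    x0, slope = np.log10(curve["ec50_um"]), curve["slope"]
    cc = np.repeat(c, reps)
    resp = r_min + (r_max - r_min) / (1.0 + np.exp((x0 - np.log10(cc)) / slope))
    (rng,) = _streams(seed, 1)
    return DoseResponseData(concentrations_um=cc, responses=noise.apply(rng, resp))


def synth_ca_trace(
    baseline_level: float = 117.0,
    peak_delta: float = 150.0,
    peak_time_offset: float | None = None,
    tau_rise: float = 15.0,
    tau_decay: float = 120.0,
    stim_time: float = 60.0,
    duration: float = 600.0,
    sampling_interval: float = 2.0,
    noise: NoiseModel = NoiseModel(additive_sd=0.0),
    seed: int = 0,
) -> CaTrace:
    """Somatic Ca2+ trace: baseline, then a smooth transient after the stimulus.

    The transient is a difference of exponentials whose time constants are
    rescaled so the peak lands ``peak_time_offset`` seconds after the
    stimulus (drawn uniformly in [75, 85] s when not given, matching the
    observed latency of the LPA response) with maximum ``peak_delta`` above
    baseline.  Samples every ``sampling_interval`` s (default 2 s).
    """
    if tau_decay <= tau_rise or tau_rise <= 0:
        raise ValueError("need 0 < tau_rise < tau_decay")
    if sampling_interval <= 0 or duration <= stim_time:
        raise ValueError("invalid sampling/stimulus timing")
    offset_rng, noise_rng = _streams(seed, 2)
    if peak_time_offset is None:
        peak_time_offset = float(offset_rng.uniform(75.0, 85.0))
    if peak_time_offset <= 0:
        raise ValueError("peak_time_offset must be > 0")

    # natural peak time of exp(-t/td) - exp(-t/tr), then rescale both taus
    t_nat = tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)
    scale = peak_time_offset / t_nat
    tr, td = tau_rise * scale, tau_decay * scale
    t = np.arange(0.0, duration + 0.5 * sampling_interval, sampling_interval)
    rel = np.clip(t - stim_time, 0.0, None)
    kernel = np.exp(-rel / td) - np.exp(-rel / tr)
    kernel[t < stim_time] = 0.0
    peak_val = np.exp(-peak_time_offset / td) - np.exp(-peak_time_offset / tr)
    values = baseline_level + peak_delta * kernel / peak_val
    return CaTrace(times=t, values=noise.apply(noise_rng, values), stim_time=stim_time)


def synth_phluorin_trace(
    traj: Trajectory,
    gain: float = 1000.0,
    baseline_f: float = 100.0,
    noise: NoiseModel = NoiseModel(additive_sd=0.0),
    seed: int = 0,
) -> PHluorinTrace:
    """Noisy SynaptopHluorin trace for a trajectory (fused-fraction signal
    plus additive noise); equals :func:`phluorin_signal` at zero noise."""
    clean = phluorin_signal(traj, gain=gain, baseline_f=baseline_f)
    (rng,) = _streams(seed, 1)
    return PHluorinTrace(times=clean.times, fluorescence=noise.apply(rng, clean.fluorescence))
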