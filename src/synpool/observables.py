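"""Measurable quantities and their quantification and curve-fitting rules.

This module maps model trajectories onto the three observables the
experiments record — miniature EPSC event rates, SynaptopHluorin
fluorescence and ratiometric Ca2+ traces — and implements the analysis
procedures applied to them:

* ``ca_peak``: peak = mean of the five highest post-stimulus samples minus
  the pre-stimulus baseline; ``normalize_to_reference`` expresses a peak as
  percent of a reference (e.g. glutamate) peak.
* ``fit_boltzmann``: sigmoid dose-response fit on a log10 concentration
  axis, yielding the EC50.
* ``fit_exp_decay``: single-exponential fit of a fluorescence decay,
  yielding the membrane-residence time constant tau.
* event-train utilities: binning to frequencies, per-recording before/after
  frequency ratios and pooled cumulative amplitude distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .kinetics import Trajectory
from .scenario import FluxSeries

__all__ = [
    "FitError",
    "EventTrain",
    "FrequencySeries",
    "CaTrace",
    "PHluorinTrace",
    "DoseResponseData",
    "BoltzmannFit",
    "ExpDecayFit",
    "EmpiricalCDF",
    "mepsc_rate",
    "phluorin_signal",
    "ca_peak",
    "normalize_to_reference",
    "fit_boltzmann",
    "fit_exp_decay",
    "bin_events",
    "frequency_ratio",
    "cumulative_amplitudes",
]


class FitError(RuntimeError):
    """A curve fit failed to converge or the data cannot identify the model."""


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class EventTrain:
    """Timestamps (and optional amplitudes) of miniature synaptic events."""

    times: np.ndarray                  # sorted, within [0, duration]
    duration: float                    # recording length (s)
    amplitudes: np.ndarray | None = None  # pA, > 0, same length as times

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1:
            raise ValueError("event times must be a 1-d array")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if t.size:
            if np.any(np.diff(t) < 0):
                raise ValueError("event times must be nondecreasing")
            if t[0] < 0 or t[-1] > self.duration:
                raise ValueError("event times must lie within [0, duration]")
        object.__setattr__(self, "times", t)
        if self.amplitudes is not None:
            a = np.asarray(self.amplitudes, dtype=float)
            if a.shape != t.shape:
                raise ValueError("amplitudes must match times in length")
            if np.any(a <= 0):
                raise ValueError("amplitudes must be > 0")
            object.__setattr__(self, "amplitudes", a)

    @property
    def n_events(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class FrequencySeries:
    """Event rate per bin (Hz) over strictly increasing bin edges (s)."""

    edges: np.ndarray
    rate_hz: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        r = np.asarray(self.rate_hz, dtype=float)
        if e.ndim != 1 or e.size < 2 or not np.all(np.diff(e) > 0):
            raise ValueError("edges must be strictly increasing with >= 2 entries")
        if r.shape != (e.size - 1,):
            raise ValueError("need one rate per bin")
        if np.any(r < 0):
            raise ValueError("rates must be >= 0")
        object.__setattr__(self, "edges", e)
        object.__setattr__(self, "rate_hz", r)


@dataclass(frozen=True)
class CaTrace:
    """Background-corrected ratiometric Ca2+ trace with a stimulus marker."""

    times: np.ndarray
    values: np.ndarray      # F340/F380 ratio or calibrated concentration
    stim_time: float        # time the agonist was applied (s)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be 1-d arrays of equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("trace values must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class PHluorinTrace:
    """SynaptopHluorin fluorescence (arbitrary fluorescence units)."""

    times: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if t.ndim != 1 or t.shape != f.shape:
            raise ValueError("times and fluorescence must be 1-d arrays of equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fluorescence", f)


@dataclass(frozen=True)
class DoseResponseData:
    """Concentration-response pairs (concentration in uM, > 0); replicates allowed."""

    concentrations_um: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations_um, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        if c.ndim != 1 or c.shape != r.shape:
            raise ValueError("concentrations and responses must be 1-d and matched")
        if np.any(c <= 0):
            raise ValueError("concentrations must be > 0")
        if not np.all(np.isfinite(r)):
            raise ValueError("responses must be finite")
        object.__setattr__(self, "concentrations_um", c)
        object.__setattr__(self, "responses", r)


@dataclass(frozen=True)
class BoltzmannFit:
    """Sigmoid dose-response fit R(c) = r_min + (r_max - r_min) /
    (1 + exp((log10_ec50 - log10 c) / slope))."""

    r_min: float
    r_max: float
    log10_ec50: float
    slope: float            # decades; > 0
    rss: float
    stderr: dict[str, float]
    converged: bool
    n: int

    @property
    def ec50(self) -> float:
        """Half-maximal concentration in uM."""
        return float(10.0 ** self.log10_ec50)

    def predict(self, concentrations_um) -> np.ndarray:
        c = np.asarray(concentrations_um, dtype=float)
        return _boltzmann(np.log10(c), self.r_min, self.r_max, self.log10_ec50, self.slope)

    def to_dict(self) -> dict:
        return {
            "model": "boltzmann",
            "r_min": self.r_min,
            "r_max": self.r_max,
            "log10_ec50": self.log10_ec50,
            "ec50_uM": self.ec50,
            "slope_decades": self.slope,
            "rss": self.rss,
            "stderr": self.stderr,
            "converged": self.converged,
            "n": self.n,
        }


@dataclass(frozen=True)
class ExpDecayFit:
    """Single-exponential decay F(t) = amplitude * exp(-(t - t_start)/tau) + offset."""

    amplitude: float
    tau: float              # s, > 0
    offset: float
    t_start: float
    rss: float
    stderr: dict[str, float]
    converged: bool
    n: int

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")

    def to_dict(self) -> dict:
        return {
            "model": "exp_decay",
            "amplitude": self.amplitude,
            "tau_s": self.tau,
            "offset": self.offset,
            "t_start_s": self.t_start,
            "rss": self.rss,
            "stderr": self.stderr,
            "converged": self.converged,
            "n": self.n,
        }


@dataclass(frozen=True)
class EmpiricalCDF:
    """Right-continuous ECDF with steps 1/N at each order statistic."""

    values: np.ndarray  # sorted

    def __post_init__(self) -> None:
        v = np.sort(np.asarray(self.values, dtype=float))
        if v.size == 0:
            raise ValueError("ECDF needs at least one value")
        object.__setattr__(self, "values", v)

    def __call__(self, x) -> np.ndarray | float:
        out = np.searchsorted(self.values, np.asarray(x, dtype=float), side="right") / self.values.size
        return float(out) if np.isscalar(x) else out


# ---------------------------------------------------------------------------
# model -> observable maps


def mepsc_rate(traj: Trajectory, n_pool: float) -> FluxSeries:
    """Instantaneous mEPSC rate n_pool * alpha(t) * u1(t) in events/s.

    One fused vesicle is identified with one detected mini; detection losses
    are folded into the effective pool size ``n_pool``.
    """
    if n_pool <= 0:
        raise ValueError("n_pool must be > 0")
    return FluxSeries(times=traj.times, flux=n_pool * traj.rates[:, 0] * traj.states[:, 0])


def phluorin_signal(traj: Trajectory, gain: float, baseline_f: float = 0.0) -> PHluorinTrace:
    """SynaptopHluorin fluorescence F(t) = baseline_f + gain * u2(t).

    The reporter is quenched in the acidic vesicle lumen and fluoresces only
    while a vesicle is merged with the membrane, so the signal is
    proportional to the fused fraction u2.
    """
    if gain < 0:
        raise ValueError("gain must be >= 0")
    return PHluorinTrace(times=traj.times, fluorescence=baseline_f + gain * traj.states[:, 1])


# ---------------------------------------------------------------------------
# trace quantification


def ca_peak(trace: CaTrace) -> float:
    """Peak amplitude: mean of the five highest post-stimulus samples minus
    the pre-stimulus baseline (mean of all samples before ``stim_time``)."""
    pre = trace.values[trace.times < trace.stim_time]
    post = trace.values[trace.times >= trace.stim_time]
    if pre.size < 1:
        raise ValueError("need at least one pre-stimulus sample for the baseline")
    if post.size < 5:
        raise ValueError(f"need >= 5 post-stimulus samples, got {post.size}")
    top5 = np.sort(post)[-5:]
    return float(top5.mean() - pre.mean())


def normalize_to_reference(peak: float, ref_peak: float) -> float:
    """Express ``peak`` as percent of a reference peak (e.g. the glutamate
    response marking the cell's maximal Ca2+ increase)."""
    if ref_peak <= 0:
        raise ValueError("reference peak must be > 0")
    return 100.0 * peak / ref_peak


# ---------------------------------------------------------------------------
# curve fits


def _boltzmann(logc, r_min, r_max, log10_ec50, slope):
    return r_min + (r_max - r_min) / (1.0 + np.exp((log10_ec50 - logc) / slope))


def fit_boltzmann(data: DoseResponseData, max_restarts: int = 10) -> BoltzmannFit:
    """Least-squares Boltzmann (sigmoid) fit on the log10-concentration axis.

    Initialisation takes the asymptotes from the data extremes, the midpoint
    from the half-maximum crossing and a slope of 0.5 decades; up to
    ``max_restarts`` perturbed restarts are attempted before the fit is
    declared failed.  Raises :class:`FitError` on degenerate data or
    non-convergence — never fails silently.
    """
    c = data.concentrations_um
    r = data.responses
    if np.unique(c).size < 4:
        raise ValueError("need >= 4 distinct concentrations to fit a sigmoid")
    spread = float(np.ptp(r))
    if spread == 0 or spread < 1e-12 * max(1.0, float(np.abs(r).max())):
        raise FitError("responses do not vary across concentrations; slope unidentifiable")

    logc = np.log10(c)
    r_min0, r_max0 = float(r.min()), float(r.max())
    half = 0.5 * (r_min0 + r_max0)
    # log-concentration whose (mean) response is nearest the half-maximum
    order = np.argsort(logc)
    x0 = float(np.interp(half, r[order], logc[order])) if np.all(np.diff(r[order]) >= 0) else float(
        logc[np.argmin(np.abs(r - half))]
    )
    p0 = np.array([r_min0, r_max0, x0, 0.5])
    lo = [-np.inf, -np.inf, logc.min() - 2.0, 1e-3]
    hi = [np.inf, np.inf, logc.max() + 2.0, 10.0]

    rng = np.random.default_rng(1234)  # deterministic restart perturbations
    best = None
    for attempt in range(max_restarts + 1):
        trial = p0 if attempt == 0 else p0 + rng.normal(0, [0.1 * spread, 0.1 * spread, 0.5, 0.2], 4)
        trial = np.clip(trial, lo, hi)
        try:
            popt, pcov = curve_fit(
                _boltzmann, logc, r, p0=trial, bounds=(lo, hi), maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((r - _boltzmann(logc, *popt)) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    if best is None:
        raise FitError(f"Boltzmann fit did not converge in {max_restarts + 1} attempts")
    popt, pcov, rss = best
    if popt[1] <= popt[0]:
        raise FitError("fitted upper asymptote does not exceed the lower one")
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    names = ("r_min", "r_max", "log10_ec50", "slope")
    return BoltzmannFit(
        r_min=float(popt[0]),
        r_max=float(popt[1]),
        log10_ec50=float(popt[2]),
        slope=float(popt[3]),
        rss=rss,
        stderr={k: float(v) for k, v in zip(names, se)},
        converged=True,
        n=int(c.size),
    )


def fit_exp_decay(
    trace: PHluorinTrace,
    window: tuple[float, float],
) -> ExpDecayFit:
    """Fit a single-exponential decay to the trace restricted to ``window``.

    ``window`` should start at or after the fluorescence peak; a trace that
    does not decrease over the window is rejected as a model mismatch.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window end must exceed window start")
    mask = (trace.times >= t0) & (trace.times <= t1)
    t = trace.times[mask]
    f = trace.fluorescence[mask]
    if t.size < 4:
        raise ValueError(f"need >= 4 samples in the fit window, got {t.size}")
    trend = np.polyfit(t, f, 1)[0]
    if trend >= 0:
        raise FitError("trace does not decay over the fit window")

    def model(tt, amp, tau, off):
        return amp * np.exp(-(tt - t0) / tau) + off

    off0 = float(f.min())
    amp0 = max(float(f[0] - off0), 1e-12)
    tau0 = (t1 - t0) / 3.0
    lo = [0.0, 1e-9, -np.inf]
    hi = [np.inf, 1e9, np.inf]
    try:
        popt, pcov = curve_fit(model, t, f, p0=[amp0, tau0, off0], bounds=(lo, hi), maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"exponential-decay fit did not converge: {exc}") from exc
    amp, tau, off = popt
    if tau <= 2e-9 or tau >= 0.5e9 or amp <= 0:
        raise FitError("exponential-decay fit hit a parameter bound (no identifiable decay)")
    rss = float(np.sum((f - model(t, *popt)) ** 2))
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    names = ("amplitude", "tau", "offset")
    return ExpDecayFit(
        amplitude=float(amp),
        tau=float(tau),
        offset=float(off),
        t_start=float(t0),
        rss=rss,
        stderr={k: float(v) for k, v in zip(names, se)},
        converged=True,
        n=int(t.size),
    )


# ---------------------------------------------------------------------------
# event-train statistics


def bin_events(train: EventTrain, edges: Sequence[float] | np.ndarray) -> FrequencySeries:
    """Bin events into rates (count / bin width, Hz); conserves total count."""
    e = np.asarray(edges, dtype=float)
    if e.ndim != 1 or e.size < 2 or not np.all(np.diff(e) > 0):
        raise ValueError("edges must be strictly increasing with >= 2 entries")
    if e[0] < 0 or e[-1] > train.duration:
        raise ValueError("edges must lie within [0, duration]")
    counts, _ = np.histogram(train.times, bins=e)
    return FrequencySeries(edges=e, rate_hz=counts / np.diff(e))


def frequency_ratio(
    train: EventTrain,
    pre_window: tuple[float, float],
    post_window: tuple[float, float],
) -> float:
    """Per-recording frequency ratio (post rate / pre rate).

    This is the per-neuron before/after statistic used to summarise drug
    effects on mini frequency; a ratio < 1 indicates a reduction.  Windows
    are normally disjoint (before vs after treatment) but this is left to
    the caller: identical windows legitimately give a ratio of 1.
    """
    (a0, a1), (b0, b1) = pre_window, post_window
    if a1 <= a0 or b1 <= b0:
        raise ValueError("windows must have positive width")
    n_pre = int(np.searchsorted(train.times, a1) - np.searchsorted(train.times, a0))
    n_post = int(np.searchsorted(train.times, b1) - np.searchsorted(train.times, b0))
    if n_pre == 0:
        raise ValueError("pre-window contains no events; ratio undefined")
    return (n_post / (b1 - b0)) / (n_pre / (a1 - a0))


def cumulative_amplitudes(trains: EventTrain | Sequence[EventTrain]) -> EmpiricalCDF:
    """Pooled empirical CDF of event amplitudes across one or more trains."""
    if isinstance(trains, EventTrain):
        trains = [trains]
    amps = []
    for tr in trains:
        if tr.amplitudes is None:
            raise ValueError("all trains must carry amplitudes for a cumulative histogram")
        amps.append(tr.amplitudes)
    return EmpiricalCDF(values=np.concatenate(amps))
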