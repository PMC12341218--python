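"""Single-pool, three-state kinetics of the synaptic vesicle cycle.

The model partitions one presynaptic vesicle pool into three fractions:

* ``u1`` — vesicles docked and ready for release (readily releasable pool),
* ``u2`` — vesicles fused/merged with the presynaptic membrane,
* ``u3`` — vesicles in the recycling pathway after retrieval.

Transitions are first order with three rate constants: exocytosis ``alpha``
(u1 -> u2), endocytosis ``sigma`` (u2 -> u3) and recycling ``beta``
(u3 -> u1), giving the linear system

    du1/dt = -alpha*u1 + beta*u3
    du2/dt = +alpha*u1 - sigma*u2
    du3/dt = +sigma*u2 - beta*u3

Because the system is linear, propagation over any interval with constant
rates is exact via the matrix exponential of the generator; piecewise-
constant rate schedules are handled by chaining exact propagations across
segment boundaries.  No step-size tuning is needed and trajectories are
independent of output-grid refinement.

All times are in seconds and all rates in 1/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

__all__ = [
    "SIMPLEX_TOL",
    "DEFAULT_RATES",
    "DEFAULT_HORIZON",
    "RateSet",
    "PoolState",
    "RateSchedule",
    "Trajectory",
    "derivative",
    "generator_matrix",
    "steady_state",
    "propagate",
    "simulate",
]

#: Tolerance on the conservation constraint u1 + u2 + u3 = 1.
SIMPLEX_TOL = 1e-9

#: Default horizon of a scenario simulation (18 min).
DEFAULT_HORIZON = 1080.0


@dataclass(frozen=True)
class RateSet:
    """Kinetic rate constants of the three-state vesicle cycle (1/s)."""

    alpha: float  # exocytosis / activation, u1 -> u2
    beta: float   # recycling back to the releasable pool, u3 -> u1
    sigma: float  # endocytosis after release, u2 -> u3

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "sigma"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate {name} must be finite and >= 0, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.sigma], dtype=float)


#: Baseline rate constants of the model (literature values for hippocampal
#: boutons): alpha = 0.008/s, beta = 0.5/s, sigma = 1.67/s.
DEFAULT_RATES = RateSet(alpha=0.008, beta=0.5, sigma=1.67)


@dataclass(frozen=True)
class PoolState:
    """Fractions of the vesicle pool in each state; must lie on the simplex."""

    u1: float  # ready for release
    u2: float  # fused with the membrane
    u3: float  # recycling

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"pool state has non-finite components: {arr}")
        if np.any(arr < -SIMPLEX_TOL) or np.any(arr > 1 + SIMPLEX_TOL):
            raise ValueError(f"pool-state components outside [0, 1]: {arr}")
        total = float(arr.sum())
        if abs(total - 1.0) > SIMPLEX_TOL:
            # Renormalisation is refused on purpose: a broken simplex signals
            # a bug upstream, not measurement noise.
            raise ValueError(f"pool-state components sum to {total}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.u1, self.u2, self.u3], dtype=float)

    @staticmethod
    def from_array(arr: np.ndarray) -> "PoolState":
        return PoolState(float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass(frozen=True)
class RateSchedule:
    """Piecewise-constant rate time course.

    ``segments[i]`` is in force on ``[breakpoints[i-1], breakpoints[i])``,
    with the first segment starting at -inf (in practice, the simulation
    start) and the last extending to +inf.  Rates are right-continuous at
    breakpoints: at ``t == breakpoints[i]`` the new segment applies.
    """

    breakpoints: tuple[float, ...]
    segments: tuple[RateSet, ...]

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        if bp.size and not np.all(np.diff(bp) > 0):
            raise ValueError("breakpoints must be strictly increasing")
        if len(self.segments) != len(self.breakpoints) + 1:
            raise ValueError(
                f"need {len(self.breakpoints) + 1} segments for "
                f"{len(self.breakpoints)} breakpoints, got {len(self.segments)}"
            )
        if not all(isinstance(s, RateSet) for s in self.segments):
            raise TypeError("segments must be RateSet instances")

    @staticmethod
    def constant(rates: RateSet) -> "RateSchedule":
        return RateSchedule(breakpoints=(), segments=(rates,))

    def segment_index(self, t: float) -> int:
        return int(np.searchsorted(self.breakpoints, t, side="right"))

    def rates_at(self, t: float) -> RateSet:
        """Rates in force at time ``t`` (right-continuous)."""
        return self.segments[self.segment_index(t)]

    def iter_segments(self, t_start: float, t_end: float) -> Iterable[tuple[float, float, RateSet]]:
        """Yield ``(t0, t1, rates)`` covering ``[t_start, t_end]`` in order."""
        if t_end < t_start:
            raise ValueError("t_end must be >= t_start")
        edges = [t_start] + [b for b in self.breakpoints if t_start < b < t_end] + [t_end]
        for t0, t1 in zip(edges[:-1], edges[1:]):
            yield t0, t1, self.rates_at(t0)


@dataclass(frozen=True)
class Trajectory:
    """States and rates-in-force on a strictly increasing time grid."""

    times: np.ndarray         # (n,)
    states: np.ndarray        # (n, 3) rows (u1, u2, u3)
    rates: np.ndarray         # (n, 3) rows (alpha, beta, sigma), right-continuous

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.states, dtype=float)
        r = np.asarray(self.rates, dtype=float)
        if t.ndim != 1 or s.shape != (t.size, 3) or r.shape != (t.size, 3):
            raise ValueError("inconsistent trajectory array shapes")
        if t.size and not np.all(np.diff(t) > 0):
            raise ValueError("trajectory times must be strictly increasing")
        if np.any(np.abs(s.sum(axis=1) - 1.0) > SIMPLEX_TOL):
            raise ValueError("trajectory violates the conservation constraint")
        if np.any(s < -SIMPLEX_TOL) or np.any(s > 1 + SIMPLEX_TOL):
            raise ValueError("trajectory state components outside [0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", s)
        object.__setattr__(self, "rates", r)

    @property
    def u1(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def u2(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def u3(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def alpha(self) -> np.ndarray:
        return self.rates[:, 0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "u1": self.states[:, 0],
                "u2": self.states[:, 1],
                "u3": self.states[:, 2],
                "alpha": self.rates[:, 0],
                "beta": self.rates[:, 1],
                "sigma": self.rates[:, 2],
            }
        )


def derivative(state: PoolState, rates: RateSet) -> tuple[float, float, float]:
    """Time derivative (du1/dt, du2/dt, du3/dt) at ``state`` under ``rates``.

    The three components sum to zero exactly (conservation of the pool).
    """
    a, b, s = rates.alpha, rates.beta, rates.sigma
    d1 = -a * state.u1 + b * state.u3
    d2 = +a * state.u1 - s * state.u2
    d3 = +s * state.u2 - b * state.u3
    return (d1, d2, d3)


def generator_matrix(rates: RateSet) -> np.ndarray:
    """Generator ``M`` with ``d(state)/dt = M @ state``; columns sum to 0."""
    a, b, s = rates.alpha, rates.beta, rates.sigma
    return np.array(
        [
            [-a, 0.0, b],
            [a, -s, 0.0],
            [0.0, s, -b],
        ]
    )


def steady_state(rates: RateSet) -> PoolState:
    """Closed-form equilibrium of the cycle.

    For all-positive rates the unique equilibrium is
    ``u1 = 1 / (1 + alpha/sigma + alpha/beta)`` with
    ``u2 = (alpha/sigma) u1`` and ``u3 = (alpha/beta) u1``.  With
    ``alpha == 0`` the pool rests entirely in u1.  ``beta == 0`` or
    ``sigma == 0`` with ``alpha > 0`` is degenerate (mass drains out of the
    cycle and piles up in one compartment) and is rejected.
    """
    a, b, s = rates.alpha, rates.beta, rates.sigma
    if a == 0:
        return PoolState(1.0, 0.0, 0.0)
    if b == 0 or s == 0:
        raise ValueError(
            "degenerate rates: alpha > 0 with beta == 0 or sigma == 0 has no "
            "interior equilibrium (vesicles accumulate downstream)"
        )
    u1 = 1.0 / (1.0 + a / s + a / b)
    return PoolState(u1, (a / s) * u1, (a / b) * u1)


def propagate(state: PoolState, rates: RateSet, dt: float) -> PoolState:
    """Exact propagation over ``dt`` seconds of constant rates.

    Computes ``expm(M dt) @ state``; exact for the linear model up to
    floating-point rounding, hence free of discretisation error.
    """
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    if dt == 0:
        return state
    x = expm(generator_matrix(rates) * dt) @ state.as_array()
    return PoolState.from_array(x)


def simulate(
    schedule: RateSchedule,
    initial: PoolState,
    grid: Sequence[float] | np.ndarray,
) -> Trajectory:
    """Simulate the pool over ``grid`` under a piecewise-constant schedule.

    The state at ``grid[0]`` is ``initial``; between output times the state
    is advanced by exact propagation, splitting at schedule breakpoints.
    The result is therefore independent of how finely ``grid`` is chosen.
    """
    t = np.asarray(grid, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise ValueError("grid must be a non-empty 1-d array of times")
    if not np.all(np.diff(t) > 0):
        raise ValueError("grid times must be strictly increasing")

    states = np.empty((t.size, 3))
    rates = np.empty((t.size, 3))
    x = initial.as_array()
    states[0] = x
    rates[0] = schedule.rates_at(t[0]).as_array()
    for i in range(1, t.size):
        for t0, t1, seg in schedule.iter_segments(t[i - 1], t[i]):
            if t1 > t0:
                x = expm(generator_matrix(seg) * (t1 - t0)) @ x
        states[i] = x
        rates[i] = schedule.rates_at(t[i]).as_array()
    return Trajectory(times=t, states=states, rates=rates)


# ---------------------------------------------------------------------------
# Spectral helpers shared by the event-rate machinery in :mod:`synpool.inference`.
# The generator of a healthy rate set is diagonalisable; a near-defective
# eigenbasis triggers a dense expm fallback.

def _spectral(Mmat: np.ndarray):
    w, V = np.linalg.eig(Mmat)
    ok = np.linalg.cond(V) < 1e10
    return w, V, ok


def propagate_states_at(Mmat: np.ndarray, x0: np.ndarray, dts: np.ndarray) -> np.ndarray:
    """States ``exp(M dt) x0`` for every dt in ``dts`` (shape (len(dts), 3))."""
    dts = np.asarray(dts, dtype=float)
    w, V, ok = _spectral(Mmat)
    if ok:
        c = np.linalg.solve(V, x0.astype(complex))
        out = (V @ (np.exp(np.outer(w, dts)) * c[:, None])).T
        return out.real
    return np.stack([expm(Mmat * d) @ x0 for d in dts])


def integrate_state(Mmat: np.ndarray, x0: np.ndarray, dt: float) -> np.ndarray:
    """Exact ``\\int_0^dt exp(M s) x0 ds`` for the linear model."""
    if dt == 0:
        return np.zeros(3)
    w, V, ok = _spectral(Mmat)
    if ok:
        # phi(w) = (exp(w dt) - 1)/w, via a series near w = 0 (the conserved
        # mode has an eigenvalue that is structurally zero).
        x = w * dt
        phi = np.empty_like(x)
        small = np.abs(x) < 1e-8
        phi[small] = dt * (1.0 + x[small] / 2.0 + x[small] ** 2 / 6.0)
        phi[~small] = (np.exp(x[~small]) - 1.0) / w[~small]
        c = np.linalg.solve(V, x0.astype(complex))
        return (V @ (phi * c)).real
    # Augmented-generator fallback: exp([[M, I], [0, 0]] dt) has the integral
    # of the propagator in its upper-right block.
    aug = np.zeros((6, 6))
    aug[:3, :3] = Mmat
    aug[:3, 3:] = np.eye(3)
    return expm(aug * dt)[:3, 3:] @ x0
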