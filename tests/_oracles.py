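"""Independent numerical oracles for the test suite.

Forward Euler integration of the three-state system, JIT-compiled so the
very small step sizes used for oracle comparisons stay cheap.  The oracle is
deliberately naive (first-order, fixed step) and shares no code with the
production matrix-exponential propagator.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _euler_chunks(M: np.ndarray, x0: np.ndarray, h: float, n_per: int, n_chunks: int) -> np.ndarray:
    out = np.empty((n_chunks, 3))
    x = x0.copy()
    for k in range(n_chunks):
        for _ in range(n_per):
            x = x + h * (M @ x)
        out[k] = x
    return out


def euler_final(M: np.ndarray, x0: np.ndarray, h: float, t_end: float) -> np.ndarray:
    """State after forward-Euler integration to t_end with step h."""
    n = int(round(t_end / h))
    return _euler_chunks(M, x0.astype(np.float64), h, n, 1)[0]


def euler_checkpoints(M: np.ndarray, x0: np.ndarray, h: float, t_check: float, n_check: int) -> np.ndarray:
    """States at times t_check, 2*t_check, ..., n_check*t_check."""
    n_per = int(round(t_check / h))
    return _euler_chunks(M, x0.astype(np.float64), h, n_per, n_check)
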