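"""Third-order cumulant estimation.

For a zero-mean stationary process the third-order cumulant equals the
third-moment sequence

    R(tau1, tau2) = E{ x(k) x(k+tau1) x(k+tau2) },

estimated here by the biased sample average (divide by N, the standard
higher-order-statistics convention) or, behind a flag, the unbiased variant
(divide by the number of valid triples).

Only the fundamental wedge 0 <= tau2 <= tau1 is computed directly (via an
FFT cross-correlation); every other lag pair is filled from the six-fold
symmetry group of the third-order cumulant, so the symmetry
R(tau1,tau2) = R(tau2,tau1) holds exactly by construction.

This matrix is a diagnostic/testing surface: the production bispectrum path
(`bispecg.bispectrum`) uses the direct FFT method and does not route
through it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .exceptions import ParameterError
from .signal_io import Signal, demean

__all__ = ["CumulantMatrix", "third_order_cumulant"]


@dataclass(frozen=True)
class CumulantMatrix:
    """Third-order cumulant estimates over the square lag grid [-L, L]^2.

    ``values[i, j]`` holds R(tau1, tau2) with tau1 = i - L, tau2 = j - L.
    """

    values: np.ndarray
    max_lag: int
    n_samples_used: int
    biased: bool = True
    demeaned: bool = True

    @property
    def lags(self) -> np.ndarray:
        """Lag axis in samples, from -max_lag to +max_lag."""
        return np.arange(-self.max_lag, self.max_lag + 1)

    def at(self, tau1: int, tau2: int) -> float:
        return float(self.values[tau1 + self.max_lag, tau2 + self.max_lag])


def _wedge(x: np.ndarray, a_max: int, biased: bool) -> np.ndarray:
    """R(a, b) for 0 <= b <= a <= a_max, via FFT cross-correlation.

    For fixed a, R(a, b) = (1/d) * sum_k x[k] x[k+a] x[k+b]; the sum over b
    is the cross-correlation of z = x[:N-a] * x[a:] with x.
    """
    N = x.size
    W = np.zeros((a_max + 1, a_max + 1))
    xr = x[::-1]
    for a in range(0, min(a_max, N - 1) + 1):
        z = x[: N - a] * x[a:]
        c = fftconvolve(z, xr)  # c[N-1-b] = sum_k z[k] x[k+b]
        b = np.arange(0, a + 1)
        s = c[N - 1 - b]
        d = N if biased else max(N - a, 1)
        W[a, : a + 1] = s / d
    return W


def third_order_cumulant(signal: Signal, max_lag: int, biased: bool = True) -> CumulantMatrix:
    """Estimate R(tau1, tau2) on the lag square [-max_lag, max_lag]^2.

    The signal is demeaned internally (zero-mean premise of the cumulant /
    third-moment identity). The canonical representative of a lag pair under
    the cumulant symmetry group is (max - min, median - min) of the triple
    {0, tau1, tau2}, which lives in the wedge 0 <= b <= a <= 2*max_lag; the
    wedge is computed directly and the square is filled from it, so symmetry
    is a construction guarantee and the number of summed triples (hence the
    unbiased divisor) is constant along each orbit.
    """
    if max_lag < 1:
        raise ParameterError(f"max_lag must be >= 1, got {max_lag}")
    N = signal.n
    if max_lag >= N:
        raise ParameterError(f"max_lag ({max_lag}) must be < number of samples ({N})")
    x = demean(signal).samples
    L = max_lag
    W = _wedge(x, 2 * L, biased)

    t = np.arange(-L, L + 1)
    T1, T2 = np.meshgrid(t, t, indexing="ij")
    zero = np.zeros_like(T1)
    hi = np.maximum(zero, np.maximum(T1, T2))
    lo = np.minimum(zero, np.minimum(T1, T2))
    a = hi - lo
    b = (T1 + T2) - hi - 2 * lo  # median of {0,t1,t2} minus its min
    values = W[a, b]
    return CumulantMatrix(values=values, max_lag=L, n_samples_used=N, biased=biased)
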