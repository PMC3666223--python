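"""Independent brute-force oracles used by the test suite.

These deliberately use naive loops (or closed forms) distinct from the
vectorized production code paths they are checked against.
"""

from __future__ import annotations

import numpy as np


def naive_third_order_cumulant(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased R(tau1, tau2) on [-L, L]^2 by direct triple summation."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    N = x.size
    L = max_lag
    R = np.zeros((2 * L + 1, 2 * L + 1))
    for t1 in range(-L, L + 1):
        for t2 in range(-L, L + 1):
            s = 0.0
            for k in range(N):
                if 0 <= k + t1 < N and 0 <= k + t2 < N:
                    s += x[k] * x[k + t1] * x[k + t2]
            R[t1 + L, t2 + L] = s / N
    return R


def naive_principal_bispectrum(
    x: np.ndarray, fs: float, nfft: int, seg: int
) -> dict[tuple[int, int], complex]:
    """Mean triple product at every principal-region bin, by explicit loops
    over non-overlapping segments and bins."""
    segments = []
    for start in range(0, len(x) - seg + 1, seg):
        s = x[start : start + seg]
        segments.append(np.fft.fft(s - s.mean(), n=nfft))
    out: dict[tuple[int, int], complex] = {}
    half = int(nfft * (fs / 2) / fs)  # Nyquist bin
    for k1 in range(nfft):
        for k2 in range(k1 + 1):
            f1 = k1 * fs / nfft
            f2 = k2 * fs / nfft
            if f1 + f2 > fs / 2:
                continue
            acc = 0.0 + 0.0j
            for X in segments:
                acc += X[k1] * X[k2] * np.conj(X[(k1 + k2) % nfft])
            out[(k1, k2)] = acc / len(segments)
    return out


def naive_hidden_matrix(W: np.ndarray, b: np.ndarray, g, X: np.ndarray) -> np.ndarray:
    """Scalar double-loop H[k, i] = g(w_i . x_k + b_i)."""
    N, M = X.shape[0], W.shape[0]
    H = np.zeros((N, M))
    for k in range(N):
        for i in range(M):
            z = float(b[i])
            for j in range(X.shape[1]):
                z += W[i, j] * X[k, j]
            H[k, i] = g(np.array([z]))[0]
    return H


def streaming_stats(values) -> dict[str, float]:
    """One-pass accumulator for energy/min/max/mean/population std
    (Welford), independent of numpy reductions."""
    n = 0
    mean = 0.0
    m2 = 0.0
    energy = 0.0
    lo = float("inf")
    hi = float("-inf")
    for v in values:
        v = float(v)
        n += 1
        d = v - mean
        mean += d / n
        m2 += d * (v - mean)
        energy += v * v
        lo = min(lo, v)
        hi = max(hi, v)
    return {
        "energy": energy,
        "min": lo,
        "max": hi,
        "mean": mean,
        "std": (m2 / n) ** 0.5,
    }
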