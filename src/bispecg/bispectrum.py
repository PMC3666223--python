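"""Bispectrum estimation by the direct FFT method.

The bispectrum of a zero-mean stationary process,

    B(w1, w2) = E{ X(w1) X(w2) X*(w1 + w2) },

is estimated by segmenting the record, demeaning (and optionally tapering)
each segment, taking length-``nfft`` FFTs, averaging the triple products
over segments on the full two-sided bifrequency grid, and smoothing the
average in the frequency domain with a 2-D window to reduce estimation
variance. Frequency bin ``k`` maps to ``k * fs / nfft`` Hz (bins above
Nyquist are the negative frequencies); the index of the sum frequency is
taken modulo ``nfft``.

The default smoother is the Rao-Gabr optimal window (hexagonal support),
which is invariant under the full bispectral symmetry group and therefore
preserves all symmetries of the raw estimate; the "uniform" square window
preserves the transpose and conjugate symmetries only.

Squared bicoherence,

    b2(w1, w2) = |B(w1, w2)|^2 / (P(w1) P(w2) P(w1+w2)),

normalizes the (unsmoothed) bispectrum by the segment-averaged power
spectrum P, giving a scale-free coupling index in [0, 1] used by the QPC
detector as a threshold that does not depend on signal amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal.windows import hann

from .exceptions import ConfigurationError, DataError, ParameterError
from .signal_io import Signal

__all__ = [
    "BispectrumEstimate",
    "estimate_bispectrum",
    "bicoherence",
    "rao_gabr_window",
    "reconstruct_from_principal",
    "save_estimate",
    "load_estimate",
]

WINDOW_NAMES = ("rao-gabr", "uniform", "none")
TAPER_NAMES = ("boxcar", "hann")


@dataclass(frozen=True)
class BispectrumEstimate:
    """Direct-method bispectrum estimate over the two-sided bifrequency grid.

    Attributes
    ----------
    values : complex ndarray, (nfft, nfft)
        Smoothed estimate; ``values[k1, k2]`` is B at bifrequency
        ``(freqs[k1], freqs[k2])``.
    raw_values : complex ndarray, (nfft, nfft)
        Segment-averaged triple products before 2-D smoothing (the input to
        bicoherence, whose normalization must match the power spectra).
    power : ndarray, (nfft,)
        Segment-averaged power spectrum ``mean_j |X_j(w)|^2``.
    freqs : ndarray, (nfft,)
        Two-sided frequency axis in Hz (``numpy.fft.fftfreq`` convention).
    """

    values: np.ndarray
    raw_values: np.ndarray
    power: np.ndarray
    freqs: np.ndarray
    nfft: int
    n_segments: int
    window_name: str
    fs: float
    segment_samples: int


def rao_gabr_window(size: int = 5) -> np.ndarray:
    """Rao-Gabr optimal 2-D smoothing window of odd side ``size``.

    w(m, n) = 1 - (2/size)^2 (m^2 + m n + n^2) on the hexagonal support
    |m| + |n| + |m + n| < size, zero outside, normalized to unit sum. The
    quadratic form and the hexagon are invariant under the bispectral
    symmetry maps (transpose, negation, shear), so smoothing with this
    window commutes with them.
    """
    if size < 3 or size % 2 == 0:
        raise ParameterError(f"window size must be odd and >= 3, got {size}")
    m = np.arange(-(size // 2), size // 2 + 1)
    M, N = np.meshgrid(m, m, indexing="ij")
    w = 1.0 - (2.0 / size) ** 2 * (M * M + M * N + N * N)
    hexmask = (np.abs(M) + np.abs(N) + np.abs(M + N)) < size
    w = np.where(hexmask, np.clip(w, 0.0, None), 0.0)
    return w / w.sum()


def _smoothing_kernel(window_name: str, size: int) -> np.ndarray | None:
    if window_name == "none":
        return None
    if window_name == "uniform":
        return np.full((size, size), 1.0 / (size * size))
    if window_name == "rao-gabr":
        return rao_gabr_window(size)
    raise ConfigurationError(
        f"unknown window {window_name!r}; expected one of {WINDOW_NAMES}"
    )


def _circular_convolve(values: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    re = ndimage.convolve(values.real, kernel, mode="wrap")
    im = ndimage.convolve(values.imag, kernel, mode="wrap")
    return re + 1j * im


def estimate_bispectrum(
    signal: Signal,
    nfft: int = 128,
    segment_samples: int | None = None,
    overlap_fraction: float = 0.0,
    window_name: str = "rao-gabr",
    window_size: int = 5,
    taper: str = "boxcar",
) -> BispectrumEstimate:
    """Estimate the bispectrum of ``signal`` by the direct FFT method.

    Parameters
    ----------
    nfft : int
        FFT length, a power of two; the bifrequency resolution is
        ``fs / nfft`` Hz (1 Hz for the defaults: 128-sample segments at
        128 Hz).
    segment_samples : int, optional
        Samples per segment, default ``nfft`` (one 1-s episode at the
        defaults). Must satisfy ``2 <= segment_samples <= nfft``; shorter
        trailing remainders are dropped, never zero-padded.
    overlap_fraction : float
        Segment overlap in [0, 1); default 0 (a 1-minute record at the
        defaults yields 60 segments).
    window_name : {"rao-gabr", "uniform", "none"}
        2-D frequency-domain smoother.
    taper : {"boxcar", "hann"}
        Per-segment time-domain taper; default boxcar (none).

    Each segment is demeaned individually so the zero-mean premise holds
    under slow drift.
    """
    if nfft < 4 or (nfft & (nfft - 1)) != 0:
        raise ParameterError(f"nfft must be a power of two >= 4, got {nfft}")
    if segment_samples is None:
        segment_samples = nfft
    if not 2 <= segment_samples <= nfft:
        raise ParameterError(
            f"segment_samples must be in [2, nfft={nfft}], got {segment_samples}"
        )
    if not 0.0 <= overlap_fraction < 1.0:
        raise ParameterError(f"overlap_fraction must be in [0, 1), got {overlap_fraction}")
    if taper not in TAPER_NAMES:
        raise ConfigurationError(f"unknown taper {taper!r}; expected one of {TAPER_NAMES}")
    kernel = _smoothing_kernel(window_name, window_size)

    x = signal.samples
    if segment_samples > x.size:
        raise DataError(
            f"record of {x.size} samples shorter than one segment ({segment_samples})"
        )
    stride = max(1, int(round(segment_samples * (1.0 - overlap_fraction))))
    starts = range(0, x.size - segment_samples + 1, stride)
    n_seg = len(starts)

    win = hann(segment_samples, sym=False) if taper == "hann" else None
    k = np.arange(nfft)
    idx3 = (k[:, None] + k[None, :]) % nfft  # bin of the sum frequency

    acc = np.zeros((nfft, nfft), dtype=np.complex128)
    pacc = np.zeros(nfft)
    for s in starts:
        seg = x[s : s + segment_samples]
        seg = seg - seg.mean()
        if win is not None:
            seg = seg * win
        X = np.fft.fft(seg, n=nfft)
        acc += (X[:, None] * X[None, :]) * np.conj(X[idx3])
        pacc += (X.real * X.real + X.imag * X.imag)

    raw = acc / n_seg
    power = pacc / n_seg
    values = _circular_convolve(raw, kernel) if kernel is not None else raw.copy()
    freqs = np.fft.fftfreq(nfft, d=1.0 / signal.fs)
    return BispectrumEstimate(
        values=values,
        raw_values=raw,
        power=power,
        freqs=freqs,
        nfft=nfft,
        n_segments=n_seg,
        window_name=window_name,
        fs=signal.fs,
        segment_samples=segment_samples,
    )


def bicoherence(
    estimate: BispectrumEstimate, power: np.ndarray | None = None
) -> np.ndarray:
    """Squared bicoherence in [0, 1] on the estimate's grid.

    Uses the unsmoothed triple-product average and the matching
    segment-averaged power spectra; entries whose denominator is below
    machine tolerance (relative to its maximum) are set to 0.
    """
    if power is None:
        power = estimate.power
    power = np.asarray(power, dtype=np.float64)
    if power.shape != (estimate.nfft,):
        raise DataError(
            f"power spectrum has shape {power.shape}, expected ({estimate.nfft},)"
        )
    n = estimate.nfft
    k = np.arange(n)
    denom = power[:, None] * power[None, :] * power[(k[:, None] + k[None, :]) % n]
    tol = np.finfo(np.float64).eps * max(denom.max(), np.finfo(np.float64).tiny)
    ok = denom > tol
    num = np.abs(estimate.raw_values) ** 2
    b2 = np.zeros_like(denom)
    np.divide(num, denom, out=b2, where=ok)
    return np.clip(b2, 0.0, 1.0)


# ---------------------------------------------------------------------------
# symmetry reconstruction
# ---------------------------------------------------------------------------


def reconstruct_from_principal(
    estimate: BispectrumEstimate,
) -> tuple[np.ndarray, np.ndarray]:
    """Rebuild the grid from the principal triangular region by symmetry.

    Starting from the bins with 0 <= f2 <= f1 and f1 + f2 <= fs/2, the
    closure under the three generating symmetries of a real signal's
    bispectrum —

        B(w2, w1) = B(w1, w2)
        B(-w1, -w2) = conj(B(w1, w2))
        B(-w1-w2, w2) = B(w1, w2)

    — is propagated over the discrete grid. Returns ``(values, known)``
    where ``known`` marks the reconstructed bins. The reachable set is the
    hexagon |w1 + w2| <= Nyquist; the aliasing corner of the two-sided
    square grid is not related to the principal triangle by any symmetry
    and is left unknown (NaN).
    """
    from .qpc import principal_region_mask

    n = estimate.nfft
    mask = principal_region_mask(n, estimate.fs)
    vals = np.full((n, n), np.nan + 0j, dtype=np.complex128)
    known = mask.copy()
    vals[known] = estimate.values[known]

    K1, K2 = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    transforms = (
        (K2, K1, False),  # transpose (involution)
        ((-K1) % n, (-K2) % n, True),  # negation + conjugation (involution)
        ((-K1 - K2) % n, K2, False),  # shear (involution)
        (K1, (-K1 - K2) % n, False),  # transpose-conjugate of the shear
    )
    changed = True
    while changed:
        changed = False
        for s1, s2, conj in transforms:
            fill = (~known) & known[s1, s2]
            if fill.any():
                src = vals[s1, s2][fill]
                vals[fill] = np.conj(src) if conj else src
                known |= fill
                changed = True
    return vals, known


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_estimate(path, estimate: BispectrumEstimate) -> None:
    """Persist an estimate as a self-describing .npz archive."""
    np.savez(
        path,
        values=estimate.values,
        raw_values=estimate.raw_values,
        power=estimate.power,
        freqs=estimate.freqs,
        nfft=estimate.nfft,
        n_segments=estimate.n_segments,
        window_name=np.array(estimate.window_name),
        fs=estimate.fs,
        segment_samples=estimate.segment_samples,
    )


def load_estimate(path) -> BispectrumEstimate:
    with np.load(path, allow_pickle=False) as z:
        return BispectrumEstimate(
            values=z["values"],
            raw_values=z["raw_values"],
            power=z["power"],
            freqs=z["freqs"],
            nfft=int(z["nfft"]),
            n_segments=int(z["n_segments"]),
            window_name=str(z["window_name"]),
            fs=float(z["fs"]),
            segment_samples=int(z["segment_samples"]),
        )
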