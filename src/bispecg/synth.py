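"""Synthetic signals with known higher-order structure.

Every stage of the toolkit is testable without recorded data through three
generators, all pure functions of their parameters and a seed:

* :func:`gen_triad` — the canonical quadratic-phase-coupling test signal:
  cosines at f1, f2 and f1+f2 in additive white Gaussian noise. The first
  two phases are redrawn uniformly for every block (default 1 s, matching
  the analysis segmentation); the third phase is their sum when coupled,
  or an independent draw when uncoupled. Coupled and uncoupled versions
  have the same three line frequencies and powers — only the bispectrum
  separates them.

* :func:`gen_class_signal` — class surrogates mirroring the reported
  contrast between atrial-fibrillation and normal ECG bispectra: AF-like
  records superpose three coupled triads with bifrequencies in the
  5-15 Hz band at high coupling amplitude; normal-like records carry one
  weaker coupled triad near (3, 3) Hz. Both ride on pink-like background
  noise (cumulative-sum-filtered white noise, scaled to the target SNR),
  which keeps the classification task from being trivially easy.

* :func:`gen_dataset` — a labeled cohort with the default counts
  25 N + 20 S + 35 T + 50 NORMAL, one-minute records at 128 Hz. The
  N/S/T termination classes are separated by coupling-amplitude tiers
  (T > S > N). This tier mechanism is surrogate structure invented for
  testing the pipeline: nothing here is a claim about how AF termination
  classes actually differ bispectrally.
"""

from __future__ import annotations

import math

import numpy as np

from .exceptions import ParameterError
from .signal_io import Signal

__all__ = ["gen_triad", "gen_class_signal", "gen_dataset", "DEFAULT_COHORT"]

#: Default per-class record counts of the synthetic cohort.
DEFAULT_COHORT = {"N": 25, "S": 20, "T": 35, "NORMAL": 50}

#: Per-triad coupling amplitude tiers for the termination classes and the
#: normal surrogate (surrogate structure; see module docstring).
CLASS_AMPLITUDE = {"N": 0.7, "S": 1.0, "T": 1.4, "NORMAL": 0.4}


def _block_cosine(f: float, phases: np.ndarray, fs: float, n: int, block: int) -> np.ndarray:
    t = np.arange(n) / fs
    return np.cos(2.0 * np.pi * f * t + phases[np.arange(n) // block])


def _triad(
    f1: float,
    f2: float,
    coupled: bool,
    fs: float,
    n: int,
    block: int,
    rng: np.random.Generator,
    amplitudes=(1.0, 1.0, 1.0),
) -> np.ndarray:
    n_blocks = math.ceil(n / block)
    phi1 = rng.uniform(0.0, 2.0 * np.pi, n_blocks)
    phi2 = rng.uniform(0.0, 2.0 * np.pi, n_blocks)
    phi3 = phi1 + phi2 if coupled else rng.uniform(0.0, 2.0 * np.pi, n_blocks)
    a1, a2, a3 = amplitudes
    return (
        a1 * _block_cosine(f1, phi1, fs, n, block)
        + a2 * _block_cosine(f2, phi2, fs, n, block)
        + a3 * _block_cosine(f1 + f2, phi3, fs, n, block)
    )


def _noise_scale(signal_power: float, snr_db: float) -> float:
    if math.isinf(snr_db):
        return 0.0
    return math.sqrt(signal_power / 10.0 ** (snr_db / 10.0))


def gen_triad(
    f1: float,
    f2: float,
    coupled: bool = True,
    fs: float = 128.0,
    duration: float = 60.0,
    snr_db: float = math.inf,
    seed: int | np.random.SeedSequence = 0,
    amplitudes=(1.0, 1.0, 1.0),
    block_seconds: float = 1.0,
    label: str | None = None,
    record_id: str = "",
) -> Signal:
    """Three-cosine test signal with or without quadratic phase coupling.

    Phases are redrawn per ``block_seconds`` block (default 1 s, aligning
    blocks with the default analysis segments). ``snr_db`` sets the white
    Gaussian noise power relative to the total sinusoidal power;
    ``snr_db=inf`` gives a noise-free, fully deterministic signal for a
    given seed.
    """
    nyq = fs / 2.0
    if not (0 < f1 < nyq and 0 < f2 < nyq and f1 + f2 < nyq):
        raise ParameterError(
            f"triad ({f1}, {f2}, {f1 + f2}) Hz violates the Nyquist limit {nyq} Hz"
        )
    n = int(round(duration * fs))
    block = max(1, int(round(block_seconds * fs)))
    rng = np.random.default_rng(seed)
    x = _triad(f1, f2, coupled, fs, n, block, rng, amplitudes)
    sig_power = sum(a * a for a in amplitudes) / 2.0
    s = _noise_scale(sig_power, snr_db)
    if s > 0:
        x = x + s * rng.standard_normal(n)
    return Signal(x, fs, label=label, record_id=record_id)


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Cumulative-sum-filtered white noise (1/f^2-like), demeaned, unit power."""
    p = np.cumsum(rng.standard_normal(n))
    p -= p.mean()
    sd = p.std()
    return p / sd if sd > 0 else p


def _distinct_pairs(
    rng: np.random.Generator, k: int, lo: int, hi: int, min_sep: int = 3
) -> list[tuple[int, int]]:
    """k integer bifrequency pairs with lo <= f2 <= f1 <= hi, mutually
    separated by at least ``min_sep`` bins (Chebyshev) and with all 3k
    component frequencies {f1, f2, f1+f2} distinct.

    Separation keeps distinct couplings resolvable after 2-D smoothing;
    distinct components keep each coupling fully coherent (two cosines at
    one frequency with independent phases would dilute the bicoherence of
    both triads).
    """
    pairs: list[tuple[int, int]] = []
    comps: set[int] = set()
    tries = 0
    while len(pairs) < k:
        tries += 1
        if tries > 200:  # dead-end draw order: restart the rejection loop
            pairs, comps, tries = [], set(), 0
        f1 = int(rng.integers(lo, hi + 1))
        f2 = int(rng.integers(lo, f1 + 1))
        if {f1, f2, f1 + f2} & comps or f1 == f2:
            continue
        if any(max(abs(f1 - p1), abs(f2 - p2)) < min_sep for p1, p2 in pairs):
            continue
        pairs.append((f1, f2))
        comps |= {f1, f2, f1 + f2}
    return sorted(pairs)


def gen_class_signal(
    kind: str,
    fs: float = 128.0,
    duration: float = 60.0,
    seed: int | np.random.SeedSequence = 0,
    snr_db: float = 10.0,
    amplitude: float | None = None,
    label: str | None = None,
    record_id: str = "",
) -> Signal:
    """AF-like or normal-like surrogate record.

    ``af_like``: three coupled triads with integer bifrequencies drawn from
    the 5-15 Hz band (per-triad amplitude ``amplitude``, default 1.0).
    ``normal_like``: one weaker coupled triad with bifrequency near
    (3, 3) +- 1 Hz (default amplitude 0.4). Integer frequencies land on the
    1 Hz analysis grid of the default 128-point FFT. Both kinds add
    pink-like background noise scaled so the total sinusoid-to-noise ratio
    is ``snr_db``.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    block = max(1, int(round(1.0 * fs)))
    if kind == "af_like":
        amp = 1.0 if amplitude is None else amplitude
        pairs = _distinct_pairs(rng, 3, 5, 15)
    elif kind == "normal_like":
        amp = 0.4 if amplitude is None else amplitude
        f1 = int(rng.integers(2, 5))
        f2 = int(rng.integers(2, f1 + 1))
        pairs = [(f1, f2)]
    else:
        raise ParameterError(f"unknown kind {kind!r}; expected 'af_like' or 'normal_like'")

    x = np.zeros(n)
    for f1, f2 in pairs:
        x += _triad(float(f1), float(f2), True, fs, n, block, rng, (amp, amp, amp))
    sig_power = len(pairs) * 3 * amp * amp / 2.0
    s = _noise_scale(sig_power, snr_db)
    if s > 0:
        x = x + s * _pink_noise(n, rng)
    return Signal(x, fs, label=label, record_id=record_id)


def gen_dataset(
    n_per_class: dict[str, int] | None = None,
    fs: float = 128.0,
    duration: float = 60.0,
    seed: int = 0,
    snr_db: float = 10.0,
) -> list[Signal]:
    """Labeled synthetic cohort (default 25 N + 20 S + 35 T + 50 NORMAL).

    Record seeds are spawned deterministically from ``seed``; per-record
    coupling amplitudes are the class tier jittered by +-10% so the tiers
    overlap estimation noise rather than forming exact point masses.
    """
    counts = dict(DEFAULT_COHORT) if n_per_class is None else dict(n_per_class)
    for label, c in counts.items():
        if label not in CLASS_AMPLITUDE:
            raise ParameterError(f"unknown class {label!r}")
        if c < 1:
            raise ParameterError(f"count for class {label!r} must be >= 1, got {c}")
    master = np.random.default_rng(seed)
    children = np.random.SeedSequence(seed).spawn(sum(counts.values()))
    signals: list[Signal] = []
    i = 0
    for label in sorted(counts):  # deterministic class order
        kind = "normal_like" if label == "NORMAL" else "af_like"
        for j in range(counts[label]):
            amp = CLASS_AMPLITUDE[label] * master.uniform(0.9, 1.1)
            signals.append(
                gen_class_signal(
                    kind,
                    fs=fs,
                    duration=duration,
                    seed=children[i],
                    snr_db=snr_db,
                    amplitude=amp,
                    label=label,
                    record_id=f"{label}-{j:03d}",
                )
            )
            i += 1
    return signals
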