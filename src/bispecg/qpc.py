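"""Quadratic-phase-coupling detection and feature extraction.

A quadratically phase-coupled triple — components at f1, f2 and f1+f2 whose
third phase is the sum of the first two — produces a peak of the bispectrum
magnitude at the bifrequency (f1, f2). Because of the bispectral symmetries
the principal triangular region 0 <= f2 <= f1, f1 + f2 <= fs/2 suffices to
describe the estimate, so peaks are searched there only.

A bin is reported as a QPC when it is (a) inside the principal region,
(b) a strict local maximum of |B| over its 8-neighborhood (plateau ties
resolved toward the lexicographically smallest bin), (c) at least
``rel_threshold`` times the region-wide maximum of |B|, and (d) at least
``bicoh_floor`` in squared bicoherence. The magnitude criterion alone is
scale-dependent (|B| scales with the cube of signal amplitude); the
bicoherence floor supplies a scale-free coupling criterion.

Peak geometry (b)-(c) is evaluated on the unsmoothed segment-averaged
field. The 2-D smoother reduces the variance of the density estimate but
spreads each peak together with its transpose mirror across the f1 = f2
diagonal, which can displace the maximum of a near-diagonal coupling onto
an incoherent saddle bin; the unsmoothed field keeps couplings localized,
and the bicoherence floor supplies the noise control that smoothing would
otherwise provide.

Detected peaks are reduced to the five summary statistics used as
classifier inputs: energy (sum of squared magnitudes), minimum, maximum,
mean and population standard deviation of the peak magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bispectrum import BispectrumEstimate, bicoherence
from .exceptions import DataError, ParameterError

__all__ = [
    "QPCPeak",
    "QPCSet",
    "FeatureVector",
    "principal_region_mask",
    "detect_qpc",
    "extract_features",
    "FEATURE_NAMES",
]

FEATURE_NAMES = ("energy", "min", "max", "mean", "std")


@dataclass(frozen=True)
class QPCPeak:
    """One detected coupling: bifrequency in Hz (f2 <= f1), |B| magnitude,
    squared bicoherence."""

    f1: float
    f2: float
    magnitude: float
    bicoherence: float


@dataclass(frozen=True)
class QPCSet:
    """Peaks detected in the principal region, sorted by descending magnitude."""

    peaks: list[QPCPeak]
    region_mask: np.ndarray
    threshold_used: float
    source_record: str = ""

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def magnitudes(self) -> np.ndarray:
        return np.array([p.magnitude for p in self.peaks], dtype=np.float64)


@dataclass(frozen=True)
class FeatureVector:
    """Five-number summary of QPC peak magnitudes (classifier input)."""

    energy: float
    minimum: float
    maximum: float
    mean: float
    std: float
    n_peaks: int
    degenerate: bool = False  # True when no peaks were found (all-zero vector)

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.energy, self.minimum, self.maximum, self.mean, self.std],
            dtype=np.float64,
        )


def principal_region_mask(nfft: int, fs: float) -> np.ndarray:
    """Boolean mask of the principal triangle on the nfft x nfft grid.

    Bin (k1, k2) maps to (f1, f2) = (k1, k2) * fs / nfft; the mask is true
    exactly where 0 <= f2 <= f1 and f1 + f2 <= fs/2. As nfft grows the true
    fraction tends to 1/16 of the two-sided grid (triangle area fs^2/16
    over grid area fs^2).
    """
    if nfft < 4:
        raise ParameterError(f"nfft must be >= 4, got {nfft}")
    f = np.arange(nfft) * (fs / nfft)
    F1, F2 = np.meshgrid(f, f, indexing="ij")
    return (F2 <= F1) & (F1 + F2 <= fs / 2.0)


def detect_qpc(
    estimate: BispectrumEstimate,
    bicoh: np.ndarray | None = None,
    rel_threshold: float = 0.1,
    bicoh_floor: float = 0.3,
) -> QPCSet:
    """Detect QPC peaks in the principal region of a bispectrum estimate.

    ``bicoh`` is the squared-bicoherence matrix on the same grid; computed
    from the estimate when omitted. An all-zero estimate yields an empty
    peak set, not an error.
    """
    if not 0.0 < rel_threshold <= 1.0:
        raise ParameterError(f"rel_threshold must be in (0, 1], got {rel_threshold}")
    if not 0.0 <= bicoh_floor <= 1.0:
        raise ParameterError(f"bicoh_floor must be in [0, 1], got {bicoh_floor}")
    if bicoh is None:
        bicoh = bicoherence(estimate)
    if bicoh.shape != estimate.values.shape:
        raise DataError("bicoherence matrix does not share the estimate's grid")

    n = estimate.nfft
    mask = principal_region_mask(n, estimate.fs)
    mag = np.abs(estimate.raw_values)  # unsmoothed: see module docstring
    region_max = mag[mask].max()
    peaks: list[QPCPeak] = []
    if region_max > 0.0:
        candidate = mask & (mag >= rel_threshold * region_max) & (bicoh >= bicoh_floor)
        for k1, k2 in np.argwhere(candidate):
            c = mag[k1, k2]
            is_peak = True
            for d1 in (-1, 0, 1):
                for d2 in (-1, 0, 1):
                    if d1 == 0 and d2 == 0:
                        continue
                    j1, j2 = k1 + d1, k2 + d2
                    if not (0 <= j1 < n and 0 <= j2 < n):
                        continue
                    # out-of-region neighbors are mirror copies of region
                    # bins (possibly of the center itself) under the
                    # bispectral symmetries; comparing against them would
                    # veto genuine peaks adjacent to the f1 = f2 diagonal
                    if not mask[j1, j2]:
                        continue
                    v = mag[j1, j2]
                    if v > c or (v == c and (j1, j2) < (k1, k2)):
                        is_peak = False
                        break
                if not is_peak:
                    break
            if is_peak:
                scale = estimate.fs / n
                peaks.append(
                    QPCPeak(
                        f1=k1 * scale,
                        f2=k2 * scale,
                        magnitude=float(c),
                        bicoherence=float(bicoh[k1, k2]),
                    )
                )
    peaks.sort(key=lambda p: (-p.magnitude, p.f1, p.f2))
    return QPCSet(
        peaks=peaks,
        region_mask=mask,
        threshold_used=rel_threshold,
        source_record="",
    )


def extract_features(
    qpcs: QPCSet,
    energy_mode: str = "peaks",
    estimate: BispectrumEstimate | None = None,
) -> FeatureVector:
    """Reduce a peak set to the five-feature summary.

    ``energy_mode="peaks"`` (default) sums squared peak magnitudes;
    ``energy_mode="region"`` integrates |B|^2 over the whole principal
    region of ``estimate`` instead. With no peaks all five features are 0
    and the vector is flagged degenerate.
    """
    if energy_mode not in ("peaks", "region"):
        raise ParameterError(f"unknown energy_mode {energy_mode!r}")
    m = qpcs.magnitudes
    if m.size == 0:
        return FeatureVector(0.0, 0.0, 0.0, 0.0, 0.0, 0, degenerate=True)
    if energy_mode == "region":
        if estimate is None:
            raise ParameterError("energy_mode='region' requires the estimate")
        energy = float(np.sum(np.abs(estimate.values[qpcs.region_mask]) ** 2))
    else:
        energy = float(np.sum(m * m))
    return FeatureVector(
        energy=energy,
        minimum=float(m.min()),
        maximum=float(m.max()),
        mean=float(m.mean()),
        std=float(m.std()),  # population convention: one peak -> 0
        n_peaks=int(m.size),
    )
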