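"""Contour rendering of bispectrum magnitude over the principal region."""

from __future__ import annotations

import numpy as np

from .bispectrum import BispectrumEstimate
from .qpc import principal_region_mask


def plot_bispectrum(estimate: BispectrumEstimate, ax=None, levels: int = 20):
    """Filled contour plot of |B| over the principal triangular region.

    Returns the matplotlib Axes. Matplotlib is imported lazily so that the
    numerical API stays importable in headless batch use without touching a
    display backend.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    n = estimate.nfft
    half = n // 2 + 1
    mag = np.abs(estimate.values)[:half, :half].copy()
    mask = principal_region_mask(n, estimate.fs)[:half, :half]
    mag[~mask] = np.nan
    f = np.arange(half) * estimate.fs / n
    cs = ax.contourf(f, f, mag.T, levels=levels, cmap="viridis")
    ax.figure.colorbar(cs, ax=ax, label="|B|")
    ax.set_xlabel("f1 (Hz)")
    ax.set_ylabel("f2 (Hz)")
    ax.set_title(f"Bispectrum magnitude ({estimate.n_segments} segments)")
    return ax
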