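"""Signal container and I/O.

A :class:`Signal` is a uniformly sampled, real-valued, single-channel series
with a sampling frequency in Hz and optional class metadata. Two on-disk
formats are supported:

* plain delimited text — one sample per line (first column if several),
  optional single header line, decimal point, no thousands separators;
* a minimal subset of the WFDB header/signal format: ``<record>.hea`` plus a
  binary ``<record>.dat`` in format 16 (little-endian 16-bit integers,
  channels interleaved), with gain/baseline applied to recover physical
  units. Other WFDB storage formats are not handled.

Loaded samples must be finite: by default a non-finite value is a format
error, because silently imputed samples bias third-order statistics. Linear
interpolation over non-finite runs is available behind an explicit flag.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .exceptions import ConfigurationError, DataError, FormatError, ParameterError

__all__ = [
    "Signal",
    "load_signal",
    "write_signal",
    "read_wfdb",
    "write_wfdb",
    "segment",
    "demean",
]

#: Class tags used by the atrial-fibrillation task: N (non-terminating AF),
#: S (AF terminating within a minute of the record end), T (AF terminating
#: immediately), NORMAL (sinus rhythm).
VALID_LABELS = frozenset({"N", "S", "T", "NORMAL"})


@dataclass(frozen=True)
class Signal:
    """Uniformly sampled real-valued series.

    Parameters
    ----------
    samples : array-like of float
        Sample values in arbitrary physical units (e.g. mV). At least two
        samples; all finite.
    fs : float
        Sampling frequency in Hz, strictly positive.
    label : str, optional
        Class tag, one of ``{"N", "S", "T", "NORMAL"}`` or ``None``.
    record_id : str
        Opaque identifier carried through segmentation and feature tables.
    """

    samples: np.ndarray
    fs: float
    label: str | None = None
    record_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64)
        if arr.ndim != 1:
            raise DataError(f"samples must be 1-D, got shape {arr.shape}")
        if arr.size < 2:
            raise DataError(f"need at least 2 samples, got {arr.size}")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise DataError(f"fs must be a positive finite number, got {self.fs}")
        if not np.all(np.isfinite(arr)):
            raise DataError("samples contain non-finite values")
        if self.label is not None and self.label not in VALID_LABELS:
            raise DataError(f"unknown label {self.label!r}; expected one of {sorted(VALID_LABELS)}")
        object.__setattr__(self, "samples", arr)
        object.__setattr__(self, "fs", float(self.fs))

    @property
    def n(self) -> int:
        """Number of samples."""
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record duration in seconds (n / fs)."""
        return self.samples.size / self.fs


def demean(signal: Signal) -> Signal:
    """Subtract the arithmetic mean, enforcing the zero-mean premise of
    third-order statistics. Idempotent up to floating-point rounding."""
    return replace(signal, samples=signal.samples - signal.samples.mean())


# ---------------------------------------------------------------------------
# delimited text
# ---------------------------------------------------------------------------

_SPLIT_RE = re.compile(r"[,\t;]|\s+")


def _parse_text(path: Path, nonfinite: str) -> np.ndarray:
    try:
        text = path.read_text()
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    lines = [ln.strip() for ln in text.splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: no data rows")
    values: list[float] = []
    for i, ln in enumerate(lines):
        token = _SPLIT_RE.split(ln)[0]
        try:
            values.append(float(token))
        except ValueError:
            if i == 0:  # a single non-numeric header line is tolerated
                continue
            raise FormatError(f"{path}: unparseable value {token!r} on line {i + 1}")
    if not values:
        raise FormatError(f"{path}: no numeric samples")
    arr = np.asarray(values, dtype=np.float64)
    bad = ~np.isfinite(arr)
    if bad.any():
        if nonfinite == "error":
            raise FormatError(
                f"{path}: {int(bad.sum())} non-finite sample(s); "
                "pass nonfinite='interpolate' to repair"
            )
        if nonfinite == "interpolate":
            if bad.all():
                raise FormatError(f"{path}: all samples non-finite")
            good = np.flatnonzero(~bad)
            arr[bad] = np.interp(np.flatnonzero(bad), good, arr[good])
        else:
            raise ConfigurationError(f"unknown nonfinite policy {nonfinite!r}")
    return arr


def write_signal(path: str | Path, signal: Signal, header: bool = False) -> None:
    """Write one sample per line with full float precision (round-trips
    bit-exactly through :func:`load_signal`)."""
    path = Path(path)
    lines = []
    if header:
        lines.append("sample")
    lines.extend(f"{v:.17g}" for v in signal.samples)
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# minimal WFDB (.hea + .dat, format 16)
# ---------------------------------------------------------------------------

_GAIN_RE = re.compile(r"^([-+0-9.eE]+)(?:\(([-+0-9]+)\))?(?:/(\S+))?$")


def read_wfdb(path: str | Path, channel: int = 0, fs_override: float | None = None) -> Signal:
    """Read one channel of a WFDB record stored in format 16.

    ``path`` may point at the ``.hea`` file or at the bare record stem.
    Amplitudes are converted to physical units as ``(raw - baseline) / gain``
    with the WFDB default gain of 200 adu/mV when the header gives none.
    """
    path = Path(path)
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FormatError(f"header file not found: {hea}")
    lines = [ln.strip() for ln in hea.read_text().splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{hea}: empty header")
    head = lines[0].split()
    if len(head) < 2:
        raise FormatError(f"{hea}: malformed record line {lines[0]!r}")
    record_name = head[0].split("/")[0]
    try:
        n_sig = int(head[1])
    except ValueError:
        raise FormatError(f"{hea}: bad signal count {head[1]!r}")
    fs = 250.0  # WFDB default
    if len(head) >= 3:
        try:
            fs = float(head[2].split("/")[0])
        except ValueError:
            raise FormatError(f"{hea}: bad sampling frequency {head[2]!r}")
    if n_sig < 1 or channel >= n_sig:
        raise FormatError(f"{hea}: channel {channel} not in record with {n_sig} signal(s)")
    if len(lines) < 1 + n_sig:
        raise FormatError(f"{hea}: expected {n_sig} signal line(s)")

    spec = lines[1 + channel].split()
    dat_name, fmt_token = spec[0], spec[1]
    fmt = int(re.match(r"(\d+)", fmt_token).group(1))
    if fmt != 16:
        raise FormatError(f"{hea}: unsupported WFDB storage format {fmt} (only 16)")
    gain, baseline = 200.0, 0.0
    if len(spec) >= 3:
        m = _GAIN_RE.match(spec[2])
        if m is None:
            raise FormatError(f"{hea}: bad gain field {spec[2]!r}")
        g = float(m.group(1))
        gain = g if g != 0 else 200.0
        if m.group(2) is not None:
            baseline = float(m.group(2))
        elif len(spec) >= 5:  # adc zero column doubles as baseline
            try:
                baseline = float(spec[4])
            except ValueError:
                baseline = 0.0

    dat = hea.parent / dat_name
    if not dat.exists():
        raise FormatError(f"signal file not found: {dat}")
    raw = np.fromfile(dat, dtype="<i2")
    if raw.size == 0 or raw.size % n_sig:
        raise FormatError(f"{dat}: size {raw.size} not a multiple of {n_sig} channel(s)")
    samples = (raw.reshape(-1, n_sig)[:, channel].astype(np.float64) - baseline) / gain
    return Signal(samples, fs_override if fs_override is not None else fs, record_id=record_name)


def write_wfdb(stem: str | Path, signal: Signal, gain: float = 200.0, units: str = "mV") -> None:
    """Write a single-channel format-16 WFDB record (``stem.hea`` +
    ``stem.dat``). Quantization error is bounded by ``1/(2*gain)``."""
    stem = Path(stem)
    digital = np.clip(np.rint(signal.samples * gain), -32768, 32767).astype("<i2")
    fs = signal.fs
    fs_str = f"{fs:g}"
    hea = (
        f"{stem.name} 1 {fs_str} {digital.size}\n"
        f"{stem.name}.dat 16 {gain:g}(0)/{units} 16 0 {digital[0]} 0 0\n"
    )
    stem.with_suffix(".hea").write_text(hea)
    digital.tofile(stem.with_suffix(".dat"))


# ---------------------------------------------------------------------------
# loading dispatch
# ---------------------------------------------------------------------------


def load_signal(
    path: str | Path,
    fs_override: float | None = None,
    *,
    nonfinite: str = "error",
    label: str | None = None,
    record_id: str | None = None,
    channel: int = 0,
) -> Signal:
    """Load a signal from a WFDB record or a single-column text file.

    The sampling frequency comes from the WFDB header when present;
    text files require ``fs_override``.
    """
    path = Path(path)
    if not path.exists() and not path.with_suffix(".hea").exists():
        raise FormatError(f"no such file: {path}")
    is_wfdb = path.suffix in {".hea", ".dat"} or (
        path.suffix == "" and path.with_suffix(".hea").exists()
    )
    if is_wfdb:
        sig = read_wfdb(path, channel=channel, fs_override=fs_override)
    else:
        arr = _parse_text(path, nonfinite)
        if fs_override is None:
            raise ConfigurationError(
                f"{path}: text input carries no sampling frequency; pass fs_override"
            )
        sig = Signal(arr, fs_override, record_id=path.stem)
    if label is not None:
        sig = replace(sig, label=label)
    if record_id is not None:
        sig = replace(sig, record_id=record_id)
    return sig


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def segment(
    signal: Signal, episode_seconds: float, overlap_fraction: float = 0.0
) -> list[Signal]:
    """Cut a record into consecutive fixed-length episodes.

    Episode length is ``round(episode_seconds * fs)`` samples; the hop is
    ``round(n_ep * (1 - overlap_fraction))``. A trailing remainder shorter
    than one episode is dropped. Episodes inherit fs, label and record_id
    (suffixed with the episode index).
    """
    if not 0.0 <= overlap_fraction < 1.0:
        raise ParameterError(f"overlap_fraction must be in [0, 1), got {overlap_fraction}")
    n_ep = int(round(episode_seconds * signal.fs))
    if n_ep < 2:
        raise DataError(f"episode of {episode_seconds} s at fs={signal.fs} has {n_ep} sample(s)")
    if n_ep > signal.n:
        raise DataError(
            f"episode ({n_ep} samples) longer than record ({signal.n} samples): no episodes"
        )
    stride = max(1, int(round(n_ep * (1.0 - overlap_fraction))))
    starts = range(0, signal.n - n_ep + 1, stride)
    return [
        Signal(
            signal.samples[s : s + n_ep],
            signal.fs,
            label=signal.label,
            record_id=f"{signal.record_id}#{i}" if signal.record_id else f"#{i}",
        )
        for i, s in enumerate(starts)
    ]
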