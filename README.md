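# bispecg

Higher-order spectral analysis of single-channel physiological signals —
bispectrum estimation, quadratic-phase-coupling (QPC) detection, and an
extreme learning machine (ELM) classifier — aimed at the atrial-fibrillation
(AF) ECG classification problem: distinguishing non-terminating (N),
terminating (S) and immediately terminating (T) AF records, and separating
AF from normal sinus rhythm.

During AF the heart behaves more nonlinearly, and second-order tools are
blind to that: the power spectrum of a signal discards all phase
information. The **bispectrum**

```
B(ω₁, ω₂) = E{ X(ω₁) X(ω₂) X*(ω₁ + ω₂) }
```

— the Fourier transform of the third-order cumulant
R(τ₁, τ₂) = E{x(k) x(k+τ₁) x(k+τ₂)} of a zero-mean stationary process —
retains phase relations. A component at ω₁+ω₂ whose phase is the *sum* of
the phases at ω₁ and ω₂ (the fingerprint of a quadratic nonlinearity) shows
up as a peak of |B| at the bifrequency (ω₁, ω₂); the same three components
with an unrelated third phase average out. By symmetry, the triangular
region 0 ≤ ω₂ ≤ ω₁, ω₁ + ω₂ ≤ π describes the whole bispectrum, so peaks
are searched there only. Each record is reduced to five features — energy,
minimum, maximum, mean and standard deviation of its detected QPC peak
magnitudes — and classified by an ELM: a single-hidden-layer network whose
hidden weights are random and fixed, with output weights solved in one
shot as β̂ = H†Y via the Moore–Penrose pseudoinverse.

The package contains:

| module | contents |
| --- | --- |
| `bispecg.signal_io` | `Signal` container, CSV/WFDB-subset readers, segmentation, demeaning |
| `bispecg.cumulant` | third-order cumulant matrix (FFT cross-correlation, symmetry-complete) |
| `bispecg.bispectrum` | direct FFT-method estimator, Rao–Gabr smoothing, bicoherence, symmetry reconstruction |
| `bispecg.qpc` | principal-region mask, QPC peak detector, five-feature summary |
| `bispecg.elm` | activations, hidden-layer matrix, pseudoinverse training, prediction, grid search |
| `bispecg.synth` | coupled/uncoupled triads, AF-like / normal-like surrogates, labeled cohorts |
| `bispecg.pipeline` | stratified record-level 50/50 experiment driver with leakage guard |
| `bispecg.cli` | `bispecg` command-line interface over all of the above |

## Worked example

```python
import numpy as np
from bispecg import (gen_triad, estimate_bispectrum, bicoherence, detect_qpc,
                     extract_features, gen_dataset, ExperimentConfig, run_experiment)

# a quadratically coupled cosine triad: 5, 10 and 15 Hz, third phase = sum
# of the first two, 10 dB white noise, 64 seconds at 128 Hz
sig = gen_triad(f1=5.0, f2=10.0, coupled=True, duration=64.0, snr_db=10.0, seed=0)
est = estimate_bispectrum(sig)          # 64 one-second segments, nfft=128
qpcs = detect_qpc(est, bicoherence(est))
top = qpcs.peaks[0]
print(f"top peak: ({top.f1:g}, {top.f2:g}) Hz, b2 = {top.bicoherence:.3f}")
# -> top peak: (10, 5) Hz, b2 = 0.988

fv = extract_features(qpcs)
print(f"energy={fv.energy:.3g} mean={fv.mean:.1f} n_peaks={fv.n_peaks}")
# -> energy=6.71e+10 mean=259008.5 n_peaks=1

# synthetic cohort: 25 N + 20 S + 35 T + 50 NORMAL one-minute records
signals = gen_dataset(seed=0)
report = run_experiment(ExperimentConfig(task="af_vs_normal", seed=0), signals)
print(f"accuracy: {report.accuracy:.2f}%")
# -> accuracy: 100.00%
```

The detector finds exactly one coupling, at the true bifrequency (10, 5) Hz
(ordered so f₂ ≤ f₁), with squared bicoherence 0.988 — essentially full
coupling; the residual 0.012 is the 10 dB noise share of the bin powers.
The five-feature vector of a single-peak record collapses to that peak's
magnitude (std = 0). On the synthetic cohort the stratified 50/50
experiment trains the ELM on 65 records and classifies all 65 held-out
records correctly (AF surrogates carry three strong couplings in the
5–15 Hz band; normal surrogates one weak coupling near 3 Hz).

The same flows are available from the shell:

```sh
bispecg synth --kind dataset --out-dir data/
bispecg features data/T-000.csv --fs 128 --out features.csv
bispecg run --seed 0 --out-dir results/
```

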