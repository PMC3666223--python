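# Methods

## Bispectrum estimation (direct FFT method)

For a zero-mean stationary discrete process x(n), the third-order cumulant
equals the third moment, R(τ₁, τ₂) = E{x(k)x(k+τ₁)x(k+τ₂)}, and its 2-D
Fourier transform is the bispectrum, equivalently
B(ω₁, ω₂) = E{X(ω₁)X(ω₂)X*(ω₁+ω₂)}. The estimator segments the record,
demeans each segment individually (so the zero-mean premise survives slow
baseline drift), applies an optional time-domain taper, takes length-nfft
FFTs, averages the triple products over segments on the full two-sided
grid, and smooths the average with a 2-D frequency-domain window. Bin k
maps to k·fs/nfft Hz; the sum-frequency index is taken modulo nfft.

Defaults and rationale:

* **nfft = 128, segment = nfft samples, 0 % overlap** — one 1-second
  episode per segment for the target recordings (128 Hz), giving 1 Hz
  bifrequency resolution and 60 averaged segments per one-minute record.
  Trailing remainders are dropped, never zero-padded (padding would bias
  triple products). Overlap is configurable up to 75 %.
* **Smoothing window: Rao–Gabr, size 5** — w(m,n) = 1 − (2/size)²(m²+mn+n²)
  on the hexagonal support |m|+|n|+|m+n| < size, normalized to unit sum.
  The quadratic form and the hexagon are invariant under the bispectral
  symmetry group (transpose, negation-conjugation, shear), so smoothing
  preserves every symmetry of the raw estimate. A "uniform" square window
  and "none" are provided; the square support is *not* shear-invariant, so
  the 12-fold reconstruction property below holds only for the hexagonal
  window or no smoothing.
* **Taper: boxcar** (none) by default; Hann available. Tapering trades
  leakage against peak magnitude and is left off so that QPC magnitudes
  are directly comparable across records.

Estimates store the smoothed field (`values`), the unsmoothed averaged
triple products (`raw_values`) and the segment-averaged power spectrum
(`power`). **Squared bicoherence** b²(ω₁,ω₂) = |B|²/(P(ω₁)P(ω₂)P(ω₁+ω₂))
is computed from the *unsmoothed* field with the matching power spectra
(the normalization is only exact for matching accumulations); entries with
a denominator below machine tolerance are set to 0, and values are clipped
to [0, 1]. For a fully coupled noiseless triad b² = 1 exactly; for white
noise it concentrates near 1/n_segments.

### Symmetries and the reconstruction caveat

The raw estimator satisfies B(ω₂,ω₁) = B(ω₁,ω₂),
B(−ω₁,−ω₂) = B*(ω₁,ω₂) and B(−ω₁−ω₂, ω₂) = B(ω₁,ω₂) to rounding error,
and the principal triangular region 0 ≤ ω₂ ≤ ω₁, ω₁+ω₂ ≤ π determines the
bispectrum through them. On a discrete two-sided grid one caveat applies:
the closure of the principal region under the symmetry group is the
hexagon |ω₁+ω₂| ≤ π (about 3/4 of the square grid). The corner bins —
where the aliased sum frequency wraps past Nyquist — are not related to
the principal triangle by any symmetry; they are genuinely independent
estimator values. `reconstruct_from_principal` therefore returns both the
reconstructed grid and a reachability mask, and the test suite asserts
exact agreement on the reachable set and that the reachable set covers the
hexagon.

## Third-order cumulant module

A diagnostic surface (the production bispectrum path never routes through
it). The biased estimate (divide by N — the standard higher-order-statistics
convention; an unbiased flag divides by the valid-triple count) is computed
on the fundamental wedge 0 ≤ b ≤ a ≤ 2L via FFT cross-correlation of
z = x(k)x(k+a) with x, then the lag square [−L, L]² is filled through the
six-element symmetry group of the cumulant, whose canonical representative
of (τ₁, τ₂) is (max−min, median−min) of {0, τ₁, τ₂}. Symmetry is thus a
construction guarantee, and the valid-triple count is constant along each
orbit, so the unbiased variant is symmetry-consistent too.

## QPC detection

The operational definition of "a QPC" (no standard exists) is: a bin that
is (a) inside the principal region, (b) a strict local maximum of |B| over
its 8-neighborhood, with plateau ties broken toward the lexicographically
smallest bin, (c) ≥ `rel_threshold` (default 0.1) of the region-wide
maximum of |B|, and (d) ≥ `bicoh_floor` (default 0.3) in squared
bicoherence. Magnitude alone scales with the cube of signal amplitude;
the bicoherence floor is the scale-free coupling criterion, and in
white-noise trials it is the binding constraint (median spurious count 0
at the defaults).

Two geometry rules matter near the f₁ = f₂ diagonal:

* Neighbors *outside* the principal region are skipped in (b): they are
  transpose mirror copies of region bins — for a peak at f₂ = f₁ − 1 the
  mirror is an adjacent bin with *exactly* equal magnitude, and comparing
  against it would veto every such coupling.
* (b) and (c) are evaluated on the **unsmoothed** field. Smoothing spreads
  a peak and its mirror across the diagonal; for couplings with
  f₁ − f₂ = 2 their midpoint (an incoherent bin with near-zero
  bicoherence) can exceed both, displacing the maximum. The unsmoothed
  field keeps couplings localized; the bicoherence floor provides the
  noise control that smoothing would otherwise contribute.

Features over the detected peak magnitudes: energy = Σm² (a flag switches
to ∫|B|² over the region), minimum, maximum, mean, and *population*
standard deviation (a single peak must give 0, not NaN). A record with no
peaks yields an all-zero vector flagged degenerate rather than an error,
so the classifier remains total. By default features are computed from the
record-level averaged bispectrum; a per-episode mode emits one vector per
1-second episode instead.

## Extreme learning machine

Single hidden layer, H[k,i] = g(wᵢ·xₖ + bᵢ) with g ∈ {sigmoid, sine,
gaussian, hardlim} (all bounded — no overflow is possible), linear
outputs, one-hot targets, argmax decoding with ties to the lowest class
index. Hidden weights and biases are i.i.d. uniform on [−scale, +scale]
(default scale 1, standard ELM practice; the distribution is otherwise a
free choice) drawn *per neuron* from the seeded generator, so for a fixed
seed an M-neuron network is a prefix of any larger one — training error is
then provably non-increasing in M. Output weights are β̂ = H†Y with H† the
SVD pseudoinverse under the relative cutoff max(N,M)·eps·σ_max;
rank-deficient H yields the minimum-norm least-squares solution. Training
is single-shot; there is no iteration.

Features are z-scored with training-set statistics before training
(default, disableable): QPC energies scale with the sixth power of signal
amplitude and would saturate the sigmoid raw. Default hidden size M = 20;
`grid_search_hidden` picks M ∈ {5, 10, 20, 40, 80} by validation accuracy
when wanted.

## Synthetic data — what it emulates and what it does not

* `gen_triad` builds the canonical QPC test signal: cosines at f₁, f₂,
  f₁+f₂ with the first two phases redrawn uniformly per 1-second block
  (aligned with the default segmentation) and the third phase equal to
  their sum (coupled) or independent (uncoupled), plus white Gaussian
  noise at a stated SNR. Coupled and uncoupled versions are spectrally
  identical; only the bispectrum separates them. The uncoupled peak decays
  as 1/√n_segments, so the coupled/uncoupled ratio at 64 segments is ~9 in
  expectation and a clear order of magnitude needs ≥ 256 segments — the
  suppression tests use 256 segments and a 9-seed paired battery for that
  reason.
* `gen_class_signal` mirrors the reported AF-vs-normal contrast:
  AF-like records superpose three coupled triads with integer bifrequencies
  in the 5–15 Hz band; normal-like records carry one weaker triad near
  (3, 3) ± 1 Hz. The three AF pairs are drawn with all nine component
  frequencies distinct and pairs ≥ 3 bins apart: a component frequency
  shared between two triads (independent phases at one frequency) dilutes
  the bicoherence of both couplings and would make the surrogate's own
  couplings undetectable. Background noise is pink-like (cumulative-sum-
  filtered white noise, demeaned, unit variance) scaled to 10 dB total SNR.
* `gen_dataset` produces the default cohort 25 N + 20 S + 35 T + 50 NORMAL
  (one-minute records, 128 Hz). The N/S/T classes differ by coupling
  amplitude tiers (0.7 / 1.0 / 1.4, jittered ±10 % per record);
  NORMAL uses amplitude 0.4. **The tier mechanism is invented surrogate
  structure**: nothing is known (or claimed) about how AF termination
  classes actually differ bispectrally. Passing the synthetic experiments
  therefore shows that the pipeline recovers known bispectral structure
  end to end — not that these accuracies transfer to recorded ECG, which
  additionally has waveform morphology, nonstationarity and artifacts the
  surrogates do not model.

## Experiment protocol

Records are split 50/50 (configurable) into train/test, stratified per
class and always at the record level — episodes of one record are strongly
dependent, and an episode-level split would leak; the driver asserts that
no record id appears on both sides. Standardization constants come from
the training half only. Accuracy (percent, = 100·trace/n_test) is the
headline metric; per-class recall and the full confusion matrix are always
attached, and with an output directory the features, per-record
predictions, JSON report, config and parameter log are persisted. Reruns
with the same config and cohort are bit-identical.

## Problem sizes used by the test suite and acceptance script

Detector operating characteristics use 200 coupled trials (10 dB SNR, 64
one-second segments) and 200 white-noise trials; cumulant cross-checks use
N ≤ 512, L ≤ 8 against a triple-loop oracle; symmetry checks use 50 random
64-point-grid estimates; the classification experiment uses the full
default cohort over 10 seeds. The whole suite runs in well under a minute
on one CPU.

## Known limitations

* WFDB support covers the header + format-16 subset only (no 212/311/…,
  no multi-segment records); plain CSV is the primary interchange format.
* The bispectrum is estimated on a fixed dyadic grid; couplings between
  bins (non-integer frequencies at the default resolution) smear across
  neighbors and lose bicoherence.
* The aliasing-corner bins of the two-sided grid cannot be reconstructed
  from the principal region (see above); consumers of the full grid should
  use the direct estimate.
* Accuracies reported on surrogates are sanity bounds for the machinery,
  not clinical performance claims.
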