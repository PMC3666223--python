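import numpy as np
import pytest

from bispecg import (
    ConfigurationError,
    DataError,
    ParameterError,
    Signal,
    bicoherence,
    estimate_bispectrum,
    gen_triad,
    principal_region_mask,
    rao_gabr_window,
    reconstruct_from_principal,
)
from bispecg.bispectrum import load_estimate, save_estimate
from oracles import naive_principal_bispectrum

NFFT = 128
FS = 128.0


def region_argmax(estimate):
    mask = principal_region_mask(estimate.nfft, estimate.fs)
    mag = np.where(mask, np.abs(estimate.values), -1.0)
    return np.unravel_index(np.argmax(mag), mag.shape)


class TestTriad:
    def test_coupled_peak_at_bifrequency_matches_oracle(self):
        sig = gen_triad(5.0, 10.0, coupled=True, duration=64.0, snr_db=np.inf, seed=0)
        est = estimate_bispectrum(sig)
        assert est.n_segments == 64
        assert region_argmax(est) == (10, 5)
        oracle = naive_principal_bispectrum(sig.samples, FS, NFFT, NFFT)
        oracle_argmax = max(oracle, key=lambda k: abs(oracle[k]))
        assert oracle_argmax == (10, 5)
        # oracle and production agree bin-by-bin on the unsmoothed field
        errs = [abs(est.raw_values[k] - v) for k, v in oracle.items()]
        assert max(errs) <= 1e-8 * abs(oracle[(10, 5)])

    def test_uncoupled_suppression_order_of_magnitude(self):
        # phases of the sum component decohere across segments; the peak
        # shrinks ~ 1/sqrt(n_segments), so 256 segments put the coupled /
        # uncoupled ratio well above 10 (median over a paired seed battery)
        ratios = []
        for seed in range(9):
            c = estimate_bispectrum(
                gen_triad(5.0, 10.0, True, duration=256.0, snr_db=np.inf, seed=seed)
            )
            u = estimate_bispectrum(
                gen_triad(5.0, 10.0, False, duration=256.0, snr_db=np.inf, seed=seed)
            )
            ratios.append(abs(c.values[10, 5]) / abs(u.values[10, 5]))
        assert np.median(ratios) >= 10.0

    def test_zero_signal_zero_bispectrum(self):
        est = estimate_bispectrum(Signal(np.zeros(1024), FS))
        assert np.all(est.values == 0) and np.all(est.power == 0)


class TestSymmetries:
    @pytest.mark.parametrize("window", ["rao-gabr", "none", "uniform"])
    def test_transpose_and_conjugate(self, rng, window):
        x = rng.standard_normal(512)
        est = estimate_bispectrum(Signal(x, 64.0), nfft=64, window_name=window)
        B = est.values
        scale = np.abs(B).max()
        assert np.abs(B - B.T).max() <= 1e-10 * scale
        neg = (-np.arange(64)) % 64
        assert np.abs(B - np.conj(B[np.ix_(neg, neg)])).max() <= 1e-10 * scale

    @pytest.mark.parametrize("window", ["rao-gabr", "none"])
    def test_principal_region_determines_hexagon(self, rng, window):
        est = estimate_bispectrum(Signal(rng.standard_normal(640), 64.0),
                                  nfft=64, window_name=window)
        rec, known = reconstruct_from_principal(est)
        f = est.freqs
        K1, K2 = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        hexagon = np.abs(f[K1] + f[K2]) <= est.fs / 2.0
        assert known[hexagon].all()
        scale = np.abs(est.values).max()
        assert np.abs(rec[known] - est.values[known]).max() <= 1e-10 * scale

    def test_cubic_scaling(self, rng):
        x = rng.standard_normal(512)
        a = estimate_bispectrum(Signal(x, 64.0), nfft=64).values
        b = estimate_bispectrum(Signal(3.0 * x, 64.0), nfft=64).values
        assert np.abs(b - 27.0 * a).max() <= 1e-10 * np.abs(b).max()

    def test_segment_averaging_reduces_noise_level(self):
        # mean |B| over the principal region falls as segments accumulate
        mask = principal_region_mask(NFFT, FS)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(128 * NFFT)
            few = estimate_bispectrum(Signal(x[: 8 * NFFT], FS))
            many = estimate_bispectrum(Signal(x, FS))
            assert np.abs(many.values)[mask].mean() < np.abs(few.values)[mask].mean()


class TestBicoherence:
    def test_fully_coupled_triad_near_one(self):
        sig = gen_triad(5.0, 10.0, True, duration=64.0, snr_db=np.inf, seed=1)
        b2 = bicoherence(estimate_bispectrum(sig))
        assert b2[10, 5] >= 0.95
        assert b2.min() >= 0.0 and b2.max() <= 1.0

    def test_white_noise_null_level(self):
        rng = np.random.default_rng(42)
        sig = Signal(rng.standard_normal(128 * NFFT), FS)  # 128 segments
        est = estimate_bispectrum(sig)
        mask = principal_region_mask(NFFT, FS)
        assert np.percentile(bicoherence(est)[mask], 95) < 0.25

    def test_zero_bispectrum_gives_zero_matrix(self):
        est = estimate_bispectrum(Signal(np.zeros(1024), FS))
        assert np.array_equal(bicoherence(est), np.zeros((NFFT, NFFT)))


class TestValidation:
    def test_bad_nfft(self):
        with pytest.raises(ParameterError):
            estimate_bispectrum(Signal(np.zeros(256), FS), nfft=100)

    def test_unknown_window(self):
        with pytest.raises(ConfigurationError):
            estimate_bispectrum(Signal(np.zeros(256), FS), window_name="hamming2d")

    def test_record_shorter_than_segment(self):
        with pytest.raises(DataError):
            estimate_bispectrum(Signal(np.zeros(64), FS), nfft=128, segment_samples=128)

    def test_rao_gabr_window_properties(self):
        w = rao_gabr_window(5)
        assert w.shape == (5, 5)
        assert w.sum() == pytest.approx(1.0)
        assert np.array_equal(w, w.T)
        assert np.array_equal(w, w[::-1, ::-1])  # point symmetry

    def test_estimate_round_trips_through_archive(self, tmp_path, rng):
        est = estimate_bispectrum(Signal(rng.standard_normal(512), 64.0), nfft=64)
        save_estimate(tmp_path / "b.npz", est)
        back = load_estimate(tmp_path / "b.npz")
        assert np.array_equal(back.values, est.values)
        assert back.window_name == est.window_name and back.fs == est.fs
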