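import numpy as np
import pytest
from scipy.signal import get_window

from gammacoh.coherence import (
    band_mean_z,
    band_z,
    coherogram,
    msc,
    shuffle_surrogate,
    shuffled_psd_identical,
    z_transform,
    z_transform_alt,
)
from gammacoh.synth import generate_recording

from conftest import coupled_pair_config

FS = 1024.0


def naive_msc(x, y, fs, nfft, overlap=0.5):
    """Brute-force oracle: direct-DFT block spectra, then the MSC formula."""
    w = get_window("hann", nfft)
    step = nfft - int(round(nfft * overlap))
    n_blocks = 1 + (len(x) - nfft) // step
    n = np.arange(nfft)
    K = nfft // 2 + 1
    X = np.zeros((n_blocks, K), complex)
    Y = np.zeros((n_blocks, K), complex)
    for b in range(n_blocks):
        for k in range(K):
            e = np.exp(-2j * np.pi * k * n / nfft)
            X[b, k] = np.sum(w * x[b * step : b * step + nfft] * e)
            Y[b, k] = np.sum(w * y[b * step : b * step + nfft] * e)
    sxy = (X * np.conj(Y)).mean(axis=0)
    return np.abs(sxy) ** 2 / ((np.abs(X) ** 2).mean(axis=0) *
                               (np.abs(Y) ** 2).mean(axis=0))


class TestMsc:
    def test_self_coherence_is_one(self, rng):
        x = rng.standard_normal(8192)
        prof = msc(x, x, FS)
        assert np.allclose(prof.msc, 1.0, atol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        nfft = 64
        x = rng.standard_normal(4 * nfft)
        y = rng.standard_normal(4 * nfft)
        prof = msc(x, y, FS, nfft=nfft, overlap=0.0)
        oracle = naive_msc(x, y, FS, nfft, overlap=0.0)
        assert np.allclose(prof.msc, oracle, rtol=1e-9, atol=1e-12)

    def test_symmetry_and_scaling_invariance(self, rng):
        x = rng.standard_normal(8192)
        y = rng.standard_normal(8192)
        m1 = msc(x, y, FS).msc
        m2 = msc(y, x, FS).msc
        m3 = msc(3.7 * x, -0.2 * y, FS).msc
        assert np.allclose(m1, m2, atol=1e-12)
        assert np.allclose(m1, m3, atol=1e-9)

    def test_independent_noise_bias_near_1_over_L(self, rng):
        # smaller sibling of the acceptance check: 20 seeds, L=50 blocks
        L, nfft = 50, 2048
        vals = []
        for _ in range(20):
            x = rng.standard_normal(L * nfft)
            y = rng.standard_normal(L * nfft)
            prof = msc(x, y, FS, nfft=nfft, overlap=0.0)
            band = (prof.freqs >= 30) & (prof.freqs <= 45)
            vals.append(prof.msc[band].mean())
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 1 / L) <= 3 * se + 1e-4

    def test_common_source_snr_closed_form(self, rng):
        # y and x share a source with per-channel SNR 1 -> MSC = 0.25 in band
        n = int(400 * FS)
        s = rng.standard_normal(n)
        x = s + rng.standard_normal(n)
        y = s + rng.standard_normal(n)
        prof = msc(x, y, FS)
        band = (prof.freqs >= 30) & (prof.freqs <= 45)
        assert prof.msc[band].mean() == pytest.approx(0.25, abs=0.02)

    def test_length_mismatch_and_short_input(self, rng):
        with pytest.raises(ValueError):
            msc(rng.standard_normal(4096), rng.standard_normal(4097), FS)
        with pytest.raises(ValueError):
            msc(np.zeros(2048), np.zeros(2048), FS)  # single block


class TestZTransform:
    def test_zero_maps_to_zero(self):
        assert z_transform(0.0) == 0.0

    def test_formula_value(self):
        expected = 0.5 * np.log((1 + np.sqrt(0.75)) / (1 - np.sqrt(0.75)))
        assert z_transform(0.75) == pytest.approx(expected, rel=1e-12)

    def test_strictly_increasing(self):
        v = np.linspace(0, 0.999, 200)
        assert np.all(np.diff(z_transform(v)) > 0)

    def test_unity_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            z = z_transform(1.0)
        assert np.isfinite(z) and z > 10

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            z_transform(-0.1)
        with pytest.raises(ValueError):
            z_transform(1.5)

    def test_alternative_convention_available(self):
        assert z_transform_alt(0.5) == pytest.approx(np.arctanh(0.5))


class TestBandMeanZ:
    def test_constant_profile_any_band(self, rng):
        x = rng.standard_normal(16384)
        prof = msc(x, x, FS)
        prof.msc = np.full_like(prof.msc, 0.5)
        expected = np.arctanh(np.sqrt(0.5))
        assert band_mean_z(prof, (30, 45)) == pytest.approx(expected)
        assert band_mean_z(prof, (5, 20)) == pytest.approx(expected)

    def test_inclusive_half_hz_grid_has_31_points(self, rng):
        x = rng.standard_normal(16384)
        prof = msc(x, x, FS)
        m = (prof.freqs >= 30.0) & (prof.freqs <= 45.0)
        assert m.sum() == 31

    def test_inverted_band_rejected(self, rng):
        x = rng.standard_normal(8192)
        with pytest.raises(ValueError):
            band_mean_z(msc(x, x, FS), (45, 30))

    def test_synthetic_coupling_recovered_within_oracle(self):
        from gammacoh.synth import expected_band_msc

        cfg = coupled_pair_config(coupling=0.75, dur_s=600.0, seed=4)
        rec, _, _ = generate_recording(cfg)
        prof = msc(rec.samples[0], rec.samples[1], rec.fs)
        band = (prof.freqs >= 30) & (prof.freqs <= 45)
        est = prof.msc[band].mean()
        oracle = expected_band_msc(cfg.per_state["AW"])
        assert abs(est - oracle) <= 0.05


class TestCoherogram:
    def test_stationary_pair_is_flat(self):
        cfg = coupled_pair_config(coupling=0.8, dur_s=400.0, seed=5)
        rec, _, _ = generate_recording(cfg)
        coh = coherogram(rec.samples[0], rec.samples[1], rec.fs,
                         seg_s=100.0, step_s=50.0)
        band = (coh.freqs >= 30) & (coh.freqs <= 45)
        series = coh.z[:, band].mean(axis=1)
        assert series.max() - series.min() < 0.25 * series.mean()

    def test_coupling_step_detected(self):
        # coupling drops 0.8 -> 0.05 mid-recording (ketamine-like switch)
        from gammacoh.synth import SyntheticConfig, SyntheticStateParams

        hi = SyntheticStateParams("AW", burst_rate=1.5, burst_amp=25.0,
                                  coupling_fraction=0.8, jitter_ms=0.0,
                                  amp_scatter=0.0)
        lo = SyntheticStateParams("K15", burst_rate=1.5, burst_amp=25.0,
                                  coupling_fraction=0.05, jitter_ms=0.0,
                                  amp_scatter=0.0)
        cfg = SyntheticConfig(per_state={"AW": hi, "K15": lo},
                              state_sequence=[("AW", 300.0), ("K15", 300.0)],
                              seed=6)
        rec, _, _ = generate_recording(cfg)
        coh = coherogram(rec.samples[0], rec.samples[1], rec.fs,
                         seg_s=100.0, step_s=100.0)
        band = (coh.freqs >= 30) & (coh.freqs <= 45)
        series = coh.z[:, band].mean(axis=1)
        before = series[coh.times < 300.0]
        after = series[coh.times > 300.0]
        assert before.min() > 5 * after.std() + after.max()

    def test_nonpositive_step_rejected(self, rng):
        x = rng.standard_normal(int(200 * FS))
        with pytest.raises(ValueError):
            coherogram(x, x, FS, step_s=0.0)

    def test_timestamps_are_segment_centers(self, rng):
        x = rng.standard_normal(int(220 * FS))
        coh = coherogram(x, x, FS, seg_s=100.0, step_s=10.0)
        assert coh.times[0] == pytest.approx(50.0)
        assert coh.times[1] == pytest.approx(60.0)


class TestShuffleSurrogate:
    def test_psd_exactly_invariant_under_block_shuffle(self, rng):
        y = rng.standard_normal(int(100 * FS))
        assert shuffled_psd_identical(y, FS, rng=rng) == 0.0

    def test_identity_permutation_preserves_observed(self):
        cfg = coupled_pair_config(coupling=0.8, dur_s=150.0, seed=7)
        rec, _, _ = generate_recording(cfg)
        x, y = rec.samples
        res = shuffle_surrogate(x, y, rec.fs, n_shuffles=5, rng=0)
        # observed equals the non-overlapping-block band z' computed directly
        obs2 = shuffle_surrogate(x, y, rec.fs, n_shuffles=5, rng=1).observed_z
        assert res.observed_z == pytest.approx(obs2, rel=1e-12)

    def test_coupled_pair_beats_null(self):
        cfg = coupled_pair_config(coupling=0.8, dur_s=150.0, seed=8)
        rec, _, _ = generate_recording(cfg)
        res = shuffle_surrogate(rec.samples[0], rec.samples[1], rec.fs,
                                n_shuffles=100, rng=0)
        assert res.observed_z > res.null_z.max()
        assert res.quantile == 1.0

    def test_uncoupled_pair_within_null(self, rng):
        x = rng.standard_normal(int(100 * FS))
        y = rng.standard_normal(int(100 * FS))
        res = shuffle_surrogate(x, y, FS, n_shuffles=100, rng=2)
        assert res.quantile < 1.0

    def test_invalid_arguments(self, rng):
        x = rng.standard_normal(int(10 * FS))
        with pytest.raises(ValueError):
            shuffle_surrogate(x, x, FS, n_shuffles=0)
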