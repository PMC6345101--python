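import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gammacoh.io import Event
from gammacoh.preprocess import (
    CapacityError,
    design_fir_bandpass,
    envelope,
    fir_bandpass,
    flag_artifacts,
    select_windows,
)
from gammacoh.synth import generate_burst

from conftest import make_annotation

FS = 1024.0


class TestSelectWindows:
    def test_twelve_windows_total_1200s(self, rng):
        ann = make_annotation([("REM", 1500.0)])
        ws = select_windows(ann, "REM", n=12, dur=100.0, rng=rng)
        assert len(ws) == 12
        assert sum(w.duration for w in ws) == pytest.approx(1200.0)

    def test_absent_state_raises_capacity_error(self, rng):
        ann = make_annotation([("AW", 500.0)])
        with pytest.raises(CapacityError, match="REM"):
            select_windows(ann, "REM", rng=rng)

    def test_insufficient_time_raises_with_available_seconds(self, rng):
        ann = make_annotation([("REM", 600.0)])
        with pytest.raises(CapacityError, match="600"):
            select_windows(ann, "REM", n=12, rng=rng)

    def test_stimulus_exclusion_interval(self, rng):
        ann = make_annotation([("K15", 3000.0)],
                              events=[Event(1000.0, "sound_on")])
        ws = select_windows(ann, "K15", n=12, dur=100.0,
                            stimulus_exclusion=300.0, rng=rng)
        for w in ws:
            assert w.end <= 700.0 or w.start >= 1300.0

    def test_artifact_interval_excluded(self, rng):
        ann = make_annotation([("NREM", 2000.0)],
                              events=[Event(500.0, "artifact_start"),
                                      Event(650.0, "artifact_end")])
        ws = select_windows(ann, "NREM", n=12, dur=100.0, rng=rng)
        for w in ws:
            assert w.end <= 500.0 or w.start >= 650.0

    def test_deterministic_given_rng_state(self):
        ann = make_annotation([("QW", 2000.0)])
        w1 = select_windows(ann, "QW", rng=np.random.default_rng(11))
        w2 = select_windows(ann, "QW", rng=np.random.default_rng(11))
        assert w1 == w2

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.tuples(st.sampled_from(["AW", "QW", "REM"]),
                              st.integers(10, 60).map(lambda v: 10.0 * v)),
                    min_size=1, max_size=6),
           st.integers(0, 2 ** 31 - 1))
    def test_windows_never_overlap_and_respect_state_runs(self, blocks, seed):
        ann = make_annotation(blocks)
        rng = np.random.default_rng(seed)
        state = blocks[0][0]
        runs = ann.state_runs(state)
        n = min(3, sum(int((e - s) // 100.0) for s, e in runs))
        if n == 0:
            with pytest.raises(CapacityError):
                select_windows(ann, state, n=1, dur=100.0, rng=rng)
            return
        ws = select_windows(ann, state, n=n, dur=100.0, rng=rng)
        ws = sorted(ws, key=lambda w: w.start)
        for a, b in zip(ws, ws[1:]):
            assert a.end <= b.start + 1e-9
        for w in ws:
            assert any(s - 1e-9 <= w.start and w.end <= e + 1e-9
                       for s, e in runs)


class TestFirBandpass:
    def _gain(self, freq, fs=FS, dur=4.0):
        t = np.arange(int(dur * fs)) / fs
        x = np.sin(2 * np.pi * freq * t)
        y = fir_bandpass(x, fs)
        core = slice(int(fs), int((dur - 1) * fs))  # skip edges
        return np.max(np.abs(y[core]))

    def test_passband_within_1db(self):
        for f in (33.0, 37.0, 43.0):
            assert 0.89 <= self._gain(f) <= 1.12

    def test_stopband_attenuation(self):
        assert self._gain(10.0) <= 0.01
        assert self._gain(60.0) <= 0.01

    def test_zero_input_zero_output(self):
        y = fir_bandpass(np.zeros(4096), FS)
        assert not y.any() and len(y) == 4096

    def test_output_length_preserved(self, rng):
        x = rng.standard_normal(5000)
        assert fir_bandpass(x, FS).shape == x.shape

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            design_fir_bandpass(64.0, 30.0, 45.0)

    def test_out_of_band_energy_below_1pct_white_noise(self, rng):
        x = rng.standard_normal(int(60 * FS))
        y = fir_bandpass(x, FS)
        spec = np.abs(np.fft.rfft(y)) ** 2
        f = np.fft.rfftfreq(len(y), 1 / FS)
        out_band = spec[(f < 25.0) | (f > 50.0)].sum()
        assert out_band / spec.sum() <= 0.01

    def test_zero_phase_no_lag_on_burst(self):
        # symmetric-FIR application must not shift the burst peak
        x = np.zeros(int(4 * FS))
        w = generate_burst(0.3, 25.0, 37.0, FS)
        k0 = int(2 * FS)
        x[k0 : k0 + len(w)] += w
        y = fir_bandpass(x, FS)
        env_in = np.abs(x)
        lag = abs(int(np.argmax(np.abs(y))) - int(np.argmax(env_in)))
        assert lag <= int(0.015 * FS)


class TestEnvelope:
    def test_analytic_recovers_constant_amplitude(self):
        t = np.arange(int(4 * FS)) / FS
        x = 3.0 * np.sin(2 * np.pi * 40.0 * t)
        env = envelope(x, FS, method="analytic")
        core = slice(int(FS), int(3 * FS))
        assert np.allclose(env[core], 3.0, rtol=0.01)

    def test_zero_signal_zero_envelope(self):
        for method in ("analytic", "rectify_smooth"):
            assert not envelope(np.zeros(2048), FS, method=method).any()

    def test_burst_envelope_peak_and_support(self):
        x = np.zeros(int(4 * FS))
        w = generate_burst(0.3, 25.0, 37.0, FS)
        k0 = int(2 * FS)
        x[k0 : k0 + len(w)] += w
        env = envelope(x, FS, method="analytic")
        assert abs(env.max() - 25.0) / 25.0 < 0.10
        above = np.flatnonzero(env > 2.5)
        assert above[0] / FS > 2.0 - 0.05
        assert above[-1] / FS < 2.3 + 0.05

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            envelope(np.zeros(128), FS, method="magic")

    def test_envelope_nonnegative(self, rng):
        x = rng.standard_normal(4096)
        for method in ("analytic", "rectify_smooth"):
            assert (envelope(x, FS, method=method) >= 0).all()


class TestArtifactFlagger:
    def test_flags_large_amplitude_interval(self):
        from gammacoh.io import ChannelInfo, MultichannelRecording

        x = np.zeros((1, int(10 * FS)))
        x[0, int(4 * FS) : int(5 * FS)] = 800.0
        rec = MultichannelRecording(fs=FS, samples=x,
                                    channels=[ChannelInfo("Pf-r", "Pf", "r")])
        flags = flag_artifacts(rec)
        assert len(flags) == 1
        s, e = flags[0]
        assert s < 4.0 < 5.0 < e

    def test_clean_signal_unflagged(self, rng):
        from gammacoh.io import ChannelInfo, MultichannelRecording

        x = 30 * rng.standard_normal((1, int(5 * FS)))
        rec = MultichannelRecording(fs=FS, samples=x,
                                    channels=[ChannelInfo("Pf-r", "Pf", "r")])
        assert flag_artifacts(rec) == []
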