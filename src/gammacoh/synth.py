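"""Synthetic multichannel EEG with known cross-cortical gamma coupling.

The generator emulates monopolar cortical EEG sampled at 1,024 Hz in which
low-gamma (30-45 Hz) "bursts" -- amplitude-modulated oscillation packets of
200-500 ms and roughly 25 uV -- ride on band-limited background noise.
Cross-channel coupling is controlled by a single dial per behavioral state:
``coupling_fraction`` is the fraction of the per-channel burst rate that is
driven by a source shared across all channels (each channel receives a
jittered, amplitude-scattered copy), the remainder being independent
per-channel bursts.  Slow waves, a beta peak and elevated >45 Hz content are
extra band-noise components used by the NREM and ketamine presets.

Because shared and independent bursts have identical spectra, the two-channel
mixing model has a closed-form band coherence,

    MSC = ( S / (S + N) )**2 ,

with S the shared and N the independent in-band power, which
:func:`expected_band_msc` evaluates from the state parameters.  This is the
oracle against which the downstream Welch coherence estimator is validated.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.signal.windows import hann

from .io import (
    ChannelInfo,
    Epoch,
    Event,
    MultichannelRecording,
    StateAnnotation,
)

STATE_LABELS = ("AW", "QW", "NREM", "REM", "K5", "K10", "K15")

#: Analysis band of interest (Hz); presets concentrate burst carriers here.
GAMMA_BAND = (30.0, 45.0)

#: Mean power fraction of a Hann-enveloped sinusoid: mean(hann^2) * mean(sin^2).
_HANN_SIN_POWER = 3.0 / 16.0


class ConfigError(ValueError):
    pass


@dataclass
class SyntheticStateParams:
    """Generative parameters for one behavioral/pharmacological state.

    Parameters
    ----------
    burst_rate : float
        Gamma bursts per second per channel.
    burst_amp : float
        Peak burst amplitude in uV (center of the modeled range).
    burst_dur_range : (float, float)
        Burst duration range in ms.
    coupling_fraction : float in [0, 1]
        Fraction of the burst rate driven by the shared source.
    background_spec : list of ((lo_hz, hi_hz), power_uv2)
        Band-limited Gaussian background components; ``power_uv2`` is the
        variance contributed by that component.
    slow_wave_amp : float
        Peak-ish amplitude (uV) of 0.5-4 Hz slow waves (NREM / ketamine);
        realized as band noise of variance ``amp**2 / 2``.
    beta_peak : (center_hz, power_uv2) or None
        Narrow beta-band component (ketamine signature).
    high_gamma_gain : float
        Multiplier on a 45-60 Hz noise component whose base power equals the
        in-band burst power (ketamine's broadened gamma); 0 disables it.
    jitter_ms : float
        Shared-burst copies are shifted per channel by U(-jitter, +jitter) ms.
    amp_scatter : float
        Relative SD of per-channel amplitude scatter on shared-burst copies.
    carrier_range : (float, float)
        Burst carrier frequency drawn uniformly from this range (Hz).
    """

    state_label: str
    burst_rate: float = 1.0
    burst_amp: float = 25.0
    burst_dur_range: tuple[float, float] = (200.0, 500.0)
    coupling_fraction: float = 0.5
    background_spec: list = field(default_factory=list)
    slow_wave_amp: float = 0.0
    beta_peak: tuple[float, float] | None = None
    high_gamma_gain: float = 0.0
    jitter_ms: float = 2.0
    amp_scatter: float = 0.1
    carrier_range: tuple[float, float] = (35.0, 40.0)

    def __post_init__(self):
        if not 0.0 <= self.coupling_fraction <= 1.0:
            raise ConfigError("coupling_fraction must be in [0, 1]")
        lo, hi = self.burst_dur_range
        if not (0 < lo <= hi <= 2000):
            raise ConfigError("burst_dur_range must lie in (0, 2000] ms, min<=max")
        if self.burst_rate < 0 or self.burst_amp < 0:
            raise ConfigError("rates and amplitudes must be >= 0")
        for (lo_f, hi_f), p in self.background_spec:
            if p < 0 or lo_f < 0 or hi_f <= lo_f:
                raise ConfigError("invalid background_spec entry")
        if self.slow_wave_amp < 0 or self.high_gamma_gain < 0:
            raise ConfigError("powers must be >= 0")

    def effective_background(self) -> list[tuple[tuple[float, float], float]]:
        """Full background component list including slow-wave/beta/high-gamma."""
        comps = [((float(lo), float(hi)), float(p))
                 for (lo, hi), p in self.background_spec]
        if self.slow_wave_amp > 0:
            comps.append(((0.5, 4.0), self.slow_wave_amp ** 2 / 2.0))
        if self.beta_peak is not None:
            c, p = self.beta_peak
            comps.append(((c - 2.0, c + 2.0), float(p)))
        if self.high_gamma_gain > 0:
            comps.append(((45.0, 60.0),
                          self.high_gamma_gain * self.burst_band_power()))
        return comps

    def burst_band_power(self) -> float:
        """Expected in-band power (uV^2) contributed by the burst stream."""
        mean_dur_s = 0.5 * (self.burst_dur_range[0] + self.burst_dur_range[1]) / 1e3
        return self.burst_rate * _HANN_SIN_POWER * self.burst_amp ** 2 * mean_dur_s


@dataclass
class SyntheticConfig:
    fs: float = 1024.0
    n_channels: int = 2
    channel_sites: list = field(default_factory=lambda: ["Pf-r", "Pp-r"])
    per_state: dict = field(default_factory=dict)
    state_sequence: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 0:
            raise ConfigError("fs must be positive")
        if len(self.channel_sites) != self.n_channels:
            raise ConfigError("channel_sites must match n_channels")
        for state, dur in self.state_sequence:
            if dur <= 0:
                raise ConfigError("state durations must be positive")
            if state not in self.per_state:
                raise ConfigError(f"state {state!r} has no parameters")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        per_state = {}
        for k, v in d.get("per_state", {}).items():
            v = dict(v)
            for key in ("burst_dur_range", "carrier_range"):
                if key in v and v[key] is not None:
                    v[key] = tuple(v[key])
            if v.get("beta_peak") is not None:
                v["beta_peak"] = tuple(v["beta_peak"])
            v["background_spec"] = [
                ((float(b[0][0]), float(b[0][1])), float(b[1]))
                for b in v.get("background_spec", [])
            ]
            per_state[k] = SyntheticStateParams(**v)
        d["per_state"] = per_state
        d["state_sequence"] = [(s, float(t)) for s, t in d.get("state_sequence", [])]
        return cls(**d)


@dataclass
class GroundTruth:
    """Per-channel burst inventory plus the oracle band coherence per state."""

    burst_times: list  # per channel: list of (onset_s, duration_s, shared)
    expected_band_msc: dict  # state -> MSC in [0, 1]

    def to_json(self, path):
        payload = {
            "burst_times": [[(float(o), float(d), bool(s)) for o, d, s in ch]
                            for ch in self.burst_times],
            "expected_band_msc": {k: float(v)
                                  for k, v in self.expected_band_msc.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# Presets.  Chosen to encode the qualitative state contrast: cross-channel
# coupling high in alert wakefulness, intermediate in quiet wakefulness and
# NREM, near-absent in REM and after 15 mg/kg ketamine, with in-band gamma
# power comparable across QW, REM and ketamine, maximal in AW and minimal in
# NREM.  Rates are free parameters (no quantitative per-state burst rate is
# established for this preparation); see the methods note.

def state_presets() -> dict[str, SyntheticStateParams]:
    gamma_bg = lambda p: [((30.0, 45.0), p)]

    def P(label, rate, amp, coupling, bg, **kw):
        return SyntheticStateParams(
            state_label=label, burst_rate=rate, burst_amp=amp,
            coupling_fraction=coupling, background_spec=gamma_bg(bg), **kw)

    return {
        "AW": P("AW", 2.0, 25.0, 0.80, 10.0),
        "QW": P("QW", 1.2, 18.0, 0.45, 8.0),
        "NREM": P("NREM", 0.8, 15.0, 0.35, 6.0, slow_wave_amp=150.0),
        "REM": P("REM", 1.2, 18.0, 0.05, 8.0),
        "K5": P("K5", 1.2, 18.0, 0.30, 8.0, slow_wave_amp=80.0,
                beta_peak=(20.0, 10.0), high_gamma_gain=0.5),
        "K10": P("K10", 1.2, 18.0, 0.15, 8.0, slow_wave_amp=90.0,
                 beta_peak=(20.0, 12.0), high_gamma_gain=0.7),
        "K15": P("K15", 1.2, 18.0, 0.05, 8.0, slow_wave_amp=100.0,
                 beta_peak=(20.0, 15.0), high_gamma_gain=1.0),
    }


def default_config(states=("AW", "QW", "NREM", "REM", "K15"),
                   dur_per_state: float = 1300.0, seed: int = 0,
                   n_channels: int = 2) -> SyntheticConfig:
    """A study-sized session: each requested state long enough for twelve
    non-overlapping 100-s analysis windows."""
    sites = ["Pf-r", "Pp-r", "S1-r", "V1-r"][:n_channels]
    return SyntheticConfig(
        fs=1024.0, n_channels=n_channels, channel_sites=sites,
        per_state=state_presets(),
        state_sequence=[(s, dur_per_state) for s in states],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Primitive generators

def generate_burst(dur: float, amp: float, carrier_freq: float, fs: float,
                   phase: float = 0.0) -> np.ndarray:
    """A Hann-enveloped sinusoidal gamma burst.

    The waveform is rescaled so its peak absolute value equals ``amp``
    exactly; the Hann envelope forces zero endpoints and a smooth unimodal
    shape, keeping spectral energy concentrated around ``carrier_freq``.
    """
    if dur <= 0 or fs <= 0:
        raise ValueError("duration and fs must be positive")
    n = int(round(dur * fs))
    if n < 3:
        raise ValueError("burst too short for the sampling rate")
    t = np.arange(n) / fs
    w = hann(n, sym=True) * np.sin(2 * np.pi * carrier_freq * t + phase)
    peak = np.max(np.abs(w))
    if amp == 0 or peak == 0:
        return np.zeros(n)
    return amp / peak * w


def band_noise(n: int, fs: float, lo: float, hi: float, power: float,
               rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise strictly band-limited to [lo, hi] Hz with realized
    variance equal to ``power`` (normalized per segment)."""
    if power <= 0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    mask = (freqs >= lo) & (freqs <= min(hi, fs / 2))
    if not mask.any():
        return np.zeros(n)
    coef = np.zeros(len(freqs), dtype=complex)
    m = int(mask.sum())
    coef[mask] = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    x = np.fft.irfft(coef, n)
    sd = x.std()
    if sd == 0:
        return np.zeros(n)
    return x * (np.sqrt(power) / sd)


def _place(sig: np.ndarray, wave: np.ndarray, start_idx: int):
    n = len(sig)
    i0 = max(start_idx, 0)
    i1 = min(start_idx + len(wave), n)
    if i1 > i0:
        sig[i0:i1] += wave[i0 - start_idx : i1 - start_idx]


def _state_segment(params: SyntheticStateParams, dur_s: float, n_ch: int,
                   fs: float, rng: np.random.Generator):
    """Generate one state's segment; returns (samples, per-channel bursts)."""
    n = int(round(dur_s * fs))
    out = np.zeros((n_ch, n))
    bursts: list[list[tuple[float, float, bool]]] = [[] for _ in range(n_ch)]

    for (lo, hi), p in params.effective_background():
        for ch in range(n_ch):
            out[ch] += band_noise(n, fs, lo, hi, p, rng)

    max_dur_s = params.burst_dur_range[1] / 1e3
    jit = params.jitter_ms / 1e3

    def draw_burst():
        d = rng.uniform(*params.burst_dur_range) / 1e3
        f = rng.uniform(*params.carrier_range)
        ph = rng.uniform(0, 2 * np.pi)
        return d, f, ph

    # shared bursts: one source, copied to every channel with jitter/scatter
    n_shared = rng.poisson(params.burst_rate * params.coupling_fraction * dur_s)
    for _ in range(n_shared):
        onset = rng.uniform(0, max(dur_s - max_dur_s, 1e-3))
        d, f, ph = draw_burst()
        wave = generate_burst(d, 1.0, f, fs, ph)
        for ch in range(n_ch):
            tau = rng.uniform(-jit, jit) if jit > 0 else 0.0
            a = params.burst_amp
            if params.amp_scatter > 0:
                a = max(a * (1 + params.amp_scatter * rng.standard_normal()), 0.0)
            _place(out[ch], a * wave, int(round((onset + tau) * fs)))
            bursts[ch].append((onset + tau, d, True))

    # independent bursts per channel
    indep_rate = params.burst_rate * (1 - params.coupling_fraction)
    for ch in range(n_ch):
        for _ in range(rng.poisson(indep_rate * dur_s)):
            onset = rng.uniform(0, max(dur_s - max_dur_s, 1e-3))
            d, f, ph = draw_burst()
            _place(out[ch], generate_burst(d, params.burst_amp, f, fs, ph),
                   int(round(onset * fs)))
            bursts[ch].append((onset, d, False))

    for ch in range(n_ch):
        bursts[ch].sort()
    return out, bursts


def generate_recording(config: SyntheticConfig):
    """Synthesize a full session.

    Returns ``(recording, annotation, ground_truth)``.  The annotation holds
    10-s epochs consistent with the state sequence and an ``injection`` event
    at the start of each ketamine segment.  Identical configs (including the
    seed) give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    seg_arrays = []
    epochs: list[Epoch] = []
    events: list[Event] = []
    all_bursts: list[list[tuple[float, float, bool]]] = [
        [] for _ in range(config.n_channels)]
    t0 = 0.0
    for state, dur in config.state_sequence:
        params = config.per_state[state]
        seg, bursts = _state_segment(params, dur, config.n_channels, fs, rng)
        seg_arrays.append(seg)
        n_ep = int(dur // 10.0)
        for k in range(n_ep):
            epochs.append(Epoch(t0 + 10.0 * k, 10.0, state))
        rem = dur - 10.0 * n_ep
        if rem > 1e-9:
            epochs.append(Epoch(t0 + 10.0 * n_ep, rem, state))
        if state.startswith("K"):
            events.append(Event(t0, "injection", state))
        for ch in range(config.n_channels):
            all_bursts[ch].extend((t0 + o, d, s) for o, d, s in bursts[ch])
        t0 += dur

    samples = np.concatenate(seg_arrays, axis=1) if seg_arrays else \
        np.zeros((config.n_channels, 0))
    channels = [ChannelInfo.from_label(name) for name in config.channel_sites]
    rec = MultichannelRecording(fs=fs, samples=samples, channels=channels)
    ann = StateAnnotation(epochs=epochs, events=events)
    gt = GroundTruth(
        burst_times=all_bursts,
        expected_band_msc={s: expected_band_msc(p)
                           for s, p in config.per_state.items()},
    )
    return rec, ann, gt


def expected_band_msc(params: SyntheticStateParams,
                      band: tuple[float, float] = GAMMA_BAND) -> float:
    """Closed-form band coherence of the two-channel mixing model.

    With shared in-band power ``S = coupling * P_burst`` and independent
    in-band power ``N = (1-coupling) * P_burst + P_background(band)`` per
    channel, the magnitude-squared coherence is ``(S / (S+N))**2``.  The
    formula assumes zero jitter and zero amplitude scatter and is therefore
    an upper bound when either is positive (jitter rotates, scatter dilutes,
    the cross-spectral phase alignment).
    """
    p_burst = params.burst_band_power()
    s = params.coupling_fraction * p_burst
    n = (1 - params.coupling_fraction) * p_burst
    lo, hi = band
    for (b_lo, b_hi), p in params.effective_background():
        overlap = max(0.0, min(hi, b_hi) - max(lo, b_lo))
        if b_hi > b_lo:
            n += p * overlap / (b_hi - b_lo)
    if s == 0:
        return 0.0
    if n == 0:
        return 1.0
    return float((s / (s + n)) ** 2)


def jitter_attenuation(freq_hz: float, jitter_s: float) -> float:
    """Expected cross-spectral amplitude factor per channel for uniform
    timing jitter on [-jitter_s, +jitter_s]: sinc(2*f*jitter)."""
    if jitter_s <= 0:
        return 1.0
    x = 2 * np.pi * freq_hz * jitter_s
    return float(np.sin(x) / x)
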