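"""Gamma-burst detection and burst-triggered averaging.

A burst is a maximal run where the gamma envelope exceeds its window mean by
``thresh_sd`` standard deviations for at least ``min_dur`` ms; the trigger is
the extremum of the band-passed trace inside the run (the peak of the wave
with the greatest amplitude).  The triggered average aligns randomly chosen
bursts at their triggers -- polarity-corrected so the trigger extremum is
positive -- revealing the stereotyped burst waveform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class BurstEvent:
    channel: str
    trigger_time: float
    onset: float
    offset: float
    peak_amp: float

    def __post_init__(self):
        if not (self.onset <= self.trigger_time <= self.offset):
            raise ValueError("trigger must lie within [onset, offset]")
        if self.peak_amp <= 0:
            raise ValueError("peak amplitude must be positive")


@dataclass
class BurstAverage:
    waveform: np.ndarray  # length 2*half_window*fs + 1, centered on trigger
    times: np.ndarray  # seconds relative to trigger
    n_bursts: int
    channel: str


def detect_bursts(env: np.ndarray, filtered: np.ndarray, fs: float,
                  thresh_sd: float = 2.0, min_dur_ms: float = 100.0,
                  channel: str = "") -> list[BurstEvent]:
    """Threshold-crossing burst detector on the gamma envelope.

    Threshold statistics (mean + ``thresh_sd`` * SD) are computed over the
    supplied window; detection count is monotone non-increasing in
    ``thresh_sd``.
    """
    env = np.asarray(env, dtype=float)
    filtered = np.asarray(filtered, dtype=float)
    if env.size == 0 or filtered.size == 0:
        raise ValueError("empty signal")
    if env.shape != filtered.shape:
        raise ValueError("envelope and filtered trace must be aligned")
    thr = env.mean() + thresh_sd * env.std()
    above = env > thr
    if not above.any():
        return []
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(above)]
    min_len = int(round(min_dur_ms / 1e3 * fs))
    events = []
    for s, e in zip(starts, ends):
        if e - s < min_len:
            continue
        k = s + int(np.argmax(np.abs(filtered[s:e])))
        events.append(BurstEvent(channel=channel, trigger_time=k / fs,
                                 onset=s / fs, offset=(e - 1) / fs,
                                 peak_amp=float(abs(filtered[k]))))
    return events


def burst_triggered_average(events: list[BurstEvent], trace: np.ndarray,
                            fs: float, n: int = 100,
                            half_window: float = 0.25,
                            rng=None) -> BurstAverage:
    """Average ``min(n, available)`` randomly selected bursts aligned at
    their triggers.

    Each segment spans trigger +/- ``half_window`` seconds and is flipped so
    the value at the trigger is positive before averaging.  ``trace`` may be
    the band-passed signal or a wider-band (e.g. 3 Hz high-pass) trace.
    """
    rng = np.random.default_rng(rng)
    trace = np.asarray(trace, dtype=float)
    half = int(round(half_window * fs))
    eligible = [ev for ev in events
                if half <= int(round(ev.trigger_time * fs)) < len(trace) - half]
    if not eligible:
        raise ValueError("no burst with a full window inside the recording")
    if len(eligible) > n:
        pick = rng.choice(len(eligible), size=n, replace=False)
        chosen = [eligible[i] for i in sorted(pick)]
    else:
        chosen = eligible
    segs = np.empty((len(chosen), 2 * half + 1))
    for i, ev in enumerate(chosen):
        k = int(round(ev.trigger_time * fs))
        seg = trace[k - half : k + half + 1]
        sign = np.sign(seg[half]) or 1.0
        segs[i] = sign * seg
    times = (np.arange(2 * half + 1) - half) / fs
    channel = chosen[0].channel if chosen else ""
    return BurstAverage(waveform=segs.mean(axis=0), times=times,
                        n_bursts=len(chosen), channel=channel)


def burst_cooccurrence(events_a: list[BurstEvent], events_b: list[BurstEvent],
                       tol_s: float = 0.05) -> float:
    """Diagnostic: fraction of channel-A bursts with a channel-B trigger
    within ``tol_s`` seconds (coherence remains the primary coupling
    statistic)."""
    if not events_a:
        return 0.0
    tb = np.array([ev.trigger_time for ev in events_b])
    if tb.size == 0:
        return 0.0
    hits = sum(np.min(np.abs(tb - ev.trigger_time)) <= tol_s
               for ev in events_a)
    return hits / len(events_a)
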