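"""Analysis-window selection and gamma-band filtering/envelopes.

Per behavioral state, twelve artifact-free 100-s windows (1,200 s in total)
are drawn from the scored epochs, avoiding artifact intervals and keeping a
300-s guard around sound/visual stimuli when stimulus-clear windows are
required.  Signals are band-passed 30-45 Hz with a zero-phase FIR filter and
reduced to amplitude envelopes for burst analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io import MultichannelRecording, StateAnnotation


class CapacityError(RuntimeError):
    """Not enough eligible same-state time to place the requested windows."""


@dataclass(frozen=True)
class AnalysisWindow:
    start: float
    duration: float
    state: str
    flags: dict = field(default_factory=lambda: {"artifact_free": True,
                                                 "stimulus_clear": True})

    @property
    def end(self) -> float:
        return self.start + self.duration


def _subtract_intervals(runs, exclusions):
    """Remove closed exclusion intervals from a list of (start, end) runs."""
    out = list(runs)
    for (xs, xe) in exclusions:
        nxt = []
        for (s, e) in out:
            if xe <= s or xs >= e:
                nxt.append((s, e))
                continue
            if xs > s:
                nxt.append((s, xs))
            if xe < e:
                nxt.append((xe, e))
        out = nxt
    return [(s, e) for (s, e) in out if e - s > 0]


def _exclusion_intervals(ann: StateAnnotation, stimulus_exclusion: float,
                         stimulus_clear: bool):
    ex = []
    # artifact intervals come as start/end event pairs
    starts = [ev.time for ev in ann.events if ev.kind == "artifact_start"]
    ends = [ev.time for ev in ann.events if ev.kind == "artifact_end"]
    for s, e in zip(sorted(starts), sorted(ends)):
        ex.append((s, e))
    if stimulus_clear:
        for ev in ann.events:
            if ev.kind in ("sound_on", "sound_off", "visual_on", "visual_off"):
                ex.append((ev.time - stimulus_exclusion,
                           ev.time + stimulus_exclusion))
    return ex


def select_windows(ann: StateAnnotation, state: str, n: int = 12,
                   dur: float = 100.0, stimulus_exclusion: float = 300.0,
                   rng=None, stimulus_clear: bool = True) -> list[AnalysisWindow]:
    """Choose ``n`` non-overlapping ``dur``-second windows inside contiguous
    runs of ``state``.

    Windows never overlap artifact intervals and, when ``stimulus_clear``,
    never come within ``stimulus_exclusion`` seconds of a sound/visual event.
    Placement among eligible positions is randomized under ``rng``; windows
    may abut but not overlap.  Raises :class:`CapacityError` (naming the
    state and the eligible seconds) when the annotation cannot host them.
    """
    rng = np.random.default_rng(rng)
    runs = ann.state_runs(state)
    eligible = _subtract_intervals(
        runs, _exclusion_intervals(ann, stimulus_exclusion, stimulus_clear))
    caps = [int((e - s) // dur) for (s, e) in eligible]
    avail = sum((e - s) for (s, e) in eligible)
    if sum(caps) < n:
        raise CapacityError(
            f"state {state!r}: only {avail:.0f} eligible seconds "
            f"({sum(caps)} windows of {dur:.0f} s); {n} requested")

    # allocate window counts across eligible intervals with probability
    # proportional to remaining capacity, then place each interval's windows
    # by the sorted-uniform-gaps construction (uniform, non-overlapping)
    counts = [0] * len(eligible)
    remaining = list(caps)
    for _ in range(n):
        total = sum(remaining)
        i = int(rng.choice(len(eligible), p=[r / total for r in remaining]))
        counts[i] += 1
        remaining[i] -= 1
    windows: list[AnalysisWindow] = []
    for (s, e), k in zip(eligible, counts):
        if k == 0:
            continue
        slack = (e - s) - k * dur
        offsets = np.sort(rng.uniform(0.0, slack, size=k)) if slack > 0 \
            else np.zeros(k)
        for j in range(k):
            windows.append(AnalysisWindow(s + offsets[j] + j * dur, dur, state))
    windows.sort(key=lambda w: w.start)
    return windows


# ---------------------------------------------------------------------------
# Filtering

def design_fir_bandpass(fs: float, lo: float = 30.0, hi: float = 45.0,
                        transition: float = 4.0) -> np.ndarray:
    """Windowed-sinc (Hamming) band-pass taps.

    The order follows the Hamming transition-width rule N ~ 3.3 * fs / df,
    giving >50 dB stopband attenuation 10 Hz outside the band and <0.2%
    passband ripple; -6 dB points sit at ``lo`` and ``hi``.
    """
    if not (0 < lo < hi < fs / 2):
        raise ValueError("band must satisfy 0 < lo < hi < fs/2")
    numtaps = int(np.ceil(3.3 * fs / transition)) | 1  # odd -> integer delay
    return signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs,
                         window="hamming")


def fir_bandpass(data, fs: float | None = None, lo: float = 30.0,
                 hi: float = 45.0):
    """Zero-phase 30-45 Hz band-pass.

    Accepts a :class:`MultichannelRecording` (returns a filtered copy) or a
    plain array with ``fs``.  The symmetric FIR is applied in a single pass
    by FFT convolution with the group delay compensated, which is exactly
    zero-phase for a linear-phase filter; output length equals input length.
    """
    if isinstance(data, MultichannelRecording):
        out = fir_bandpass(data.samples, data.fs, lo, hi)
        return MultichannelRecording(fs=data.fs, samples=out,
                                     channels=list(data.channels),
                                     start_time=data.start_time)
    if fs is None:
        raise ValueError("fs is required for array input")
    x = np.asarray(data, dtype=float)
    taps = design_fir_bandpass(fs, lo, hi)
    pad = len(taps) // 2
    shape = x.shape
    x2 = np.atleast_2d(x)
    padded = np.pad(x2, ((0, 0), (pad, pad)), mode="reflect")
    y = signal.fftconvolve(padded, taps[None, :], mode="same")[:, pad:-pad]
    return y.reshape(shape)


def envelope(x: np.ndarray, fs: float, method: str = "analytic",
             smooth_ms: float = 50.0) -> np.ndarray:
    """Amplitude envelope of a band-limited signal.

    ``analytic``: magnitude of the analytic (Hilbert) signal.
    ``rectify_smooth``: |x| convolved with a ``smooth_ms`` moving average.
    """
    x = np.asarray(x, dtype=float)
    if method == "analytic":
        n = len(x)
        from scipy.fft import next_fast_len

        nfast = next_fast_len(n)
        return np.abs(signal.hilbert(x, N=nfast)[:n])
    if method == "rectify_smooth":
        w = max(int(round(smooth_ms / 1e3 * fs)), 1)
        kernel = np.ones(w) / w
        return signal.fftconvolve(np.abs(x), kernel, mode="same")
    raise ValueError(f"unknown envelope method {method!r}")


def flag_artifacts(rec: MultichannelRecording, thresh_uv: float = 500.0,
                   pad_s: float = 0.5):
    """Optional amplitude pre-flagger: intervals where any channel exceeds
    ``thresh_uv`` (absolute), padded by ``pad_s``.  Off by default in the
    pipeline; scoring-based artifact events are the primary mechanism."""
    mask = (np.abs(rec.samples) > thresh_uv).any(axis=0)
    if not mask.any():
        return []
    idx = np.flatnonzero(mask)
    gaps = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[gaps + 1]]
    ends = np.r_[idx[gaps], idx[-1]]
    return [(max(s / rec.fs - pad_s, 0.0), e / rec.fs + pad_s)
            for s, e in zip(starts, ends)]
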