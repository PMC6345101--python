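"""Recording and annotation containers plus EDF/CSV input-output.

Signals are exchanged as 16-bit EDF (European Data Format) files; state
scoring and stimulus/artifact events travel as plain CSV tables.  All sample
data are held in microvolts, channels x time, at a single uniform sampling
rate.  Channel names follow the ``SITE-HEMISPHERE`` convention (for example
``Pf-r`` = right prefrontal cortex) used for cortical screw-electrode
montages; unknown labels degrade gracefully to site ``other``.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Cortical site codes understood by the label parser.
SITES = ("Pf", "M1", "S1", "Pp", "V1")
HEMISPHERES = ("r", "l")

#: Event kinds accepted in an events table.
EVENT_KINDS = (
    "injection",
    "sound_on",
    "sound_off",
    "visual_on",
    "visual_off",
    "artifact_start",
    "artifact_end",
)

#: Scoring epoch length in seconds.
EPOCH_S = 10.0


class UnsupportedFormatError(ValueError):
    """Raised for files the reader cannot represent (e.g. mixed rates)."""


def parse_site_label(name: str) -> tuple[str, str]:
    """Split a channel label into ``(site, hemisphere)``.

    ``"Pf-r"`` -> ``("Pf", "r")``.  Labels that do not follow the
    ``SITE-HEMISPHERE`` convention map to ``("other", "unknown")`` with a
    warning, so arbitrary EDF files still load.
    """
    parts = name.strip().split("-")
    if len(parts) == 2 and parts[0] in SITES and parts[1] in HEMISPHERES:
        return parts[0], parts[1]
    warnings.warn(f"channel label {name!r} does not parse as SITE-HEMISPHERE")
    return "other", "unknown"


@dataclass(frozen=True)
class ChannelInfo:
    """Metadata for one EEG channel."""

    name: str
    site: str = "other"
    hemisphere: str = "unknown"
    unit: str = "uV"

    def __post_init__(self):
        if not self.name:
            raise ValueError("channel name must be non-empty")

    @classmethod
    def from_label(cls, name: str) -> "ChannelInfo":
        site, hemi = parse_site_label(name)
        return cls(name=name, site=site, hemisphere=hemi)


@dataclass
class MultichannelRecording:
    """Uniform-rate multichannel signal in microvolts.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz.
    samples : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    channels : list of ChannelInfo
    start_time : float
        Offset of the first sample in seconds.
    """

    fs: float
    samples: np.ndarray
    channels: list[ChannelInfo]
    start_time: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channels) != self.samples.shape[0]:
            raise ValueError("channel metadata does not match sample rows")
        if np.isnan(self.samples).any():
            raise ValueError("samples contain NaN")
        seen = set()
        for ch in self.channels:
            key = (ch.site, ch.hemisphere)
            if ch.site != "other" and key in seen:
                raise ValueError(f"duplicate site/hemisphere {key}")
            seen.add(key)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}") from None

    def get_channel(self, name: str) -> np.ndarray:
        return self.samples[self.channel_index(name)]

    def slice(self, start_s: float, dur_s: float) -> np.ndarray:
        """Return samples of the window [start_s, start_s+dur_s)."""
        i0 = int(round((start_s - self.start_time) * self.fs))
        i1 = i0 + int(round(dur_s * self.fs))
        if i0 < 0 or i1 > self.n_samples:
            raise ValueError("window outside recording span")
        return self.samples[:, i0:i1]


@dataclass(frozen=True)
class Epoch:
    start: float
    duration: float
    state: str


@dataclass(frozen=True)
class Event:
    time: float
    kind: str
    payload: str = ""

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class StateAnnotation:
    """Ordered 10-s scoring epochs plus point events.

    Epochs must be sorted and non-overlapping; every epoch lasts exactly
    ``EPOCH_S`` seconds except, optionally, a trailing short epoch (allowed
    when ``allow_trailing`` is set at load time).
    """

    epochs: list[Epoch] = field(default_factory=list)
    events: list[Event] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self, allow_trailing: bool = True, tol: float = 1e-6):
        prev_end = -np.inf
        for i, ep in enumerate(self.epochs):
            if ep.start < prev_end - tol:
                raise ValueError(f"epoch {i} overlaps its predecessor")
            is_last = i == len(self.epochs) - 1
            if abs(ep.duration - EPOCH_S) > tol:
                if not (allow_trailing and is_last and 0 < ep.duration < EPOCH_S):
                    raise ValueError(
                        f"epoch {i} has duration {ep.duration} s (expected {EPOCH_S})"
                    )
            prev_end = ep.start + ep.duration

    @property
    def span(self) -> tuple[float, float]:
        if not self.epochs:
            return (0.0, 0.0)
        return self.epochs[0].start, self.epochs[-1].start + self.epochs[-1].duration

    @property
    def states(self) -> list[str]:
        out: list[str] = []
        for ep in self.epochs:
            if ep.state not in out:
                out.append(ep.state)
        return out

    def state_runs(self, state: str) -> list[tuple[float, float]]:
        """Contiguous (start, end) intervals scored as ``state``."""
        runs: list[tuple[float, float]] = []
        tol = 1e-6
        for ep in self.epochs:
            if ep.state != state:
                continue
            end = ep.start + ep.duration
            if runs and abs(runs[-1][1] - ep.start) < tol:
                runs[-1] = (runs[-1][0], end)
            else:
                runs.append((ep.start, end))
        return runs


# ---------------------------------------------------------------------------
# EDF writing.  EDF = 256-byte fixed header + 256 bytes per signal of ASCII
# metadata, followed by data records of little-endian int16 samples scaled
# between per-signal physical and digital extrema.

_DIG_MIN, _DIG_MAX = -32768, 32767


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def write_recording(rec: MultichannelRecording, path) -> Path:
    """Write a recording as a 16-bit EDF file (one data record per second).

    Recordings whose length is not an integer number of seconds are
    zero-padded to the next full record (with a warning); the sampling rate
    must therefore be a whole number of samples per second.
    """
    path = Path(path)
    if rec.n_samples == 0:
        raise ValueError("cannot write zero-length recording")
    sps = int(round(rec.fs))
    if abs(sps - rec.fs) > 1e-9:
        raise UnsupportedFormatError("EDF writer requires an integer Hz rate")
    n_records = int(np.ceil(rec.n_samples / sps))
    total = n_records * sps
    data = rec.samples
    if total != rec.n_samples:
        warnings.warn("recording padded with zeros to a whole number of records")
        data = np.pad(data, ((0, 0), (0, total - rec.n_samples)))

    ns = rec.n_channels
    phys_max = np.maximum(np.max(np.abs(data), axis=1), 1.0)
    header = b""
    header += _pad("0", 8)
    header += _pad("synthetic", 80)  # patient id
    header += _pad("gammacoh", 80)  # recording id
    header += _pad("01.01.00", 8)
    header += _pad("00.00.00", 8)
    header += _pad(str(256 * (1 + ns)), 8)
    header += _pad("", 44)
    header += _pad(str(n_records), 8)
    header += _pad("1", 8)  # record duration, seconds
    header += _pad(str(ns), 4)
    header += b"".join(_pad(c.name, 16) for c in rec.channels)
    header += b"".join(_pad("", 80) for _ in range(ns))  # transducer
    header += b"".join(_pad("uV", 8) for _ in range(ns))
    header += b"".join(_pad(f"{-m:.6g}", 8) for m in phys_max)
    header += b"".join(_pad(f"{m:.6g}", 8) for m in phys_max)
    header += b"".join(_pad(str(_DIG_MIN), 8) for _ in range(ns))
    header += b"".join(_pad(str(_DIG_MAX), 8) for _ in range(ns))
    header += b"".join(_pad("", 80) for _ in range(ns))  # prefiltering
    header += b"".join(_pad(str(sps), 8) for _ in range(ns))
    header += b"".join(_pad("", 32) for _ in range(ns))

    # physical -> digital, rounded to nearest integer
    scale = (_DIG_MAX - _DIG_MIN) / (2 * phys_max)
    dig = np.rint((data + phys_max[:, None]) * scale[:, None]) + _DIG_MIN
    dig = np.clip(dig, _DIG_MIN, _DIG_MAX).astype("<i2")
    # interleave into records: for each record, each signal's sps samples
    recs = dig.reshape(ns, n_records, sps).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(recs.tobytes())
    return path


def _edf_signal_headers(path) -> tuple[list[str], list[float], float]:
    """Parse per-signal labels and sampling rates from an EDF header."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise UnsupportedFormatError("truncated EDF header")
        record_dur = float(head[244:252])
        ns = int(head[252:256])
        sig = fh.read(256 * ns)
    labels = [sig[16 * i : 16 * (i + 1)].decode("ascii").strip() for i in range(ns)]
    off = ns * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    sps = [int(sig[off + 8 * i : off + 8 * (i + 1)]) for i in range(ns)]
    rates = [s / record_dur for s in sps]
    return labels, rates, record_dur


def read_recording(path) -> MultichannelRecording:
    """Read an EDF file into a :class:`MultichannelRecording` (microvolts).

    All selected signals must share one sampling rate; EDF annotation
    channels are dropped.  Site/hemisphere metadata is parsed from the
    channel labels.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    labels, rates, _ = _edf_signal_headers(path)
    data_rates = [r for lab, r in zip(labels, rates) if "Annotations" not in lab]
    if len(set(data_rates)) > 1:
        raise UnsupportedFormatError(
            f"mixed sampling rates in {path.name}: {sorted(set(data_rates))}"
        )
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    samples = raw.get_data() * 1e6  # mne loads volts
    channels = [ChannelInfo.from_label(name) for name in raw.ch_names]
    return MultichannelRecording(fs=float(raw.info["sfreq"]), samples=samples,
                                 channels=channels)


# ---------------------------------------------------------------------------
# Annotation CSV I/O

def read_annotation(path, events_path=None, allow_trailing: bool = True,
                    tol: float = 1e-6) -> StateAnnotation:
    """Load scoring epochs (``start_s,state``) and optional events
    (``time_s,kind[,payload]``) from CSV files.

    Epoch durations are inferred from consecutive starts and must equal 10 s
    (a shorter trailing epoch is tolerated when ``allow_trailing``).
    """
    rows: list[tuple[float, str]] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rows.append((float(row["start_s"]), row["state"].strip()))
    rows.sort(key=lambda r: r[0])
    epochs = []
    for i, (start, state) in enumerate(rows):
        if i + 1 < len(rows):
            dur = rows[i + 1][0] - start
        else:
            dur = EPOCH_S
        epochs.append(Epoch(start, dur, state))
    events: list[Event] = []
    if events_path is not None:
        with open(events_path, newline="") as fh:
            for row in csv.DictReader(fh):
                events.append(Event(float(row["time_s"]), row["kind"].strip(),
                                    row.get("payload", "") or ""))
    ann = StateAnnotation.__new__(StateAnnotation)
    ann.epochs = epochs
    ann.events = events
    ann.validate(allow_trailing=allow_trailing, tol=tol)
    return ann


def write_annotation(ann: StateAnnotation, path, events_path=None):
    """Write epochs (and optionally events) back to CSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["start_s", "state"])
        for ep in ann.epochs:
            w.writerow([f"{ep.start:g}", ep.state])
    if events_path is not None:
        with open(events_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time_s", "kind", "payload"])
            for ev in ann.events:
                w.writerow([f"{ev.time:g}", ev.kind, ev.payload])
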