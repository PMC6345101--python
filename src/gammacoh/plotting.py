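"""Matplotlib rendering of spectra, spectrograms and coherograms."""

from __future__ import annotations

import numpy as np


def _ax(ax):
    if ax is not None:
        return ax, None
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots()
    return ax, fig


def plot_spectrum(est, ax=None, log: bool = True, label=None):
    ax, fig = _ax(ax)
    y = est.power
    ax.plot(est.freqs, y, label=label)
    if log:
        ax.set_yscale("log")
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("PSD (uV$^2$/Hz)")
    return ax


def plot_spectrogram(spec, ax=None, fmax=None, db: bool = True):
    """Time-frequency power map with a log-power color scale."""
    ax, fig = _ax(ax)
    p = spec.power.T
    if db:
        p = 10 * np.log10(np.maximum(p, 1e-12))
    m = ax.pcolormesh(spec.times, spec.freqs, p, shading="auto")
    if fmax:
        ax.set_ylim(0, fmax)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    ax.figure.colorbar(m, ax=ax, label="power (dB)" if db else "power")
    return ax


def plot_coherogram(coh, ax=None, fmax=60.0):
    ax, fig = _ax(ax)
    m = ax.pcolormesh(coh.times, coh.freqs, coh.z.T, shading="auto")
    ax.set_ylim(0, fmax)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    ax.figure.colorbar(m, ax=ax, label="z'-coherence")
    return ax
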