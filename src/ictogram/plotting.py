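"""Matplotlib views of pulsograms, spectrograms and trajectory reports."""

from __future__ import annotations

import numpy as np

from .phases import PhaseMarkers
from .pulsogram import PowerPulsogram, Pulsogram
from .spectral import SpectralDecomposition


def plot_pulsogram(p: Pulsogram | PowerPulsogram, ax=None, markers: PhaseMarkers | None = None,
                   cmap: str = "RdBu_r", vlim: float | None = None):
    """Pulsogram heat map: y = pulse-relative time (ms), x = train time (s)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    v = p.values
    if vlim is None:
        vlim = float(np.nanpercentile(np.abs(v), 99))
    ax.pcolormesh(p.anchor_times, p.y_ms, v, cmap=cmap, vmin=-vlim, vmax=vlim,
                  shading="nearest")
    if markers is not None:
        for t, c in (
            (markers.divergent_point, "white"),
            (markers.paroxysmal_point, "green"),
            (markers.seizure_end, "gray"),
        ):
            if t is not None:
                ax.axvline(t, color=c, lw=1.0, ls="--")
    ax.set_xlabel("train time (s)")
    ax.set_ylabel("pulse time (ms)")
    return ax


def plot_spectrogram(spec: SpectralDecomposition, ax=None, fmax: float = 200.0):
    """Log-power spectrogram up to ``fmax`` Hz."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    m = spec.freqs <= fmax
    z = 10 * np.log10(np.maximum(spec.power[:, m].T, 1e-12))
    ax.pcolormesh(spec.times, spec.freqs[m], z, shading="nearest", cmap="magma")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    return ax


def plot_coverage(results: dict[str, "object"], ax=None):
    """Coverage curves of lower-order vs higher-order trajectories."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    for label, r in results.items():
        ax.plot(r.coverage_b, r.coverage_a, label=label)
    ax.plot([0, 100], [0, 100], "k--", lw=0.8)
    ax.set_xlabel("% higher-order trajectory")
    ax.set_ylabel("% lower-order trajectory")
    ax.legend(fontsize=7)
    return ax
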