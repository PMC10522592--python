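"""Time-frequency analysis: spectrogram, harmonic power split, event alignment.

The stimulus-driven EEG response shows up in the spectrogram as lines at the
stimulation frequency and its harmonics; paroxysmal (seizure) activity is
broad-band and unsynchronised.  Splitting spectral power into harmonic
bands (k*f0 +/- 1 Hz) versus the rest therefore separates the pulse-locked
response from aberrant activity: the harmonic fraction collapses at the
paroxysmal point.

Spectrograms use a 0.33 s Hann window with 87.5% overlap and one-sided PSD
scaling, so the full-band power integrates to the signal variance.  Power
summaries (total/harmonic/non-harmonic) integrate the PSD from above DC up
to 200 Hz.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import EEGRecording

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralDecomposition",
    "compute_spectrogram",
    "harmonic_decomposition",
    "rescale_to_template",
    "event_aligned_average",
    "grouped_average",
    "spectrogram_to_csv",
]


@dataclass
class SpectralDecomposition:
    """Spectrogram with optional per-time power summaries.

    ``power`` is time x frequency (PSD, uV^2/Hz).  After
    :func:`harmonic_decomposition`, the per-time summaries satisfy
    ``total = harmonic + nonharmonic`` exactly at every frame.
    """

    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray
    f0: float | None = None
    harmonic_power: np.ndarray | None = None
    total_power: np.ndarray | None = None
    nonharmonic_power: np.ndarray | None = None
    window_s: float = 0.33
    overlap: float = 0.875

    @property
    def hop_s(self) -> float:
        return self.window_s * (1.0 - self.overlap)

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def compute_spectrogram(
    rec: EEGRecording, window_s: float = 0.33, overlap: float = 0.875
) -> SpectralDecomposition:
    """Hann-window PSD spectrogram of a recording.

    Frame times are window centres in absolute seconds.  Raises if the
    recording is shorter than one window.
    """
    nperseg = int(round(window_s * rec.sample_rate))
    if nperseg > rec.n_samples:
        raise ValueError("recording shorter than one spectrogram window")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    noverlap = int(round(nperseg * overlap))
    f, t, sxx = sps.spectrogram(
        rec.samples,
        fs=rec.sample_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend=False,
        scaling="density",
        mode="psd",
    )
    return SpectralDecomposition(
        times=rec.t0 + t,
        freqs=f,
        power=sxx.T.copy(),
        window_s=window_s,
        overlap=overlap,
    )


def harmonic_bands_mask(
    freqs: np.ndarray, f0: float, halfwidth: float = 1.0, fmax: float = 200.0
) -> tuple[np.ndarray, np.ndarray]:
    """(in-range mask, harmonic mask) over the frequency axis.

    The in-range mask keeps 0 < f <= fmax (DC excluded).  Harmonic bands are
    k*f0 +/- halfwidth for every k >= 1 with k*f0 <= fmax, inclusive of the
    band edges; overlapping bands union.
    """
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    if f0 >= fmax:
        raise ValueError("f0 must lie below fmax")
    in_range = (freqs > 0) & (freqs <= fmax)
    harm = np.zeros_like(in_range)
    k = 1
    while k * f0 <= fmax:
        harm |= np.abs(freqs - k * f0) <= halfwidth
        k += 1
    return in_range, harm & in_range


def harmonic_decomposition(
    spec: SpectralDecomposition,
    f0: float,
    halfwidth: float = 1.0,
    fmax: float = 200.0,
) -> SpectralDecomposition:
    """Fill the per-time harmonic/total/non-harmonic power summaries.

    Powers are PSD integrals (uV^2): band power = sum(PSD) * df.
    """
    in_range, harm = harmonic_bands_mask(spec.freqs, f0, halfwidth, fmax)
    df = spec.df
    total = spec.power[:, in_range].sum(axis=1) * df
    harmonic = spec.power[:, harm].sum(axis=1) * df
    return replace(
        spec,
        f0=f0,
        total_power=total,
        harmonic_power=harmonic,
        nonharmonic_power=total - harmonic,
    )


# --------------------------------------------------------------------------
# event-aligned time rescaling
# --------------------------------------------------------------------------


def rescale_to_template(
    times: np.ndarray,
    values: np.ndarray,
    boundaries: list[float],
    points_per_segment: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Warp a per-time trace onto a fixed grid segment by segment.

    ``boundaries`` are k+1 strictly increasing event times splitting the
    trace into k segments (e.g. 15 s pre-stimulation | stimulation start ->
    paroxysmal | paroxysmal -> stimulation end | 15 s post).  Each segment
    is mapped by a monotone linear time warp onto ``points_per_segment``
    points; the returned x-axis is the segment fraction (0..k).
    """
    b = np.asarray(boundaries, dtype=float)
    if b.size < 2 or np.any(np.diff(b) <= 0):
        raise ValueError("boundaries must be at least 2 strictly increasing times")
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    axes, out = [], []
    for s in range(b.size - 1):
        frac = np.linspace(0.0, 1.0, points_per_segment, endpoint=(s == b.size - 2))
        tt = b[s] + frac * (b[s + 1] - b[s])
        axes.append(s + frac)
        out.append(np.interp(tt, t, v))
    return np.concatenate(axes), np.concatenate(out)


def event_aligned_average(
    traces: list[tuple[np.ndarray, np.ndarray]],
    boundaries_per_trace: list[list[float | None]],
    points_per_segment: int = 100,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Average traces on a common event-rescaled axis.

    Traces whose boundary list contains a missing (None) or non-monotone
    marker are excluded with a logged reason.  Returns (axis, mean, n_used).
    """
    stack, axis = [], None
    for i, ((t, v), b) in enumerate(zip(traces, boundaries_per_trace)):
        if any(x is None for x in b):
            logger.warning("trace %d excluded: missing alignment marker", i)
            continue
        bb = [float(x) for x in b]
        if any(y <= x for x, y in zip(bb, bb[1:])):
            logger.warning("trace %d excluded: markers out of order", i)
            continue
        axis, vv = rescale_to_template(t, v, bb, points_per_segment)
        stack.append(vv)
    if not stack:
        raise ValueError("no trace carries a complete marker set")
    return axis, np.mean(np.stack(stack), axis=0), len(stack)


def grouped_average(groups: dict[str, list[np.ndarray]]) -> np.ndarray:
    """Hierarchical mean: average within each group (subject) first, then
    across groups, so subjects weigh equally regardless of trace counts."""
    if not groups:
        raise ValueError("no groups to average")
    return np.mean(
        np.stack([np.mean(np.stack(v), axis=0) for v in groups.values()]), axis=0
    )


def spectrogram_to_csv(spec: SpectralDecomposition, path: str | Path) -> None:
    """Time rows x frequency columns CSV plus a JSON parameter sidecar."""
    df = pd.DataFrame(spec.power, index=spec.times, columns=spec.freqs)
    df.index.name = "time_s"
    df.to_csv(path)
    sidecar = Path(str(path) + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "window_s": spec.window_s,
                "overlap": spec.overlap,
                "hop_s": spec.hop_s,
                "f0": spec.f0,
                "n_times": int(spec.times.size),
                "n_freqs": int(spec.freqs.size),
            },
            indent=1,
        )
    )
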