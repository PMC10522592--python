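"""Pulsograms: pulse- or spike-locked time-vs-time views of an EEG response.

A pulsogram stacks fixed-length EEG snippets anchored to each stimulus
pulse (or each detected interictal spike) in chronological order: the
vertical axis is pulse-relative time in milliseconds, the horizontal axis
is the anchor sequence in seconds.  Pulse-locked structure (the immediate
discharge at 0-10 ms, the secondary discharge at 20-50 ms) appears as
horizontal bands; non-locked paroxysmal activity destroys the banding.

For trajectory analysis each vertical strip is treated as one point of an
n-dimensional trajectory.  Before that, the pulsogram is smoothed along the
pulse-time axis (2 ms Savitzky-Golay), each strip is divided by a
regularized power scale

    kappa[x] = sqrt((v[x] + v0) / 2),

where ``v[x]`` is the strip's energy over the -5..50 ms analysis window and
``v0`` the mean energy over the stimulation strips, and finally smoothed
along the strip axis (2 s Savitzky-Golay).  The regularization bounds the
influence of spuriously loud strips (motion artifacts, paroxysmal
activity): after scaling, the strip energy v/kappa^2 = 2*v*v0/(v+v0) is
monotone in v but saturates at 2*v0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, hilbert, savgol_filter

from .io import EEGRecording, StimProtocol
from .phases import PhaseMarkers

logger = logging.getLogger(__name__)

__all__ = [
    "Pulsogram",
    "PowerPulsogram",
    "TrajectoryMatrix",
    "SpikeTrain",
    "build_pulsogram",
    "extend_anchors",
    "detect_spikes",
    "power_pulsogram",
    "preprocess_trajectory",
    "delta_power",
    "pulsogram_to_csv",
    "pulsogram_from_csv",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass
class Pulsogram:
    """Voltage pulsogram: pulse-relative time (rows) x strip index (cols)."""

    values: np.ndarray
    y_ms: np.ndarray
    anchor_times: np.ndarray
    anchor_kind: str  # "pulse" | "spike"
    sample_rate: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.anchor_times) <= 0):
            raise ValueError("anchor_times must be strictly increasing")
        if self.values.shape != (self.y_ms.size, self.anchor_times.size):
            raise ValueError("values shape must be (n_y, n_strips)")

    @property
    def n_strips(self) -> int:
        return int(self.anchor_times.size)


@dataclass
class PowerPulsogram:
    """Pulsogram of smoothed Hilbert instantaneous power, in dB.

    ``reference_power`` is the per-row linear power defining 0 dB (the mean
    over the reference strips at each pulse-relative time)."""

    values: np.ndarray
    y_ms: np.ndarray
    anchor_times: np.ndarray
    anchor_kind: str
    sample_rate: float
    reference_power: np.ndarray
    reference_mask: np.ndarray

    def validate(self, tol_db: float = 3.0) -> None:
        """Mean dB over the reference region should sit near 0 dB (the gap
        is the Jensen offset between mean-of-logs and log-of-mean)."""
        m = float(np.mean(self.values[:, self.reference_mask]))
        if abs(m) > tol_db:
            raise ValueError(f"reference region mean {m:.2f} dB exceeds {tol_db} dB")


@dataclass
class TrajectoryMatrix:
    """Preprocessed pulsogram restricted to -5..50 ms, one point per strip."""

    values: np.ndarray
    y_ms: np.ndarray
    anchor_times: np.ndarray
    kappa: np.ndarray
    strip_power: np.ndarray
    mean_power: float
    n_stim: int

    @property
    def points(self) -> np.ndarray:
        """Trajectory points, shape (n_strips, n_dims)."""
        return self.values.T

    @property
    def n_strips(self) -> int:
        return int(self.anchor_times.size)


@dataclass
class SpikeTrain:
    """Detected interictal spikes (positive-going peaks)."""

    spike_times: np.ndarray
    threshold: float
    mad: float

    def __post_init__(self) -> None:
        if self.spike_times.size > 1 and np.any(np.diff(self.spike_times) < 0.020 - 1e-12):
            raise ValueError("spikes closer than the 20 ms refractory gap")


# --------------------------------------------------------------------------
# construction
# --------------------------------------------------------------------------


def extend_anchors(protocol: StimProtocol, extrapolate_s: float) -> np.ndarray:
    """Pulse anchors extended at the pulse period past each train's end."""
    period = 1.0 / protocol.frequency
    out = []
    for e in range(protocol.epoch_count):
        on = protocol.pulses_in_epoch(e)
        out.append(on)
        if extrapolate_s > 0 and on.size:
            k = np.arange(1, int(round(extrapolate_s * protocol.frequency)) + 1)
            out.append(on[-1] + k * period)
    return np.concatenate(out)


def _anchor_array(anchors, extrapolate_s: float) -> tuple[np.ndarray, str]:
    if isinstance(anchors, StimProtocol):
        return extend_anchors(anchors, extrapolate_s), "pulse"
    if isinstance(anchors, SpikeTrain):
        return np.asarray(anchors.spike_times, dtype=float), "spike"
    return np.asarray(anchors, dtype=float), "pulse"


def _slice_strips(
    samples: np.ndarray,
    fs: float,
    t0: float,
    anchor_times: np.ndarray,
    y_window: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Strip matrix + y-axis + mask of anchors whose window fits."""
    i_lo = int(round(y_window[0] * fs))
    i_hi = int(round(y_window[1] * fs))
    offsets = np.arange(i_lo, i_hi)
    centers = np.round((anchor_times - t0) * fs).astype(int)
    ok = (centers + i_lo >= 0) & (centers + i_hi <= samples.size)
    if not np.all(ok):
        logger.info("dropping %d strips whose window exceeds the recording",
                    int(np.sum(~ok)))
    idx = centers[ok][None, :] + offsets[:, None]
    return samples[idx], offsets / fs * 1000.0, ok


def build_pulsogram(
    rec: EEGRecording,
    anchors,
    y_window: tuple[float, float] = (-0.005, 0.060),
    extrapolate_s: float = 0.0,
) -> Pulsogram:
    """Extract pulse- (or spike-) anchored snippets into a pulsogram.

    ``anchors`` may be a :class:`~ictogram.io.StimProtocol` (optionally
    extrapolated ``extrapolate_s`` seconds past each train at the pulse
    period), a :class:`SpikeTrain`, or a plain array of anchor times.
    Strips whose window would leave the recording are dropped with a log
    entry.  Strip extraction is exact re-slicing: no smoothing or scaling.
    """
    at, kind = _anchor_array(anchors, extrapolate_s)
    if at.size == 0:
        raise ValueError("empty anchor set")
    vals, y_ms, ok = _slice_strips(rec.samples, rec.sample_rate, rec.t0, at, y_window)
    if vals.shape[1] == 0:
        raise ValueError("no strip window fits inside the recording")
    return Pulsogram(
        values=vals.astype(float),
        y_ms=y_ms,
        anchor_times=at[ok],
        anchor_kind=kind,
        sample_rate=rec.sample_rate,
    )


# --------------------------------------------------------------------------
# spike detection
# --------------------------------------------------------------------------


def _sg_window(length_s: float, fs: float, polyorder: int = 2) -> int:
    w = max(int(round(length_s * fs)), polyorder + 1)
    return w + 1 if w % 2 == 0 else w


def smooth_savgol(x: np.ndarray, length_s: float, fs: float, axis: int = -1) -> np.ndarray:
    """2nd-order Savitzky-Golay smoothing with polynomial-fit edges."""
    w = _sg_window(length_s, fs)
    if w >= x.shape[axis]:
        return x.copy()
    return savgol_filter(x, w, 2, axis=axis, mode="interp")


def detect_spikes(
    rec: EEGRecording,
    k_mad: float = 6.0,
    refractory_s: float = 0.020,
    smooth_s: float = 0.010,
) -> SpikeTrain:
    """Detect positive EEG spikes above ``k_mad`` median absolute deviations.

    The MAD here is the unscaled median of |samples| about zero.  Peaks are
    local maxima of the 10 ms Savitzky-Golay-smoothed trace above
    ``k_mad * mad``; within any pair closer than the refractory gap the
    later peak is discarded, keeping only the first peak of a multi-phasic
    discharge.
    """
    mad = float(np.median(np.abs(rec.samples)))
    if mad == 0:
        raise ValueError(
            "signal MAD about zero is 0; supply a recording with activity or "
            "override the threshold"
        )
    thr = k_mad * mad
    sm = smooth_savgol(rec.samples, smooth_s, rec.sample_rate)
    idx, _ = find_peaks(sm, height=thr)
    times = rec.t0 + idx / rec.sample_rate
    kept: list[float] = []
    for t in times:
        if not kept or t - kept[-1] >= refractory_s:
            kept.append(float(t))
    return SpikeTrain(spike_times=np.asarray(kept), threshold=thr, mad=mad)


# --------------------------------------------------------------------------
# power pulsogram
# --------------------------------------------------------------------------


def instantaneous_power(rec: EEGRecording, smooth_s: float = 0.010) -> np.ndarray:
    """Squared Hilbert envelope, Savitzky-Golay smoothed (10 ms, order 2).

    The polynomial smoother can undershoot below zero at sharp transients;
    the result is floored at a millionth of the mean power (-60 dB) to keep
    the dB conversion well defined without letting isolated undershoots
    dominate averages.
    """
    env2 = np.abs(hilbert(rec.samples)) ** 2
    sm = smooth_savgol(env2, smooth_s, rec.sample_rate)
    floor = 1e-6 * float(env2.mean())
    return np.maximum(sm, floor if floor > 0 else 1e-300)


def _reference_span(markers: PhaseMarkers, kind: str, anchor_times: np.ndarray):
    if kind == "spike":
        if markers.divergent_point is None:
            raise ValueError("spike-anchored reference needs a divergent point")
        return markers.divergent_point - 60.0, markers.divergent_point
    stop = (
        markers.divergent_point
        if markers.divergent_point is not None
        else float(anchor_times[-1]) + 1e-9
    )
    return markers.epoch_start, stop


def power_pulsogram(
    rec: EEGRecording,
    anchors,
    markers: PhaseMarkers | tuple[float, float],
    y_window: tuple[float, float] = (-0.005, 0.060),
    smooth_s: float = 0.010,
    extrapolate_s: float = 0.0,
) -> PowerPulsogram:
    """Pulsogram of smoothed instantaneous power in dB re a reference phase.

    The reference region (0 dB) is the induction phase for pulse anchors
    (epoch start to divergent point) or the 60 s before the divergent point
    for spike anchors; a plain ``(start, stop)`` span may be given instead
    of markers.  The reference is per pulse-time row: at each row the mean
    linear power over the reference strips defines 0 dB.
    """
    at, kind = _anchor_array(anchors, extrapolate_s)
    if at.size == 0:
        raise ValueError("empty anchor set")
    pw = instantaneous_power(rec, smooth_s)
    vals, y_ms, ok = _slice_strips(pw, rec.sample_rate, rec.t0, at, y_window)
    at = at[ok]
    if isinstance(markers, PhaseMarkers):
        a, b = _reference_span(markers, kind, at)
    else:
        a, b = markers
    ref_mask = (at >= a) & (at < b)
    if not np.any(ref_mask):
        raise ValueError("reference region contains no strips")
    ref = vals[:, ref_mask].mean(axis=1)
    db = 10.0 * np.log10(vals / ref[:, None])
    return PowerPulsogram(
        values=db,
        y_ms=y_ms,
        anchor_times=at,
        anchor_kind=kind,
        sample_rate=rec.sample_rate,
        reference_power=ref,
        reference_mask=ref_mask,
    )


# --------------------------------------------------------------------------
# trajectory preprocessing
# --------------------------------------------------------------------------


def preprocess_trajectory(
    p: Pulsogram,
    stim_mask: np.ndarray | None = None,
    y_smooth_s: float = 0.002,
    x_smooth_s: float = 2.0,
    y_analysis_ms: tuple[float, float] = (-5.0, 50.0),
) -> TrajectoryMatrix:
    """Three-stage preprocessing of a pulsogram into a trajectory matrix.

    1. Savitzky-Golay smoothing along pulse time (2 ms, order 2);
    2. per-strip division by ``kappa[x] = sqrt((v[x]+v0)/2)`` with ``v[x]``
       the strip energy over -5..50 ms and ``v0`` its mean over the
       stimulation strips (``stim_mask``; all strips by default);
    3. Savitzky-Golay smoothing along the strip axis (2 s, order 2,
       converted to strips at the anchor rate).

    The output is cropped to the -5..50 ms analysis window.
    """
    lo, hi = y_analysis_ms
    if p.y_ms[0] > lo or p.y_ms[-1] < hi - 1e-9:
        raise ValueError("pulsogram does not cover the -5..50 ms analysis window")
    sm = smooth_savgol(p.values, y_smooth_s, p.sample_rate, axis=0)
    rows = (p.y_ms >= lo - 1e-9) & (p.y_ms < hi - 1e-9)
    sm = sm[rows]
    v = np.sum(sm**2, axis=0)
    if stim_mask is None:
        stim_mask = np.ones(p.n_strips, dtype=bool)
    stim_mask = np.asarray(stim_mask, dtype=bool)
    n_stim = int(stim_mask.sum())
    if n_stim == 0:
        raise ValueError("stim_mask selects no strips")
    v0 = float(v[stim_mask].mean())
    if v0 == 0:
        raise ValueError("degenerate recording: zero mean strip power")
    kappa = np.sqrt((v + v0) / 2.0)
    sm = sm / kappa[None, :]
    if p.n_strips >= 5:
        strip_rate = 1.0 / float(np.median(np.diff(p.anchor_times)))
        w = _sg_window(x_smooth_s, strip_rate)
        if w < p.n_strips:
            sm = savgol_filter(sm, w, 2, axis=1, mode="interp")
    return TrajectoryMatrix(
        values=sm,
        y_ms=p.y_ms[rows],
        anchor_times=p.anchor_times.copy(),
        kappa=kappa,
        strip_power=v,
        mean_power=v0,
        n_stim=n_stim,
    )


# --------------------------------------------------------------------------
# band power changes about the divergent point
# --------------------------------------------------------------------------


def delta_power(
    pp: PowerPulsogram,
    markers: PhaseMarkers,
    early_ms: tuple[float, float] = (0.0, 20.0),
    late_ms: tuple[float, float] = (20.0, 50.0),
    reverberant_stop: float | None = None,
) -> tuple[float, float]:
    """Mean band-power change (dB) from the induction to the reverberant phase.

    Returns ``(delta_early, delta_late)``: for each pulse-time band, the mean
    dB over reverberant strips (divergent to paroxysmal point, or to
    ``reverberant_stop``/stimulation end when no paroxysmal point) minus the
    mean dB over induction strips.  For spike-anchored pulsograms pass
    ``late_ms=(15.0, 50.0)``.
    """
    if markers.divergent_point is None:
        raise ValueError("delta_power requires a divergent point")
    at = pp.anchor_times
    stop = markers.paroxysmal_point
    if stop is None:
        stop = reverberant_stop if reverberant_stop is not None else float(at[-1]) + 1e-9
    ind = (at >= markers.epoch_start) & (at < markers.divergent_point)
    rev = (at >= markers.divergent_point) & (at < stop)
    if ind.sum() < 1 or rev.sum() < 1:
        raise ValueError("induction or reverberant phase shorter than one strip")
    out = []
    for band in (early_ms, late_ms):
        rows = (pp.y_ms >= band[0]) & (pp.y_ms < band[1])
        out.append(
            float(pp.values[np.ix_(rows, rev)].mean() - pp.values[np.ix_(rows, ind)].mean())
        )
    return out[0], out[1]


# --------------------------------------------------------------------------
# persistence
# --------------------------------------------------------------------------


def pulsogram_to_csv(p: Pulsogram | PowerPulsogram, path: str | Path) -> None:
    """CSV matrix: header row = strip anchor times (s), first column =
    pulse-relative time (ms)."""
    df = pd.DataFrame(p.values, index=p.y_ms, columns=p.anchor_times)
    df.index.name = "pulse_time_ms"
    df.to_csv(path)


def pulsogram_from_csv(path: str | Path, sample_rate: float, anchor_kind: str = "pulse") -> Pulsogram:
    df = pd.read_csv(path, index_col=0)
    return Pulsogram(
        values=df.to_numpy(dtype=float),
        y_ms=df.index.to_numpy(dtype=float),
        anchor_times=np.asarray([float(c) for c in df.columns]),
        anchor_kind=anchor_kind,
        sample_rate=sample_rate,
    )
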