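"""Phases of ictogenesis: transition detection and response classification.

The EEG response to a pulse train moves through up to three phases:

* **induction** — a stereotyped immediate discharge time-locked 0-10 ms after
  each pulse;
* **reverberant** — beginning at the *divergent point* (Di), a secondary
  discharge appears time-locked 20-50 ms after each pulse and may evolve;
* **paroxysmal** — beginning at the *paroxysmal point* (Px), high-amplitude
  activity that is no longer time-locked to the stimulus; Px is the
  electrographic seizure-onset surrogate.

Epoch responses are classified from which phases they contain: Flat
(induction only), Evolving (induction + reverberant), and three seizure
types - first-of-day (SzF, epoch 1), break-short (SzKS, ends within 5 s of
stimulation end) and break-long (SzKL, ends later).

The detectors in this module locate Di from the late (20-50 ms) pulse-locked
power, Px from the collapse of stimulation-frequency harmonic power together
with a broad power rise, and the seizure end from the return of total power
to the pre-stimulation baseline.  Threshold values are pragmatic defaults
anchored to those qualitative signatures and are all exposed in
:class:`DetectorParams`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PhaseMarkers",
    "ResponseLabel",
    "DetectorParams",
    "SpikeRateContrast",
    "classify_response",
    "detect_transitions",
    "spike_rate_contrast",
    "write_markers",
    "read_markers",
    "summary_table",
]


class ResponseLabel(str, Enum):
    """Epoch response classes."""

    FLAT = "Flat"
    EVOLVING = "Evolving"
    SZKS = "SzKS"
    SZKL = "SzKL"
    SZF = "SzF"


@dataclass
class PhaseMarkers:
    """Transition timestamps for one epoch, absolute seconds.

    ``behavioral_point`` is a manual video-derived annotation and is only
    ever carried through, never computed.
    """

    epoch_start: float
    divergent_point: float | None = None
    paroxysmal_point: float | None = None
    seizure_end: float | None = None
    behavioral_point: float | None = None
    epoch: int | None = None

    def __post_init__(self) -> None:
        if self.paroxysmal_point is not None and self.divergent_point is None:
            raise ValueError("paroxysmal point requires a divergent point")
        seq = [
            t
            for t in (
                self.divergent_point,
                self.paroxysmal_point,
                self.seizure_end,
            )
            if t is not None
        ]
        if any(b <= a for a, b in zip(seq, seq[1:])):
            raise ValueError("markers must be strictly ordered Di < Px < end")
        if seq and seq[0] < self.epoch_start:
            raise ValueError("markers cannot precede epoch start")

    @property
    def induction_span(self) -> tuple[float, float] | None:
        if self.divergent_point is None:
            return None
        return (self.epoch_start, self.divergent_point)

    def reverberant_span(self, fallback_stop: float | None = None) -> tuple[float, float] | None:
        if self.divergent_point is None:
            return None
        stop = self.paroxysmal_point if self.paroxysmal_point is not None else fallback_stop
        if stop is None:
            return None
        return (self.divergent_point, stop)


def classify_response(
    markers: PhaseMarkers, epoch_index: int, stim_end: float
) -> ResponseLabel:
    """Classify one epoch response from its phase markers.

    ``epoch_index`` is 1-based.  ``stim_end`` is the absolute time the pulse
    train ends; a seizure ending within 5 s of it is break-short.
    """
    if epoch_index < 1:
        raise ValueError("epoch_index is 1-based")
    if markers.divergent_point is None:
        return ResponseLabel.FLAT
    if markers.paroxysmal_point is None:
        return ResponseLabel.EVOLVING
    if epoch_index == 1:
        return ResponseLabel.SZF
    if markers.seizure_end is not None and markers.seizure_end <= stim_end + 5.0:
        return ResponseLabel.SZKS
    return ResponseLabel.SZKL


# --------------------------------------------------------------------------
# transition detection
# --------------------------------------------------------------------------


@dataclass
class DetectorParams:
    """Tunable thresholds of the transition detectors.

    All durations in seconds, bands in ms of pulse-relative time.
    """

    late_band_ms: tuple[float, float] = (20.0, 50.0)
    #: early-stimulation strips used as the divergent-detector baseline
    baseline_stim_s: float = 2.0
    divergent_k_sd: float = 3.0
    divergent_sustain_s: float = 1.0
    #: moving-average smoothing of the late-band power series (strips)
    divergent_smooth_s: float = 0.3
    #: minimum meaningful late-band jump (dB); guards against a quiet
    #: baseline making the k-SD threshold arbitrarily sensitive
    divergent_min_jump_db: float = 3.0
    #: Px: harmonic fraction must fall below this multiple of its
    #: pre-paroxysmal running median
    harmonic_drop_frac: float = 0.5
    trailing_median_s: float = 5.0
    #: guard gap between the running-median window and the evaluated frame,
    #: so the reference stays strictly pre-transition while the locked
    #: discharges are collapsing
    trailing_gap_s: float = 1.5
    #: moving-average smoothing of the harmonic-fraction series
    harmonic_smooth_s: float = 0.3
    #: confirmation window after a candidate collapse and the fraction of
    #: its frames that must confirm (the collapse must be sustained, but
    #: bursting ictal activity makes the fraction flicker frame to frame)
    paroxysmal_sustain_s: float = 1.0
    paroxysmal_confirm_frac: float = 0.6
    total_power_k_sd: float = 3.0
    end_k_sd: float = 2.0
    end_sustain_s: float = 2.0
    #: fraction of the sustain window that must sit below the end threshold
    #: (occasional heavy-tailed noise frames should not postpone the end)
    end_confirm_frac: float = 0.9
    prestim_baseline_s: float = 15.0


def _first_sustained(mask: np.ndarray, min_run: int) -> int | None:
    """Index of the first run of True at least ``min_run`` long."""
    if min_run <= 1:
        idx = np.nonzero(mask)[0]
        return int(idx[0]) if idx.size else None
    run = 0
    for i, m in enumerate(mask):
        run = run + 1 if m else 0
        if run >= min_run:
            return i - min_run + 1
    return None


def _trailing_median(x: np.ndarray, n: int, gap: int = 0) -> np.ndarray:
    """Median over samples ``[i-gap-n, i-gap)`` for each position ``i``."""
    out = np.empty_like(x, dtype=float)
    for i in range(x.size):
        hi = max(0, i - gap)
        lo = max(0, hi - n)
        out[i] = np.median(x[lo:hi]) if hi > lo else x[0]
    return out


def detect_transitions(
    spec,
    pp,
    protocol,
    epoch: int,
    params: DetectorParams | None = None,
    search_stop: float | None = None,
) -> PhaseMarkers:
    """Detect divergent, paroxysmal and seizure-end points for one epoch.

    Parameters
    ----------
    spec:
        :class:`~ictogram.spectral.SpectralDecomposition` with harmonic
        summaries filled, covering the recording.
    pp:
        :class:`~ictogram.pulsogram.PowerPulsogram` whose strips are
        anchored to this epoch's pulses (reference region = early
        stimulation).
    protocol:
        :class:`~ictogram.io.StimProtocol`; supplies the epoch window.
    epoch:
        0-based epoch index into ``protocol.epoch_windows``.
    search_stop:
        Absolute time bounding the seizure-end search (default: start of the
        next epoch, or end of the spectrogram).

    Returns markers that are individually absent when the corresponding
    signature never appears; the returned set always satisfies the phase
    ordering invariant.
    """
    p = params or DetectorParams()
    a, b = protocol.epoch_windows[epoch]
    if search_stop is None:
        search_stop = (
            protocol.epoch_windows[epoch + 1][0]
            if epoch + 1 < protocol.epoch_count
            else float(spec.times[-1])
        )

    # -- divergent point: late pulse-locked band power over strips ----------
    strip_t = np.asarray(pp.anchor_times)
    in_stim = (strip_t >= a) & (strip_t < b)
    y = np.asarray(pp.y_ms)
    rows = (y >= p.late_band_ms[0]) & (y < p.late_band_ms[1])
    late_db = np.nanmean(np.asarray(pp.values)[np.ix_(rows, in_stim)], axis=0)
    t_strips = strip_t[in_stim]
    if t_strips.size < 4:
        raise ValueError("epoch too short: not enough strips for detection")
    n_sm = max(1, int(round(p.divergent_smooth_s * protocol.frequency)))
    late_sm = np.convolve(late_db, np.ones(n_sm) / n_sm, mode="same")
    base = late_sm[t_strips < a + p.baseline_stim_s]
    if base.size < 2:
        raise ValueError("epoch shorter than the divergent baseline window")
    thr = base.mean() + max(
        p.divergent_k_sd * base.std(ddof=1), p.divergent_min_jump_db
    )
    min_run = max(1, int(np.ceil(p.divergent_sustain_s * protocol.frequency)))
    i = _first_sustained(late_sm > thr, min_run)
    divergent = float(t_strips[i]) if i is not None else None

    # -- paroxysmal point: harmonic-fraction collapse + power rise ----------
    ft = np.asarray(spec.times)
    hf = np.asarray(spec.harmonic_power) / np.maximum(np.asarray(spec.total_power), 1e-300)
    tot = np.asarray(spec.total_power)
    pre = (ft >= a - p.prestim_baseline_s) & (ft < a)
    if pre.sum() < 2:
        raise ValueError("epoch lacks a pre-stimulation baseline window")
    mu, sd = tot[pre].mean(), tot[pre].std(ddof=1)
    frame_dt = float(np.median(np.diff(ft)))
    win = (ft >= a) & (ft < search_stop)
    hf_e, tot_e, t_e = hf[win], tot[win], ft[win]
    n_sm = max(1, int(round(p.harmonic_smooth_s / frame_dt)))
    hf_s = np.convolve(hf_e, np.ones(n_sm) / n_sm, mode="same")
    runmed = _trailing_median(
        hf_s,
        max(1, int(round(p.trailing_median_s / frame_dt))),
        gap=int(round(p.trailing_gap_s / frame_dt)),
    )
    min_run = max(1, int(np.ceil(p.paroxysmal_sustain_s / frame_dt)))
    power_ok = tot_e > mu + p.total_power_k_sd * sd
    # candidate frames must have their analysis window fully inside the
    # train: as the window slides off the last pulse the harmonic fraction
    # collapses trivially; confirmation frames may extend past the train,
    # where only genuine paroxysmal activity keeps total power elevated
    last_center = b - 0.5 * spec.window_s - p.harmonic_smooth_s
    paroxysmal = None
    for j in range(hf_s.size):
        if t_e[j] > last_center:
            break
        # the reference is frozen at the candidate frame so that frames
        # inside the putative seizure do not dilute the pre-paroxysmal level
        ref = p.harmonic_drop_frac * runmed[j]
        if not (hf_s[j] < ref and power_ok[j]):
            continue
        run = slice(j, min(j + min_run, hf_s.size))
        confirmed = np.mean((hf_s[run] < ref) & power_ok[run])
        if confirmed >= p.paroxysmal_confirm_frac:
            # onset semantics: the signature may begin anywhere inside the
            # first triggering frame, so report the frame start
            paroxysmal = float(max(t_e[j] - 0.5 * spec.window_s, a))
            break

    # -- seizure end: total power back at baseline --------------------------
    seizure_end = None
    if paroxysmal is not None:
        post = (ft > paroxysmal) & (ft < search_stop)
        below = tot[post] < mu + p.end_k_sd * sd
        n_run = max(1, int(np.ceil(p.end_sustain_s / frame_dt)))
        t_post = ft[post]
        for k in range(below.size):
            run = below[k : min(k + n_run, below.size)]
            if below[k] and run.mean() >= p.end_confirm_frac:
                seizure_end = float(t_post[k])
                break

    if divergent is None and paroxysmal is not None:
        logger.warning(
            "epoch %d: paroxysmal signature without a divergent point; "
            "dropping paroxysmal/end markers to keep ordering",
            epoch,
        )
        paroxysmal = seizure_end = None
    if divergent is not None and paroxysmal is not None and paroxysmal <= divergent:
        paroxysmal = seizure_end = None
    return PhaseMarkers(
        epoch_start=a,
        divergent_point=divergent,
        paroxysmal_point=paroxysmal,
        seizure_end=seizure_end,
        epoch=epoch,
    )


# --------------------------------------------------------------------------
# spontaneous-seizure spike-rate contrast
# --------------------------------------------------------------------------


@dataclass
class SpikeRateContrast:
    interictal_rate: float
    reverberant_rate: float
    ratio: float
    ratio_defined: bool


def spike_rate_contrast(
    spike_times: np.ndarray,
    markers: PhaseMarkers,
    interictal_window_s: float = 60.0,
) -> SpikeRateContrast:
    """Spike rate in the reverberant phase vs the preceding interictal window.

    Interictal rate is measured over the ``interictal_window_s`` seconds
    before the divergent point, reverberant rate between divergent and
    paroxysmal points.
    """
    if markers.divergent_point is None or markers.paroxysmal_point is None:
        raise ValueError("divergent and paroxysmal markers are required")
    st = np.asarray(spike_times, dtype=float)
    di, px = markers.divergent_point, markers.paroxysmal_point
    n_inter = int(np.sum((st >= di - interictal_window_s) & (st < di)))
    n_rev = int(np.sum((st >= di) & (st < px)))
    r_inter = n_inter / interictal_window_s
    r_rev = n_rev / (px - di)
    if n_inter == 0:
        return SpikeRateContrast(0.0, r_rev, float("nan"), False)
    return SpikeRateContrast(r_inter, r_rev, r_rev / r_inter, True)


# --------------------------------------------------------------------------
# marker persistence
# --------------------------------------------------------------------------


def write_markers(
    markers: list[PhaseMarkers],
    path: str | Path,
    labels: list[ResponseLabel] | None = None,
) -> None:
    """Write per-epoch markers (and optional labels) as JSON keyed by epoch."""
    payload = {}
    for i, m in enumerate(markers):
        d = {k: v for k, v in asdict(m).items() if v is not None and k != "epoch"}
        if labels is not None:
            d["label"] = labels[i].value
        payload[str(m.epoch if m.epoch is not None else i)] = d
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_markers(path: str | Path) -> tuple[list[PhaseMarkers], list[ResponseLabel | None]]:
    payload = json.loads(Path(path).read_text())
    markers, labels = [], []
    for key in sorted(payload, key=int):
        d = dict(payload[key])
        lbl = d.pop("label", None)
        markers.append(PhaseMarkers(epoch=int(key), **d))
        labels.append(ResponseLabel(lbl) if lbl is not None else None)
    return markers, labels


def summary_table(
    markers: list[PhaseMarkers],
    labels: list[ResponseLabel],
    protocol,
) -> pd.DataFrame:
    """Per-recording summary: epoch, label, marker times and latencies."""
    rows = []
    for i, (m, lbl) in enumerate(zip(markers, labels)):
        stim_start = m.epoch_start
        rows.append(
            {
                "epoch": (m.epoch if m.epoch is not None else i) + 1,
                "label": lbl.value,
                "divergent_s": m.divergent_point,
                "paroxysmal_s": m.paroxysmal_point,
                "seizure_end_s": m.seizure_end,
                "induction_latency_s": (
                    None if m.divergent_point is None else m.divergent_point - stim_start
                ),
                "reverberant_duration_s": (
                    None
                    if m.divergent_point is None or m.paroxysmal_point is None
                    else m.paroxysmal_point - m.divergent_point
                ),
                "seizure_duration_s": (
                    None
                    if m.paroxysmal_point is None or m.seizure_end is None
                    else m.seizure_end - m.paroxysmal_point
                ),
            }
        )
    return pd.DataFrame(rows)
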