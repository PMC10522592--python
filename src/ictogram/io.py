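"""Recording containers, EDF and event-table I/O, acquisition-style filtering.

Time convention used throughout the package: seconds from recording start,
0-based sample indexing, sample ``i`` covering ``[i/fs, (i+1)/fs)``.

EEG is stored as single-channel EDF (16-bit, physical range declared per
file, default +/-5000 uV).  Stimulation pulses and generic event tables are
tab-separated text with columns ``onset_s  duration_s  label  epoch``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "EEGRecording",
    "StimProtocol",
    "AnnotationTable",
    "FormatError",
    "write_recording",
    "read_recording",
    "write_events",
    "read_events",
    "protocol_to_events",
    "protocol_from_events",
    "filter_recording",
]


class FormatError(ValueError):
    """Raised when an on-disk file violates the expected format."""


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass
class EEGRecording:
    """Continuous single-channel voltage trace.

    Attributes
    ----------
    samples:
        Voltage samples in microvolts.
    sample_rate:
        Sampling rate in Hz (acquisition default 3000 Hz).
    t0:
        Time of the first sample, seconds.
    channel_name:
        Free-text channel label.
    """

    samples: np.ndarray
    sample_rate: float
    t0: float = 0.0
    channel_name: str = "CA1"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sample_rate

    def index_of(self, t: float) -> int:
        """Sample index whose interval covers time ``t``."""
        return int(np.floor((t - self.t0) * self.sample_rate + 1e-9))

    def segment(self, start: float, stop: float) -> "EEGRecording":
        i0 = max(self.index_of(start), 0)
        i1 = min(self.index_of(stop), self.n_samples)
        if i1 <= i0:
            raise ValueError("empty segment requested")
        return EEGRecording(
            self.samples[i0:i1],
            self.sample_rate,
            t0=self.t0 + i0 / self.sample_rate,
            channel_name=self.channel_name,
        )


@dataclass
class StimProtocol:
    """Pulse-train stimulation protocol for one recording.

    The standard paradigm is 15 epochs, each a 30 s train of 5 ms pulses at
    5, 10 or 20 Hz, separated by 90 s breaks.  ``epoch_windows`` hold the
    (train start, train end) of each epoch in seconds.
    """

    pulse_onsets: np.ndarray
    frequency: float
    epoch_windows: list[tuple[float, float]]
    pulse_width: float = 0.005
    #: tolerance (s) used when checking inter-onset regularity; one sample
    #: at the 3 kHz acquisition rate
    onset_tol: float = 1.0 / 3000.0

    def __post_init__(self) -> None:
        self.pulse_onsets = np.asarray(self.pulse_onsets, dtype=float)
        if self.pulse_onsets.size == 0:
            raise ValueError("protocol needs at least one pulse")
        if np.any(np.diff(self.pulse_onsets) <= 0):
            raise ValueError("pulse_onsets must be strictly increasing")
        if not self.frequency > 0:
            raise ValueError("frequency must be positive")
        starts = [w[0] for w in self.epoch_windows]
        stops = [w[1] for w in self.epoch_windows]
        if any(b <= a for a, b in self.epoch_windows):
            raise ValueError("epoch windows must have positive length")
        for (a0, b0), (a1, b1) in zip(self.epoch_windows, self.epoch_windows[1:]):
            if a1 < b0:
                raise ValueError("epoch windows overlap")
        period = 1.0 / self.frequency
        for i, (a, b) in enumerate(self.epoch_windows):
            on = self.pulses_in_epoch(i)
            if on.size and (on[0] < a - self.onset_tol or on[-1] > b + self.onset_tol):
                raise ValueError(f"pulses outside epoch window {i}")
            if on.size > 1:
                ioi = np.diff(on)
                if np.any(np.abs(ioi - period) > self.onset_tol):
                    raise ValueError(
                        f"inter-onset interval in epoch {i} deviates from 1/frequency"
                    )
        del starts, stops

    @classmethod
    def standard(
        cls,
        frequency: float = 10.0,
        epoch_count: int = 15,
        train_s: float = 30.0,
        break_s: float = 90.0,
        baseline_s: float = 15.0,
        pulse_width: float = 0.005,
    ) -> "StimProtocol":
        """The multi-epoch paradigm: ``epoch_count`` trains of ``train_s``
        seconds at ``frequency`` Hz separated by ``break_s`` breaks, with a
        ``baseline_s`` quiet lead-in before the first train."""
        n_per = int(round(train_s * frequency))
        onsets = []
        windows = []
        for e in range(epoch_count):
            start = baseline_s + e * (train_s + break_s)
            windows.append((start, start + train_s))
            onsets.append(start + np.arange(n_per) / frequency)
        return cls(
            pulse_onsets=np.concatenate(onsets),
            frequency=frequency,
            epoch_windows=windows,
            pulse_width=pulse_width,
        )

    @property
    def epoch_count(self) -> int:
        return len(self.epoch_windows)

    def pulses_in_epoch(self, epoch: int) -> np.ndarray:
        a, b = self.epoch_windows[epoch]
        m = (self.pulse_onsets >= a - self.onset_tol) & (
            self.pulse_onsets < b + self.onset_tol
        )
        return self.pulse_onsets[m]

    def stim_end(self, epoch: int) -> float:
        return self.epoch_windows[epoch][1]


@dataclass
class AnnotationTable:
    """Optional per-epoch manual annotations (behavioral point, Racine score).

    The behavioral point is video-derived and is only ever carried through as
    an annotation; the package never computes it.
    """

    behavioral_point: dict[int, float] = field(default_factory=dict)
    racine_score: dict[int, int] = field(default_factory=dict)

    def validate(self, protocol: StimProtocol, span_after_s: float = 90.0) -> None:
        for e, t in self.behavioral_point.items():
            a, b = protocol.epoch_windows[e]
            if not (a <= t <= b + span_after_s):
                raise ValueError(f"behavioral point of epoch {e} outside its span")
        for e, r in self.racine_score.items():
            if not 0 <= int(r) <= 7:
                raise ValueError(f"racine score of epoch {e} outside 0-7")


# --------------------------------------------------------------------------
# EDF container (16-bit, single channel)
# --------------------------------------------------------------------------

_DIG_MIN, _DIG_MAX = -32768, 32767


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"header field too long: {text!r}")
    return b.ljust(width)


def _record_layout(n: int, fs: float) -> tuple[int, Fraction]:
    """Choose (samples per record, record duration) so fs is stored exactly."""
    frac = Fraction(fs).limit_denominator(10**6)
    q, p = frac.numerator, frac.denominator  # fs = q / p exactly
    # keep records around a second where possible
    return q, Fraction(p)


def write_recording(
    rec: EEGRecording,
    path: str | Path,
    physical_range_uv: float = 5000.0,
) -> None:
    """Write a recording as single-channel EDF.

    Samples are quantized to 16 bits over ``+/-physical_range_uv``.  A
    recording whose final data record is partial is zero-padded on disk; the
    true sample count is kept in the reserved header field and restored by
    :func:`read_recording`.
    """
    if not np.all(np.isfinite(rec.samples)):
        raise ValueError("refusing to write non-finite samples")
    if np.max(np.abs(rec.samples)) > physical_range_uv:
        raise ValueError("samples exceed the declared physical range")
    spr, dur = _record_layout(rec.n_samples, rec.sample_rate)
    n_rec = int(np.ceil(rec.n_samples / spr))
    pmin, pmax = -physical_range_uv, physical_range_uv
    scale = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
    dig = np.round((rec.samples - pmin) * scale + _DIG_MIN).astype("<i2")
    dig = np.concatenate([dig, np.zeros(n_rec * spr - dig.size, dtype="<i2")])

    dur_str = str(int(dur)) if dur.denominator == 1 else f"{float(dur):.6f}"[:8]
    header = b"".join(
        [
            _pad("0", 8),
            _pad("X", 80),
            _pad(f"Startdate X T0={rec.t0:.9g}", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 + 256), 8),
            _pad(f"NS={rec.n_samples}", 44),
            _pad(str(n_rec), 8),
            _pad(dur_str, 8),
            _pad("1", 4),
            # one signal header, field-by-field
            _pad(rec.channel_name[:16], 16),
            _pad("", 80),
            _pad("uV", 8),
            _pad(f"{pmin:.6g}"[:8], 8),
            _pad(f"{pmax:.6g}"[:8], 8),
            _pad(str(_DIG_MIN), 8),
            _pad(str(_DIG_MAX), 8),
            _pad("", 80),
            _pad(str(spr), 8),
            _pad("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(dig.tobytes())


def _field(raw: bytes, start: int, width: int, name: str) -> str:
    try:
        return raw[start : start + width].decode("ascii").strip()
    except UnicodeDecodeError as e:  # pragma: no cover - corrupt input
        raise FormatError(f"undecodable header field {name!r}") from e


def read_recording(path: str | Path) -> EEGRecording:
    """Read a single-channel EDF file written by :func:`write_recording`
    (or any plain 16-bit single-channel EDF)."""
    raw = Path(path).read_bytes()
    if len(raw) < 512:
        raise FormatError("file shorter than an EDF header (field 'version')")
    if _field(raw, 0, 8, "version") != "0":
        raise FormatError("unsupported EDF version (field 'version')")
    recording_id = _field(raw, 88, 80, "recording_id")
    try:
        header_bytes = int(_field(raw, 184, 8, "header_bytes"))
        n_rec = int(_field(raw, 236, 8, "n_data_records"))
        dur = float(_field(raw, 244, 8, "record_duration"))
        n_sig = int(_field(raw, 252, 4, "n_signals"))
    except ValueError as e:
        raise FormatError(f"malformed numeric header field: {e}") from e
    if n_sig != 1:
        raise FormatError(f"expected 1 signal, found {n_sig} (field 'n_signals')")
    reserved = _field(raw, 192, 44, "reserved")
    sig = raw[256 : 256 + 256]
    label = sig[0:16].decode("ascii").strip()
    try:
        pmin = float(sig[104:112].decode("ascii"))
        pmax = float(sig[112:120].decode("ascii"))
        dmin = int(sig[120:128].decode("ascii"))
        dmax = int(sig[128:136].decode("ascii"))
        spr = int(sig[216:224].decode("ascii"))
    except ValueError as e:
        raise FormatError(f"malformed signal header field: {e}") from e
    if pmax <= pmin or dmax <= dmin:
        raise FormatError("inverted physical/digital range (field 'physical_min')")
    data = np.frombuffer(raw[header_bytes:], dtype="<i2")
    if data.size < n_rec * spr:
        raise FormatError("truncated data section (field 'n_data_records')")
    data = data[: n_rec * spr].astype(float)
    samples = (data - dmin) / (dmax - dmin) * (pmax - pmin) + pmin
    n_true = n_rec * spr
    if reserved.startswith("NS="):
        n_true = min(int(reserved[3:]), n_true)
    t0 = 0.0
    if "T0=" in recording_id:
        t0 = float(recording_id.split("T0=")[1].split()[0])
    fs = spr / dur
    # recover an exact rational rate when the duration string was rounded
    fs = float(Fraction(fs).limit_denominator(10**6))
    return EEGRecording(samples[:n_true], fs, t0=t0, channel_name=label or "EEG")


# --------------------------------------------------------------------------
# event tables
# --------------------------------------------------------------------------

EVENT_COLUMNS = ["onset_s", "duration_s", "label", "epoch"]
KNOWN_LABELS = {"pulse", "train", "spike", "divergent", "paroxysmal", "seizure_end"}


def write_events(table: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"event table missing columns {missing}")
    table[EVENT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated event table, preserving row order.

    Onsets must be non-decreasing within each label group; a regression in
    raw onset order across the whole table is reported with its row index.
    Unknown labels are kept with a warning.
    """
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"event table missing columns {missing}")
    onsets = table["onset_s"].to_numpy(dtype=float)
    for lbl, grp in table.groupby("label", sort=False):
        o = grp["onset_s"].to_numpy(dtype=float)
        bad = np.nonzero(np.diff(o) < 0)[0]
        if bad.size:
            row = int(grp.index[bad[0] + 1])
            raise FormatError(f"onset of row {row} precedes its predecessor")
    unknown = sorted(set(table["label"].astype(str)) - KNOWN_LABELS)
    if unknown:
        import warnings

        warnings.warn(f"unknown event labels kept: {unknown}", stacklevel=2)
    del onsets
    return table


def protocol_to_events(protocol: StimProtocol) -> pd.DataFrame:
    rows = []
    for e, (a, b) in enumerate(protocol.epoch_windows):
        rows.append((a, b - a, "train", e))
    for e in range(protocol.epoch_count):
        for t in protocol.pulses_in_epoch(e):
            rows.append((t, protocol.pulse_width, "pulse", e))
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def protocol_from_events(table: pd.DataFrame) -> StimProtocol:
    """Rebuild a :class:`StimProtocol` from an event table.

    Pulse frequency is inferred from the median inter-onset interval of
    pulse rows; train windows come from ``train`` rows, or are inferred
    from pulse extents when absent.
    """
    pulses = table[table["label"] == "pulse"].sort_values("onset_s")
    if pulses.empty:
        raise FormatError("event table contains no pulse rows")
    onsets = pulses["onset_s"].to_numpy(dtype=float)
    widths = pulses["duration_s"].to_numpy(dtype=float)
    by_epoch = pulses.groupby("epoch")["onset_s"]
    iois = np.concatenate(
        [np.diff(g.to_numpy(dtype=float)) for _, g in by_epoch if len(g) > 1]
    )
    freq = 1.0 / float(np.median(iois))
    trains = table[table["label"] == "train"]
    if len(trains):
        windows = [
            (float(r.onset_s), float(r.onset_s + r.duration_s))
            for r in trains.itertuples()
        ]
    else:
        windows = [
            (float(g.min()), float(g.max()) + 1.0 / freq) for _, g in by_epoch
        ]
    return StimProtocol(
        pulse_onsets=onsets,
        frequency=float(np.round(freq, 6)),
        epoch_windows=windows,
        pulse_width=float(np.median(widths)),
    )


# --------------------------------------------------------------------------
# filtering
# --------------------------------------------------------------------------


def filter_recording(
    rec: EEGRecording,
    band: tuple[float, float] = (3.0, 1000.0),
    notch: Sequence[float] = (60.0, 120.0, 180.0),
    order: int = 4,
    notch_q: float = 30.0,
) -> EEGRecording:
    """Acquisition-equivalent band-pass plus line-noise notches, zero-phase.

    Mirrors the hardware chain (3-1000 Hz band-pass, notches at 60 Hz and
    harmonics) with forward-backward filtering so event latencies are not
    shifted relative to the raw trace.
    """
    low, high = band
    nyq = rec.sample_rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError("band must satisfy 0 < low < high < Nyquist")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.sample_rate, output="sos")
    x = signal.sosfiltfilt(sos, rec.samples)
    for f0 in notch:
        if not 0 < f0 < nyq:
            raise ValueError("notch frequency outside (0, Nyquist)")
        b, a = signal.iirnotch(f0, notch_q, fs=rec.sample_rate)
        x = signal.filtfilt(b, a, x)
    return replace(rec, samples=x)
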