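"""End-to-end convenience drivers tying the pipeline stages together."""

from __future__ import annotations

from .io import EEGRecording, StimProtocol
from .phases import (
    DetectorParams,
    PhaseMarkers,
    ResponseLabel,
    classify_response,
    detect_transitions,
)
from .pulsogram import (
    PowerPulsogram,
    build_pulsogram,
    power_pulsogram,
    preprocess_trajectory,
)
from .spectral import SpectralDecomposition, compute_spectrogram, harmonic_decomposition
from .trajectory import TrajectoryMatrix

__all__ = ["analyze_optogenetic", "epoch_power_pulsogram", "epoch_trajectory"]


def epoch_power_pulsogram(
    rec: EEGRecording,
    protocol: StimProtocol,
    epoch: int,
    reference_s: float = 2.0,
    y_window: tuple[float, float] = (-0.005, 0.060),
) -> PowerPulsogram:
    """Power pulsogram for one epoch, referenced to its first ``reference_s``
    seconds of stimulation (a pre-divergent proxy usable before markers are
    known)."""
    pulses = protocol.pulses_in_epoch(epoch)
    a, _ = protocol.epoch_windows[epoch]
    return power_pulsogram(rec, pulses, (a, a + reference_s), y_window=y_window)


def epoch_trajectory(
    rec: EEGRecording,
    protocol: StimProtocol,
    epoch: int,
    y_window: tuple[float, float] = (-0.005, 0.060),
) -> TrajectoryMatrix:
    """Preprocessed trajectory of one epoch's 30 s stimulation segment."""
    pulses = protocol.pulses_in_epoch(epoch)
    p = build_pulsogram(rec, pulses, y_window=y_window)
    return preprocess_trajectory(p)


def analyze_optogenetic(
    rec: EEGRecording,
    protocol: StimProtocol,
    params: DetectorParams | None = None,
) -> tuple[list[PhaseMarkers], list[ResponseLabel], SpectralDecomposition]:
    """Detect transitions and classify the response of every epoch."""
    spec = harmonic_decomposition(compute_spectrogram(rec), f0=protocol.frequency)
    markers, labels = [], []
    for e in range(protocol.epoch_count):
        pp = epoch_power_pulsogram(rec, protocol, e)
        m = detect_transitions(spec, pp, protocol, e, params=params)
        markers.append(m)
        labels.append(classify_response(m, e + 1, stim_end=protocol.stim_end(e)))
    return markers, labels, spec
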