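"""Synthetic EEG generator for pulse-train stimulation and spontaneous seizures.

Emulates the in-vivo study conditions end-to-end so every downstream stage
can be exercised against exported ground truth: 15-epoch recordings of 30 s
pulse trains (5 ms pulses at 5/10/20 Hz) with 90 s breaks, sampled at
3 kHz; pulse-locked immediate discharges (0-10 ms), secondary discharges
(20-50 ms) emerging at a divergent point with ramping amplitude, and
non-phase-locked high-amplitude paroxysmal activity after a paroxysmal
point; plus spontaneous-seizure recordings whose interictal spikes
accelerate and acquire a delayed secondary component before seizure onset.

Waveform morphology is not constrained by the phenomenology the pipeline
targets (only latency windows and power signatures are); the kernel shapes
here are therefore explicit modelling choices, documented in the methods
note:

* immediate discharge - damped biphasic oscillation confined to 0-10 ms;
* secondary discharge - Gaussian-windowed oscillation centred at a latency
  in the 20-50 ms window.  Response "complexity" is realized as
  ``complexity_loops`` distinct secondary latency sub-patterns visited
  sequentially through the reverberant phase (each switch is a distinct
  sub-pattern, giving first seizures their extra trajectory structure);
* paroxysmal activity - amplitude-modulated 2-8 Hz oscillations with
  seeded random phase plus a band-limited stochastic component, replacing
  the pulse-locked discharges;
* background - 1/f-shaped Gaussian noise.

All randomness derives from ``NoiseSpec.seed``; identical inputs give
bit-identical recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng
from scipy.fft import irfft, rfft, rfftfreq

from .io import EEGRecording, StimProtocol
from .phases import PhaseMarkers, ResponseLabel, classify_response

__all__ = [
    "NoiseSpec",
    "ResponseSpec",
    "SynthParams",
    "generate_optogenetic_recording",
    "generate_epoch_response",
    "generate_spontaneous_recording",
]

DEFAULT_SAMPLE_RATE = 3000.0

_SEIZURE_TYPES = {ResponseLabel.SZKS, ResponseLabel.SZKL, ResponseLabel.SZF}
#: canonical immediate-discharge shape progression, indexed by activity
#: phase: every response traverses the same path, flat responses covering
#: only its beginning and seizures the whole of it, with progression tied
#: to phase fraction rather than wall time
_MORPH_FLAT_END = 0.25
_MORPH_INDUCTION_END = 0.35
_MORPH_EVOLVING_END = 0.55
_MORPH_REVERBERANT_END = 0.70


def _morph_at(t_rel: float, spec: "ResponseSpec", train_s: float) -> float:
    """Position along the canonical shape progression at ``t_rel`` seconds
    into the train."""
    if spec.divergent_time is None:
        return _MORPH_FLAT_END * min(t_rel / train_s, 1.0)
    di = spec.divergent_time
    if t_rel < di:
        return _MORPH_INDUCTION_END * t_rel / di
    if spec.paroxysmal_time is None:
        stop = _MORPH_EVOLVING_END
        span = max(train_s - di, 1e-9)
        return _MORPH_INDUCTION_END + (stop - _MORPH_INDUCTION_END) * min(
            (t_rel - di) / span, 1.0
        )
    px = spec.paroxysmal_time
    if t_rel < px:
        return _MORPH_INDUCTION_END + (
            _MORPH_REVERBERANT_END - _MORPH_INDUCTION_END
        ) * (t_rel - di) / (px - di)
    return _MORPH_REVERBERANT_END


_DEFAULT_LOOPS = {
    ResponseLabel.FLAT: 0,
    ResponseLabel.EVOLVING: 2,
    ResponseLabel.SZKS: 3,
    ResponseLabel.SZKL: 3,
    ResponseLabel.SZF: 5,
}


@dataclass(frozen=True)
class NoiseSpec:
    """Background-noise model: 1/f-shaped Gaussian noise plus optional
    transient artifacts.  ``background_sd`` defaults to 10% of the immediate
    discharge amplitude."""

    background_sd: float = 30.0
    artifact_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.background_sd > 0:
            raise ValueError("background_sd must be positive")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be non-negative")


@dataclass(frozen=True)
class ResponseSpec:
    """Scheduled response for one stimulation epoch.

    Times are seconds from the epoch's train start.  ``complexity_loops``
    counts the distinct secondary-discharge sub-patterns visited during the
    reverberant phase (0 for Flat; first seizures use more).
    """

    response_type: ResponseLabel
    divergent_time: float | None = None
    paroxysmal_time: float | None = None
    end_time: float | None = None
    complexity_loops: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "response_type", ResponseLabel(self.response_type))
        if self.complexity_loops is None:
            object.__setattr__(
                self, "complexity_loops", _DEFAULT_LOOPS[self.response_type]
            )
        if self.complexity_loops < 0:
            raise ValueError("complexity_loops must be >= 0")

    def validate(self, train_s: float, epoch_index: int | None = None) -> None:
        """Check internal consistency against a train length (and optional
        1-based epoch position)."""
        kind = self.response_type
        if kind is ResponseLabel.FLAT:
            if any(
                t is not None
                for t in (self.divergent_time, self.paroxysmal_time, self.end_time)
            ):
                raise ValueError("Flat responses carry no transition times")
            return
        if self.divergent_time is None or not 0 < self.divergent_time:
            raise ValueError(f"{kind.value} requires 0 < divergent_time")
        if kind is ResponseLabel.EVOLVING:
            if self.paroxysmal_time is not None or self.end_time is not None:
                raise ValueError("Evolving responses stop before the paroxysmal point")
            if self.divergent_time >= train_s:
                raise ValueError("divergent_time must fall within the train")
            return
        # seizure types
        if self.paroxysmal_time is None or self.end_time is None:
            raise ValueError(f"{kind.value} requires paroxysmal and end times")
        if not (
            self.divergent_time < self.paroxysmal_time < self.end_time
        ):
            raise ValueError("need divergent < paroxysmal < end")
        if self.divergent_time >= train_s:
            raise ValueError("divergent_time must fall within the train")
        if self.paroxysmal_time >= train_s:
            raise ValueError("paroxysmal_time must fall within the train")
        if kind is ResponseLabel.SZKS and self.end_time > train_s + 5.0:
            raise ValueError("SzKS must end within 5 s of stimulation end")
        if kind is ResponseLabel.SZKL and self.end_time <= train_s + 5.0:
            raise ValueError("SzKL must end beyond 5 s of stimulation end")
        if epoch_index is not None:
            if kind is ResponseLabel.SZF and epoch_index != 1:
                raise ValueError("SzF is only allowed at epoch 1")
            if kind in (ResponseLabel.SZKS, ResponseLabel.SZKL) and epoch_index == 1:
                raise ValueError("breakthrough seizures occur at epoch 2+")

    @classmethod
    def typical(
        cls, kind: ResponseLabel | str, rng: Generator | None = None, train_s: float = 30.0
    ) -> "ResponseSpec":
        """A response with study-typical transition times.

        With ``rng``, latencies are jittered within their ranges.  First
        seizures have the shortest induction phase.  Across the non-seizure
        -> seizure ladder the phase durations shorten (Flat spends the whole
        train in induction; Evolving diverges late; break-short diverges
        earlier; break-long reaches the paroxysmal phase earliest and so
        carries the longest in-train ictal progression), which realizes the
        successive nesting of response phases.
        """
        kind = ResponseLabel(kind)
        u = (lambda a, b: float(rng.uniform(a, b))) if rng is not None else (
            lambda a, b: 0.5 * (a + b)
        )
        if kind is ResponseLabel.FLAT:
            return cls(kind)
        if kind is ResponseLabel.EVOLVING:
            return cls(kind, divergent_time=u(12.0, 18.0))
        if kind is ResponseLabel.SZF:
            di = u(3.0, 6.0)
            px = di + u(6.0, 10.0)
            return cls(kind, di, px, train_s + u(6.0, 12.0))
        if kind is ResponseLabel.SZKS:
            di = u(9.5, 12.0)
            px = di + u(8.0, 11.0)
            return cls(kind, di, px, train_s + u(1.0, 4.5))
        di = u(6.0, 8.5)
        px = di + u(4.0, 7.0)
        return cls(kind, di, px, train_s + u(8.0, 18.0))


@dataclass(frozen=True)
class SynthParams:
    """Waveform parameters of the generator (amplitudes in uV, times in s)."""

    immediate_amp: float = 300.0
    secondary_amp: float = 220.0
    paroxysmal_amp: float = 800.0
    #: fractional linear growth of the immediate-discharge gain over a train
    gain_drift: float = 0.08
    #: fractional evolution of the immediate-discharge shape over a train
    #: (the immediate discharge visibly evolves during the induction phase)
    shape_drift: float = 1.0
    #: secondary-discharge amplitude ramp after the divergent point; the
    #: emergence is abrupt, so the ramp is short
    ramp_s: float = 0.75
    #: crossfade between secondary latency sub-patterns
    crossfade_s: float = 1.0
    #: latency cycle (s post-pulse) visited by successive sub-patterns
    latency_cycle: tuple[float, ...] = (0.030, 0.044, 0.035, 0.047, 0.039)
    secondary_sigma: float = 0.004
    secondary_freq: float = 35.0
    immediate_freq: float = 150.0
    immediate_tau: float = 0.003
    #: paroxysmal suppression of pulse-locked discharges; slow enough that
    #: the collapse is resolvable as its own trajectory displacement
    suppress_s: float = 0.8
    suppress_residual: float = 0.05
    #: rise time of the paroxysmal bursting envelope
    par_rise_s: float = 1.2
    #: carrier band of the paroxysmal bursting
    par_band: tuple[float, float] = (2.5, 7.5)
    #: weight of the per-epoch band-limited stochastic ictal component
    #: relative to the stereotyped chirp progression
    par_rough_weight: float = 0.1
    spike_amp: float = 300.0
    spike_secondary_latency: float = 0.025


# --------------------------------------------------------------------------
# primitive waveforms
# --------------------------------------------------------------------------


def immediate_kernel(
    fs: float, params: SynthParams | None = None, morph: float = 0.0
) -> np.ndarray:
    """Damped biphasic deflection with 10 ms support (unit peak x amplitude).

    ``morph`` in [0, 1] broadens, slows and delays the waveform along a
    canonical progression, emulating the gradual shape evolution of the
    immediate discharge over a train.
    """
    p = params or SynthParams()
    n = int(round(0.010 * fs))
    t = np.arange(n) / fs
    m = morph * p.shape_drift
    tau = p.immediate_tau * (1.0 + 0.6 * m)
    freq = p.immediate_freq * (1.0 - 0.25 * m)
    shift = 0.0030 * m  # peak latency creeps later, still inside 0-10 ms
    k = np.sin(2 * np.pi * freq * np.maximum(t - shift, 0.0)) * np.exp(
        -np.maximum(t - shift, 0.0) / tau
    )
    # cosine taper over the last millisecond so support is exactly 0-10 ms
    n_tap = max(1, int(round(0.001 * fs)))
    k[-n_tap:] *= 0.5 * (1 + np.cos(np.linspace(0, np.pi, n_tap)))
    # constant energy across the morph: the immediate-discharge shape
    # evolves over a train while its power stays stable
    k0 = np.sin(2 * np.pi * p.immediate_freq * t) * np.exp(-t / p.immediate_tau)
    k0[-n_tap:] *= 0.5 * (1 + np.cos(np.linspace(0, np.pi, n_tap)))
    ref_energy = np.linalg.norm(k0 / np.max(np.abs(k0)))
    return p.immediate_amp * ref_energy * k / np.linalg.norm(k)


def secondary_kernel(
    fs: float, latency_s: float, params: SynthParams | None = None
) -> np.ndarray:
    """Gaussian-windowed oscillation centred ``latency_s`` after the pulse,
    defined on a 0-60 ms support (unit peak x amplitude)."""
    p = params or SynthParams()
    n = int(round(0.060 * fs))
    t = np.arange(n) / fs
    k = np.exp(-((t - latency_s) ** 2) / (2 * p.secondary_sigma**2)) * np.sin(
        2 * np.pi * p.secondary_freq * (t - latency_s)
    )
    m = np.max(np.abs(k))
    return p.secondary_amp * k / m if m > 0 else k


def pink_noise(n: int, fs: float, sd: float, rng: Generator) -> np.ndarray:
    """1/f-power-shaped Gaussian noise, flattened below 1 Hz, scaled to sd."""
    white = rng.standard_normal(n)
    spec = rfft(white)
    f = rfftfreq(n, 1.0 / fs)
    spec *= 1.0 / np.sqrt(np.maximum(f, 1.0))
    x = irfft(spec, n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _cos_edge(t: np.ndarray, t0: float, t1: float, rise: float) -> np.ndarray:
    """Smooth 0->1->0 envelope over [t0, t1] with cosine edges of ``rise`` s."""
    env = np.zeros_like(t)
    inside = (t >= t0) & (t < t1)
    env[inside] = 1.0
    up = inside & (t < t0 + rise)
    env[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - t0) / rise))
    dn = inside & (t >= t1 - rise)
    env[dn] = np.minimum(env[dn], 0.5 * (1 - np.cos(np.pi * (t1 - t[dn]) / rise)))
    return env


@dataclass(frozen=True)
class _ParProfile:
    """Stereotyped ictal progression, shared by all seizures of a recording.

    Within a subject the electrographic evolution of a seizure is
    stereotyped: the bursting is generated as a deterministic downward
    chirp with amplitude-modulated bursts, indexed by the *completion
    fraction* of the ictal progression rather than wall time.  Every
    seizure of a recording traverses the same progression, a short seizure
    being a time-compressed rendition of a long one.  Per-epoch
    variability enters through phase-free band-limited stochastic activity.
    """

    f_start: float
    n_bursts: float
    ph1: float
    ph2: float
    ph_am: float
    #: nominal progression duration (s) of the evolving (tonic-like) part
    nominal_span: float = 13.0
    #: completion fraction at which the progression saturates into a steady
    #: ictal state; every seizure lasting beyond nominal_span * c_sat shares
    #: the same terminal activity
    c_sat: float = 0.5

    @classmethod
    def sample(cls, rng: Generator, params: SynthParams) -> "_ParProfile":
        lo, hi = params.par_band
        return cls(
            # kept well below the stimulation fundamental so window leakage
            # into the first harmonic band stays small
            f_start=float(rng.uniform(0.5 * hi, 0.75 * hi)),
            n_bursts=float(rng.uniform(1.5, 3.5)),
            ph1=float(rng.uniform(0, 2 * np.pi)),
            ph2=float(rng.uniform(0, 2 * np.pi)),
            ph_am=float(rng.uniform(0, 2 * np.pi)),
        )


def _paroxysmal_wave(
    t: np.ndarray,
    t0: float,
    t1: float,
    params: SynthParams,
    profile: _ParProfile,
    rng: Generator,
    fs: float,
) -> np.ndarray:
    """High-amplitude bursting not locked to any pulse.

    The deterministic part is a stereotyped progression of
    ``tau`` = time since the paroxysmal point, shared by all seizures of a
    recording: a slow amplitude-modulated carrier chirping down from
    ``f_start`` to the band floor, plus a clonic-like spikelet train that
    densifies and sharpens as the seizure evolves.  The progression
    saturates into a steady ictal state at completion ``c_sat``, so every
    seizure that lasts long enough shares the same terminal activity and
    a short seizure's ictal content is a prefix of a longer one's.  A
    per-epoch band-limited stochastic component is added on top.
    """
    tau = t - t0
    lo, _ = params.par_band
    c = np.minimum(tau / profile.nominal_span, profile.c_sat)
    f_slow = lo + (profile.f_start - lo) * np.maximum(1.0 - c / profile.c_sat, 0.0)
    phase_slow = 2 * np.pi * np.cumsum(f_slow) / fs
    am = 0.55 + 0.45 * np.sin(2 * np.pi * profile.n_bursts * c + profile.ph_am)
    grow = 1.0 + 0.4 * c / profile.c_sat
    w = am * np.sin(phase_slow + profile.ph1)
    # clonic-like sharp spikelets at irregular (comb-free) profile-fixed
    # times, densifying, sharpening and growing until saturation
    tau_j = 0.3
    j = 0
    tau_max = float(tau[-1]) if tau.size else 0.0
    while tau_j < tau_max:
        cj = min(tau_j / profile.nominal_span, profile.c_sat) / profile.c_sat * 1.5
        width = 0.010 - 0.005 * cj / 1.5
        # low amplitude and low duty cycle: visible to strip-level
        # trajectory comparison, negligible in the power spectrum
        a_sp = 0.12 + 0.35 * cj / 1.5
        n_k = int(round(width * fs))
        i0 = int(round((tau_j - float(tau[0])) * fs))
        if 0 <= i0 and i0 + n_k <= w.size and n_k > 2:
            u = np.arange(n_k) / fs
            kern = np.sin(2 * np.pi * u / width) * np.exp(-(((u - width / 3) / (width / 3)) ** 2))
            w[i0 : i0 + n_k] += a_sp * kern
        j += 1
        frac = np.modf(np.sin((j + 1) * (1.0 + profile.ph2)) * 4375.85)[0]
        isi = (0.16 + 0.12 * abs(frac)) * (1.0 - 0.5 * cj / 1.5)
        tau_j += isi
    w *= grow / 1.6
    # per-epoch stochastic ictal component (part of the seizure, not noise)
    rough = rng.standard_normal(t.size)
    spec = rfft(rough)
    f = rfftfreq(t.size, 1.0 / fs)
    spec[f > 40.0] = 0.0
    rough = irfft(spec, t.size)
    s = rough.std()
    if s > 0:
        rough *= params.par_rough_weight / s
    return params.paroxysmal_amp * _cos_edge(t, t0, t1, params.par_rise_s) * (w + rough)


def _suppression(t: float, px: float | None, params: SynthParams) -> float:
    """Pulse-locked discharges fade to a residual once paroxysmal activity
    takes over."""
    if px is None or t < px:
        return 1.0
    frac = min(1.0, (t - px) / params.suppress_s)
    return 1.0 - (1.0 - params.suppress_residual) * frac


# --------------------------------------------------------------------------
# epoch assembly
# --------------------------------------------------------------------------


def _add_epoch_response(
    x: np.ndarray,
    fs: float,
    t0: float,
    train_start: float,
    train_s: float,
    pulses: np.ndarray,
    spec: ResponseSpec,
    params: SynthParams,
    profile: _ParProfile,
    rng: Generator,
) -> None:
    """Add one epoch's deterministic response components to ``x`` in place.

    ``t0`` is the absolute time of ``x[0]``; ``pulses`` are absolute onsets.
    """
    di = None if spec.divergent_time is None else train_start + spec.divergent_time
    px = None if spec.paroxysmal_time is None else train_start + spec.paroxysmal_time
    end = None if spec.end_time is None else train_start + spec.end_time

    # bank of immediate-discharge shapes along the canonical progression
    morph_grid = np.linspace(0.0, 1.0, 41)
    imm_bank = [immediate_kernel(fs, params, m) for m in morph_grid]
    n_pat = max(1, spec.complexity_loops)
    kernels = [
        secondary_kernel(fs, params.latency_cycle[j % len(params.latency_cycle)], params)
        for j in range(n_pat)
    ]
    rev_stop = px if px is not None else train_start + train_s
    bounds = None
    if di is not None:
        bounds = np.linspace(di, rev_stop, n_pat + 1)

    def _add(at: float, kern: np.ndarray, scale: float) -> None:
        i = int(round((at - t0) * fs))
        if i < 0 or i + kern.size > x.size:
            return
        x[i : i + kern.size] += scale * kern

    for tk in pulses:
        frac = (tk - train_start) / train_s
        gain = 1.0 + params.gain_drift * frac
        supp = _suppression(tk, px, params)
        m = _morph_at(tk - train_start, spec, train_s)
        k_imm = imm_bank[int(round(np.clip(m, 0, 1) * (morph_grid.size - 1)))]
        _add(tk, k_imm, gain * supp)
        if di is None or tk < di:
            continue
        # secondary discharge: ramping amplitude, sub-pattern crossfades
        ramp = min(1.0, (tk - di) / params.ramp_s)
        grow = 1.0 + 0.4 * (tk - di) / max(rev_stop - di, 1e-9)
        j = min(int(np.searchsorted(bounds, tk, side="right")) - 1, n_pat - 1)
        w_new = 1.0
        if j > 0:
            w_new = min(1.0, (tk - bounds[j]) / params.crossfade_s)
        amp = ramp * grow * supp
        _add(tk, kernels[j], amp * w_new)
        if j > 0 and w_new < 1.0:
            _add(tk, kernels[j - 1], amp * (1.0 - w_new))

    if px is not None and end is not None:
        i0 = max(0, int(round((px - t0) * fs)))
        i1 = min(x.size, int(round((end - t0) * fs)))
        if i1 > i0:
            tt = t0 + np.arange(i0, i1) / fs
            x[i0:i1] += _paroxysmal_wave(tt, px, end, params, profile, rng, fs)


def _markers_for(
    spec: ResponseSpec, train_start: float, epoch: int
) -> PhaseMarkers:
    return PhaseMarkers(
        epoch_start=train_start,
        divergent_point=(
            None if spec.divergent_time is None else train_start + spec.divergent_time
        ),
        paroxysmal_point=(
            None if spec.paroxysmal_time is None else train_start + spec.paroxysmal_time
        ),
        seizure_end=(None if spec.end_time is None else train_start + spec.end_time),
        epoch=epoch,
    )


# --------------------------------------------------------------------------
# public generators
# --------------------------------------------------------------------------


def generate_optogenetic_recording(
    protocol: StimProtocol,
    schedule: list[ResponseSpec],
    noise: NoiseSpec,
    params: SynthParams | None = None,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    post_s: float = 90.0,
) -> tuple[EEGRecording, list[PhaseMarkers], list[ResponseLabel]]:
    """Synthesize a full multi-epoch stimulation recording.

    Returns the recording (starting at t=0, spanning all epochs plus pre-
    and post-baseline), the scheduled ground-truth markers per epoch, and
    the ground-truth response labels (derived from the markers via the
    response classification, so generation and classification agree by
    construction).
    """
    params = params or SynthParams()
    if len(schedule) != protocol.epoch_count:
        raise ValueError("schedule length must equal the epoch count")
    for e, spec in enumerate(schedule):
        a, b = protocol.epoch_windows[e]
        spec.validate(train_s=b - a, epoch_index=e + 1)

    stops = [w[1] for w in protocol.epoch_windows]
    ends = [
        protocol.epoch_windows[e][0] + s.end_time
        for e, s in enumerate(schedule)
        if s.end_time is not None
    ]
    duration = max(stops[-1] + post_s, (max(ends) + 10.0) if ends else 0.0)
    n = int(round(duration * sample_rate))

    ss = SeedSequence(noise.seed)
    kids = ss.spawn(3 + protocol.epoch_count)
    x = pink_noise(n, sample_rate, noise.background_sd, default_rng(kids[0]))
    _add_artifacts(x, sample_rate, noise, default_rng(kids[1]))
    profile = _ParProfile.sample(default_rng(kids[2]), params)

    markers: list[PhaseMarkers] = []
    labels: list[ResponseLabel] = []
    for e, spec in enumerate(schedule):
        a, b = protocol.epoch_windows[e]
        _add_epoch_response(
            x,
            sample_rate,
            0.0,
            a,
            b - a,
            protocol.pulses_in_epoch(e),
            spec,
            params,
            profile,
            default_rng(kids[3 + e]),
        )
        m = _markers_for(spec, a, e)
        markers.append(m)
        labels.append(classify_response(m, e + 1, stim_end=b))
    rec = EEGRecording(x, sample_rate, t0=0.0, channel_name="CA1-synth")
    return rec, markers, labels


def _add_artifacts(
    x: np.ndarray, fs: float, noise: NoiseSpec, rng: Generator
) -> None:
    if noise.artifact_rate <= 0:
        return
    duration = x.size / fs
    n_ev = rng.poisson(noise.artifact_rate * duration)
    width = int(round(0.2 * fs))
    bump = np.hanning(width)
    for t in np.sort(rng.uniform(0, duration, n_ev)):
        i = int(t * fs)
        j = min(x.size, i + width)
        x[i:j] += rng.choice([-1, 1]) * 10.0 * noise.background_sd * bump[: j - i]


def generate_epoch_response(
    spec: ResponseSpec,
    pulse_times: np.ndarray,
    noise: NoiseSpec,
    params: SynthParams | None = None,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    tail_s: float = 20.0,
) -> EEGRecording:
    """Synthesize a single epoch in isolation.

    ``pulse_times`` are seconds from the segment start; the train is taken
    to start at the first pulse.  The returned recording covers
    ``[0, last_pulse + tail_s)`` (extended to the scheduled end time if the
    seizure outlasts it).
    """
    params = params or SynthParams()
    pulses = np.asarray(pulse_times, dtype=float)
    if pulses.size == 0 or np.any(np.diff(pulses) <= 0):
        raise ValueError("pulse_times must be non-empty and strictly increasing")
    train_start = float(pulses[0])
    period = float(np.median(np.diff(pulses))) if pulses.size > 1 else 0.1
    train_s = float(pulses[-1] - pulses[0] + period)
    spec.validate(train_s=train_s)
    duration = pulses[-1] + tail_s
    if spec.end_time is not None:
        duration = max(duration, train_start + spec.end_time + 5.0)
    n = int(round(duration * sample_rate))
    ss = SeedSequence(noise.seed)
    kids = ss.spawn(3)
    x = pink_noise(n, sample_rate, noise.background_sd, default_rng(kids[0]))
    profile = _ParProfile.sample(default_rng(kids[1]), params)
    _add_epoch_response(
        x, sample_rate, 0.0, train_start, train_s, pulses, spec, params,
        profile, default_rng(kids[2]),
    )
    return EEGRecording(x, sample_rate, t0=0.0, channel_name="CA1-synth")


def generate_spontaneous_recording(
    interictal_rate: float,
    seizure_specs: list[tuple[float, float, float]],
    reverberant_rate: float,
    noise: NoiseSpec,
    params: SynthParams | None = None,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    duration_s: float | None = None,
) -> tuple[EEGRecording, np.ndarray, list[PhaseMarkers]]:
    """Synthesize a spontaneous-seizure recording with interictal spikes.

    Parameters
    ----------
    interictal_rate:
        Baseline spike rate (spikes/s) outside seizure windows.
    seizure_specs:
        ``(divergent, paroxysmal, end)`` absolute times per seizure, s.
    reverberant_rate:
        Spike rate between divergent and paroxysmal points; each
        reverberant spike carries an added secondary component 15-50 ms
        after the spike.

    Returns the recording, the ground-truth spike times, and per-seizure
    markers (``epoch_start`` set 60 s before the divergent point).
    """
    params = params or SynthParams()
    if interictal_rate <= 0 or reverberant_rate <= 0:
        raise ValueError("spike rates must be positive")
    if reverberant_rate <= interictal_rate:
        raise ValueError("reverberant_rate must exceed interictal_rate")
    specs = sorted(seizure_specs)
    for di, px, end in specs:
        if not 0 < di < px < end:
            raise ValueError("each seizure needs 0 < divergent < paroxysmal < end")
    for (_, _, e0), (d1, _, _) in zip(specs, specs[1:]):
        if d1 <= e0:
            raise ValueError("seizure windows overlap")
    if duration_s is None:
        duration_s = (specs[-1][2] + 60.0) if specs else 300.0
    n = int(round(duration_s * sample_rate))

    ss = SeedSequence(noise.seed)
    kids = ss.spawn(4 + len(specs))
    x = pink_noise(n, sample_rate, noise.background_sd, default_rng(kids[0]))
    rng_sp = default_rng(kids[1])
    _add_artifacts(x, sample_rate, noise, default_rng(kids[2]))
    profile = _ParProfile.sample(default_rng(kids[3]), params)

    def _poisson_times(t0: float, t1: float, rate: float, min_gap: float) -> np.ndarray:
        raw = np.sort(rng_sp.uniform(t0, t1, rng_sp.poisson(rate * (t1 - t0))))
        keep: list[float] = []
        for t in raw:
            if not keep or t - keep[-1] >= min_gap:
                keep.append(t)
        return np.asarray(keep)

    spike = _spike_kernel(sample_rate, params)
    sec = secondary_kernel(sample_rate, params.spike_secondary_latency, params)

    def _add(at: float, kern: np.ndarray, scale: float = 1.0) -> None:
        i = int(round(at * sample_rate))
        if 0 <= i and i + kern.size <= n:
            x[i : i + kern.size] += scale * kern

    ictal = [(px, end) for _, px, end in specs]
    rev = [(di, px) for di, px, _ in specs]
    blocked = [(di, end) for di, _, end in specs]

    def _outside_blocks(t: float) -> bool:
        return all(not (a <= t < b) for a, b in blocked)

    spikes = [t for t in _poisson_times(0.0, duration_s, interictal_rate, 0.15)
              if _outside_blocks(t)]
    for di, px in rev:
        for t in _poisson_times(di, px, reverberant_rate, 0.06):
            spikes.append(t)
            frac = (t - di) / (px - di)
            # the added secondary component stays near the spike-detection
            # threshold so it reads as part of the discharge, not a new spike
            _add(t, sec, (0.22 + 0.2 * frac) * params.spike_amp / params.secondary_amp)
    spikes = np.sort(np.asarray(spikes))
    for t in spikes:
        _add(t, spike)

    markers = []
    for i, ((di, px, end), kid) in enumerate(zip(specs, kids[4:])):
        i0 = max(0, int(round(px * sample_rate)))
        i1 = min(n, int(round(end * sample_rate)))
        tt = np.arange(i0, i1) / sample_rate
        x[i0:i1] += _paroxysmal_wave(
            tt, px, end, params, profile, default_rng(kid), sample_rate
        )
        markers.append(
            PhaseMarkers(
                epoch_start=max(0.0, di - 60.0),
                divergent_point=di,
                paroxysmal_point=px,
                seizure_end=end,
                epoch=i,
            )
        )
    rec = EEGRecording(x, sample_rate, t0=0.0, channel_name="CA1-KA-synth")
    return rec, spikes, markers


def _spike_kernel(fs: float, params: SynthParams) -> np.ndarray:
    """Positive-leading biphasic interictal-spike waveform (~25 ms), broad
    enough to survive the detector's 10 ms pre-detection smoothing."""
    n = int(round(0.025 * fs))
    t = np.arange(n) / fs
    k = np.sin(2 * np.pi * 55.0 * t) * np.exp(-t / 0.010)
    n_tap = max(1, int(round(0.002 * fs)))
    k[-n_tap:] *= 0.5 * (1 + np.cos(np.linspace(0, np.pi, n_tap)))
    return params.spike_amp * k / np.max(np.abs(k))
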