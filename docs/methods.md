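# Methods

This note documents the models implemented in `ictogram`, the defaults
that matter, the design choices made where the design was genuinely open,
and what the synthetic data generator does and does not emulate.

## Signal path and conventions

Time is seconds from recording start; sample `i` covers
`[i/fs, (i+1)/fs)`. The nominal acquisition rate is 3 kHz. EEG is stored
as single-channel EDF (16-bit, default physical range ±5000 µV, so the
quantization step is ~0.15 µV); events are TSV
(`onset_s duration_s label epoch`), markers JSON keyed by epoch.
Acquisition-equivalent filtering is a 4th-order Butterworth band-pass
(default 3–1000 Hz) plus IIR notches at 60/120/180 Hz (Q = 30), applied
forward–backward so filtering adds no group delay and marker latencies
remain comparable to the raw trace. How many line-noise harmonics the
acquisition hardware notched is not documented; three notches is the
default and the list is a parameter.

## Pulsogram

`build_pulsogram` is exact re-slicing: strip `x` is the raw samples at
`anchor_times[x] + y`, `y ∈ [−5, 60) ms` by default, with no resampling
or smoothing — concatenating strips reproduces the corresponding raw
samples. Strips whose window leaves the recording are dropped with a log
entry. For pulse anchors the train can be extrapolated at the pulse
period past stimulation end (`extrapolate_s`), which visualizes whether
locked structure outlives the drive.

The display window is −5..60 ms; all quantitative analysis (strip energy,
trajectory preprocessing) uses −5..50 ms.

### Spike anchoring

For spontaneous recordings the anchors are detected spikes: local maxima
of the 10 ms, 2nd-order Savitzky–Golay-smoothed trace above
`6 × median(|x|)`. The MAD here is deliberately the unscaled median
absolute deviation about zero (no 1.4826 factor, no centering on the
median) and only positive-going peaks are detected. Of any two peaks
closer than 20 ms the later one is discarded, keeping only the first peak
of a multi-phasic discharge. The pre-detection smoothing length is not
independently documented for the original analysis; the 10 ms kernel is
reused from the power smoothing for consistency.

### Power pulsogram

Instantaneous power is the squared Hilbert envelope, smoothed with a
10 ms, 2nd-order Savitzky–Golay filter. The polynomial smoother can
undershoot zero at sharp transients, so the smoothed power is floored at
10⁻⁶ of the mean power (−60 dB) before the dB conversion. Values are
`10·log10(P / reference)` where the reference is computed **per
pulse-time row** as the mean linear power over the reference strips — the
induction phase for pulse anchors, the 60 s before the divergent point
for spike anchors (so the reference region averages 0 dB up to the Jensen
gap between mean-of-logs and log-of-mean). When markers are not yet
known, the pipeline uses the first 2 s of stimulation as a pre-divergent
reference proxy.

Band-power changes about the divergent point (`delta_power`) compare the
mean dB over the reverberant strips against the induction strips, for the
early (0–20 ms) and late (20–50 ms) pulse-time bands; the spontaneous
variant uses 15–50 ms for the late band.

## Trajectory preprocessing

Three stages, in order:

1. Savitzky–Golay smoothing along pulse time (2 ms, order 2);
2. per-strip scaling by `κ[x] = sqrt((v[x] + v0)/2)` with
   `v[x] = Σ_{y∈[−5,50] ms} s[y]²` computed after stage 1 and `v0` the
   mean of `v` over the stimulation strips. The scaled strip energy is
   `v/κ² = 2v/(v+v0)`: monotone in `v` but saturating below 2, so motion
   artifacts and overwhelming paroxysmal strips are attenuated without
   discarding them, and quiet strips are not blown up;
3. Savitzky–Golay smoothing along strips (2 s converted at the anchor
   rate, i.e. 21 strips at 10 Hz, order 2).

Savitzky–Golay edges use polynomial fits (`mode="interp"`), not
reflection padding. For spike-anchored trajectories `v0` averages over
all strips by default (configurable via `stim_mask`).

## Spectral analysis

Spectrograms use a 0.33 s Hann window with 87.5 % overlap (hop
41.25 ms), one-sided PSD scaling, so the full-band power integrates to
the signal variance. Harmonic power sums the PSD over bands `k·f0 ± 1 Hz`
(k ≥ 1, k·f0 ≤ 200 Hz, bands unioned so overlaps are not double-counted);
total power integrates 0 < f ≤ 200 Hz, excluding the DC bin; non-harmonic
power is their difference, exactly, at every frame.

One estimator property worth knowing: a 0.33 s Hann window's mainlobe is
wider than the ±1 Hz harmonic band, so even a perfectly periodic signal
shows only ≈45 % of its power inside the bands at this resolution. All
detector logic therefore works with *relative* changes of the harmonic
fraction, never its absolute level; tests that assert near-complete
harmonic capture use a 1 s window, where the bands are resolvable.

Event-aligned averaging rescales each trace segment-by-segment (e.g.
15 s pre-stimulation | stimulation→Px | Px→stimulation end | 15 s post)
onto a fixed grid of 100 points per segment with a monotone linear warp,
then averages pointwise; traces with missing or out-of-order markers are
excluded with a logged reason. `grouped_average` supports the
within-subject-then-across-subjects hierarchy.

## Transition detection

All thresholds live in `DetectorParams` and are pragmatic defaults
anchored to the qualitative signatures, not biological constants:

* **divergent point** — late-band (20–50 ms) mean dB per strip, smoothed
  0.3 s; baseline = first 2 s of stimulation strips; threshold = baseline
  mean + max(3 SD, 3 dB) (the absolute floor guards against an
  arbitrarily quiet baseline); first run above threshold sustained 1 s.
* **paroxysmal point** — harmonic fraction of the spectrogram, smoothed
  0.3 s, compared to 50 % of its running median over the preceding 5 s
  with a 1.5 s guard gap (so the reference stays strictly pre-transition
  while the locked discharges collapse); a candidate must also exceed the
  pre-stimulation total-power baseline + 3 SD, and is confirmed when 60 %
  of the following 1 s satisfies both conditions. Candidates are limited
  to frames whose analysis window lies fully inside the train (as the
  window slides off the last pulse the harmonic fraction collapses
  trivially), while confirmation may use post-train frames — there, only
  genuine seizure activity keeps total power elevated. The reported time
  is the start of the first triggering frame.
* **seizure end** — first post-Px frame with total power below the
  pre-stimulation baseline + 2 SD where ≥90 % of the following 2 s stays
  below (a fraction, because heavy-tailed noise frames should not
  postpone the end).

Markers that never trigger are absent; a paroxysmal signature without a
divergent point is dropped (with a warning) to preserve the phase
ordering invariant. Classification is a total function of the markers:
no Di → Flat; Di without Px → Evolving; Px at epoch 1 → SzF; otherwise
SzKS if the seizure ends within 5 s of stimulation end (boundary
inclusive), else SzKL (also when the end is unresolved). The behavioral
point is an annotation pass-through and is never computed.

## Trajectory structure

* **PCA** — strips are observations, mean-centered, no variance scaling
  (strips share units after the κ normalization); `n_components_90` is
  the smallest count reaching 90 % cumulative explained variance.
* **DTW** — classic symmetric steps {(1,0), (0,1), (1,1)}, per-point
  Euclidean cost, no window constraint; the separation distance is the
  summed cost along the optimal path; backtracking prefers the diagonal
  on exact ties. Distances within a recording are normalized by the mean
  distance from the epoch-1 trajectory to all other epochs. Coverage
  curves report the cumulative percentage of each trajectory consumed
  along the path, in both directions.
* **Angular segmentation** — the turning angle at point `x` is measured
  between the displacements from the preceding 1 s mean to the point and
  from the point to the following 1 s mean, reported so that 180° means
  the direction is maintained and 0° a full reversal. (The verbal
  convention "sharper turns give larger angles" is ambiguous about its
  reference; with this orientation, trough detection — below 90° with
  ≥30° prominence — finds sharp corners and returns no breakpoints on a
  straight path, which is the behaviour that matters.) A candidate trough
  is retained, checked left-to-right against the last retained
  breakpoint, only if it is >0.67 s later, the two segment means it
  separates differ by more than `d/√2` in Euclidean norm (`d` = mean step
  between consecutive points; the difference of two mean vectors is
  compared as a norm since a scalar inequality needs one), and their
  correlation is below 0.9.
* **RDP** — standard recursive farthest-point simplification in the full
  n-dimensional space. The default tolerance is 8× the mean step: at
  these signal-to-noise ratios a 2×-step tolerance sits inside the
  smoothed-noise wander and retains mostly noise vertices, which erases
  complexity differences. When comparing epochs of one recording, use
  `common_rdp_epsilon` (8× the mean step pooled over the recording's
  trajectories): a per-epoch tolerance scales with each epoch's own
  excursion size and again hides the differences the comparison is after.

## Optics

On-axis irradiance below the fiber tip combines conical spread with
half-angle `arcsin(NA/n)` — equivalently, distance-squared decay from the
virtual cone apex at `ρ = r·sqrt((n/NA)² − 1)` behind the fiber face —
with Kubelka–Munk zero-absorption scattering `1/(S·z + 1)`. The default
scatter coefficient is the standard mouse gray-matter value for blue
light, `S = 11.2 mm⁻¹` (the classical rat value 10.3 mm⁻¹ is provided as
a constant). The activation depth solves irradiance = threshold by
Brent's method (absolute tolerance 10⁻⁹ mm) and is 0 when the surface
irradiance is already at or below threshold. Reported depths are
sensitive to the scattering coefficient and to whether a quoted fiber
dimension is a radius or a diameter; both are explicit parameters
(`scatter_per_mm`, `radius_is_diameter`).

## The synthetic generator

The generator emulates the study conditions so the pipeline can be
validated against exported ground truth: 15-epoch recordings (30 s trains
of 5 ms pulses at 5/10/20 Hz, 90 s breaks, 15 s lead-in) at 3 kHz, and
spontaneous-seizure recordings with interictal spikes. Only latency
windows and power signatures of the responses are constrained by
observation; waveform morphology is a modelling choice, as follows.

* **Immediate discharge** — damped biphasic oscillation (150 Hz carrier,
  3 ms decay) confined to 0–10 ms, peak 300 µV. Its shape evolves along a
  canonical progression (slower, broader, slightly delayed) — the
  immediate discharge visibly evolves during a train — while its energy
  is held constant (the immediate-discharge power is observed to be
  stable across phases). Crucially, the progression is indexed by
  *activity-phase fraction*, not wall time, and each response type
  traverses a different extent of the same path (Flat to 0.25, Evolving
  to 0.55, seizures to 0.70 by their paroxysmal point). This realizes the
  observation that all response types traverse one common response
  sequence progressively further, and it is what makes a simpler
  response's trajectory a genuine sub-segment of a richer one's.
* **Secondary discharge** — Gaussian-windowed 35 Hz oscillation (σ =
  4 ms) centred at a latency from the 30–47 ms cycle, appearing abruptly
  at the divergent point (0.75 s amplitude ramp, peak 220 µV, mild growth
  through the reverberant phase). `complexity_loops` distinct latency
  sub-patterns are visited sequentially through the reverberant phase
  with 1 s crossfades; each switch is a direction reversal in response
  space and hence one angular breakpoint. Defaults: Flat 0, Evolving 2,
  breakthrough 3, first seizures 5 — first seizures contain the most
  sub-patterns ("loops").
* **Paroxysmal activity** — amplitude-modulated low-frequency bursting
  (carrier chirping down from ~4–5.6 Hz to 2.5 Hz), plus a clonic-like
  train of sharp spikelets at irregular, comb-free times that densifies
  and sharpens as the seizure evolves, plus a per-epoch band-limited
  stochastic component. The deterministic part is a stereotyped function
  of time-since-Px shared by all seizures of a recording, saturating into
  a steady ictal state after ~6.5 s: within one recording every seizure
  traverses the same ictal progression for as long as its paroxysmal
  phase lasts, so a short seizure's ictal content is a prefix of a long
  one's. The carrier starts well below the stimulation fundamental so
  spectral leakage into the first harmonic band stays small, and the
  spikelets have low amplitude and duty cycle — visible to strip-level
  trajectory comparison, negligible in the power spectrum. While
  paroxysmal activity runs, the pulse-locked discharges fade to 5 % over
  0.8 s (their collapse is itself a resolvable trajectory displacement).
* **Scheduled latencies** (`ResponseSpec.typical`) — induction shortest
  for first seizures (3–6 s vs 6–12 s), as observed. Across the
  non-seizure → seizure ladder the scheduled phase durations shorten
  (Evolving diverges at 12–18 s, break-short at 9.5–12 s, break-long at
  6–8.5 s with the earliest paroxysmal entry), so lower-order responses
  traverse the shared path more slowly and are consumed faster under
  DTW — the phase-aligned nesting geometry. Break-long seizures entering
  the paroxysmal phase earliest encodes their richer in-train ictal
  content; their scheduled reverberant phase is correspondingly the
  shortest, a simplification adopted for the nesting geometry.
* **Spontaneous recordings** — 25 ms positive-leading biphasic interictal
  spikes (300 µV = 10× the background SD; broad enough to survive the
  detector's 10 ms smoothing) at Poisson times with a 150 ms minimum gap;
  between the divergent and paroxysmal points the rate switches to the
  reverberant rate (60 ms minimum gap) and each spike gains a secondary
  component ~25 ms later whose amplitude ramps from just below the 6-MAD
  detection threshold — it reads as part of the discharge, not as a new
  spike. After Px the same ictal construct runs until the seizure end.
* **Noise** — 1/f-power-shaped Gaussian background (default SD 30 µV =
  10 % of the immediate-discharge amplitude; spectrum flattened below
  1 Hz), optional transient artifacts (default off). All randomness
  derives from `NoiseSpec.seed` through a spawned seed tree; identical
  inputs give bit-identical recordings, and the response content is
  independent of the background-noise level.

What the generator does **not** emulate: biophysical network dynamics,
behavioral (Racine) correlates, electrode drift or impedance change
across sessions, movement artifacts beyond the optional bumps,
multi-channel fields, and any between-animal variability. Tests passing
on this data show that the pipeline recovers the structures the generator
encodes under realistic noise — not that those structures exhaust real
recordings.

## Problem sizes used by the test suite

The suite exercises the full paradigm at reduced bulk: batteries use
5-epoch recordings (one per response type, first seizure at epoch 1, the
rest shuffled) with 30 s inter-train breaks and a 30 s tail; 50 such
recordings for the complexity/nesting batteries and 20 recordings × 5
seizure epochs (100 epochs) for transition recovery. Nesting is evaluated
at every warping-path vertex with a one-path-step slack (0.33 % of a
300-strip trajectory), the discretization limit of the curve.

## Known limitations

* The divergent/paroxysmal detectors are validated on synthetic ground
  truth only; for spontaneous seizures especially, automated
  spike-pulsogram detection extrapolates beyond what manual marking can
  confirm.
* The harmonic-fraction contrast is bounded by the 0.33 s window's
  leakage (locked ceiling ≈ 0.45, broadband floor ≈ 0.3 of the ≤200 Hz
  power), so the paroxysmal detector depends on ictal power being
  concentrated at low frequencies; strongly broadband seizure onsets
  would need a wider-band criterion.
* DTW separation distance is not a metric (no triangle inequality); only
  symmetry and identity are asserted.
* The optics model ignores absorption, interface losses and beam
  structure; its output should be read as an order-of-magnitude estimate
  whose value moves materially with the scattering coefficient and the
  radius convention.
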