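# ictogram

Pulse-locked **pulsogram** analysis of EEG/LFP ictogenesis: build
time-vs-time maps of the response to optogenetic pulse trains (or to
detected interictal spikes), locate the discrete transition points of
seizure generation, classify epoch responses, and quantify how responses
nest inside each other and how complex they are.

## The problem and who this is for

When hippocampal CA1 excitatory neurons are driven with 30 s trains of
5 ms light pulses (5/10/20 Hz), the EEG response evolves through discrete
phases rather than gradually:

* **induction** — a stereotyped *immediate discharge* time-locked 0–10 ms
  after each pulse;
* **reverberant** — from the *divergent point* (Di), a *secondary
  discharge* appears 20–50 ms after each pulse and evolves with continued
  stimulation;
* **paroxysmal** — from the *paroxysmal point* (Px), high-amplitude
  activity that is no longer time-locked to the pulses: the
  electrographic seizure-onset surrogate.

Non-seizure responses stop after the first (Flat) or second (Evolving)
phase; seizures traverse all three and split into first-of-day (SzF),
break-short (SzKS, ending within 5 s of stimulation end) and break-long
(SzKL). The package is aimed at electrophysiologists who want to run this
analysis on their own single-channel recordings, and ships a seeded
synthetic generator that emulates the paradigm end-to-end so every stage
is testable without animal data.

## The core constructs

**Pulsogram.** EEG snippets `s[y]`, y ∈ [−5, 60] ms around each pulse (or
detected spike), stacked in chronological order: rows are pulse-relative
time, columns are strips. Pulse-locked structure shows as horizontal
bands; paroxysmal activity destroys the banding.

**Trajectory preprocessing.** Each strip is a point of an n-dimensional
trajectory. After 2 ms Savitzky–Golay smoothing along pulse time, every
strip is divided by a regularized power scale

```
κ[x] = sqrt((v[x] + v0) / 2),   v[x] = Σ_{y ∈ [−5,50] ms} s[y]²,
v0 = mean of v over the stimulation strips,
```

which bounds the influence of spuriously loud strips (scaled strip energy
`2 v/(v+v0) < 2`), followed by 2 s Savitzky–Golay smoothing along strips.

**Transition detection.** Di is the first sustained rise of the late
(20–50 ms) pulse-locked Hilbert power above its early-stimulation
baseline (+3 SD); Px is the first sustained collapse of the
stimulation-harmonic power fraction below 50 % of its pre-paroxysmal
running median together with a broad power rise; the seizure end is the
return of total power to the pre-stimulation baseline.

**Nesting and complexity.** Dynamic time warping ties the ends of two
trajectories and aligns them monotonically with minimal summed Euclidean
separation; the warping-path coverage curve rises above the diagonal when
the simpler response is contained in the richer one. Complexity is
counted as angular segments (troughs of the turning-angle series below
90° with ≥30° prominence, pruned by spacing/displacement/correlation
rules), cross-checked by Ramer–Douglas–Peucker simplification, and as the
number of principal components needed for 90 % variance.

## Worked example

```python
import numpy as np
from ictogram import (NoiseSpec, ResponseSpec, StimProtocol,
                      generate_optogenetic_recording)
from ictogram.pipeline import analyze_optogenetic
from ictogram.phases import summary_table

protocol = StimProtocol.standard(frequency=10.0, epoch_count=5,
                                 train_s=30.0, break_s=30.0)
rng = np.random.default_rng(1)
kinds = ["SzF", "Flat", "Evolving", "SzKS", "SzKL"]
schedule = [ResponseSpec.typical(k, rng) for k in kinds]
rec, truth, truth_labels = generate_optogenetic_recording(
    protocol, schedule, NoiseSpec(seed=1), post_s=30.0)
markers, labels, spec = analyze_optogenetic(rec, protocol)
print(summary_table(markers, labels, protocol).round(2).to_string(index=False))
```

prints

```
 epoch    label  divergent_s  paroxysmal_s  seizure_end_s  induction_latency_s  reverberant_duration_s  seizure_duration_s
     1      SzF         19.8         29.93          53.73                  4.8                   10.13               23.81
     2     Flat          NaN           NaN            NaN                  NaN                     NaN                 NaN
     3 Evolving        152.7           NaN            NaN                 17.7                     NaN                 NaN
     4     SzKS        205.6        215.02         228.70                 10.6                    9.42               13.68
     5     SzKL        262.4        268.05         293.05                  7.4                    5.65               25.01
```

— every epoch correctly classified from the detected markers, with the
first seizure showing the shortest induction latency (4.8 s). Trajectory
analysis of the same recording (`epoch_trajectory`, `angular_segmentation`,
`pca_embed`, `dtw_compare`) yields

```
epoch 1 (SzF     ) angular segments=17  PCs for 90% variance=6
epoch 2 (Flat    ) angular segments= 1  PCs for 90% variance=5
epoch 3 (Evolving) angular segments= 7  PCs for 90% variance=2
epoch 4 (SzKS    ) angular segments=15  PCs for 90% variance=4
epoch 5 (SzKL    ) angular segments=18  PCs for 90% variance=5

Flat->Evolving coverage when Evolving is 80% consumed: 91.6%
```

— the flat response is a single segment, complexity grows along the
response ladder, and the flat trajectory is consumed faster than the
evolving one in the warping (coverage above the diagonal): the simpler
response is nested inside the richer one.

The same pipeline is scriptable from a shell:

```
ictogram simulate --seed 1 --schedule SzF,Flat,Evolving,SzKS,SzKL --out rec
ictogram detect --edf rec.edf --events rec.events.tsv --out-json markers.json
ictogram report --edf rec.edf --events rec.events.tsv --out-tsv summary.tsv
ictogram optics-depth --power-mw 1.46 --na 0.57 --radius-mm 0.4
```

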