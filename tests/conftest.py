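"""Shared fixtures: seeded synthetic batteries reused across test modules.

The batteries emulate the study conditions (30 s trains of 5 ms pulses at
10 Hz, 15 s pre-train baseline) with inter-train breaks shortened to 30 s
to keep the suite fast; every epoch carries exported ground truth.
"""

from __future__ import annotations

import numpy as np
import pytest

from ictogram import (
    NoiseSpec,
    ResponseSpec,
    StimProtocol,
    common_rdp_epsilon,
    angular_segmentation,
    dtw_compare,
    generate_optogenetic_recording,
    pca_embed,
    rdp_segmentation,
)
from ictogram.pipeline import analyze_optogenetic, epoch_trajectory

KINDS = ["SzF", "Flat", "Evolving", "SzKS", "SzKL"]
NEST_PAIRS = [("Flat", "Evolving"), ("Evolving", "SzKS"), ("SzKS", "SzKL")]
BATTERY_SEED = 73000
N_COMPLEXITY = 50
N_TRANSITION_RECORDINGS = 20  # x 5 seizure epochs = 100 epochs


def make_recording(seed: int, break_s: float = 30.0):
    """One 5-epoch recording with all five response types (SzF at epoch 1,
    the rest in seeded random order)."""
    rng = np.random.default_rng(seed)
    order = ["SzF"] + [str(k) for k in rng.permutation(["Flat", "Evolving", "SzKS", "SzKL"])]
    protocol = StimProtocol.standard(frequency=10.0, epoch_count=5, train_s=30.0, break_s=break_s)
    specs = [ResponseSpec.typical(k, rng) for k in order]
    rec, markers, labels = generate_optogenetic_recording(
        protocol, specs, NoiseSpec(seed=seed), post_s=30.0
    )
    return protocol, order, specs, rec, markers, labels


@pytest.fixture(scope="session")
def complexity_battery():
    """50 seeded recordings analyzed for trajectory complexity and nesting.

    Per recording: angular/RDP segment counts and PCA dimensionality per
    response type, coverage-curve nesting verdicts for the ordered pairs,
    DTW distances of SzKL to the other types plus the epoch-1 reference
    distances, and the kappa-normalization fields of every trajectory.
    """
    out = []
    for i in range(N_COMPLEXITY):
        protocol, order, specs, rec, markers, labels = make_recording(BATTERY_SEED + i)
        tms = {k: epoch_trajectory(rec, protocol, e) for e, k in enumerate(order)}
        eps = common_rdp_epsilon(list(tms.values()))
        entry = {
            "order": order,
            "specs": specs,
            "markers": markers,
            "labels": labels,
            "stim_end": [protocol.stim_end(e) for e in range(5)],
            "segments": {},
            "rdp": {},
            "n90": {},
            "kappa_fields": [],
        }
        for k in KINDS:
            tm = tms[k]
            entry["segments"][k] = angular_segmentation(tm).segment_count
            entry["rdp"][k] = rdp_segmentation(tm, epsilon=eps).segment_count
            entry["n90"][k] = pca_embed(tm).n_components_90
            entry["kappa_fields"].append(
                (tm.kappa.copy(), tm.strip_power.copy(), tm.mean_power)
            )
        entry["nesting"] = {}
        for lo, hi in NEST_PAIRS:
            r = dtw_compare(tms[lo], tms[hi])
            step = 100.0 / (r.n_a - 1)
            entry["nesting"][(lo, hi)] = bool(
                np.all(r.coverage_a >= r.coverage_b - step - 1e-9)
            )
        ref = [dtw_compare(tms["SzF"], tms[k]).distance for k in KINDS if k != "SzF"]
        entry["epoch1_mean_distance"] = float(np.mean(ref))
        entry["szkl_distances"] = {
            k: dtw_compare(tms["SzKL"], tms[k]).distance
            for k in ("SzKS", "Evolving", "Flat")
        }
        out.append(entry)
    return out


@pytest.fixture(scope="session")
def transition_battery():
    """100 seeded seizure epochs run through the full detection pipeline.

    20 recordings scheduled [SzF, SzKS, SzKL, SzKS, SzKL]; returns signed
    divergent and paroxysmal detection errors (inf when a marker was
    missed) plus scheduled/classified labels.
    """
    kinds = ["SzF", "SzKS", "SzKL", "SzKS", "SzKL"]
    protocol = StimProtocol.standard(frequency=10.0, epoch_count=5, train_s=30.0, break_s=30.0)
    di_err, px_err = [], []
    truth_labels, detected_labels, schedule_kinds = [], [], []
    for i in range(N_TRANSITION_RECORDINGS):
        seed = BATTERY_SEED + 1000 + i
        rng = np.random.default_rng(seed)
        specs = [ResponseSpec.typical(k, rng) for k in kinds]
        rec, markers, labels = generate_optogenetic_recording(
            protocol, specs, NoiseSpec(seed=seed), post_s=30.0
        )
        det, det_labels, _ = analyze_optogenetic(rec, protocol)
        for m, d, lbl, dl, k in zip(markers, det, labels, det_labels, kinds):
            di_err.append(
                np.inf if d.divergent_point is None
                else d.divergent_point - m.divergent_point
            )
            px_err.append(
                np.inf if d.paroxysmal_point is None
                else d.paroxysmal_point - m.paroxysmal_point
            )
            truth_labels.append(lbl)
            detected_labels.append(dl)
            schedule_kinds.append(k)
    return {
        "di_err": np.asarray(di_err),
        "px_err": np.asarray(px_err),
        "truth_labels": truth_labels,
        "detected_labels": detected_labels,
        "schedule_kinds": schedule_kinds,
    }
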