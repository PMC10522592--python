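"""Trajectory structure of the preprocessed pulsogram.

Each strip of a preprocessed pulsogram is a point of an n-dimensional
response trajectory.  This module quantifies that trajectory three ways:

* **PCA** - latent dimensionality as the number of principal components
  needed to explain 90% of the variance across strips;
* **DTW** - dynamic time warping ties the ends of two trajectories and
  monotonically aligns everything between to minimize summed Euclidean
  separation.  The warping-path *coverage curve* (cumulative % of one
  trajectory consumed against the other) exposes response nesting: when a
  simpler response is a sub-segment of a richer one, its curve rises above
  the diagonal.  The summed separation along the optimal path is the
  separation distance; distances within one recording are normalized by
  the mean distance from the epoch-1 trajectory to all other epochs;
* **segmentation** - the trajectory is divided into segments either at
  troughs of the turning-angle series (angle between the mean displacement
  over 1 s before and after each point; 180 deg = collinear continuation,
  0 deg = full reversal, so sharp direction changes are dips), or with the
  Ramer-Douglas-Peucker polyline simplification.  More segments = a more
  complex response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from .pulsogram import TrajectoryMatrix

try:  # numba accelerates the DP fill; plain numpy loops otherwise
    from numba import njit
except ImportError:  # pragma: no cover
    njit = None

__all__ = [
    "PCAEmbedding",
    "DTWResult",
    "SegmentationResult",
    "pca_embed",
    "restrict_trajectory",
    "dtw_compare",
    "normalize_distances",
    "angular_segmentation",
    "rdp_segmentation",
    "common_rdp_epsilon",
    "turning_angles",
]


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------


def restrict_trajectory(tm: TrajectoryMatrix, span: tuple[float, float]) -> TrajectoryMatrix:
    """Restrict a trajectory to strips whose anchors fall in [start, stop)."""
    a, b = span
    m = (tm.anchor_times >= a) & (tm.anchor_times < b)
    if m.sum() < 2:
        raise ValueError("span keeps fewer than 2 strips")
    return TrajectoryMatrix(
        values=tm.values[:, m],
        y_ms=tm.y_ms,
        anchor_times=tm.anchor_times[m],
        kappa=tm.kappa[m],
        strip_power=tm.strip_power[m],
        mean_power=tm.mean_power,
        n_stim=int(m.sum()),
    )


def _points(tm) -> np.ndarray:
    return tm.points if isinstance(tm, TrajectoryMatrix) else np.asarray(tm, dtype=float)


def _times(tm, n: int) -> np.ndarray:
    if isinstance(tm, TrajectoryMatrix):
        return tm.anchor_times
    return np.arange(n, dtype=float)


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------


@dataclass
class PCAEmbedding:
    scores: np.ndarray
    explained_variance_fraction: np.ndarray
    n_components_90: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.explained_variance_fraction) > 1e-12):
            raise ValueError("explained variance fractions must be non-increasing")


def pca_embed(tm, span: tuple[float, float] | None = None) -> PCAEmbedding:
    """PCA of the trajectory (strips are observations, mean-centered,
    no variance scaling).

    ``span`` restricts to a time window first (per-epoch stimulation scope).
    ``n_components_90`` is the smallest component count whose cumulative
    explained variance reaches 90%.
    """
    if span is not None:
        tm = restrict_trajectory(tm, span)
    pts = _points(tm)
    if pts.shape[0] < 2:
        raise ValueError("PCA needs at least 2 strips")
    pca = PCA(n_components=min(pts.shape))
    scores = pca.fit_transform(pts)
    evf = pca.explained_variance_ratio_
    n90 = int(np.searchsorted(np.cumsum(evf), 0.90 - 1e-12) + 1)
    n90 = min(n90, evf.size)
    return PCAEmbedding(scores=scores, explained_variance_fraction=evf, n_components_90=n90)


# --------------------------------------------------------------------------
# DTW
# --------------------------------------------------------------------------


def _accumulate_py(C: np.ndarray) -> np.ndarray:
    n, m = C.shape
    D = np.empty((n, m))
    D[0, 0] = C[0, 0]
    for j in range(1, m):
        D[0, j] = D[0, j - 1] + C[0, j]
    for i in range(1, n):
        D[i, 0] = D[i - 1, 0] + C[i, 0]
        for j in range(1, m):
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = C[i, j] + best
    return D


_accumulate = njit(cache=True)(_accumulate_py) if njit is not None else _accumulate_py


@dataclass
class DTWResult:
    """Optimal monotone alignment of two trajectories.

    ``path`` runs from (0, 0) to (nA-1, nB-1) with both indices
    non-decreasing.  ``coverage_a``/``coverage_b`` are the cumulative
    percentages of each trajectory consumed along the path;
    ``coverage_at_80`` is the % of A consumed when B reaches 80%.
    """

    path: np.ndarray
    distance: float
    n_a: int
    n_b: int
    normalized_distance: float | None = None

    @property
    def coverage_a(self) -> np.ndarray:
        return 100.0 * self.path[:, 0] / max(self.n_a - 1, 1)

    @property
    def coverage_b(self) -> np.ndarray:
        return 100.0 * self.path[:, 1] / max(self.n_b - 1, 1)

    def coverage_at(self, pct_b: float) -> float:
        """% of A consumed when B is ``pct_b`` % consumed (upper envelope)."""
        cb, ca = self.coverage_b, self.coverage_a
        m = cb <= pct_b + 1e-12
        return float(ca[m].max()) if np.any(m) else 0.0

    @property
    def coverage_at_80(self) -> float:
        return self.coverage_at(80.0)


def dtw_compare(a, b) -> DTWResult:
    """Globally optimal DTW alignment under per-point Euclidean cost.

    Classic symmetric step set {(1,0), (0,1), (1,1)}, no window constraint;
    the separation distance is the sum of point distances along the path.
    Accepts :class:`TrajectoryMatrix` or plain (n, d) arrays of equal
    dimensionality.
    """
    A, B = _points(a), _points(b)
    if A.ndim == 1:
        A = A[:, None]
    if B.ndim == 1:
        B = B[:, None]
    if A.shape[1] != B.shape[1]:
        raise ValueError("trajectory dimensionalities differ")
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ValueError("empty trajectory")
    C = cdist(A, B)
    D = _accumulate(C)
    # backtrack, preferring the diagonal step on ties
    i, j = A.shape[0] - 1, B.shape[0] - 1
    rev = [(i, j)]
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            diag, up, left = D[i - 1, j - 1], D[i - 1, j], D[i, j - 1]
            if diag <= up and diag <= left:
                i, j = i - 1, j - 1
            elif up <= left:
                i -= 1
            else:
                j -= 1
        rev.append((i, j))
    path = np.asarray(rev[::-1], dtype=int)
    return DTWResult(
        path=path, distance=float(D[-1, -1]), n_a=A.shape[0], n_b=B.shape[0]
    )


def normalize_distances(
    results: list[DTWResult], epoch1_results: list[DTWResult]
) -> np.ndarray:
    """Normalize separation distances by the recording's epoch-1 reference.

    ``epoch1_results`` are the DTW comparisons from the epoch-1 trajectory
    to every other epoch of the same recording; the normalization factor is
    their mean raw distance (so that average is 1.0 by construction).
    Sets ``normalized_distance`` on each result and returns the values.
    """
    if len(epoch1_results) < 2:
        raise ValueError(
            "normalization needs epoch 1 compared against at least 2 other epochs"
        )
    factor = float(np.mean([r.distance for r in epoch1_results]))
    if factor <= 0:
        raise ValueError("degenerate epoch-1 reference (zero mean distance)")
    out = np.empty(len(results))
    for k, r in enumerate(results):
        r.normalized_distance = r.distance / factor
        out[k] = r.normalized_distance
    return out


# --------------------------------------------------------------------------
# angular segmentation
# --------------------------------------------------------------------------


@dataclass
class SegmentationResult:
    breakpoints: np.ndarray  # times (s)
    segment_count: int
    turning_angles: np.ndarray = field(default_factory=lambda: np.empty(0))
    angle_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    segment_means: np.ndarray | None = None
    mean_step: float = 0.0
    n_x: int = 0
    method: str = "angular"

    def __post_init__(self) -> None:
        if self.breakpoints.size > 1 and np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if self.segment_count != self.breakpoints.size + 1:
            raise ValueError("segment_count must equal breakpoints + 1")


def turning_angles(points: np.ndarray, w: int) -> np.ndarray:
    """Turning-angle series over a trajectory.

    At each interior point the angle is measured between the displacement
    from the preceding ``w``-point mean to the point and from the point to
    the following ``w``-point mean; reported so that 180 deg means the
    direction is maintained and 0 deg a full reversal.  Points lacking a
    full window on either side get NaN.
    """
    n = points.shape[0]
    ang = np.full(n, np.nan)
    cs = np.vstack([np.zeros((1, points.shape[1])), np.cumsum(points, axis=0)])
    for x in range(w, n - w):
        before = (cs[x] - cs[x - w]) / w
        after = (cs[x + 1 + w] - cs[x + 1]) / w
        a = points[x] - before
        b = after - points[x]
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            continue
        cosv = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
        ang[x] = 180.0 - np.degrees(np.arccos(cosv))
    return ang


def _segment_mean(points: np.ndarray, i0: int, i1: int) -> np.ndarray:
    """Mean response between trajectory indices i0..i1 inclusive."""
    return points[i0 : i1 + 1].mean(axis=0)


def angular_segmentation(
    tm,
    window_s: float = 1.0,
    trough_max_deg: float = 90.0,
    prominence_min_deg: float = 30.0,
    min_gap_s: float = 0.67,
    corr_max: float = 0.9,
) -> SegmentationResult:
    """Segment a trajectory at sharp direction changes.

    Candidate breakpoints are troughs of the turning-angle series below
    ``trough_max_deg`` with prominence at least ``prominence_min_deg``.
    A candidate is retained (checked left-to-right against the last
    retained breakpoint) only if all three hold:

    * it is more than ``min_gap_s`` seconds after the last retained point;
    * the means of the two segments it would separate differ by more than
      ``d/sqrt(2)`` in Euclidean norm, ``d`` being the mean step between
      consecutive trajectory points;
    * the correlation of those two segment means is below ``corr_max``
      (otherwise the trough is a short excursion of one overall trend).
    """
    pts = _points(tm)
    t = _times(tm, pts.shape[0])
    rate = 1.0 / float(np.median(np.diff(t)))
    w = max(1, int(round(window_s * rate)))
    if pts.shape[0] < 2 * w + 1:
        raise ValueError("trajectory shorter than twice the angle window")
    ang = turning_angles(pts, w)
    d = float(np.mean(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    valid = ~np.isnan(ang)
    series = np.where(valid, ang, 180.0)
    cand, _ = find_peaks(
        -series, height=-trough_max_deg, prominence=prominence_min_deg
    )
    retained: list[int] = []
    bounds = [0]
    for c in cand:
        last = bounds[-1]
        prev = bounds[-2] if len(bounds) > 1 else 0
        if retained and t[c] - t[retained[-1]] <= min_gap_s:
            continue
        new_mean = _segment_mean(pts, last, c)
        prev_mean = _segment_mean(pts, prev, last)
        if np.linalg.norm(new_mean - prev_mean) <= d / np.sqrt(2.0):
            continue
        if new_mean.std() > 0 and prev_mean.std() > 0:
            r = float(np.corrcoef(new_mean, prev_mean)[0, 1])
            if r >= corr_max:
                continue
        retained.append(int(c))
        bounds.append(int(c))
    bounds.append(pts.shape[0] - 1)
    seg_means = np.vstack(
        [_segment_mean(pts, a, b) for a, b in zip(bounds[:-1], bounds[1:])]
    )
    return SegmentationResult(
        breakpoints=t[np.asarray(retained, dtype=int)] if retained else np.empty(0),
        segment_count=len(retained) + 1,
        turning_angles=ang,
        angle_times=t,
        segment_means=seg_means,
        mean_step=d,
        n_x=pts.shape[0],
        method="angular",
    )


# --------------------------------------------------------------------------
# Ramer-Douglas-Peucker segmentation
# --------------------------------------------------------------------------


def _perp_dist(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Perpendicular distance of each point to the line through a-b
    (distance to a when the chord is degenerate)."""
    chord = b - a
    L2 = float(np.dot(chord, chord))
    if L2 == 0:
        return np.linalg.norm(points - a, axis=1)
    tproj = (points - a) @ chord / L2
    foot = a + tproj[:, None] * chord
    return np.linalg.norm(points - foot, axis=1)


def _rdp_indices(points: np.ndarray, lo: int, hi: int, eps: float, keep: list[int]) -> None:
    if hi <= lo + 1:
        return
    seg = points[lo + 1 : hi]
    dist = _perp_dist(seg, points[lo], points[hi])
    k = int(np.argmax(dist))
    if dist[k] > eps:
        mid = lo + 1 + k
        _rdp_indices(points, lo, mid, eps, keep)
        keep.append(mid)
        _rdp_indices(points, mid, hi, eps, keep)


def common_rdp_epsilon(tms: list, mult: float = 8.0) -> float:
    """RDP tolerance shared by all epochs of one recording.

    ``mult`` times the mean step between consecutive trajectory points,
    pooled across the given trajectories.  A per-epoch tolerance would
    scale with each epoch's own excursion size and erase complexity
    differences between epochs; a pooled tolerance keeps the segment
    counts comparable.
    """
    steps = np.concatenate(
        [np.linalg.norm(np.diff(_points(tm), axis=0), axis=1) for tm in tms]
    )
    return mult * float(steps.mean())


def rdp_segmentation(tm, epsilon: float | None = None) -> SegmentationResult:
    """Ramer-Douglas-Peucker simplification of the n-D trajectory.

    Keeps the subset of vertices such that every dropped point lies within
    ``epsilon`` perpendicular distance of the simplified polyline.  The
    default tolerance is 8x the trajectory's mean step, a scale that sits
    above the smoothed-noise wander while resolving genuine phase
    excursions; when comparing epochs of one recording pass a shared
    tolerance from :func:`common_rdp_epsilon` instead.  With
    ``epsilon = 0`` every off-chord point is retained.
    """
    pts = _points(tm)
    t = _times(tm, pts.shape[0])
    if pts.shape[0] < 2:
        raise ValueError("trajectory needs at least 2 points")
    d = float(np.mean(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    if epsilon is None:
        epsilon = 8.0 * d
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    keep: list[int] = []
    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, pts.shape[0] + 100))
    try:
        _rdp_indices(pts, 0, pts.shape[0] - 1, epsilon, keep)
    finally:
        sys.setrecursionlimit(old)
    keep = sorted(keep)
    return SegmentationResult(
        breakpoints=t[np.asarray(keep, dtype=int)] if keep else np.empty(0),
        segment_count=len(keep) + 1,
        mean_step=d,
        n_x=pts.shape[0],
        method="rdp",
    )
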