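"""PCA embedding, DTW alignment/coverage, angular and RDP segmentation."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from ictogram import (
    angular_segmentation,
    dtw_compare,
    normalize_distances,
    pca_embed,
    rdp_segmentation,
)
from ictogram.pulsogram import TrajectoryMatrix


def _tm(points, strip_dt=0.1):
    """Wrap an (n, d) point array into a TrajectoryMatrix."""
    pts = np.asarray(points, dtype=float)
    n, d = pts.shape
    return TrajectoryMatrix(
        values=pts.T.copy(),
        y_ms=np.arange(d, dtype=float),
        anchor_times=np.arange(n) * strip_dt,
        kappa=np.ones(n),
        strip_power=np.ones(n),
        mean_power=1.0,
        n_stim=n,
    )


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------


class TestPCA:
    def test_rank_one_matrix(self):
        rng = np.random.default_rng(0)
        pattern = rng.normal(size=8)
        pts = np.outer(np.linspace(1, 3, 20), pattern)
        emb = pca_embed(_tm(pts))
        assert emb.n_components_90 == 1
        assert emb.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-9)

    def test_explained_variance_sorted(self):
        rng = np.random.default_rng(1)
        emb = pca_embed(_tm(rng.normal(size=(30, 6))))
        assert np.all(np.diff(emb.explained_variance_fraction) <= 1e-12)

    def test_eigenvalues_match_covariance_oracle(self):
        """sklearn variances equal a brute-force eigendecomposition of the
        sample covariance, to 1e-8 relative."""
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(20, 8)) * rng.uniform(0.5, 3.0, size=8)
        emb = pca_embed(_tm(pts))
        cov = np.cov(pts, rowvar=False, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        frac = eig / eig.sum()
        np.testing.assert_allclose(
            emb.explained_variance_fraction, frac, rtol=1e-8, atol=1e-12
        )

    def test_single_strip_rejected(self):
        with pytest.raises(ValueError):
            pca_embed(_tm(np.ones((1, 4))))


# --------------------------------------------------------------------------
# DTW
# --------------------------------------------------------------------------


def dtw_distance_oracle(A, B):
    """Independent exhaustive DP over the same step set, memoized recursion."""
    import functools

    A = np.asarray(A, float)
    B = np.asarray(B, float)

    @functools.lru_cache(maxsize=None)
    def rec(i, j):
        c = float(np.linalg.norm(A[i] - B[j]))
        if i == 0 and j == 0:
            return c
        best = np.inf
        if i > 0:
            best = min(best, rec(i - 1, j))
        if j > 0:
            best = min(best, rec(i, j - 1))
        if i > 0 and j > 0:
            best = min(best, rec(i - 1, j - 1))
        return c + best

    return rec(A.shape[0] - 1, B.shape[0] - 1)


class TestDTW:
    def test_identical_trajectories(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(25, 4))
        r = dtw_compare(_tm(pts), _tm(pts))
        assert r.distance == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_array_equal(r.path[:, 0], r.path[:, 1])
        np.testing.assert_allclose(r.coverage_a, r.coverage_b)

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            a = rng.normal(size=(rng.integers(5, 25), 3))
            b = rng.normal(size=(rng.integers(5, 25), 3))
            assert dtw_compare(a, b).distance == pytest.approx(
                dtw_compare(b, a).distance
            )

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = rng.normal(size=(rng.integers(2, 18), rng.integers(1, 4)))
            b = rng.normal(size=(rng.integers(2, 18), a.shape[1]))
            r = dtw_compare(a, b)
            assert r.distance == pytest.approx(dtw_distance_oracle(a, b), rel=1e-12)

    def test_path_monotone_and_tied_at_ends(self):
        rng = np.random.default_rng(6)
        r = dtw_compare(rng.normal(size=(12, 2)), rng.normal(size=(17, 2)))
        assert tuple(r.path[0]) == (0, 0)
        assert tuple(r.path[-1]) == (11, 16)
        assert np.all(np.diff(r.path, axis=0) >= 0)

    def test_nested_trajectory_coverage_above_diagonal(self):
        """When B extends A with a distinct terminal excursion, A is
        consumed at least as fast as B everywhere."""
        rng = np.random.default_rng(7)
        base = np.cumsum(rng.normal(size=(30, 3)), axis=0)
        excursion = base[-1] + np.cumsum(np.ones((20, 3)) * 2.0, axis=0)
        A = _tm(base)
        B = _tm(np.vstack([base, excursion]))
        r = dtw_compare(A, B)
        assert np.all(r.coverage_a >= r.coverage_b - 1e-9)
        # A is a strict prefix of B: it is fully consumed well before B,
        # and consumed faster than B from the start
        assert r.coverage_at_80 == pytest.approx(100.0)
        assert r.coverage_at(30.0) > 30.0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dtw_compare(np.ones((5, 2)), np.ones((5, 3)))


class TestNormalizeDistances:
    def _result(self, d):
        r = dtw_compare(np.zeros((2, 1)), np.ones((2, 1)))
        r.distance = d
        return r

    def test_reference_arithmetic(self):
        ref = [self._result(2.0), self._result(4.0)]
        out = normalize_distances([self._result(6.0)], ref)
        assert out[0] == pytest.approx(2.0)
        # the mean of the reference normalizes to 1.0 by construction
        assert np.mean(normalize_distances(ref, ref)) == pytest.approx(1.0)

    def test_self_comparison_normalizes_to_zero(self):
        ref = [self._result(2.0), self._result(4.0)]
        assert normalize_distances([self._result(0.0)], ref)[0] == 0.0

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            normalize_distances([self._result(1.0)], [self._result(1.0)])


# --------------------------------------------------------------------------
# angular segmentation
# --------------------------------------------------------------------------


def _line(n, direction, start=None, noise=0.0, rng=None):
    d = np.asarray(direction, float)
    pts = np.outer(np.arange(n), d)
    if start is not None:
        pts = pts + start
    if noise:
        pts = pts + rng.normal(scale=noise, size=pts.shape)
    return pts


class TestAngularSegmentation:
    def test_straight_line_single_segment(self):
        pts = _line(200, [1.0, 0.5])
        seg = angular_segmentation(_tm(pts))
        assert seg.segment_count == 1
        assert seg.breakpoints.size == 0

    def test_sharp_corner_breakpoint_near_corner(self):
        # two 10 s straight arms with a 120 degree direction change
        a = _line(100, [1.0, 0.0])
        theta = np.radians(120.0)
        b = a[-1] + _line(100, [np.cos(theta), np.sin(theta)])[1:]
        seg = angular_segmentation(_tm(np.vstack([a, b])))
        assert seg.segment_count == 2
        corner_time = 99 * 0.1
        assert abs(seg.breakpoints[0] - corner_time) <= 1.0  # within the window

    def test_close_corners_limited_by_time_gap(self):
        # two corners 0.4 s apart: at most one survives the gap rule
        a = _line(60, [1.0, 0.0])
        b = a[-1] + _line(4, [-0.5, 1.0])[1:]
        c = b[-1] + _line(60, [1.0, 0.0])[1:]
        seg = angular_segmentation(_tm(np.vstack([a, b, c])))
        assert seg.breakpoints.size <= 1

    def test_turning_angle_range(self):
        rng = np.random.default_rng(8)
        seg = angular_segmentation(_tm(rng.normal(size=(100, 5))))
        finite = seg.turning_angles[~np.isnan(seg.turning_angles)]
        assert np.all((finite >= 0.0) & (finite <= 180.0))

    def test_short_trajectory_rejected(self):
        with pytest.raises(ValueError):
            angular_segmentation(_tm(np.ones((5, 2))))


# --------------------------------------------------------------------------
# RDP
# --------------------------------------------------------------------------


def rdp_oracle(points, eps):
    """Independent iterative (stack-based) simplification."""
    pts = np.asarray(points, float)
    keep = {0, pts.shape[0] - 1}
    stack = [(0, pts.shape[0] - 1)]
    while stack:
        lo, hi = stack.pop()
        if hi <= lo + 1:
            continue
        a, b = pts[lo], pts[hi]
        chord = b - a
        L2 = float(chord @ chord)
        seg = pts[lo + 1 : hi]
        if L2 == 0:
            dist = np.linalg.norm(seg - a, axis=1)
        else:
            proj = (seg - a) @ chord / L2
            dist = np.linalg.norm(seg - (a + proj[:, None] * chord), axis=1)
        k = int(np.argmax(dist))
        if dist[k] > eps:
            mid = lo + 1 + k
            keep.add(mid)
            stack.append((lo, mid))
            stack.append((mid, hi))
    return sorted(keep)


class TestRDP:
    def test_straight_line_two_vertices(self):
        pts = _line(50, [1.0, 2.0])
        seg = rdp_segmentation(_tm(pts), epsilon=0.5)
        assert seg.segment_count == 1

    def test_zero_epsilon_keeps_everything(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(40, 3))
        seg = rdp_segmentation(_tm(pts), epsilon=0.0)
        assert seg.segment_count == 39

    def test_matches_recursive_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            pts = np.cumsum(rng.normal(size=(30, 2)), axis=0)
            eps = float(rng.uniform(0.2, 3.0))
            seg = rdp_segmentation(_tm(pts), epsilon=eps)
            expected = rdp_oracle(pts, eps)
            got = [0] + [int(round(t / 0.1)) for t in seg.breakpoints] + [29]
            assert got == expected

    def test_negative_epsilon_rejected(self):
        with pytest.raises(ValueError):
            rdp_segmentation(_tm(np.ones((5, 2))), epsilon=-1.0)


# --------------------------------------------------------------------------
# cross-method agreement on the synthetic battery
# --------------------------------------------------------------------------


def test_rdp_and_angular_rank_complexity_alike(complexity_battery):
    """The two segmenters agree on how response types rank by complexity
    (Spearman >= 0.8 across the five types' median segment counts)."""
    kinds = ["Flat", "Evolving", "SzKS", "SzKL", "SzF"]
    ang = [np.median([e["segments"][k] for e in complexity_battery]) for k in kinds]
    rdp = [np.median([e["rdp"][k] for e in complexity_battery]) for k in kinds]
    assert spearmanr(ang, rdp).statistic >= 0.8
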