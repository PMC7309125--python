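"""Procrustes statistics: centroid size, rigid alignment, GPA, errors."""

import numpy as np
import pytest
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.transform import Rotation

from facemark import (
    LandmarkSet3D,
    ShapeSample,
    average_over_observers,
    centroid_size,
    gpa,
    landmark_errors,
    procrustes_distance_from_mean,
    rigid_align,
)
from facemark.landmarks import LANDMARK_NAMES


def random_shape(rng, k=12):
    labels = LANDMARK_NAMES if k == 12 else tuple(f"p{i}" for i in range(k))
    return ShapeSample(labels=labels, coords=rng.normal(size=(k, 3)) * 30)


def random_rotation(rng):
    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()


class TestCentroidSize:
    def test_unit_square(self):
        square = ShapeSample(("a", "b", "c", "d"),
                             [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
        assert np.isclose(centroid_size(square), np.sqrt(2), atol=1e-12)

    def test_homogeneity(self):
        rng = np.random.default_rng(0)
        s = random_shape(rng)
        for c in (0.5, 2.0, 17.3):
            scaled = ShapeSample(s.labels, s.coords * c)
            assert np.isclose(centroid_size(scaled), c * centroid_size(s), rtol=1e-12)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        s = random_shape(rng)
        centroid = s.coords.mean(axis=0)
        brute = np.sqrt(sum(np.sum((p - centroid) ** 2) for p in s.coords))
        assert np.isclose(centroid_size(s), brute, rtol=1e-12)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            centroid_size(ShapeSample(("a", "b", "c"), np.ones((3, 3))))


class TestRigidAlign:
    def test_exact_recovery(self):
        rng = np.random.default_rng(2)
        src = rng.normal(size=(12, 3)) * 20
        r0 = random_rotation(rng)
        t0 = rng.normal(size=3) * 50
        rot, tr = rigid_align(src, src @ r0.T + t0)
        assert np.allclose(rot, r0, atol=1e-9)
        assert np.allclose(tr, t0, atol=1e-9)

    def test_identity_on_equal_inputs(self):
        rng = np.random.default_rng(3)
        src = rng.normal(size=(8, 3))
        rot, tr = rigid_align(src, src)
        assert np.allclose(rot, np.eye(3), atol=1e-9)
        assert np.allclose(tr, 0, atol=1e-9)

    def test_proper_rotation_enforced(self):
        rng = np.random.default_rng(4)
        src = rng.normal(size=(12, 3))
        target = src @ np.diag([-1.0, 1.0, 1.0])  # reflected
        rot, _ = rigid_align(src, target)
        assert np.isclose(np.linalg.det(rot), 1.0, atol=1e-9)

    def test_beats_random_transforms(self):
        """Monte-Carlo lower bound: no random proper rigid transform does
        better than the closed-form solution."""
        rng = np.random.default_rng(5)
        src = rng.normal(size=(12, 3)) * 10
        tgt = src @ random_rotation(rng).T + rng.normal(size=3) + rng.normal(size=(12, 3))
        rot, tr = rigid_align(src, tgt)
        best = np.sum((src @ rot.T + tr - tgt) ** 2)
        for _ in range(1000):
            rr = random_rotation(rng)
            tt = tgt.mean(axis=0) - (src @ rr.T).mean(axis=0) + rng.normal(size=3)
            assert np.sum((src @ rr.T + tt - tgt) ** 2) >= best - 1e-9

    def test_rank_deficient_rejected(self):
        src = np.zeros((5, 3))
        src[:, 0] = np.arange(5)  # collinear
        with pytest.raises(ValueError, match="rank"):
            rigid_align(src, src)


def reference_gpa(configs, n_iter=200):
    """Independent GPA oracle: unit scaling once, then iterative rigid
    alignment using scipy's orthogonal Procrustes solver."""
    scaled = []
    for c in configs:
        c = c - c.mean(axis=0)
        scaled.append(c / np.sqrt(np.sum(c ** 2)))
    mean = scaled[0]
    for _ in range(n_iter):
        aligned = []
        for c in scaled:
            r, _ = orthogonal_procrustes(c, mean)
            if np.linalg.det(r) < 0:  # repair reflections
                u, s, vt = np.linalg.svd(c.T @ mean)
                r = u @ np.diag([1, 1, np.sign(np.linalg.det(u @ vt))]) @ vt
            aligned.append(c @ r)
        new_mean = np.mean(aligned, axis=0)
        if np.linalg.norm(new_mean - mean) < 1e-12:
            mean = new_mean
            break
        mean = new_mean
        scaled = aligned
    return np.array([np.linalg.norm(c - mean) for c in scaled])


class TestGPA:
    def test_identical_samples(self):
        rng = np.random.default_rng(6)
        s = random_shape(rng)
        result = gpa([s, ShapeSample(s.labels, s.coords.copy())])
        assert np.allclose(result.distances, 0, atol=1e-9)

    def test_rigid_and_scale_invariance(self):
        rng = np.random.default_rng(7)
        s = random_shape(rng)
        moved = ShapeSample(
            s.labels, 2.7 * (s.coords @ random_rotation(rng).T) + rng.normal(size=3) * 40
        )
        result = gpa([s, moved])
        assert np.all(result.distances < 1e-9)

    def test_matches_reference_implementation(self):
        """Noisy population: mean Procrustes distance within 10% of an
        independent GPA built on scipy's Procrustes solver."""
        rng = np.random.default_rng(8)
        base = rng.normal(size=(12, 3)) * 25
        configs = [base + rng.normal(size=(12, 3)) * 2.0 for _ in range(20)]
        samples = [ShapeSample(LANDMARK_NAMES, c) for c in configs]
        ours = gpa(samples).distances.mean()
        theirs = reference_gpa(configs).mean()
        assert abs(ours - theirs) / theirs < 0.10

    def test_order_invariance_of_mean(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=(12, 3)) * 25
        samples = [ShapeSample(LANDMARK_NAMES, base + rng.normal(size=(12, 3)))
                   for _ in range(8)]
        m1 = gpa(samples).mean_shape
        shuffled = samples[3:] + samples[:3]
        m2 = gpa(shuffled).mean_shape
        rot, tr = rigid_align(m2, m1)
        assert np.linalg.norm(m2 @ rot.T + tr - m1) < 1e-6

    def test_unit_centroid_size_invariant(self):
        rng = np.random.default_rng(10)
        samples = [random_shape(rng) for _ in range(5)]
        result = gpa(samples)
        for c in result.aligned:
            assert np.isclose(centroid_size(c), 1.0, atol=1e-9)
        assert np.allclose(result.mean_shape, np.mean(result.aligned, axis=0))

    def test_label_mismatch_rejected(self):
        rng = np.random.default_rng(11)
        a = random_shape(rng)
        b = ShapeSample(tuple(reversed(a.labels)), a.coords)
        with pytest.raises(ValueError, match="labels"):
            gpa([a, b])

    def test_distance_accessor_matches_brute_force(self):
        rng = np.random.default_rng(12)
        samples = [random_shape(rng) for _ in range(4)]
        result = gpa(samples)
        brute = [np.sqrt(np.sum((c - result.mean_shape) ** 2)) for c in result.aligned]
        assert np.allclose(procrustes_distance_from_mean(result), brute, atol=1e-12)
        assert np.allclose(result.distances, brute, atol=1e-12)


def _landmark_sets(rng, n):
    return [LandmarkSet3D.from_array(rng.normal(size=(12, 3)) * 30) for _ in range(n)]


class TestLandmarkErrors:
    def test_identical_sets_zero(self):
        rng = np.random.default_rng(13)
        a = _landmark_sets(rng, 5)
        report = landmark_errors(a, a)
        assert report.overall_mean == 0
        assert np.all(report.distances == 0)

    def test_constant_offset(self):
        rng = np.random.default_rng(14)
        a = _landmark_sets(rng, 6)
        offset = np.array([2.5, 0.0, 0.0])
        b = [LandmarkSet3D.from_array(x.to_array() + offset) for x in a]
        report = landmark_errors(a, b)
        assert np.allclose(report.per_landmark_mean, 2.5, atol=1e-12)
        assert np.allclose(report.per_landmark_sd, 0, atol=1e-12)
        assert np.isclose(report.overall_mean, 2.5)

    def test_overall_mean_consistency(self):
        rng = np.random.default_rng(15)
        a = _landmark_sets(rng, 7)
        b = _landmark_sets(rng, 7)
        report = landmark_errors(a, b)
        assert np.isclose(report.overall_mean, report.distances.mean())
        assert np.isclose(report.overall_mean, report.per_subject_mean.mean())
        frame = report.to_dataframe()
        assert list(frame["landmark"])[-1] == "Overall"
        assert len(frame) == 13

    def test_length_mismatch_rejected(self):
        rng = np.random.default_rng(16)
        with pytest.raises(ValueError):
            landmark_errors(_landmark_sets(rng, 2), _landmark_sets(rng, 3))


class TestAverageOverObservers:
    def test_identical_observers_match_single(self):
        rng = np.random.default_rng(17)
        m = _landmark_sets(rng, 4)
        obs = _landmark_sets(rng, 4)
        merged = average_over_observers(m, obs, obs)
        single = landmark_errors(m, obs)
        assert np.allclose(merged.distances, single.distances)

    def test_equidistant_average(self):
        rng = np.random.default_rng(18)
        m = _landmark_sets(rng, 3)
        o1 = [LandmarkSet3D.from_array(x.to_array() + [1.0, 0, 0]) for x in m]
        o2 = [LandmarkSet3D.from_array(x.to_array() + [0, 3.0, 0]) for x in m]
        merged = average_over_observers(m, o1, o2)
        assert np.allclose(merged.distances, 2.0, atol=1e-12)  # (1 + 3) / 2

    def test_matches_brute_force(self):
        rng = np.random.default_rng(19)
        m = _landmark_sets(rng, 5)
        o1 = _landmark_sets(rng, 5)
        o2 = _landmark_sets(rng, 5)
        merged = average_over_observers(m, o1, o2)
        for j in range(5):
            for i in range(12):
                d1 = np.linalg.norm(m[j].to_array()[i] - o1[j].to_array()[i])
                d2 = np.linalg.norm(m[j].to_array()[i] - o2[j].to_array()[i])
                assert np.isclose(merged.distances[j, i], (d1 + d2) / 2)
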