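"""Cluster finding, gyration-tensor shape classification, and core diameters."""

import numpy as np
import pytest

from triblock.errors import ClassificationError, ParameterError
from triblock.morphology import (
    MorphologyConfig,
    analyze_frame,
    classify_shape,
    cluster_cores,
    core_diameter,
    diameter_ratio,
    gyration_tensor,
    ratio_of_means,
    summarize_trajectory,
)
from triblock.synthetic import gen_fixture_trajectory, gen_micelle_cloud


def brute_force_clusters(points, box, cutoff):
    """Union-find over the all-pairs minimum-image distance matrix."""
    n = len(points)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            d = points[i] - points[j]
            d -= box * np.round(d / box)
            if np.linalg.norm(d) <= cutoff:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


class TestClusterCores:
    def test_two_separated_blobs(self, rng):
        a = rng.normal(0, 0.3, (20, 3)) + 5.0
        b = rng.normal(0, 0.3, (20, 3)) + 18.0
        clusters = cluster_cores(np.vstack([a, b]), box_edge=40.0, cutoff=1.3)
        sizes = sorted(len(c) for c in clusters if len(c) > 1)
        assert sizes[-2:] == [20, 20]

    def test_chain_is_transitively_one_cluster(self):
        pts = np.stack([np.arange(12) * 1.0, np.zeros(12), np.zeros(12)], axis=1)
        clusters = cluster_cores(pts, box_edge=50.0, cutoff=1.1)
        assert len(clusters) == 1 and len(clusters[0]) == 12

    def test_matches_union_find_oracle(self, rng):
        pts = rng.uniform(0, 8.0, (60, 3))
        got = {frozenset(c.tolist()) for c in cluster_cores(pts, 8.0, 1.0)}
        assert got == brute_force_clusters(pts, 8.0, 1.0)

    def test_invariant_to_relabeling_and_translation(self, rng):
        pts = rng.uniform(0, 10.0, (40, 3))
        base = {frozenset(c.tolist()) for c in cluster_cores(pts, 10.0, 1.2)}
        perm = rng.permutation(40)
        # bead i of the permuted input is original bead perm[i]
        relabeled = {
            frozenset(perm[c].tolist()) for c in cluster_cores(pts[perm], 10.0, 1.2)
        }
        assert relabeled == base
        shifted = {frozenset(c.tolist()) for c in cluster_cores((pts + 3.7) % 10.0, 10.0, 1.2)}
        assert shifted == base


class TestGyrationTensor:
    def test_two_points_closed_form(self):
        d = 1.8
        lam = gyration_tensor(np.array([[0, 0, 0], [d, 0, 0]], dtype=float))
        assert lam[0] == pytest.approx(d * d / 4, rel=1e-12)
        assert lam[1] == lam[2] == pytest.approx(0.0, abs=1e-12)

    def test_uniform_ball_moments(self):
        # R^2/5 per eigenvalue; eigenvalue sorting biases the extremes at
        # finite n, so a large sample keeps all three within 2%
        cloud = gen_micelle_cloud("sphere", radius=3.0, n_points=30_000, seed=2)
        lam = gyration_tensor(cloud.points)
        for x in lam:
            assert x == pytest.approx(9.0 / 5, rel=0.02)

    def test_collinear_points(self):
        pts = np.stack([np.linspace(0, 5, 9), np.zeros(9), np.zeros(9)], axis=1)
        lam = gyration_tensor(pts)
        assert lam[1] == pytest.approx(0.0, abs=1e-12)
        assert lam[2] == pytest.approx(0.0, abs=1e-12)

    def test_rg_matches_direct_sum(self, rng):
        pts = rng.normal(0, 1.0, (200, 3))
        lam = gyration_tensor(pts)
        rg2 = np.mean(np.sum((pts - pts.mean(axis=0)) ** 2, axis=1))
        assert sum(lam) == pytest.approx(rg2, abs=1e-10)

    def test_periodic_unwrapping(self):
        # a tight blob straddling the box corner must not be torn apart
        rng = np.random.default_rng(5)
        blob = rng.normal(0, 0.4, (50, 3))
        lam_free = gyration_tensor(blob)
        lam_wrapped = gyration_tensor(blob % 20.0, box_edge=20.0, cutoff=1.5)
        assert np.allclose(lam_free, lam_wrapped, atol=1e-10)


class TestClassifyShape:
    def test_ball_sample_is_spherical(self):
        cloud = gen_micelle_cloud("sphere", radius=2.0, n_points=3000, seed=3)
        assert classify_shape(gyration_tensor(cloud.points)) == "spherical"

    def test_long_cylinder_is_wormlike(self):
        cloud = gen_micelle_cloud("cylinder", radius=1.0, length=20.0, n_points=3000, seed=4)
        assert classify_shape(gyration_tensor(cloud.points)) == "wormlike"

    def test_band_between_thresholds_is_intermediate(self):
        assert classify_shape((3.5, 1.0, 1.0), e_lo=2.0, e_hi=5.0) == "intermediate"
        assert classify_shape((2.0, 1.0, 1.0), e_lo=2.0, e_hi=5.0) == "intermediate"

    def test_single_point_unclassifiable(self):
        with pytest.raises(ClassificationError):
            classify_shape((0.0, 0.0, 0.0))

    def test_collinear_counts_as_maximally_elongated(self):
        assert classify_shape((4.0, 0.0, 0.0)) == "wormlike"


class TestCoreDiameter:
    def test_ball_diameter_recovered(self):
        R = 2.5
        cloud = gen_micelle_cloud("sphere", radius=R, n_points=8000, seed=6)
        clusters = analyze_frame(
            cloud.points % 40.0 + 0.0, np.ones(len(cloud.points), dtype=np.uint8), 40.0
        )
        big = max(clusters, key=lambda c: c.size)
        assert big.shape_class == "spherical"
        assert core_diameter(big) == pytest.approx(2 * R, rel=0.03)

    def test_cylinder_transverse_diameter_recovered(self):
        R = 1.5
        cloud = gen_micelle_cloud(
            "cylinder", radius=R, length=15.0, n_points=8000, seed=7, orient=False
        )
        lam = gyration_tensor(cloud.points)
        d = 4 * np.sqrt((lam[1] + lam[2]) / 2)
        assert d == pytest.approx(2 * R, rel=0.03)

    def test_small_cluster_rejected(self):
        from triblock.morphology import MicelleCluster

        c = MicelleCluster(
            indices=np.arange(3),
            center_of_mass=np.zeros(3),
            eigenvalues=(1.0, 0.5, 0.2),
            shape_class="spherical",
            diameter_spherical=1.0,
            diameter_wormlike=1.0,
        )
        with pytest.raises(ParameterError):
            core_diameter(c)


class TestDiameterRatio:
    class _S:
        def __init__(self, ds, dw):
            self.mean_sphere_diameter = ds
            self.mean_worm_diameter = dw

    def test_identical_ratios(self):
        reps = [[self._S(2.0, None), self._S(None, 2.0)] for _ in range(4)]
        mean, sd = diameter_ratio(reps)
        assert (mean, sd) == (1.0, 0.0)

    def test_arithmetic(self):
        reps = [
            [self._S(1.1, None), self._S(None, 1.0)],
            [self._S(1.2, None), self._S(None, 1.0)],
            [self._S(1.3, None), self._S(None, 1.0)],
        ]
        mean, sd = diameter_ratio(reps)
        assert mean == pytest.approx(1.2)
        assert sd == pytest.approx(0.1)

    def test_incomplete_replicates_warn_then_error(self):
        good = [self._S(1.2, None), self._S(None, 1.0)]
        bad = [self._S(1.2, None), self._S(None, None)]
        with pytest.warns(UserWarning):
            mean, _ = diameter_ratio([good, bad])
        assert mean == pytest.approx(1.2)
        with pytest.raises(ParameterError):
            diameter_ratio([bad])

    def test_ratio_of_means(self):
        assert ratio_of_means([15.4], [13.0]) == pytest.approx(15.4 / 13.0)
        with pytest.raises(ParameterError):
            ratio_of_means([], [13.0])


class TestClassifierAccuracy:
    def test_labeled_cloud_accuracy(self):
        # balls and cylinders with 5% positional noise; smaller companion of
        # the 1000-cloud acceptance check
        correct = 0
        n = 200
        for i in range(n):
            if i % 2 == 0:
                cloud = gen_micelle_cloud("sphere", radius=2.0, n_points=400,
                                          noise_sd=0.1, seed=i)
                want = "spherical"
            else:
                cloud = gen_micelle_cloud("cylinder", radius=1.0, length=10.0,
                                          n_points=400, noise_sd=0.05, seed=i)
                want = "wormlike"
            got = classify_shape(gyration_tensor(cloud.points))
            correct += got == want
        assert correct / n >= 0.99


class TestEndToEnd:
    def test_planted_fixture_counts_and_ratio(self):
        traj = gen_fixture_trajectory(
            3, ["sphere", "sphere", "cylinder"], box_edge=40.0, seed=8,
            radius=2.4, worm_radius=2.0, worm_length=16.0,
        )
        summ = summarize_trajectory(traj, MorphologyConfig())
        frame_clusters = [c for c in summ.per_frame[0] if c.size >= 10]
        assert len(frame_clusters) == 3
        assert sorted(c.shape_class for c in frame_clusters) == [
            "spherical", "spherical", "wormlike",
        ]
        got = summ.mean_sphere_diameter / summ.mean_worm_diameter
        assert got == pytest.approx(2 * 2.4 / (2 * 2.0), rel=0.03)
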