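"""K-means on relevance maps, cluster-O selection, smoothing, summaries."""

import itertools

import numpy as np
import pytest

from strainpheno.attribution import RelevanceMap
from strainpheno.clustering import (
    PhenotypeAssignment,
    check_min_cluster_size,
    cluster_summary,
    kmeans_cluster,
    select_detected,
    smooth_center,
)
from strainpheno.records import NormalizedCurveSet


def _maps_from(points: np.ndarray, shape=(6, 5)) -> list[RelevanceMap]:
    return [
        RelevanceMap(f"s{i}", np.abs(p).reshape(shape)) for i, p in enumerate(points)
    ]


class TestSelectDetected:
    def test_strict_threshold(self):
        carriers = [("a", 0.9), ("b", 0.51), ("c", 0.5), ("d", 0.1)]
        detected, cluster_o = select_detected(carriers, 0.5)
        assert [s for s, _ in detected] == ["a", "b"]
        assert [s for s, _ in cluster_o] == ["c", "d"]

    def test_all_detected_leaves_o_empty(self):
        detected, cluster_o = select_detected([("a", 1.0), ("b", 1.0)])
        assert len(detected) == 2 and cluster_o == []

    def test_none_detected(self):
        detected, cluster_o = select_detected([("a", 0.0), ("b", 0.0)])
        assert detected == [] and len(cluster_o) == 2

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            select_detected([("a", 1.5)])


class TestKMeans:
    def test_identical_groups_give_zero_inertia(self):
        rng = np.random.default_rng(0)
        protos = rng.random((4, 30))
        points = np.repeat(protos, 3, axis=0)
        model = kmeans_cluster(_maps_from(points), k=4, seed=0, n_init=5)
        assert model.inertia == pytest.approx(0.0, abs=1e-20)
        centers = model.centers.reshape(4, -1)
        for proto in protos:
            assert min(np.abs(centers - proto).max(axis=1)) < 1e-12

    def test_well_separated_blobs_match_brute_force(self):
        """Oracle: exhaustive enumeration of all 4-partitions of 12 points."""
        rng = np.random.default_rng(3)
        centers = np.array([[0.0, 0], [10, 0], [0, 10], [10, 10]])
        pts2d = np.vstack([c + 0.1 * rng.normal(size=(3, 2)) for c in centers])
        points = np.zeros((12, 30))
        points[:, :2] = pts2d + 20.0  # keep maps non-negative
        maps = _maps_from(points)
        model = kmeans_cluster(maps, k=4, seed=1, n_init=10)

        # only the first two coordinates vary; inertia decomposes as
        # sum(x^2) - sum_c |sum_c x|^2 / n_c, computed per partition
        x, y = points[:, 0], points[:, 1]
        total_sq = float((x**2 + y**2).sum())

        def partition_inertia(assign):
            a = np.asarray(assign)
            n = np.bincount(a, minlength=4).astype(float)
            sx = np.bincount(a, weights=x, minlength=4)
            sy = np.bincount(a, weights=y, minlength=4)
            nz = n > 0
            return total_sq - ((sx[nz] ** 2 + sy[nz] ** 2) / n[nz]).sum()

        best = np.inf
        # restricted-growth strings enumerate set partitions into <= 4 blocks
        def rgs(prefix, maxval):
            nonlocal best
            if len(prefix) == 12:
                if maxval == 3:
                    best = min(best, partition_inertia(prefix))
                return
            for v in range(min(maxval + 1, 3) + 1):
                rgs(prefix + [v], max(maxval, v))

        rgs([0], 0)
        assert model.inertia == pytest.approx(best, rel=1e-9)
        # partition equals blob membership
        labels = [model.assignments[f"s{i}"] for i in range(12)]
        for b in range(4):
            assert len({labels[3 * b + j] for j in range(3)}) == 1
        assert len(set(labels)) == 4

    def test_k1_center_is_global_mean(self):
        rng = np.random.default_rng(5)
        points = rng.random((7, 30))
        model = kmeans_cluster(_maps_from(points), k=1, seed=0, n_init=1)
        np.testing.assert_allclose(
            model.centers.reshape(-1), points.mean(axis=0), atol=1e-12
        )

    def test_inertia_monotone_within_lloyd(self):
        rng = np.random.default_rng(9)
        points = rng.random((40, 30))
        model = kmeans_cluster(_maps_from(points), k=4, seed=2, n_init=3)
        assert all(
            b <= a + 1e-9
            for a, b in zip(model.inertia_history, model.inertia_history[1:])
        )

    def test_fewer_maps_than_k_rejected(self):
        with pytest.raises(ValueError):
            kmeans_cluster(_maps_from(np.random.default_rng(0).random((3, 30))), k=4)

    def test_matches_sklearn_on_blobs(self):
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(11)
        centers = rng.uniform(0, 50, size=(4, 30))
        points = np.vstack([c + 0.5 * rng.normal(size=(8, 30)) for c in centers])
        model = kmeans_cluster(_maps_from(points), k=4, seed=0, n_init=10)
        sk = KMeans(n_clusters=4, n_init=10, random_state=0).fit(np.abs(points))
        assert model.inertia == pytest.approx(sk.inertia_, rel=1e-6)


class TestMinClusterSize:
    def _model_with_sizes(self, sizes):
        maps, idx = [], 0
        k = len(sizes)
        for c, n in enumerate(sizes):
            for _ in range(n):
                maps.append(RelevanceMap(f"s{idx}", np.full((2, 2), float(c))))
                idx += 1
        return kmeans_cluster(maps, k=k, seed=0, n_init=2)

    def test_published_cluster_sizes_pass(self):
        model = self._model_with_sizes([84, 45, 67, 55])
        report = check_min_cluster_size(model, minimum=30)
        assert report.passed and sorted(report.sizes.values()) == [45, 55, 67, 84]

    def test_small_cluster_fails_and_is_listed(self):
        model = self._model_with_sizes([100, 10])
        report = check_min_cluster_size(model, minimum=30)
        assert not report.passed
        assert report.sizes[report.offending[0]] == 10


class TestSmoothCenter:
    def test_constant_rows_unchanged(self):
        out = smooth_center(np.full((6, 50), 0.7), window=11, polyorder=3)
        np.testing.assert_allclose(out, 0.7, atol=1e-12)

    def test_polynomial_rows_reproduced(self):
        i = np.arange(50, dtype=float)
        row = 0.02 * i**2 - 0.3 * i + 1.0
        out = smooth_center(np.tile(row, (6, 1)), window=11, polyorder=2)
        np.testing.assert_allclose(out[:, 5:-5], np.tile(row[5:-5], (6, 1)), atol=1e-9)

    def test_high_frequency_noise_contracted(self):
        row = np.tile([0.0, 1.0], 25)
        out = smooth_center(np.tile(row, (6, 1)), window=11, polyorder=2)
        assert out.var() < np.tile(row, (6, 1)).var()

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_center(np.zeros((6, 50)), window=10, polyorder=2)


class TestClusterSummary:
    def _toy_model_and_curves(self, curves_per_cluster):
        maps, curves = [], {}
        idx = 0
        for c, cluster_curves in enumerate(curves_per_cluster):
            for curve in cluster_curves:
                sid = f"s{idx}"
                maps.append(RelevanceMap(sid, np.full((6, 20), float(c) + 0.5)))
                curves[sid] = NormalizedCurveSet(sid, curve, avc_index=7)
                idx += 1
        model = kmeans_cluster(maps, k=len(curves_per_cluster), seed=0, n_init=2)
        model.letters = {i: f"K{i}" for i in range(model.k)}
        return model, curves

    def test_identical_curves_have_zero_sd(self):
        curve = np.ones((6, 20))
        model, curves = self._toy_model_and_curves([[curve, curve, curve], [2 * curve] * 3])
        out = cluster_summary(model, curves, control_mean=np.zeros((6, 20)),
                              avc_index=7, window=5, polyorder=2)
        for summ in out.values():
            np.testing.assert_array_equal(summ.sd_curves, 0.0)

    def test_antisymmetric_curves_average_to_zero(self):
        c = np.random.default_rng(0).normal(size=(6, 20))
        model, curves = self._toy_model_and_curves([[c, -c], [2 * c, 2 * c]])
        out = cluster_summary(model, curves, control_mean=np.zeros((6, 20)),
                              avc_index=7, window=5, polyorder=2)
        key = next(k for k, v in out.items() if v.n_subjects == 2 and v.mean_curves.max() < 1e-9)
        np.testing.assert_allclose(out[key].mean_curves, 0.0, atol=1e-12)

    def test_singleton_cluster_warns(self):
        c = np.ones((6, 20))
        model, curves = self._toy_model_and_curves([[c], [2 * c, 2 * c]])
        with pytest.warns(UserWarning, match="single subject"):
            cluster_summary(model, curves, control_mean=np.zeros((6, 20)),
                            avc_index=7, window=5, polyorder=2)

    def test_post_systolic_cluster_mean_peak_after_avc(self, covariates, noise_free_params):
        from strainpheno.io_preprocess import normalize_time
        from strainpheno.records import SEGMENTS
        from strainpheno.synthetic import simulate_subject

        curves = {}
        maps = []
        for i in range(30):
            rec = simulate_subject("carrier", "C", covariates, seed=300 + i,
                                   params=noise_free_params)
            ncs = normalize_time(rec)
            curves[rec.subject_id] = ncs
            maps.append(RelevanceMap(rec.subject_id, np.abs(ncs.matrix)))
        model = kmeans_cluster(maps, k=1, seed=0, n_init=1)
        model.letters = {0: "C"}
        out = cluster_summary(model, curves, control_mean=np.zeros((6, 101)))
        seg = SEGMENTS.index("apical-septal")
        assert out["C"].mean_curves[seg].argmin() > 38


def test_plot_cluster_summary_writes_figure(tmp_path):
    from strainpheno.clustering import ClusterSummary, plot_cluster_summary

    rng = np.random.default_rng(0)
    summ = ClusterSummary(
        label="A", n_subjects=12,
        mean_curves=-10 * rng.random((6, 101)),
        sd_curves=rng.random((6, 101)),
        heatmap=rng.random((6, 101)),
        control_mean=np.zeros((6, 101)),
        avc_index=38,
    )
    out = tmp_path / "cluster_A.png"
    plot_cluster_summary(summ, out)
    assert out.stat().st_size > 0


class TestPhenotypeAssignment:
    def test_cluster_o_iff_probability_at_most_half(self):
        PhenotypeAssignment("s", 0.4, "O")
        PhenotypeAssignment("s", 0.6, "A")
        with pytest.raises(ValueError):
            PhenotypeAssignment("s", 0.6, "O")
        with pytest.raises(ValueError):
            PhenotypeAssignment("s", 0.4, "A")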