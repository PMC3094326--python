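"""Two-step k-means discovery and nearest-centroid classification."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from subtypeforge.dataio import ExpressionMatrix
from subtypeforge.subtyping import (
    classify_by_centroid,
    compute_centroids,
    map_cross_platform,
    two_step_kmeans,
)


def _gaussian_clusters(rng, k=6, n_per=40, n_probes=30, sep=6.0, noise=1.0):
    centers = rng.normal(0, sep * noise / np.sqrt(2), size=(n_probes, k))
    labels = np.repeat(np.arange(k), n_per)
    values = centers[:, labels] + noise * rng.standard_normal((n_probes, k * n_per))
    m = ExpressionMatrix([f"p{i}" for i in range(n_probes)],
                         [f"s{j}" for j in range(k * n_per)], values)
    return m, labels


class TestTwoStepKmeans:
    def test_recovers_well_separated_clusters(self, rng):
        m, planted = _gaussian_clusters(rng)
        labels, model = two_step_kmeans(m, k=6, n_restarts=20, seed=0)
        assert adjusted_rand_score(planted, labels) == 1.0
        assert model.k == 6
        assert model.labels == ["I", "II", "III", "IV", "V", "VI"]

    def test_duplicated_samples_co_assigned(self, rng):
        m, _ = _gaussian_clusters(rng, k=3, n_per=15)
        dup = ExpressionMatrix(m.probe_ids,
                               m.sample_ids + [s + "_copy" for s in m.sample_ids],
                               np.hstack([m.values, m.values]))
        labels, _ = two_step_kmeans(dup, k=3, n_restarts=10, seed=1)
        n = len(m.sample_ids)
        assert labels[:n] == labels[n:]

    def test_k_below_two_rejected(self, rng):
        m, _ = _gaussian_clusters(rng, k=2, n_per=10)
        with pytest.raises(ValueError):
            two_step_kmeans(m, k=1, seed=0)

    def test_k_above_samples_rejected(self, rng):
        m, _ = _gaussian_clusters(rng, k=2, n_per=3)
        with pytest.raises(ValueError):
            two_step_kmeans(m, k=10, seed=0)

    def test_seed_required(self, rng):
        m, _ = _gaussian_clusters(rng, k=2, n_per=10)
        with pytest.raises(ValueError):
            two_step_kmeans(m, k=2, seed=None)

    def test_invariant_to_sample_order_and_probe_rescaling(self, rng):
        m, _ = _gaussian_clusters(rng, k=3, n_per=20)
        labels, _ = two_step_kmeans(m, k=3, n_restarts=10, seed=5)
        perm = rng.permutation(len(m.sample_ids))
        scale = rng.uniform(0.5, 4.0, size=len(m.probe_ids))
        shift = rng.normal(0, 3, size=len(m.probe_ids))
        m2 = ExpressionMatrix(m.probe_ids, [m.sample_ids[i] for i in perm],
                              (m.values * scale[:, None] + shift[:, None])[:, perm])
        labels2, _ = two_step_kmeans(m2, k=3, n_restarts=10, seed=5)
        by_sample_1 = dict(zip(m.sample_ids, labels))
        by_sample_2 = dict(zip(m2.sample_ids, labels2))
        assert adjusted_rand_score([by_sample_1[s] for s in m.sample_ids],
                                   [by_sample_2[s] for s in m.sample_ids]) == 1.0


class TestComputeCentroids:
    def test_single_member_cluster_equals_sample(self, rng):
        m, _ = _gaussian_clusters(rng, k=2, n_per=1, n_probes=5)
        model = compute_centroids(m, ["I", "II"])
        z = (m.values - model.center[:, None]) / model.scale[:, None]
        np.testing.assert_allclose(model.centroids[:, 0], z[:, 0])

    def test_two_member_mean(self, rng):
        v = rng.normal(size=(4, 3))
        m = ExpressionMatrix([f"p{i}" for i in range(4)], ["a", "b", "c"], v)
        model = compute_centroids(m, ["I", "I", "II"])
        z = (v - v.mean(axis=1, keepdims=True)) / v.std(axis=1, keepdims=True)
        np.testing.assert_allclose(model.centroids[:, 0], z[:, :2].mean(axis=1))

    def test_order_invariance(self, rng):
        v = rng.normal(size=(6, 8))
        m = ExpressionMatrix([f"p{i}" for i in range(6)],
                             [f"s{j}" for j in range(8)], v)
        labels = ["I", "II", "I", "II", "I", "II", "I", "II"]
        model = compute_centroids(m, labels)
        perm = rng.permutation(8)
        m2 = ExpressionMatrix(m.probe_ids, [m.sample_ids[i] for i in perm],
                              v[:, perm])
        model2 = compute_centroids(m2, [labels[i] for i in perm])
        np.testing.assert_allclose(model.centroids, model2.centroids, atol=1e-12)

    def test_unknown_label_handling(self, rng):
        v = rng.normal(size=(3, 2))
        m = ExpressionMatrix(["a", "b", "c"], ["s1", "s2"], v)
        with pytest.raises(ValueError):
            compute_centroids(m, ["I"])  # wrong length


class TestClassifyByCentroid:
    def test_centroids_classify_to_themselves(self, rng):
        m, planted = _gaussian_clusters(rng, k=4, n_per=20)
        labels, model = two_step_kmeans(m, k=4, n_restarts=10, seed=2)
        # build profiles equal to the centroids on the original scale
        values = model.centroids * model.scale[:, None] + model.center[:, None]
        profiles = ExpressionMatrix(model.classifier_probes, model.labels, values)
        out = classify_by_centroid(profiles, model)
        assert [a.label for a in out] == model.labels
        assert all(a.correlation_to_best > 0.999 for a in out)

    def test_tie_broken_toward_first_label_with_warning(self):
        probes = [f"p{i}" for i in range(6)]
        centroids = np.column_stack([np.linspace(-1, 1, 6), np.linspace(1, -1, 6)])
        from subtypeforge.subtyping import SubtypeModel
        model = SubtypeModel(probes, centroids, ["I", "II"],
                            center=np.zeros(6), scale=np.ones(6))
        flat = ExpressionMatrix(probes, ["x"], np.zeros((6, 1)))
        with pytest.warns(UserWarning, match="tie"):
            out = classify_by_centroid(flat, model)
        assert out[0].label == "I"
        assert out[0].margin == 0.0

    def test_holdout_agreement(self, rng):
        m, planted = _gaussian_clusters(rng, k=6, n_per=60)
        train = ExpressionMatrix(m.probe_ids, m.sample_ids[::2], m.values[:, ::2])
        test = ExpressionMatrix(m.probe_ids, m.sample_ids[1::2], m.values[:, 1::2])
        labels, model = two_step_kmeans(train, k=6, n_restarts=20, seed=3)
        out = classify_by_centroid(test, model)
        agreement = adjusted_rand_score(planted[1::2], [a.label for a in out])
        assert agreement >= 0.98

    def test_low_overlap_rejected_with_fraction(self, rng):
        m, _ = _gaussian_clusters(rng, k=2, n_per=10, n_probes=10)
        _, model = two_step_kmeans(m, k=2, n_restarts=5, seed=4)
        partial = m.subset_probes(m.probe_ids[:4])
        with pytest.raises(ValueError, match="%"):
            classify_by_centroid(partial, model)


class TestMapCrossPlatform:
    def test_one_to_one_is_reordering(self, rng):
        ext = ExpressionMatrix(["eA", "eB", "eC"], ["s1", "s2"],
                               rng.normal(size=(3, 2)))
        gene_map = {"t1": "gB", "t2": "gA", "eA": "gA", "eB": "gB"}
        out = map_cross_platform(["t1", "t2"], gene_map, ext)
        np.testing.assert_allclose(out.values[0], ext.values[1])
        np.testing.assert_allclose(out.values[1], ext.values[0])

    def test_multi_match_rows_averaged(self, rng):
        ext = ExpressionMatrix(["e1", "e2"], ["s1", "s2"], rng.normal(size=(2, 2)))
        gene_map = {"t1": "g", "e1": "g", "e2": "g"}
        out = map_cross_platform(["t1"], gene_map, ext)
        np.testing.assert_allclose(out.values[0], ext.values.mean(axis=0))

    def test_low_coverage_rejected(self, rng):
        ext = ExpressionMatrix(["e1"], ["s1"], rng.normal(size=(1, 1)))
        gene_map = {"t1": "g1", "e1": "g1"}
        with pytest.raises(ValueError):
            map_cross_platform(["t1", "t2", "t3", "t4", "t5"], gene_map, ext)


def test_end_to_end_cross_cohort_recovery(default_cohort):
    """Fit on the default cohort, classify an independent cohort from the
    same recipe; planted subtypes should be recovered with ARI >= 0.9."""
    from subtypeforge import SyntheticConfig, generate_cohort
    from subtypeforge.feature_selection import (
        PivotalGeneSet, ProbeFilterCriteria, select_classifier_probes)

    expr, _, truth = default_cohort
    seed = truth["config"].seed
    selected = select_classifier_probes(
        expr, PivotalGeneSet(truth["pivotal_probes"]), ProbeFilterCriteria())
    labels, model = two_step_kmeans(expr.subset_probes(selected), k=6,
                                    n_restarts=30, seed=seed)
    assert adjusted_rand_score(truth["labels"], labels) >= 0.9

    expr2, _, truth2 = generate_cohort(
        SyntheticConfig(seed=seed + 1000, structure_seed=seed))
    out = classify_by_centroid(expr2.subset_probes(model.classifier_probes), model)
    assert adjusted_rand_score(truth2["labels"], [a.label for a in out]) >= 0.9
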