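"""Probe screening: correlations, kurtosis, and the combined filter."""

import math

import numpy as np
import pytest

from subtypeforge.dataio import ExpressionMatrix
from subtypeforge.feature_selection import (
    PivotalGeneSet,
    ProbeFilterCriteria,
    kurtosis,
    linear_correlation,
    quadratic_r2,
    select_classifier_probes,
)


class TestLinearCorrelation:
    @pytest.mark.parametrize("x,y,expected", [
        ([1, 2, 3], [2, 4, 6], 1.0),
        ([1, 2, 3], [6, 4, 2], -1.0),
        ([-2, -1, 0, 1, 2], [4, 1, 0, 1, 4], 0.0),  # symmetric parabola
    ])
    def test_known_values(self, x, y, expected):
        assert linear_correlation(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_flags_undefined(self):
        assert math.isnan(linear_correlation([1, 1, 1], [1, 2, 3]))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            linear_correlation([1, 2], [1, 2])


class TestQuadraticR2:
    def test_exact_quadratic(self):
        x = np.array([-2.0, -1, 0, 1, 2])
        assert quadratic_r2(x, x**2) == pytest.approx(1.0, abs=1e-12)

    def test_linear_nested_in_quadratic(self):
        x = np.array([0.0, 1, 2, 3, 5])
        assert quadratic_r2(x, 3 * x + 1) == pytest.approx(1.0, abs=1e-12)

    def test_independent_noise_near_zero(self, rng):
        x = rng.normal(size=1000)
        y = rng.normal(size=1000)
        assert quadratic_r2(x, y) < 0.02

    def test_degenerate_design_flags_undefined(self):
        assert math.isnan(quadratic_r2([1, 1, 2, 2], [1, 2, 3, 4]))


class TestKurtosis:
    def test_normal_sample(self, rng):
        assert kurtosis(rng.standard_normal(100_000)) == pytest.approx(3.0, abs=0.1)

    def test_uniform_sample(self, rng):
        assert kurtosis(rng.uniform(size=100_000)) == pytest.approx(1.8, abs=0.05)

    def test_balanced_two_point_mixture(self):
        assert kurtosis(np.array([-1.0, 1.0] * 10)) == pytest.approx(1.0, abs=1e-12)

    def test_constant_vector_flags_undefined(self):
        assert math.isnan(kurtosis([2.0, 2.0, 2.0, 2.0]))


def _planted_matrix(rng, n=300):
    """50 probes linear in pivot 1, 50 quadratic in pivot 2, 900 noise."""
    pivot1 = rng.normal(0, 2, size=n)
    pivot2 = rng.normal(0, 2, size=n)
    probes, names = [pivot1, pivot2], ["piv1", "piv2"]
    for i in range(50):
        noise = rng.normal(0, 1, size=n)
        probes.append(1.0 * pivot1 + noise)  # r ~ 0.9
        names.append(f"lin{i}")
    for i in range(50):
        noise = rng.normal(0, 2.5, size=n)
        probes.append(pivot2**2 + noise)  # quadratic r2 ~ 0.9
        names.append(f"quad{i}")
    for i in range(900):
        probes.append(rng.normal(0, 1, size=n))
        names.append(f"noise{i}")
    return ExpressionMatrix(names, [f"s{j}" for j in range(n)], np.vstack(probes))


class TestSelectClassifierProbes:
    def test_recovers_planted_blocks_exactly(self, rng):
        m = _planted_matrix(rng)
        criteria = ProbeFilterCriteria(
            min_abs_linear_r=0.6, min_quadratic_r2=0.6,
            min_mean_intensity=-np.inf, min_range=0.0, max_kurtosis=np.inf)
        selected = select_classifier_probes(m, PivotalGeneSet(["piv1", "piv2"]), criteria)
        expected = {f"lin{i}" for i in range(50)} | {f"quad{i}" for i in range(50)}
        assert set(selected) == expected

    def test_zero_thresholds_return_all_probes(self, rng):
        m = _planted_matrix(rng, n=100)
        criteria = ProbeFilterCriteria(
            min_abs_linear_r=0.0, min_quadratic_r2=0.0,
            min_mean_intensity=-np.inf, min_range=0.0, max_kurtosis=np.inf)
        selected = select_classifier_probes(m, PivotalGeneSet(["piv1", "piv2"]), criteria)
        assert set(selected) == set(m.probe_ids)

    def test_kurtosis_filter_keeps_bimodal_drops_heavy_tail(self, rng):
        n = 400
        pivot = rng.normal(0, 2, size=n)
        bimodal = np.where(pivot > 0, 3.0, -3.0) + rng.normal(0, 0.8, size=n)
        heavy = pivot + rng.standard_t(2, size=n) * 1.2
        m = ExpressionMatrix(["piv", "bimodal", "heavy"], [f"s{j}" for j in range(n)],
                             np.vstack([pivot, bimodal, heavy]))
        assert kurtosis(bimodal) < 3 < kurtosis(heavy)
        criteria = ProbeFilterCriteria(
            min_abs_linear_r=0.3, min_quadratic_r2=0.3,
            min_mean_intensity=-np.inf, min_range=0.0, max_kurtosis=3.0)
        selected = select_classifier_probes(m, PivotalGeneSet(["piv"]), criteria)
        assert "bimodal" in selected and "heavy" not in selected

    def test_selection_monotone_in_thresholds(self, rng):
        m = _planted_matrix(rng, n=150)
        loose = ProbeFilterCriteria(0.3, 0.3, -np.inf, 0.0, np.inf)
        base = set(select_classifier_probes(m, PivotalGeneSet(["piv1", "piv2"]), loose))
        for tight in (
            ProbeFilterCriteria(0.6, 0.3, -np.inf, 0.0, np.inf),
            ProbeFilterCriteria(0.3, 0.8, -np.inf, 0.0, np.inf),
            ProbeFilterCriteria(0.3, 0.3, 0.5, 0.0, np.inf),
            ProbeFilterCriteria(0.3, 0.3, -np.inf, 2.0, np.inf),
            ProbeFilterCriteria(0.3, 0.3, -np.inf, 0.0, 2.5),
        ):
            subset = set(select_classifier_probes(m, PivotalGeneSet(["piv1", "piv2"]), tight))
            assert subset <= base

    def test_invariant_to_sample_permutation(self, rng):
        m = _planted_matrix(rng, n=120)
        criteria = ProbeFilterCriteria(0.5, 0.5, -np.inf, 0.0, np.inf)
        pivots = PivotalGeneSet(["piv1", "piv2"])
        sel = select_classifier_probes(m, pivots, criteria)
        perm = rng.permutation(len(m.sample_ids))
        m2 = ExpressionMatrix(m.probe_ids, [m.sample_ids[i] for i in perm],
                              m.values[:, perm])
        assert select_classifier_probes(m2, pivots, criteria) == sel

    def test_planted_cohort_recovery(self, default_cohort):
        expr, _, truth = default_cohort
        selected = set(select_classifier_probes(
            expr, PivotalGeneSet(truth["pivotal_probes"]), ProbeFilterCriteria()))
        planted = set(truth["classifier_probes"])
        noise = set(truth["noise_probes"])
        sensitivity = len(selected & planted) / len(planted)
        fpr = len(selected & noise) / len(noise)
        assert sensitivity >= 0.95
        assert fpr <= 0.01

    def test_missing_pivot_rejected(self, rng):
        m = _planted_matrix(rng, n=60)
        with pytest.raises(KeyError):
            select_classifier_probes(m, PivotalGeneSet(["absent"]),
                                     ProbeFilterCriteria())

    def test_empty_result_warns(self, rng):
        m = _planted_matrix(rng, n=60)
        criteria = ProbeFilterCriteria(1.0, 1.0, np.inf, np.inf, -np.inf)
        with pytest.warns(UserWarning):
            out = select_classifier_probes(m, PivotalGeneSet(["piv1"]), criteria)
        assert out == []
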