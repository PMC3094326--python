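"""Expression/clinical IO, preprocessing chain, and eligibility filters."""

import numpy as np
import pandas as pd
import pytest

from subtypeforge import dataio
from subtypeforge.dataio import ExpressionMatrix


def _matrix(values, probes=None, samples=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(probes, samples, values)


def _clinical(n, **overrides):
    base = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "age_years": 50.0,
        "t_stage": 2,
        "n_stage": 0,
        "m_stage": 0,
        "tnm_stage": "II",
        "nuclear_grade": 2,
        "er_ihc": "pos",
        "pr_ihc": "neg",
        "her2_ihc": "unknown",
        "chemo_regimen": "CMF",
        "hormonal_rx": True,
        "radiation_rx": False,
        "followup_years": 5.0,
        "dead_of_disease": False,
        "mfs_time_years": 5.0,
        "mfs_event": False,
        "os_time_years": 5.0,
        "os_event": False,
    })
    for k, v in overrides.items():
        base[k] = v
    return base


class TestExpressionIO:
    def test_round_trip(self, tmp_path, rng):
        m = _matrix(rng.normal(8, 1, size=(3, 2)))
        path = tmp_path / "m.tsv"
        dataio.write_expression(m, path)
        back = dataio.read_expression(path)
        assert back.probe_ids == m.probe_ids
        assert back.sample_ids == m.sample_ids
        np.testing.assert_array_equal(back.values, m.values)

    def test_duplicate_probe_id_is_named_in_error(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("probe_id\ts1\ts2\npA\t1\t2\npA\t3\t4\n")
        with pytest.raises(ValueError, match="pA"):
            dataio.read_expression(path)

    def test_non_numeric_cell_is_located(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("probe_id\ts1\npA\t1.0\npB\toops\n")
        with pytest.raises(ValueError, match="pB"):
            dataio.read_expression(path)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            ExpressionMatrix([], ["s1"], np.empty((0, 1)))

    def test_clinical_round_trip_preserves_unknown(self, tmp_path):
        df = _clinical(4, her2_ihc=["unknown", "pos", "neg", "unknown"])
        path = tmp_path / "c.csv"
        dataio.write_clinical(df, path)
        back = dataio.read_clinical(path)
        assert list(back["her2_ihc"]) == ["unknown", "pos", "neg", "unknown"]


class TestPreprocess:
    def test_identity_when_trimmed_mean_already_on_target(self):
        col = np.array([400.0, 450.0, 500.0, 550.0, 600.0])
        m = _matrix(col[:, None] * [1, 1])
        out = dataio.preprocess(m, target_trimmed_mean=500.0, trim_fraction=0.0)
        np.testing.assert_allclose(out.values, np.log2(m.values))

    def test_hand_computed_scaling(self):
        col = np.array([100.0, 200.0, 300.0, 400.0, 500.0])  # trimmed mean 300
        m = _matrix(col[:, None])
        out = dataio.preprocess(m, trim_fraction=0.0)
        np.testing.assert_allclose(out.values[:, 0], np.log2(col * 500.0 / 300.0))

    def test_invariant_to_per_column_rescaling(self, rng):
        v = rng.uniform(50, 5000, size=(40, 3))
        m1 = _matrix(v)
        m2 = _matrix(v * np.array([2.0, 0.5, 7.0]))
        out1 = dataio.preprocess(m1)
        out2 = dataio.preprocess(m2)
        np.testing.assert_allclose(out1.values, out2.values, atol=1e-10)

    def test_non_positive_intensity_rejected(self):
        with pytest.raises(ValueError):
            dataio.preprocess(_matrix([[1.0, -2.0], [3.0, 4.0]]))

    def test_constant_column_scales_finitely(self):
        out = dataio.preprocess(_matrix([[250.0], [250.0], [250.0]]))
        assert np.all(np.isfinite(out.values))
        np.testing.assert_allclose(out.values, np.log2(500.0))


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self, rng):
        col = rng.normal(8, 1, size=20)
        m = _matrix(np.column_stack([col, col]))
        out = dataio.quantile_normalize(m)
        np.testing.assert_allclose(out.values, m.values, atol=1e-12)

    def test_rank_mean_by_hand(self):
        m = _matrix(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]))
        out = dataio.quantile_normalize(m)
        np.testing.assert_allclose(out.values,
                                   np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]]))

    def test_sorted_columns_identical_after_normalization(self, rng):
        m = _matrix(rng.normal(size=(30, 4)))
        out = dataio.quantile_normalize(m)
        ref = np.sort(out.values[:, 0])
        for j in range(1, 4):
            np.testing.assert_allclose(np.sort(out.values[:, j]), ref, atol=1e-12)

    def test_idempotent(self, rng):
        v = rng.normal(size=(25, 3))
        once = dataio.quantile_normalize(_matrix(v))
        twice = dataio.quantile_normalize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-9)

    def test_ties_get_mean_of_tied_rank_values(self):
        # column 1 has a two-way tie at the bottom: ranks 1 and 2 share the
        # mean of the reference values at those ranks
        v = np.array([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]])
        out = dataio.quantile_normalize(_matrix(v))
        ref = np.mean(np.sort(v, axis=0), axis=1)
        expected_tie = 0.5 * (ref[0] + ref[1])
        np.testing.assert_allclose(out.values[:, 0],
                                   [expected_tie, expected_tie, ref[2]])

    def test_single_sample_warns_and_returns_input(self, rng):
        m = _matrix(rng.normal(size=(10, 1)))
        with pytest.warns(UserWarning):
            out = dataio.quantile_normalize(m)
        np.testing.assert_array_equal(out.values, m.values)


class TestEligibility:
    def _qc(self, ids, fail_rna=(), fail_sufficient=(), fail_array=()):
        return pd.DataFrame({
            "sample_id": ids,
            "rna_ok": [i not in fail_rna for i in ids],
            "rna_sufficient": [i not in fail_sufficient for i in ids],
            "array_ok": [i not in fail_array for i in ids],
        })

    def test_study_cohort_arithmetic(self):
        # 447 collected; 1 insufficient RNA, 116 poor RNA, 18 bad arrays
        ids = [f"s{i}" for i in range(447)]
        clinical = _clinical(447)
        qc = self._qc(ids, fail_sufficient=set(ids[:1]),
                      fail_rna=set(ids[1:117]), fail_array=set(ids[117:135]))
        eligible = dataio.filter_eligible(clinical, qc)
        assert len(eligible) == 312

    def test_short_followup_alive_excluded(self):
        clinical = _clinical(1, followup_years=2.0, dead_of_disease=False)
        qc = self._qc(["s0"])
        assert dataio.filter_eligible(clinical, qc) == []

    def test_short_followup_dead_of_disease_included(self):
        clinical = _clinical(1, followup_years=2.0, dead_of_disease=True)
        qc = self._qc(["s0"])
        assert dataio.filter_eligible(clinical, qc) == ["s0"]

    def test_zero_threshold_with_passing_qc_keeps_everyone(self):
        clinical = _clinical(5, followup_years=[0.1, 1, 2, 3, 10])
        qc = self._qc([f"s{i}" for i in range(5)])
        assert dataio.filter_eligible(clinical, qc, min_followup_years=0) == \
            [f"s{i}" for i in range(5)]

    def test_missing_qc_record_names_sample(self):
        clinical = _clinical(2)
        qc = self._qc(["s0"])
        with pytest.raises(ValueError, match="s1"):
            dataio.filter_eligible(clinical, qc)
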