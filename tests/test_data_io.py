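import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mocogcn import (
    CohortLabels,
    OmicsView,
    align_cohort,
    generalized_fold_change,
    load_view,
    wilcoxon_select,
    write_view,
)
from mocogcn.data_io import GFC_QUANTILES


def _view(X, view_name="species", sids=None, fids=None):
    X = np.asarray(X, dtype=float)
    sids = sids or [f"s{i}" for i in range(X.shape[0])]
    fids = fids or [f"f{j}" for j in range(X.shape[1])]
    return OmicsView(view_name, sids, fids, X)


class TestLoadWrite:
    def test_binary_exposome_round_trip(self, tmp_path):
        v = _view([[0, 1], [1, 1], [0, 0.0]], "exposome")
        assert v.X.shape == (3, 2)
        p = tmp_path / "e.tsv"
        write_view(v, p)
        v2 = load_view(p, "exposome")
        assert v2.sample_ids == v.sample_ids
        assert v2.feature_ids == v.feature_ids
        assert np.array_equal(v2.X, v.X)

    def test_species_round_trip_bit_for_bit(self, tmp_path):
        rng = np.random.default_rng(0)
        X = rng.dirichlet(np.ones(7), size=5)
        v = _view(X)
        p = tmp_path / "s.tsv"
        write_view(v, p)
        assert np.array_equal(load_view(p, "species").X, X)

    def test_non_binary_exposome_rejected(self):
        with pytest.raises(ValueError, match="non-binary"):
            _view([[0, 0.5], [1, 0]], "exposome")

    def test_missing_value_names_sample_and_feature(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("sample_id\tf0\tf1\na\t0.1\t\nb\t0.2\t0.3\n")
        with pytest.raises(ValueError, match="'a'.*'f1'"):
            load_view(p, "species")

    def test_duplicate_identifiers_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            _view([[1.0], [2.0]], sids=["a", "a"])

    def test_negative_species_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            _view([[-0.1], [0.2]])


class TestAlignCohort:
    def test_shuffled_order_realigned_nothing_dropped(self):
        a = _view([[1.0], [2.0], [3.0]], sids=["x", "y", "z"])
        b = _view([[1, 0], [0, 1], [1, 1.0]], "exposome", sids=["z", "x", "y"])
        lab = CohortLabels(["y", "z", "x"], [0, 1, 1])
        a2, b2, l2 = align_cohort(a, b, lab)
        assert a2.sample_ids == b2.sample_ids == l2.sample_ids == ["x", "y", "z"]
        assert b2.X[0].tolist() == [0, 1]  # x's row
        assert l2.y.tolist() == [1, 0, 1]

    def test_partial_overlap_keeps_intersection(self):
        a = _view([[1.0], [2.0], [3.0]], sids=["a", "b", "c"])
        b = _view([[1.0], [2.0], [3.0]], sids=["b", "c", "d"])
        lab = CohortLabels(["a", "b", "c", "d"], [0, 1, 0, 1])
        a2, b2, l2 = align_cohort(a, b, lab)
        assert a2.sample_ids == ["b", "c"]
        assert np.array_equal(b2.X, [[1.0], [2.0]])

    def test_disjoint_ids_error(self):
        a = _view([[1.0], [2.0]], sids=["a", "b"])
        b = _view([[1.0], [2.0]], sids=["c", "d"])
        with pytest.raises(ValueError, match="no samples"):
            align_cohort(a, b, CohortLabels(["a", "b", "c", "d"], [0, 1, 0, 1]))


class TestWilcoxonSelect:
    def _cohort(self, X, y):
        v = _view(X)
        return v, CohortLabels(v.sample_ids, y)

    def test_alpha_one_retains_all_but_p_equal_one(self, rng):
        X = rng.random((10, 4))
        X[:, 3] = 1.0  # constant identical in both groups -> p = 1, dropped
        v, lab = self._cohort(X, [0] * 5 + [1] * 5)
        res = wilcoxon_select(v, lab, alpha=1.0)
        assert res.retained_feature_ids == [
            f for f, p in zip(res.feature_ids, res.p_values) if p < 1
        ]
        assert "f3" not in res.retained_feature_ids

    def test_constant_identical_feature_p_one(self, rng):
        X = np.column_stack([np.full(12, 0.7), rng.random(12)])
        v, lab = self._cohort(X, [0] * 6 + [1] * 6)
        res = wilcoxon_select(v, lab, alpha=0.05)
        assert res.p_values[0] == 1.0
        assert "f0" not in res.retained_feature_ids

    def test_shifted_feature_retained_matches_independent_ranksum(self):
        rng = np.random.default_rng(77)
        X = rng.normal(size=(50, 10))
        X[25:, 0] += 3.0  # 3-SD location shift in cases
        X -= X.min()  # species views must be non-negative
        y = np.array([0] * 25 + [1] * 25)
        v, lab = self._cohort(X, y)
        res = wilcoxon_select(v, lab, alpha=0.05)
        assert "f0" in res.retained_feature_ids
        # independent oracle: scipy's rank-sum z-test per feature
        for j in range(10):
            p_oracle = stats.ranksums(X[y == 1, j], X[y == 0, j]).pvalue
            assert (res.p_values[j] < 0.05) == (p_oracle < 0.05)
            assert res.p_values[j] == pytest.approx(p_oracle, abs=0.01)

    def test_single_class_error(self, rng):
        v = _view(rng.random((4, 2)))
        with pytest.raises(ValueError):
            lab = CohortLabels(v.sample_ids, [1, 1, 1, 1], [True] * 4)
            wilcoxon_select(v, lab)

    def test_feature_permutation_equivariance_and_sample_invariance(self, rng):
        X = rng.random((30, 6))
        y = np.array([0, 1] * 15)
        v, lab = self._cohort(X, y)
        res = wilcoxon_select(v, lab)
        perm = rng.permutation(6)
        v2 = _view(X[:, perm], fids=[f"f{j}" for j in perm])
        res2 = wilcoxon_select(v2, CohortLabels(v2.sample_ids, y))
        assert np.allclose(res2.p_values, res.p_values[perm])
        sperm = rng.permutation(30)
        v3 = _view(X[sperm], sids=[f"s{i}" for i in sperm])
        res3 = wilcoxon_select(v3, CohortLabels(v3.sample_ids, y[sperm]))
        assert np.allclose(res3.p_values, res.p_values)

    def test_null_false_positive_rate_within_binomial_bounds(self):
        rng = np.random.default_rng(2024)
        n_feat = 2000
        X = rng.normal(size=(40, n_feat)) + 5.0
        v, lab = self._cohort(X, [0] * 20 + [1] * 20)
        res = wilcoxon_select(v, lab, alpha=0.05)
        frac = np.mean(res.p_values < 0.05)
        # 99% binomial band around 0.05 at n=2000
        lo, hi = stats.binom.ppf([0.005, 0.995], n_feat, 0.05) / n_feat
        assert lo <= frac <= hi


class TestGeneralizedFoldChange:
    def test_identical_distributions_zero(self, rng):
        v = rng.random(20)
        assert generalized_fold_change(v, v) == 0.0

    def test_constant_shift_recovered(self, rng):
        v = rng.random(15)
        assert generalized_fold_change(v + 0.7, v) == pytest.approx(0.7)

    def test_case_vs_zero_equals_mean_case_quantiles(self):
        case = np.array([1.0, 2.0, 3.0, 4.0])
        ctrl = np.zeros(4)
        expected = np.mean([np.quantile(case, q) for q in GFC_QUANTILES])
        got = generalized_fold_change(case, ctrl)
        assert got == pytest.approx(expected)
        assert got > 0

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            generalized_fold_change(np.array([]), np.array([1.0]))

    @settings(deadline=None, max_examples=50)
    @given(
        a=st.lists(st.floats(-50, 50), min_size=1, max_size=30),
        b=st.lists(st.floats(-50, 50), min_size=1, max_size=30),
    )
    def test_antisymmetry(self, a, b):
        a, b = np.array(a), np.array(b)
        assert generalized_fold_change(a, b) == pytest.approx(
            -generalized_fold_change(b, a), abs=1e-10
        )
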