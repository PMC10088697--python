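"""Mutual information, discretization, and greedy mRMR selection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import mutual_info_score

import il13pep as m
from il13pep.mrmr import MRMRSelector, discretize
from oracles import naive_entropy, naive_mi, naive_mrmr


class TestDiscretize:
    def test_equal_width_two_bins(self):
        d = discretize(np.array([[0.0], [5.0], [10.0]]), bin_count=2)
        assert list(d.codes[:, 0]) == [0, 1, 1]

    def test_constant_feature_single_code(self):
        d = discretize(np.full((5, 1), 3.14), bin_count=10)
        assert set(d.codes[:, 0]) == {0}
        assert d.n_levels[0] == 1

    def test_binary_feature_invariant(self):
        x = np.array([[0.0], [1.0], [0.0], [1.0], [1.0]])
        for bins in (2, 5, 10):
            d = discretize(x, bin_count=bins)
            assert list(d.codes[:, 0]) == [0, 1, 0, 1, 1]

    def test_nonfinite_names_feature(self):
        table = pd.DataFrame({"good": [0.0, 1.0], "broken": [0.0, np.nan]})
        with pytest.raises(ValueError, match="broken"):
            discretize(table)

    def test_bin_count_validated(self):
        with pytest.raises(ValueError):
            discretize(np.zeros((3, 1)), bin_count=1)


class TestMutualInformation:
    def test_identical_balanced_binary_is_one_bit(self):
        x = np.tile([0, 1], 50)
        assert m.mutual_information(x, x) == pytest.approx(1.0)

    def test_independent_is_zero(self):
        assert m.mutual_information([0, 0, 1, 1], [0, 1, 0, 1]) == 0.0

    def test_frozen_joint_histogram_case(self):
        x = [0] * 5 + [1] * 5
        y = [0, 0, 0, 0, 1, 0, 1, 1, 1, 1]  # joint {(0,0):4,(0,1):1,(1,0):1,(1,1):4}
        expected = naive_mi(x, y)
        assert expected == pytest.approx(0.2780719051126377)
        assert m.mutual_information(x, y) == pytest.approx(expected)

    def test_symmetry_exact(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.integers(0, 4, size=30)
            y = rng.integers(0, 3, size=30)
            assert m.mutual_information(x, y) == m.mutual_information(y, x)

    def test_nonnegative_and_self_mi_is_entropy(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            x = rng.integers(0, 5, size=40)
            y = rng.integers(0, 5, size=40)
            assert m.mutual_information(x, y) >= 0.0
            assert m.mutual_information(x, x) == pytest.approx(naive_entropy(x))

    def test_matches_sklearn_cross_check(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 4, size=60)
        y = rng.integers(0, 3, size=60)
        assert m.mutual_information(x, y) == pytest.approx(
            mutual_info_score(x, y) / np.log(2)
        )

    def test_merging_bins_never_increases_mi(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x = rng.integers(0, 6, size=50)
            y = rng.integers(0, 2, size=50)
            assert m.mutual_information(x // 2, y) <= m.mutual_information(x, y) + 1e-12

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            m.mutual_information([0, 1], [0, 1, 0])


class TestRelevance:
    def test_feature_identical_to_labels(self):
        y = np.tile([0, 1], 20)
        d = discretize(y.reshape(-1, 1).astype(float), bin_count=2)
        rel = m.relevance(d, y)
        assert rel.iloc[0] == pytest.approx(naive_entropy(y))

    def test_independent_feature_zero(self):
        y = np.tile([0, 1], 10)
        x = np.tile([0, 0, 1, 1], 5).reshape(-1, 1).astype(float)
        d = discretize(x, bin_count=2)
        assert m.relevance(d, y).iloc[0] == pytest.approx(0.0)

    def test_set_relevance_is_mean(self):
        rng = np.random.default_rng(4)
        X = rng.random((40, 3))
        y = rng.integers(0, 2, size=40)
        d = discretize(X, bin_count=4)
        from il13pep.mrmr import relevance_of_set

        assert relevance_of_set(d, y) == pytest.approx(float(m.relevance(d, y).mean()))

    def test_single_class_labels_warn_and_zero(self):
        d = discretize(np.random.default_rng(5).random((10, 2)))
        with pytest.warns(UserWarning, match="single-class"):
            rel = m.relevance(d, np.zeros(10, dtype=int))
        assert (rel == 0).all()


class TestMrmrSelect:
    def test_k1_picks_max_relevance(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, size=60)
        table = pd.DataFrame(
            {
                "noise_a": rng.random(60),
                "signal": y + 0.01 * rng.random(60),
                "noise_b": rng.random(60),
            }
        )
        res = m.mrmr_select(table, y, k=1)
        assert res.ranked_features == ["signal"]
        assert res.per_step.loc[0, "redundancy"] == 0.0

    def test_duplicate_of_selected_feature_penalized(self):
        """An exact copy of the first pick loses to an informative,
        less-redundant alternative at step 2 (brute-force verified)."""
        rng = np.random.default_rng(7)
        n = 200
        y = np.tile([0, 1], n // 2)
        f1 = y.copy()
        f1[:2] = 1 - f1[:2]  # near-identical to labels
        f2 = f1.copy()  # exact duplicate of F1
        f3 = y.copy()  # informative, not identical to F1
        flip = rng.choice(n, size=40, replace=False)
        f3[flip] = 1 - f3[flip]
        table = pd.DataFrame(
            {"f1": f1.astype(float), "f2": f2.astype(float), "f3": f3.astype(float)}
        )
        res = m.mrmr_select(table, y, k=2)
        assert res.ranked_features == ["f1", "f3"]
        codes = discretize(table).codes
        oracle = naive_mrmr(codes, y, k=2)
        assert oracle == [f"x{list(table.columns).index(f)}" for f in res.ranked_features]

    def test_k_equals_feature_count_is_permutation(self):
        rng = np.random.default_rng(8)
        table = pd.DataFrame(rng.random((50, 5)), columns=list("abcde"))
        y = rng.integers(0, 2, size=50)
        res = m.mrmr_select(table, y, k=5)
        assert sorted(res.ranked_features) == list("abcde")

    @pytest.mark.parametrize("variant", ["difference", "quotient"])
    def test_greedy_steps_match_bruteforce_oracle(self, variant):
        """Every pick on a 6-feature table matches an exhaustive
        recomputation of the criterion from raw joint histograms."""
        rng = np.random.default_rng(9)
        n, d = 80, 6
        y = rng.integers(0, 2, size=n)
        X = rng.random((n, d))
        X[:, 0] += y  # plant some relevance
        X[:, 3] += 0.5 * y
        table = pd.DataFrame(X, columns=[f"x{j}" for j in range(d)])
        res = m.mrmr_select(table, y, k=d, variant=variant)
        codes = discretize(table).codes
        assert res.ranked_features == naive_mrmr(codes, y, k=d, variant=variant)

    def test_all_constant_features_error(self):
        table = pd.DataFrame({"a": [1.0] * 10, "b": [2.0] * 10})
        with pytest.raises(ValueError, match="constant"):
            m.mrmr_select(table, np.tile([0, 1], 5), k=1)

    def test_k_out_of_range_errors(self):
        table = pd.DataFrame({"a": [0.0, 1.0] * 5})
        with pytest.raises(ValueError):
            m.mrmr_select(table, np.tile([0, 1], 5), k=2)


class TestTopKSlice:
    def test_prefix_and_nesting(self, planted_table):
        X, y = planted_table
        res = m.mrmr_select(X, y, k=20)
        top10 = m.top_k_slice(res, 10)
        top20 = m.top_k_slice(res, 20)
        assert top10 == res.ranked_features[:10]
        assert top20[:10] == top10
        assert m.top_k_slice(res, 5) == top10[:5]

    def test_k_too_large_errors(self, planted_table):
        X, y = planted_table
        res = m.mrmr_select(X, y, k=5)
        with pytest.raises(ValueError):
            m.top_k_slice(res, 6)


class TestMRMRSelectorEstimator:
    def test_fit_transform_selects_k_columns(self, planted_table):
        X, y = planted_table
        sel = MRMRSelector(k=10).fit(X, y)
        assert len(sel.ranking_) == 10
        assert sel.transform(X).shape == (X.shape[0], 10)
        assert set(sel.get_feature_names_out()) == set(sel.ranking_)

    def test_planted_signal_ranked_first(self, planted_table):
        X, y = planted_table
        sel = MRMRSelector(k=5).fit(X, y)
        assert "AAC_H" in sel.ranking_

    def test_clone_compatible(self):
        from sklearn.base import clone

        sel = MRMRSelector(k=3, variant="quotient", bin_count=8)
        params = clone(sel).get_params()
        assert params == {"k": 3, "variant": "quotient", "bin_count": 8}
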