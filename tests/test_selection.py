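"""Fusion and the MAD -> mRMR -> LASSO selection chain."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import mutual_info_score

from _oracles import brute_force_mrmr
from radiofuse.selection import (
    FusedFeatureMatrix,
    SelectionConfig,
    discretise_3state,
    fuse,
    lasso_select,
    mad_filter,
    mad_values,
    mrmr_select,
    select_signature,
)


def _fm(values, names=None, block="HC", pids=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"f{i}" for i in range(values.shape[1])]
    pids = pids or [f"P{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=pids, columns=names)
    return fuse([df], [block])


class TestFuse:
    def test_single_block_is_identity(self):
        m = _fm(np.arange(12).reshape(4, 3))
        assert m.n_features == 3
        assert list(m.blocks.unique()) == ["HC"]

    def test_dimension_is_sum_of_blocks(self):
        rng = np.random.default_rng(0)
        pids = [f"P{i}" for i in range(5)]
        blocks = [pd.DataFrame(rng.normal(size=(5, d)), index=pids,
                               columns=[f"{t}{i}" for i in range(d)])
                  for t, d in (("a", 4), ("b", 7), ("c", 2))]
        m = fuse(blocks, ["HC", "TL", "FT"])
        assert m.n_features == 13
        assert (m.blocks == "TL").sum() == 7

    def test_patient_mismatch_rejected(self):
        a = pd.DataFrame(np.ones((3, 2)), index=["P0", "P1", "P2"])
        b = pd.DataFrame(np.ones((3, 2)), index=["P0", "P2", "P1"],
                         columns=["x", "y"])
        with pytest.raises(ValueError, match="patient"):
            fuse([a, b], ["HC", "TL"])

    def test_duplicate_feature_names_rejected(self):
        a = pd.DataFrame(np.ones((3, 1)), columns=["f"])
        b = pd.DataFrame(np.ones((3, 1)), columns=["f"])
        with pytest.raises(ValueError, match="duplicate"):
            fuse([a, b], ["HC", "TL"])


class TestMadFilter:
    def test_hand_mad_value(self):
        m = _fm(np.array([[1.0], [2.0], [3.0], [4.0], [5.0]]))
        assert mad_values(m.matrix).iloc[0] == 1.0

    def test_constant_feature_always_removed(self):
        rng = np.random.default_rng(1)
        vals = np.column_stack([np.full(10, 7.0), rng.normal(size=(10, 3)).T.flatten().reshape(3, 10).T])
        m = _fm(vals, names=["const", "a", "b", "c"])
        kept = mad_filter(m, drop_quantile=0.0)
        assert "const" not in kept.matrix.columns
        assert kept.n_features == 3

    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(20, 5))
        m1 = mad_values(pd.DataFrame(x))
        m2 = mad_values(pd.DataFrame(-3.5 * x))
        np.testing.assert_allclose(m2.to_numpy(), 3.5 * m1.to_numpy())

    def test_quartile_drop_fraction(self):
        rng = np.random.default_rng(3)
        m = _fm(rng.normal(size=(30, 100)) * rng.uniform(0.1, 10, 100))
        kept = mad_filter(m, drop_quantile=0.25)
        assert kept.n_features == 75

    def test_all_removed_is_an_error(self):
        m = _fm(np.ones((5, 3)))
        with pytest.raises(ValueError, match="lower drop_quantile"):
            mad_filter(m)


class TestMrmr:
    def test_label_matching_feature_selected_first(self):
        rng = np.random.default_rng(4)
        y = np.array(["a", "b", "c"] * 10)
        perfect = np.array([0.0, 5.0, 10.0] * 10)  # discretises to labels
        X = np.column_stack([rng.normal(size=30), perfect,
                             rng.normal(size=30)])
        m = _fm(X, names=["n1", "hit", "n2"])
        out = mrmr_select(m, y, k=2)
        assert out.matrix.columns[0] == "hit"

    def test_duplicate_of_first_pick_deferred(self):
        # the clone's redundancy with the first pick equals the first
        # pick's own entropy, so an independently noisy informative
        # feature must win step 2
        rng = np.random.default_rng(5)
        y = np.array(["a", "b", "c"] * 12)
        base = np.array([0.0, 5.0, 10.0] * 12)
        hit = base + rng.normal(0, 0.8, 36)
        other = base + rng.normal(0, 1.8, 36)
        X = np.column_stack([hit, hit.copy(), other])
        m = _fm(X, names=["hit", "clone", "other"])
        out = mrmr_select(m, y, k=2)
        assert out.matrix.columns[0] == "hit"
        assert "clone" not in out.matrix.columns

    def test_k_equal_to_dimension_retains_all_in_score_order(self):
        rng = np.random.default_rng(6)
        y = rng.choice(["a", "b"], 40)
        m = _fm(rng.normal(size=(40, 3)))
        out = mrmr_select(m, y, k=3)
        assert set(out.matrix.columns) == {"f0", "f1", "f2"}

    def test_single_class_labels_rejected(self):
        m = _fm(np.random.default_rng(0).normal(size=(10, 4)))
        with pytest.raises(ValueError, match="single class"):
            mrmr_select(m, np.array(["a"] * 10), k=2)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_greedy_trace_matches_brute_force_mid(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 60, 7
        y = rng.choice(["a", "b", "c"], n)
        X = rng.normal(size=(n, p))
        X[:, 0] += (y == "a") * 2.0  # some signal
        m = _fm(X)
        out = mrmr_select(m, y, k=5)
        ref = brute_force_mrmr(X, pd.factorize(y)[0], 5)
        assert list(out.matrix.columns) == [f"f{j}" for j in ref]


class TestLasso:
    def test_huge_penalty_gives_empty_signature(self):
        rng = np.random.default_rng(7)
        y = np.array(["a", "b", "c"] * 10)
        m = _fm(rng.normal(size=(30, 5)))
        sig = lasso_select(m, y, folds=3, seed=0, n_lambdas=2,
                           decades=1e-4)
        assert sig.empty
        assert sig.feature_ids == []

    def test_planted_separating_feature_recovered(self):
        rng = np.random.default_rng(8)
        n = 90
        y = np.array(["a", "b", "c"] * 30)
        sep = np.array([0.0, 4.0, 8.0] * 30) + rng.normal(0, 0.3, n)
        X = np.column_stack([rng.normal(size=(n, 6)), sep])
        m = _fm(X, names=[f"noise{i}" for i in range(6)] + ["signal"])
        sig = lasso_select(m, y, folds=5, seed=1)
        assert "signal" in sig.feature_ids

    def test_trace_records_survivor_counts_and_lambda(self):
        rng = np.random.default_rng(9)
        y = np.array(["a", "b"] * 20)
        m = _fm(rng.normal(size=(40, 30)))
        sig = select_signature(m, y, source="HC",
                               config=SelectionConfig(mrmr_k=10,
                                                      lasso_folds=5))
        t = sig.trace
        assert t["input"] == 30
        assert t["input"] >= t["after_mad"] >= t["after_mrmr"] >= t["selected"]
        assert sig.lambda_min is not None and sig.lambda_min > 0

    def test_permuted_labels_no_better_than_intercept(self):
        rng = np.random.default_rng(10)
        n = 60
        y = rng.permutation(np.array(["a", "b", "c"] * 20))
        m = _fm(rng.normal(size=(n, 40)))
        sig = lasso_select(m, y, folds=5, seed=2)
        # balanced 3-class intercept deviance is ln 3 ~ 1.0986
        assert sig.trace["cv_deviance_min"] > np.log(3) - 0.05

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(11)
        y = np.array(["a", "b", "c"] * 12)
        X = rng.normal(size=(36, 12))
        a = lasso_select(_fm(X), y, folds=4, seed=5)
        b = lasso_select(_fm(X), y, folds=4, seed=5)
        assert a.feature_ids == b.feature_ids
        assert a.lambda_min == b.lambda_min
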