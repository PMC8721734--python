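"""SVM-RFE-CBR ranking: elimination trace, CBR guard, top-k selection."""

import numpy as np
import pytest
from sklearn.svm import SVC

from snaresap import (
    FeatureMatrix,
    RFEConfig,
    rank_features_rfe_cbr,
    select_top_k,
    sweep_top_k,
)
from snaresap import SVMConfig, cross_validate


def make_matrix(X, y, ids=None):
    return FeatureMatrix(
        X=X, y=y, feature_ids=np.arange(X.shape[1]) if ids is None else ids
    )


@pytest.fixture
def toy_informative(rng):
    """f0 tracks the label's sign (plus small noise); f1-f3 pure noise."""
    y = np.array([1, -1] * 20)
    X = rng.normal(size=(40, 4))
    X[:, 0] = y + rng.normal(0, 0.1, size=40)
    return make_matrix(X, y)


class TestRanking:
    def test_single_feature_degenerate(self):
        M = make_matrix(np.array([[1.0], [-1.0]]), np.array([1, -1]))
        r = rank_features_rfe_cbr(M, RFEConfig())
        assert r.order.tolist() == [0]
        assert r.iteration_eliminated.tolist() == [1]

    def test_informative_feature_ranked_first(self, toy_informative):
        """Brute force confirms f0 maximizes single-feature training accuracy,
        so it must carry the dominant weight and rank first."""
        accs = []
        for j in range(4):
            svc = SVC(kernel="linear", C=1.0)
            svc.fit(toy_informative.X[:, [j]], toy_informative.y)
            accs.append(svc.score(toy_informative.X[:, [j]], toy_informative.y))
        assert np.argmax(accs) == 0  # oracle premise
        r = rank_features_rfe_cbr(toy_informative, RFEConfig())
        assert r.order[0] == 0

    def test_single_class_rejected(self):
        M = make_matrix(np.ones((3, 2)), np.array([1, 1, 1]))
        with pytest.raises(ValueError, match="both classes"):
            rank_features_rfe_cbr(M, RFEConfig())

    def test_trace_is_exhaustive_and_consistent(self, toy_informative):
        r = rank_features_rfe_cbr(toy_informative, RFEConfig())
        assert sorted(r.order.tolist()) == [0, 1, 2, 3]
        # best-ranked features are eliminated last
        assert np.all(np.diff(r.iteration_eliminated) <= 0)
        # replaying the trace: survivors at iteration i are exactly the
        # features eliminated at iteration >= i
        for it in range(1, 5):
            assert set(r.surviving_at(it)) == set(
                r.order[r.iteration_eliminated >= it]
            )
        assert len(r.surviving_at(1)) == 4 and len(r.surviving_at(4)) == 1

    def test_determinism_bit_for_bit(self, toy_informative):
        r1 = rank_features_rfe_cbr(toy_informative, RFEConfig(seed=3))
        r2 = rank_features_rfe_cbr(toy_informative, RFEConfig(seed=3))
        assert np.array_equal(r1.order, r2.order)
        assert np.array_equal(r1.criterion, r2.criterion)

    def test_vanilla_rfe_equivalence_small(self, rng):
        """With tau=1.0 and step=1 the trace must match sklearn's plain RFE."""
        from sklearn.feature_selection import RFE

        X = rng.normal(size=(30, 8))
        y = np.where(rng.random(30) < 0.5, 1, -1)
        y[:4] = [1, 1, -1, -1]  # both classes guaranteed
        M = make_matrix(X, y)
        mine = rank_features_rfe_cbr(M, RFEConfig(corr_threshold=1.0, step=1))
        ref = RFE(SVC(kernel="linear", C=1.0), n_features_to_select=1, step=1)
        ref.fit(X, y)
        my_rank = np.empty(8, dtype=int)
        my_rank[mine.order] = np.arange(1, 9)
        assert np.array_equal(my_rank, ref.ranking_)

    def test_cbr_guard_blocks_correlated_pair(self, rng):
        """An informative feature and its exact duplicate may never leave in
        the same iteration when tau groups them."""
        y = np.array([1, -1] * 15)
        X = rng.normal(size=(30, 5))
        X[:, 0] = y + rng.normal(0, 0.05, 30)
        X[:, 1] = X[:, 0]  # exact duplicate, |r| = 1
        M = make_matrix(X, y)
        r = rank_features_rfe_cbr(M, RFEConfig(corr_threshold=0.7, step=2))
        it = {f: i for f, i in zip(r.order, r.iteration_eliminated)}
        assert it[0] != it[1]

    def test_step_batches_uncorrelated_features(self, rng):
        X = rng.normal(size=(30, 6))
        y = np.array([1, -1] * 15)
        M = make_matrix(X, y)
        r = rank_features_rfe_cbr(M, RFEConfig(corr_threshold=0.999, step=3))
        # uncorrelated noise: first iteration removes a full batch of 3
        assert np.sum(r.iteration_eliminated == 1) == 3

    def test_config_validation(self):
        with pytest.raises(ValueError):
            RFEConfig(corr_threshold=0.0)
        with pytest.raises(ValueError):
            RFEConfig(step=0)


class TestTopK:
    def test_k_equals_d_is_column_permutation(self, toy_informative):
        r = rank_features_rfe_cbr(toy_informative, RFEConfig())
        sub = select_top_k(toy_informative, r, 4)
        assert sorted(sub.feature_ids.tolist()) == [0, 1, 2, 3]
        order = [list(toy_informative.feature_ids).index(i) for i in sub.feature_ids]
        assert np.array_equal(sub.X, toy_informative.X[:, order])

    def test_k_one_takes_best(self, toy_informative):
        r = rank_features_rfe_cbr(toy_informative, RFEConfig())
        sub = select_top_k(toy_informative, r, 1)
        assert sub.feature_ids.tolist() == [r.order[0]]

    @pytest.mark.parametrize("k", [0, 5])
    def test_k_out_of_range(self, toy_informative, k):
        r = rank_features_rfe_cbr(toy_informative, RFEConfig())
        with pytest.raises(ValueError):
            select_top_k(toy_informative, r, k)


class TestSweep:
    def test_separable_data_perfect_at_any_k(self, separable_matrix):
        r = rank_features_rfe_cbr(separable_matrix, RFEConfig())
        cfg = SVMConfig(kernel="rbf", C=11.0, gamma=0.1)
        table = sweep_top_k(separable_matrix, r, ks=[1, 3, 5], cv_folds=5, svm_cfg=cfg, seed=0)
        assert np.allclose(table["mean_cv_accuracy"], 1.0)

    def test_full_k_matches_plain_cv(self, separable_matrix):
        r = rank_features_rfe_cbr(separable_matrix, RFEConfig())
        cfg = SVMConfig(kernel="rbf", C=11.0, gamma=0.1)
        table = sweep_top_k(separable_matrix, r, ks=[5], cv_folds=5, svm_cfg=cfg, seed=7)
        full = select_top_k(separable_matrix, r, 5)
        ref = cross_validate(full, cfg, folds=5, seed=7)
        assert table["mean_cv_accuracy"].iloc[0] == pytest.approx(ref.acc)

    def test_empty_ks_rejected(self, separable_matrix):
        r = rank_features_rfe_cbr(separable_matrix, RFEConfig())
        with pytest.raises(ValueError):
            sweep_top_k(separable_matrix, r, ks=[])
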