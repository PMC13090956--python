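"""Importance sources, robust rank aggregation, final ordering."""

import numpy as np
import pytest
from scipy.stats import beta, kstest
from sklearn.linear_model import LogisticRegression
from sklearn.ensemble import RandomForestClassifier

from histogate.importance import (
    aggregate_ranking,
    local_surrogate_attribution,
    native_importance,
    rank_matrix_from_scores,
    rra_score,
    shapley_attribution,
)
from histogate.io import ValidationError


def _linear_data(n=300, d=5, w=(2.0, 1.0, 0.0, 0.0, 0.0), seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n, d))
    logits = X @ np.asarray(w)
    y = (logits + rng.logistic(0, 0.3, n) > 0).astype(int)
    return X, y, np.asarray(w)


class TestNative:
    def test_coefficients_normalized(self):
        X, y, w = _linear_data()
        m = LogisticRegression().fit(X, y)
        m.coef_ = np.array([[2.0, 0.0, 0.0, 0.0, 0.0]])
        scores = native_importance(m)
        np.testing.assert_allclose(scores, [1, 0, 0, 0, 0])

    def test_tree_single_signal_ranked_first(self):
        X, y, _ = _linear_data(w=(3.0, 0, 0, 0, 0))
        m = RandomForestClassifier(n_estimators=60, random_state=0).fit(X, y)
        scores = native_importance(m)
        assert np.argmax(scores) == 0
        assert scores.sum() == pytest.approx(1.0)

    def test_permutation_fallback_null_feature_near_zero(self):
        from sklearn.neighbors import KNeighborsClassifier

        X, y, _ = _linear_data(w=(3.0, 0, 0, 0, 0), seed=4)
        m = KNeighborsClassifier().fit(X, y)
        scores = native_importance(m, X, y, seed=0)
        assert np.argmax(scores) == 0
        assert scores[2] < 0.2
        with pytest.raises(ValidationError):
            native_importance(m)  # permutation route needs X, y


class TestShapley:
    def test_additive_model_concentrates_on_signal(self):
        X, y, _ = _linear_data(w=(3.0, 0, 0, 0, 0), seed=1)
        m = LogisticRegression().fit(X, y)
        phi = shapley_attribution(m, X[:50], background=X, n_samples=32, seed=0)
        assert phi[0] / phi.sum() > 0.9

    def test_duplicated_signal_shared_symmetrically(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (400, 4))
        X[:, 1] = X[:, 0]  # exact duplicate
        y = (X[:, 0] + rng.normal(0, 0.5, 400) > 0).astype(int)
        m = LogisticRegression().fit(X, y)
        phi = shapley_attribution(m, X[:60], background=X, n_samples=48, seed=0)
        assert 0.7 <= phi[0] / phi[1] <= 1.3

    def test_constant_model_zero_attribution(self):
        X, y, _ = _linear_data(seed=3)
        m = LogisticRegression().fit(X, y)
        m.coef_[:] = 0.0
        m.intercept_[:] = 0.3
        phi = shapley_attribution(m, X[:20], background=X, n_samples=16, seed=0)
        assert np.all(phi < 1e-12)

    def test_efficiency_on_additive_score(self):
        """Per-instance attributions telescope to f(x) - E_bg[f]."""
        X, y, _ = _linear_data(seed=5)
        m = LogisticRegression().fit(X, y)
        sub, bg = X[:25], X[:200]
        phi = shapley_attribution(
            m, sub, background=bg, n_samples=64, seed=0, return_per_instance=True
        )
        fx = m.predict_proba(sub)[:, 1]
        # sampling error shrinks with orderings; allow 3 MC sigma via a loose band
        gap = phi.sum(axis=1) - (fx - m.predict_proba(bg)[:, 1].mean())
        assert np.abs(gap).mean() < 0.05

    def test_too_few_samples_rejected(self):
        X, y, _ = _linear_data()
        m = LogisticRegression().fit(X, y)
        with pytest.raises(ValidationError):
            shapley_attribution(m, X[:5], n_samples=5)


class TestLocalSurrogate:
    def test_linear_model_recovers_coefficient_direction(self):
        X, y, _ = _linear_data(n=400, w=(2.0, -1.0, 0.5, 0.0, 0.0), seed=6)
        m = LogisticRegression(C=10.0).fit(X, y)
        w_true = np.abs(m.coef_[0])
        w_est = local_surrogate_attribution(m, X[:40], n_perturb=300, seed=0)
        cos = w_est @ w_true / (np.linalg.norm(w_est) * np.linalg.norm(w_true))
        assert cos > 0.95

    def test_irrelevant_feature_small(self):
        X, y, _ = _linear_data(n=400, w=(3.0, 0, 0, 0, 0), seed=7)
        m = LogisticRegression().fit(X, y)
        w_est = local_surrogate_attribution(m, X[:40], n_perturb=300, seed=0)
        assert w_est[3] < 0.1 * w_est[0]

    def test_deterministic_and_kernel_validation(self):
        X, y, _ = _linear_data(seed=8)
        m = LogisticRegression().fit(X, y)
        a = local_surrogate_attribution(m, X[:10], n_perturb=50, seed=3)
        b = local_surrogate_attribution(m, X[:10], n_perturb=50, seed=3)
        np.testing.assert_array_equal(a, b)
        with pytest.raises(ValidationError):
            local_surrogate_attribution(m, X[:10], kernel_width=0.0)


class TestRRA:
    def test_closed_form_three_top_ranks(self):
        """Ranks 1st of 10 in all 3 columns: rho = 0.001, Bonferroni 0.003."""
        cols = {
            (f"m{j}", 0, "native"): np.array([10.0 - i for i in range(10)]) for j in range(3)
        }
        rm = rank_matrix_from_scores(cols, [f"f{i}" for i in range(10)])
        scores = rra_score(rm)
        # rho itself has the closed form min{1-0.9^3, 3(0.1)^2-2(0.1)^3, 0.1^3}
        r = np.full(3, 0.1)
        rho = float(np.min(beta.cdf(r, [1, 2, 3], [3, 2, 1])))
        assert rho == pytest.approx(0.001, rel=1e-9)
        # the exact-null correction agrees with the Bonferroni value 0.003
        # to the printed precision
        assert scores["f0"] == pytest.approx(0.003, abs=2e-4)

    def test_single_column_reduces_to_rank(self):
        cols = {("m", 0, "native"): np.array([3.0, 2.0, 1.0, 0.5])}
        rm = rank_matrix_from_scores(cols, list("abcd"))
        scores = rra_score(rm)
        assert scores["a"] == pytest.approx(0.25)
        assert scores["d"] == pytest.approx(1.0)

    def test_matches_monte_carlo_order_statistics(self):
        """Beta order-statistic probabilities agree with simulation."""
        rng = np.random.default_rng(0)
        m, n = 4, 12
        r = np.sort(rng.uniform(0, 1, m))
        sims = np.sort(rng.uniform(0, 1, (20000, m)), axis=1)
        for k in range(m):
            mc = (sims[:, k] <= r[k]).mean()
            se = np.sqrt(mc * (1 - mc) / 20000)
            assert beta.cdf(r[k], k + 1, m - k) == pytest.approx(mc, abs=3 * se + 1e-4)

    def test_null_scores_approximately_uniform(self):
        """Independent random rankings -> RRA scores ~ U(0,1), KS < 0.1."""
        rng = np.random.default_rng(42)
        n = 200
        cols = {
            ("m", j, "native"): rng.permutation(n).astype(float) for j in range(5)
        }
        rm = rank_matrix_from_scores(cols, [f"f{i}" for i in range(n)])
        vals = np.array(list(rra_score(rm).values()))
        assert kstest(vals, "uniform").statistic < 0.1

    def test_invalid_column_rejected(self):
        from histogate.importance import RankMatrix

        with pytest.raises(ValidationError):
            RankMatrix(
                features=["a", "b"],
                columns=[("m", 0, "x")],
                ranks=np.array([[0.5], [0.5]]),  # not a permutation
            )


class TestAggregateRanking:
    def _inputs(self, feats, scores_by_col, native, shapley, surrogate):
        rm = rank_matrix_from_scores(scores_by_col, feats)
        return (
            dict(zip(feats, native)),
            dict(zip(feats, shapley)),
            dict(zip(feats, surrogate)),
            rm,
        )

    def test_unanimous_winner_first(self):
        feats = list("abcd")
        col = np.array([4.0, 3.0, 2.0, 1.0])
        args = self._inputs(
            feats,
            {("m", 0, "native"): col, ("m", 0, "shapley"): col},
            col, col, col,
        )
        ranking = aggregate_ranking(*args)
        assert ranking.features[0] == "a"
        assert ranking.rra_p["a"] < ranking.rra_p["d"]

    def test_composite_breaks_rra_ties(self):
        feats = list("ab")
        col1 = np.array([2.0, 1.0])
        col2 = np.array([1.0, 2.0])  # symmetric ranks -> equal rra
        args = self._inputs(
            feats,
            {("m", 0, "native"): col1, ("m", 1, "native"): col2},
            [0.9, 0.1], [0.9, 0.1], [0.9, 0.1],
        )
        ranking = aggregate_ranking(*args)
        assert ranking.rra_p["a"] == ranking.rra_p["b"]
        assert ranking.features[0] == "a"

    def test_feature_permutation_invariance(self):
        rng = np.random.default_rng(1)
        feats = [f"f{i}" for i in range(8)]
        cols = {("m", j, "native"): rng.uniform(0, 1, 8) for j in range(3)}
        nat, sha, sur = rng.uniform(0, 1, (3, 8))
        order1 = aggregate_ranking(
            dict(zip(feats, nat)), dict(zip(feats, sha)), dict(zip(feats, sur)),
            rank_matrix_from_scores(cols, feats),
        ).features
        perm = rng.permutation(8)
        feats_p = [feats[i] for i in perm]
        cols_p = {k: v[perm] for k, v in cols.items()}
        order2 = aggregate_ranking(
            dict(zip(feats_p, nat[perm])), dict(zip(feats_p, sha[perm])),
            dict(zip(feats_p, sur[perm])),
            rank_matrix_from_scores(cols_p, feats_p),
        ).features
        assert order1 == order2

    def test_feature_set_mismatch_rejected(self):
        feats = list("ab")
        rm = rank_matrix_from_scores({("m", 0, "native"): np.array([1.0, 2.0])}, feats)
        with pytest.raises(ValidationError):
            aggregate_ranking({"a": 1.0}, {"a": 1, "b": 2}, {"a": 1, "b": 2}, rm)
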