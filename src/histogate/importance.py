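"""Model-agnostic feature-importance ranking.

Three importance sources per (model, fold): the model's native metric
(coefficients, impurity importances, or seeded permutation importance),
Monte-Carlo Shapley-value sampling, and local linear-surrogate attributions.
Per-source rankings are pooled into a rank matrix and scored with robust
rank aggregation (RRA): for each feature the Beta order-statistic p-values
of its sorted normalized ranks are minimized, and the minimum is calibrated
against its exact null distribution (Bonferroni-like in the tail), so a low
score means the feature sits improbably near the top across sources.
The final ordering is by RRA score (ascending) with a composite of the three
min-max-normalized mean importances as tie-breaker.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import comb
from scipy.stats import beta, rankdata
from sklearn.inspection import permutation_importance
from sklearn.pipeline import Pipeline

from .classify import decision_scores
from .io import ValidationError

__all__ = [
    "RankMatrix",
    "AggregatedRanking",
    "native_importance",
    "shapley_attribution",
    "local_surrogate_attribution",
    "rank_matrix_from_scores",
    "rra_score",
    "aggregate_ranking",
]


@dataclass
class RankMatrix:
    """Normalized ranks r = rank/n per feature (rows) and ranking source (cols)."""

    features: list[str]
    columns: list[tuple]
    ranks: np.ndarray  # (n_features, n_columns), entries in (0, 1]

    def __post_init__(self):
        n, m = self.ranks.shape
        if n != len(self.features) or m != len(self.columns):
            raise ValidationError("rank matrix shape mismatch")
        if (self.ranks <= 0).any() or (self.ranks > 1).any():
            raise ValidationError("normalized ranks must lie in (0, 1]")
        # each column must be a (possibly tie-averaged) permutation's ranks
        for j in range(m):
            col = np.sort(self.ranks[:, j]) * n
            if not np.allclose(col.sum(), n * (n + 1) / 2):
                raise ValidationError(f"column {self.columns[j]} is not a valid ranking")


@dataclass
class AggregatedRanking:
    features: list[str]  # ordered, best first
    rra_p: dict[str, float]
    composite: dict[str, float]
    method_means: pd.DataFrame  # per-feature mean normalized importances

    def top(self, k: int) -> list[str]:
        return self.features[:k]


def _final_estimator(model):
    return model[-1] if isinstance(model, Pipeline) else model


def native_importance(model, X=None, y=None, seed: int = 0) -> np.ndarray:
    """Non-negative per-feature scores normalized to sum 1.

    |coefficients| for linear models, impurity importances for trees;
    otherwise seeded permutation importance (20 repeats), which needs X, y.
    """
    est = _final_estimator(model)
    if hasattr(est, "coef_"):
        scores = np.abs(np.asarray(est.coef_)).sum(axis=0)
    elif hasattr(est, "feature_importances_"):
        scores = np.asarray(est.feature_importances_, dtype=float)
    else:
        if X is None or y is None:
            raise ValidationError(
                f"{type(est).__name__} has no native importance; X and y are "
                "required for permutation importance"
            )
        res = permutation_importance(model, X, y, n_repeats=20, random_state=seed)
        scores = np.clip(res.importances_mean, 0.0, None)
    total = scores.sum()
    return scores / total if total > 0 else scores


def shapley_attribution(
    model,
    X: np.ndarray,
    background: np.ndarray | None = None,
    n_samples: int = 64,
    seed: int = 0,
    return_per_instance: bool = False,
) -> np.ndarray:
    """Monte-Carlo Shapley attributions, mean |value| per feature.

    For each sampled feature ordering, features of the explained instance are
    revealed one by one on top of a background row drawn from the training
    marginals; the attribution of feature j is the score change when j is
    revealed.  Averaging over orderings estimates the Shapley value of the
    score game per instance.
    """
    if n_samples < 10:
        raise ValidationError("n_samples must be >= 10 for stable Shapley estimates")
    X = np.asarray(X, dtype=float)
    bg = X if background is None else np.asarray(background, dtype=float)
    rng = np.random.default_rng(seed)
    n, d = X.shape
    phi = np.zeros((n, d))
    for _ in range(n_samples):
        order = rng.permutation(d)
        z = bg[rng.integers(0, len(bg), size=n)].copy()
        # stack the d+1 coalition stages into one batch prediction
        stages = np.empty((d + 1, n, d))
        stages[0] = z
        for step, j in enumerate(order):
            z[:, j] = X[:, j]
            stages[step + 1] = z
        scores = decision_scores(model, stages.reshape(-1, d)).reshape(d + 1, n)
        phi[:, order] += (scores[1:] - scores[:-1]).T
    phi /= n_samples
    if return_per_instance:
        return phi
    return np.abs(phi).mean(axis=0)


def local_surrogate_attribution(
    model,
    X: np.ndarray,
    n_perturb: int = 200,
    kernel_width: float | None = None,
    seed: int = 0,
    ridge: float = 1.0,
) -> np.ndarray:
    """Local linear-surrogate attributions, mean |weight| per feature.

    Per instance: Gaussian perturbations scaled by per-feature spread,
    exponential-kernel locality weights, and a ridge linear fit to the model
    scores; the ridge term guarantees a well-posed fit.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if kernel_width is None:
        kernel_width = 0.75 * np.sqrt(d)
    if kernel_width <= 0:
        raise ValidationError("kernel_width must be positive")
    rng = np.random.default_rng(seed)
    sigma = np.std(X, axis=0, ddof=0)
    sigma[sigma == 0] = 1.0
    noise = rng.normal(0.0, 1.0, size=(n, n_perturb, d))
    Z = X[:, None, :] + noise * sigma[None, None, :]
    scores = decision_scores(model, Z.reshape(-1, d)).reshape(n, n_perturb)
    dist2 = np.sum(noise**2, axis=2)
    w = np.exp(-dist2 / kernel_width**2)
    coefs = np.empty((n, d))
    for i in range(n):
        Zi = noise[i] * sigma[None, :]  # centered on the instance, raw units
        Wi = w[i]
        A = (Zi * Wi[:, None]).T @ Zi + ridge * np.eye(d)
        b = (Zi * Wi[:, None]).T @ (scores[i] - np.average(scores[i], weights=Wi))
        coefs[i] = np.linalg.solve(A, b)
    return np.abs(coefs).mean(axis=0)


def rank_matrix_from_scores(
    score_columns: Mapping[tuple, np.ndarray], features: Sequence[str]
) -> RankMatrix:
    """Normalized descending ranks (average ranks on ties) per scoring source."""
    features = list(features)
    n = len(features)
    cols, mat = [], []
    for key, scores in score_columns.items():
        scores = np.asarray(scores, dtype=float)
        if scores.shape != (n,):
            raise ValidationError(f"scores for {key} have wrong length")
        ranks = rankdata(-scores, method="average") / n
        cols.append(key)
        mat.append(ranks)
    return RankMatrix(features=features, columns=cols, ranks=np.array(mat).T)


def _rho_null_cdf(rho: float, m: int) -> float:
    """Exact null probability P(min_k Beta-cdf_k(U_(k)) <= rho).

    Equivalent to the crossing probability of the uniform order statistics
    over the boundaries b_k = BetaInv(rho; k, m-k+1), computed by the
    sequential-binomial recursion over interval counts.  For small rho this
    approaches the Bonferroni bound m * rho.
    """
    if rho >= 1.0:
        return 1.0
    ks = np.arange(1, m + 1)
    b = beta.ppf(rho, ks, m - ks + 1)  # increasing boundaries
    # dp[c] = P(#{U <= b_k} = c and the count stayed <= j-1 at every j <= k)
    dp = np.zeros(m + 1)
    dp[0] = 1.0
    prev_b = 0.0
    for k in range(1, m + 1):
        step = np.zeros_like(dp)
        denom = 1.0 - prev_b
        q = 0.0 if denom <= 0 else min(max((b[k - 1] - prev_b) / denom, 0.0), 1.0)
        for c in range(0, k):  # cum count so far <= k-1 enforced below
            if dp[c] == 0.0:
                continue
            n_rem = m - c
            j = np.arange(0, min(k - 1, m) - c + 1)
            pmf = comb(n_rem, j) * q**j * (1.0 - q) ** (n_rem - j)
            step[c + j] += dp[c] * pmf
        step[k:] = 0.0  # count must stay below k at boundary b_k
        dp = step
        prev_b = b[k - 1]
    return float(min(1.0, max(0.0, 1.0 - dp.sum())))


def rra_score(rank_matrix: RankMatrix) -> dict[str, float]:
    """Robust-rank-aggregation score per feature.

    rho = min_k P(Beta(k, m-k+1) <= r_(k)) over the sorted normalized ranks
    r_(1) <= ... <= r_(m), corrected for the minimum over k with the exact
    order-statistic null distribution, so the score is a p-value (uniform
    under random rankings).  In the informative tail it coincides with the
    Bonferroni bound min(1, m * rho).
    """
    m = rank_matrix.ranks.shape[1]
    if m < 1:
        raise ValidationError("rank matrix needs at least one column")
    ks = np.arange(1, m + 1)
    out = {}
    for i, feat in enumerate(rank_matrix.features):
        r = np.sort(rank_matrix.ranks[i])
        rho = float(np.min(beta.cdf(r, ks, m - ks + 1)))
        out[feat] = _rho_null_cdf(rho, m)
    return out


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    return (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)


def aggregate_ranking(
    native: Mapping[str, float],
    shapley: Mapping[str, float],
    surrogate: Mapping[str, float],
    rank_matrix: RankMatrix,
) -> AggregatedRanking:
    """Final ordering: RRA score ascending, composite importance descending.

    The composite is the mean of the three min-max-normalized importance
    means (native, Shapley, surrogate).
    """
    feats = list(rank_matrix.features)
    for src, name in ((native, "native"), (shapley, "shapley"), (surrogate, "surrogate")):
        if set(src) != set(feats):
            raise ValidationError(f"{name} importances cover a different feature set")
    nat = np.array([native[f] for f in feats])
    sha = np.array([shapley[f] for f in feats])
    sur = np.array([surrogate[f] for f in feats])
    composite = (_minmax(nat) + _minmax(sha) + _minmax(sur)) / 3.0
    rra = rra_score(rank_matrix)
    order = sorted(feats, key=lambda f: (rra[f], -composite[feats.index(f)], f))
    method_means = pd.DataFrame(
        {"native": nat, "shapley": sha, "surrogate": sur}, index=feats
    )
    return AggregatedRanking(
        features=order,
        rra_p=rra,
        composite={f: float(composite[feats.index(f)]) for f in feats},
        method_means=method_means,
    )
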