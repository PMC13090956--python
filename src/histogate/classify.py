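"""Cross-validated classifier bank over feature tables.

Slides are classified short vs long progression-free interval with
patient-grouped, label-stratified 3-fold cross-validation (fixed random
state 42 by default).  Scale-sensitive models are wrapped with per-fold
median imputation + z-scoring fit on the training folds only; tree ensembles
receive raw (imputed) features.  Models clearing AUC > 0.8 and per-class
F1 > 0.8 are retained for the interpretability stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .io import FeatureTable, PFIClass, SlideRecord, ValidationError

__all__ = [
    "CVResult",
    "PerformanceCurve",
    "MODEL_BANK",
    "DEFAULT_MODEL_SET",
    "build_model",
    "run_cv",
    "retain_models",
    "progressive_curve",
    "elbow_select",
]

POSITIVE_CLASS = "short"  # short PFI (platinum resistant) is the positive class

# Models needing feature scaling; trees get raw features.
_SCALED = {
    "nearest_neighbors",
    "linear_svm",
    "rbf_svm",
    "gaussian_process",
    "mlp",
    "naive_bayes",
    "logistic_regression",
}


def _factories(seed: int) -> dict:
    return {
        "nearest_neighbors": lambda: KNeighborsClassifier(),
        "linear_svm": lambda: SVC(kernel="linear", random_state=seed),
        "rbf_svm": lambda: SVC(kernel="rbf", random_state=seed),
        "gaussian_process": lambda: GaussianProcessClassifier(random_state=seed),
        "decision_tree": lambda: DecisionTreeClassifier(random_state=seed),
        # small-n tabular defaults: many shallowish trees over few features
        # per split generalize better than the library default here
        "random_forest": lambda: RandomForestClassifier(
            n_estimators=300, max_features=0.2, min_samples_leaf=2, random_state=seed
        ),
        "mlp": lambda: MLPClassifier(random_state=seed, max_iter=800),
        "adaboost": lambda: AdaBoostClassifier(random_state=seed),
        "naive_bayes": lambda: GaussianNB(),
        "logistic_regression": lambda: LogisticRegression(C=0.25, max_iter=2000),
        "bagging": lambda: BaggingClassifier(random_state=seed),
        "hist_gradient_boosting": lambda: HistGradientBoostingClassifier(random_state=seed),
    }


def _xgb(seed: int):
    from xgboost import XGBClassifier

    # shallow, shrunken boosting suits p ~ n tabular problems
    return XGBClassifier(
        random_state=seed,
        n_estimators=400,
        max_depth=2,
        learning_rate=0.05,
        subsample=0.8,
        colsample_bytree=0.3,
        min_child_weight=3,
        verbosity=0,
        eval_metric="logloss",
    )


def _lgbm(seed: int):
    from lightgbm import LGBMClassifier

    return LGBMClassifier(random_state=seed, verbose=-1)


MODEL_BANK: tuple[str, ...] = (
    "nearest_neighbors",
    "linear_svm",
    "rbf_svm",
    "gaussian_process",
    "decision_tree",
    "random_forest",
    "mlp",
    "adaboost",
    "naive_bayes",
    "xgboost",
    "lightgbm",
    "logistic_regression",
    "bagging",
    "hist_gradient_boosting",
)

# compact default for the end-to-end interpretability pipeline: one linear,
# one bagged-tree and one boosted-tree learner
DEFAULT_MODEL_SET: tuple[str, ...] = ("logistic_regression", "random_forest", "xgboost")


def build_model(name: str, seed: int = 42) -> Pipeline:
    """Model pipeline (imputation [+ scaling] + estimator) for a bank entry."""
    if name == "xgboost":
        est = _xgb(seed)
    elif name == "lightgbm":
        est = _lgbm(seed)
    else:
        try:
            est = _factories(seed)[name]()
        except KeyError:
            raise ValidationError(f"unknown model {name!r}; bank: {MODEL_BANK}") from None
    steps = [("impute", SimpleImputer(strategy="median"))]
    if name in _SCALED:
        steps.append(("scale", StandardScaler()))
    steps.append(("model", est))
    return Pipeline(steps)


def decision_scores(model, X) -> np.ndarray:
    """Continuous score for the positive class (probability when available)."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


@dataclass
class CVResult:
    model_name: str
    fold_metrics: list[dict]
    seed: int
    fold_assignments: dict[str, int]
    fitted: list = field(default_factory=list, repr=False)
    folds: list = field(default_factory=list, repr=False)

    def _mean(self, key: str) -> float:
        return float(np.mean([m[key] for m in self.fold_metrics]))

    @property
    def mean_auc(self) -> float:
        return self._mean("auc")

    @property
    def mean_accuracy(self) -> float:
        return self._mean("accuracy")

    @property
    def mean_f1_short(self) -> float:
        return self._mean("f1_short")

    @property
    def mean_f1_long(self) -> float:
        return self._mean("f1_long")

    def summary(self) -> dict:
        return {
            "model": self.model_name,
            "auc": self.mean_auc,
            "auc_sd": float(np.std([m["auc"] for m in self.fold_metrics], ddof=0)),
            "accuracy": self.mean_accuracy,
            "f1_short": self.mean_f1_short,
            "f1_long": self.mean_f1_long,
        }


@dataclass
class PerformanceCurve:
    ks: list[int]
    auc: list[float]
    f1: list[float]
    ranking: list[str]
    elbow_k: int | None = None


def _label_arrays(table: FeatureTable, records: Sequence[SlideRecord]):
    by_slide = {r.slide_id: r for r in records}
    slide_ids = list(table.values.index)
    missing = [s for s in slide_ids if s not in by_slide]
    if missing:
        raise ValidationError(f"slides without clinical records: {missing[:5]}")
    classes = [by_slide[s].pfi_class for s in slide_ids]
    bad = [s for s, c in zip(slide_ids, classes) if c is PFIClass.EXCLUDED]
    if bad:
        raise ValidationError(
            f"slides with excluded PFI class in feature table: {bad[:5]}; filter first"
        )
    y = np.array([1 if c is PFIClass.SHORT else 0 for c in classes])
    groups = np.array([by_slide[s].patient_id for s in slide_ids])
    return table.values.to_numpy(float), y, groups, slide_ids


def make_folds(y: np.ndarray, groups: np.ndarray, n_folds: int, seed: int):
    """Patient-grouped, label-stratified folds; errors if a training fold
    loses a class."""
    cv = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(cv.split(np.zeros_like(y), y, groups))
    for i, (tr, te) in enumerate(folds):
        if len(np.unique(y[tr])) < 2:
            raise ValidationError(f"fold {i}: a class is absent from the training split")
    return folds


def run_cv(
    table: FeatureTable,
    records: Sequence[SlideRecord],
    model_set: Sequence[str] = DEFAULT_MODEL_SET,
    n_folds: int = 3,
    seed: int = 42,
    folds=None,
) -> list[CVResult]:
    """Cross-validate each bank model on the feature table.

    Folds are patient-grouped and label-stratified; identical folds can be
    injected (``folds``) to pair runs across provenances.
    """
    X, y, groups, slide_ids = _label_arrays(table, records)
    if folds is None:
        folds = make_folds(y, groups, n_folds, seed)
    results = []
    for name in model_set:
        fold_metrics, fitted = [], []
        for tr, te in folds:
            model = build_model(name, seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X[tr], y[tr])
            scores = decision_scores(model, X[te])
            pred = model.predict(X[te])
            fold_metrics.append(
                {
                    "auc": float(roc_auc_score(y[te], scores)),
                    "accuracy": float(accuracy_score(y[te], pred)),
                    "f1_short": float(f1_score(y[te], pred, pos_label=1, zero_division=0)),
                    "f1_long": float(f1_score(y[te], pred, pos_label=0, zero_division=0)),
                }
            )
            fitted.append(model)
        assignments = {}
        for fi, (_, te) in enumerate(folds):
            for idx in te:
                assignments[slide_ids[idx]] = fi
        results.append(
            CVResult(
                model_name=name,
                fold_metrics=fold_metrics,
                seed=seed,
                fold_assignments=assignments,
                fitted=fitted,
                folds=folds,
            )
        )
    return results


def retain_models(
    results: Sequence[CVResult], auc_min: float = 0.8, f1_min: float = 0.8
) -> list[CVResult]:
    """Keep models with mean AUC > auc_min and BOTH per-class F1 > f1_min.

    Strict inequalities.  An empty retained set is a warning outcome: the
    pipeline continues with the single best model by mean AUC.
    """
    if not results:
        raise ValidationError("no CV results to filter")
    retained = [
        r
        for r in results
        if r.mean_auc > auc_min and r.mean_f1_short > f1_min and r.mean_f1_long > f1_min
    ]
    if not retained:
        best = max(results, key=lambda r: r.mean_auc)
        warnings.warn(
            f"no model cleared AUC>{auc_min} and per-class F1>{f1_min}; "
            f"continuing with best single model {best.model_name}",
            stacklevel=2,
        )
        return [best]
    return retained


def progressive_curve(
    table: FeatureTable,
    records: Sequence[SlideRecord],
    ranking: Sequence[str],
    model_name: str,
    n_folds: int = 3,
    seed: int = 42,
    n_repeats: int = 5,
) -> PerformanceCurve:
    """Mean CV AUC/F1 when the top-k ranked features are used, k = 1..K.

    The curve is averaged over ``n_repeats`` fold seeds so the elbow rule
    sees sampling noise well below its epsilon.
    """
    missing = set(table.feature_names) - set(ranking)
    if missing:
        raise ValidationError(f"ranking does not cover features {sorted(missing)[:5]}")
    X, y, groups, _ = _label_arrays(table, records)
    fold_sets = [make_folds(y, groups, n_folds, seed + 97 * r) for r in range(n_repeats)]
    aucs, f1s, ks = [], [], []
    for k in range(1, len(ranking) + 1):
        sub = FeatureTable(values=table.values[list(ranking[:k])], provenance=table.provenance)
        res = [
            run_cv(sub, records, [model_name], n_folds=n_folds, seed=seed, folds=f)[0]
            for f in fold_sets
        ]
        ks.append(k)
        aucs.append(float(np.mean([r.mean_auc for r in res])))
        f1s.append(float(np.mean([r.mean_f1_short for r in res])))
    curve = PerformanceCurve(ks=ks, auc=aucs, f1=f1s, ranking=list(ranking))
    curve.elbow_k = elbow_select(curve)
    return curve


def elbow_select(curve: PerformanceCurve, epsilon: float = 0.005) -> int:
    """Smallest k beyond which no later point beats the best-so-far by > epsilon."""
    auc = np.asarray(curve.auc)
    if len(auc) < 1:
        raise ValidationError("empty performance curve")
    best_so_far = np.maximum.accumulate(auc)
    for i in range(len(auc)):
        later = auc[i + 1 :]
        if later.size == 0 or later.max() <= best_so_far[i] + epsilon:
            return curve.ks[i]
    return curve.ks[-1]  # pragma: no cover
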