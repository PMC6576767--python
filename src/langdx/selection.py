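"""Per-condition feature selection and the three predictive models.

Model 1 ("language") is an extremely-randomized-trees classifier over the
patient language encoding — 200 topic scores plus the top-k grams selected on
the training fold.  Model 2 ("demographics") is an L2-penalized logistic
regression over age, sex, and race.  Model 3 is their ensemble, the two
probability vectors averaged with weights equal to each model's training-set
AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy import stats
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.linear_model import LogisticRegression

from .errors import DegenerateLabelsError, InvalidParameterError, InvalidWeightsError

__all__ = [
    "FeatureSelection",
    "FittedModel",
    "fwer_select",
    "fit_language_trees",
    "fit_demographics_ridge",
    "ensemble_predict",
]


@dataclass
class FeatureSelection:
    """Training-fold gram selection for one condition."""

    indices: np.ndarray  # selected column indices, ranked best first
    adjusted_p: np.ndarray  # Bonferroni-adjusted p for the selected columns
    raw_p: np.ndarray
    condition: str | None = None
    fold: int | None = None


@dataclass
class FittedModel:
    """A fitted probability model with its in-sample training AUC."""

    kind: str  # "language-trees" | "demographics-ridge"
    train_auc: float
    _predict: callable = field(repr=False)
    fold: int | None = None

    def predict_proba(self, X) -> np.ndarray:
        p = np.asarray(self._predict(X), dtype=float)
        return np.clip(p, 0.0, 1.0)


def _column_association_pvalues(X, y: np.ndarray) -> np.ndarray:
    """Two-sided point-biserial (Pearson) correlation p per column, vectorized.

    Constant columns (or degenerate correlations) get p = 1.
    """
    n = len(y)
    yc = y - y.mean()
    sy = yc.std()
    if sp.issparse(X):
        mean = np.asarray(X.mean(axis=0)).ravel()
        ex2 = np.asarray(X.power(2).mean(axis=0)).ravel()
        cross = np.asarray(X.T @ yc).ravel() / n
    else:
        X = np.asarray(X, dtype=float)
        mean = X.mean(axis=0)
        ex2 = (X**2).mean(axis=0)
        cross = (X.T @ yc) / n
    var = np.maximum(ex2 - mean**2, 0.0)
    sx = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cross / (sx * sy)
    r = np.where(np.isfinite(r), np.clip(r, -1.0, 1.0), 0.0)
    df = n - 2
    if df <= 0:
        return np.ones(X.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p[sx == 0] = 1.0
    return np.clip(p, 0.0, 1.0)


def fwer_select(
    gram_matrix_train,
    labels_train: np.ndarray,
    k: int = 500,
    gram_names: list[str] | None = None,
) -> FeatureSelection:
    """Rank grams by family-wise-error-adjusted association with the label.

    Each gram's two-sided point-biserial correlation p-value against the
    binary label is Bonferroni-adjusted (multiplied by the number of grams,
    capped at 1); the top ``min(k, n_grams)`` by adjusted p (ties: raw p, then
    lexicographic gram) are returned.  Must only ever see training rows.
    """
    y = np.asarray(labels_train)
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("labels_train contains a single class")
    m = gram_matrix_train.shape[1]
    raw = _column_association_pvalues(gram_matrix_train, y.astype(float))
    adj = np.minimum(raw * m, 1.0)
    names = gram_names if gram_names is not None else [f"{j:09d}" for j in range(m)]
    order = sorted(range(m), key=lambda j: (adj[j], raw[j], names[j]))
    keep = np.array(order[: min(k, m)], dtype=int)
    return FeatureSelection(indices=keep, adjusted_p=adj[keep], raw_p=raw[keep])


def _train_auc(scores: np.ndarray, y: np.ndarray) -> float:
    from .evaluation import auc

    return auc(scores, y)


def fit_language_trees(
    X, y: np.ndarray, n_estimators: int = 1000, seed: int = 0
) -> FittedModel:
    """Extremely randomized trees on the language encoding.

    Gini split criterion, sqrt(d) candidate features with one random
    threshold each, no depth limit; predicted probability is the mean of leaf
    positive frequencies over trees.
    """
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise InvalidParameterError("empty feature matrix")
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("labels contain a single class")
    clf = ExtraTreesClassifier(
        n_estimators=n_estimators,
        criterion="gini",
        max_features="sqrt",
        bootstrap=False,
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(X, y)
    pos = list(clf.classes_).index(1)
    predict = lambda Z: clf.predict_proba(np.asarray(Z, dtype=float))[:, pos]
    return FittedModel(
        kind="language-trees",
        train_auc=_train_auc(predict(X), y),
        _predict=predict,
    )


def fit_demographics_ridge(
    X_demo, y: np.ndarray, penalty: float = 1.0
) -> FittedModel:
    """Ridge (L2-penalized) logistic regression on standardized demographics.

    ``penalty`` is the L2 strength on standardized predictors (sklearn
    C = 1/penalty); predictors are standardized with training-fold moments,
    and the same moments are applied at prediction time.
    """
    X = np.asarray(X_demo, dtype=float)
    if X.ndim != 2 or X.size == 0:
        raise InvalidParameterError("empty or non-2D demographics matrix")
    if penalty <= 0:
        raise InvalidParameterError("penalty must be > 0")
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("labels contain a single class")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    clf = LogisticRegression(C=1.0 / penalty, solver="lbfgs", max_iter=1000)
    clf.fit((X - mu) / sd, y)
    pos = list(clf.classes_).index(1)
    predict = lambda Z: clf.predict_proba((np.asarray(Z, dtype=float) - mu) / sd)[:, pos]
    return FittedModel(
        kind="demographics-ridge",
        train_auc=_train_auc(predict(X), y),
        _predict=predict,
    )


def ensemble_predict(
    p_lang: np.ndarray,
    p_demo: np.ndarray,
    auc_lang_train: float,
    auc_demo_train: float,
) -> np.ndarray:
    """Training-AUC-weighted average of the two models' probabilities.

    p = (auc_lang * p_lang + auc_demo * p_demo) / (auc_lang + auc_demo).
    """
    p_lang = np.asarray(p_lang, dtype=float)
    p_demo = np.asarray(p_demo, dtype=float)
    if p_lang.shape != p_demo.shape:
        raise InvalidParameterError("probability vectors differ in length")
    for a in (auc_lang_train, auc_demo_train):
        if not 0.0 <= a <= 1.0:
            raise InvalidParameterError("training AUCs must lie in [0, 1]")
    total = auc_lang_train + auc_demo_train
    if total == 0:
        raise InvalidWeightsError("both training AUCs are zero")
    return (auc_lang_train * p_lang + auc_demo_train * p_demo) / total
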