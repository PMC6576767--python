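"""Cross-validated AUC comparison with permutation tests and FDR control.

AUC is the all-pairs concordance probability P(score_case > score_control)
with ties counted 1/2, computed from midranks.  Two Monte-Carlo permutation
tests are provided: a paired sign-flip test for the difference between two
models' AUCs on the same participants (each iteration independently swaps a
participant's pair of scores with probability 1/2), and a label-permutation
test for a single AUC against chance.  Both use add-one smoothing,
p = (#extreme + 1) / (n_iter + 1), so p is never exactly zero and
Benjamini-Hochberg behaves correctly downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .errors import (
    DegenerateLabelsError,
    InvalidParameterError,
    UndefinedAUCError,
)
from .selection import (
    ensemble_predict,
    fit_demographics_ridge,
    fit_language_trees,
    fwer_select,
)

__all__ = [
    "FoldAssignment",
    "CVScores",
    "EvalResult",
    "stratified_kfold",
    "auc",
    "cross_validated_scores",
    "cross_validated_ridge",
    "perm_test_auc_diff",
    "perm_test_auc_vs_chance",
    "bh_fdr",
]

_EPS = 1e-12


@dataclass
class FoldAssignment:
    """Participant -> fold index map for stratified k-fold CV."""

    fold_of: np.ndarray  # int fold index per participant
    k: int

    def train_test(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = self.fold_of == fold
        return ~test, test


@dataclass
class CVScores:
    """Out-of-fold probability vectors for the three models."""

    p_language: np.ndarray
    p_demographics: np.ndarray
    p_combined: np.ndarray
    train_aucs: list[tuple[float, float]] = field(default_factory=list)
    selections: list = field(default_factory=list)
    skipped_folds: list[int] = field(default_factory=list)


@dataclass
class EvalResult:
    """One condition's row of the model-comparison table."""

    condition: str
    n_cases: int
    n_total: int
    auc_language: float
    auc_demographics: float
    auc_combined: float
    p_lang_vs_demo: float
    p_combined_vs_demo: float
    p_lang_vs_chance: float
    q_lang_vs_demo: float = np.nan
    q_combined_vs_demo: float = np.nan
    q_lang_vs_chance: float = np.nan


def stratified_kfold(labels: np.ndarray, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Stratified, equal-sized, non-overlapping folds.

    Cases and controls are each shuffled (seeded) and dealt round-robin to
    folds; control dealing starts where the case remainder left off, so total
    fold sizes differ by at most one and per-fold case counts by at most one.
    If either class has fewer than ``k`` members, k is reduced with a warning.
    """
    if k < 2:
        raise InvalidParameterError("k must be >= 2")
    y = np.asarray(labels)
    cases = np.flatnonzero(y == 1)
    controls = np.flatnonzero(y == 0)
    if cases.size == 0 or controls.size == 0:
        raise DegenerateLabelsError("labels contain a single class")
    smallest = min(cases.size, controls.size)
    if smallest < k:
        warnings.warn(f"reducing k from {k} to {smallest}: not enough members per class")
        k = smallest
        if k < 2:
            raise InvalidParameterError("cannot stratify: a class has < 2 members")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(y.size, dtype=int)
    cases = rng.permutation(cases)
    controls = rng.permutation(controls)
    fold_of[cases] = np.arange(cases.size) % k
    offset = cases.size % k
    fold_of[controls] = (np.arange(controls.size) + offset) % k
    return FoldAssignment(fold_of=fold_of, k=k)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """All-pairs concordance AUC with ties counted 1/2 (midrank formula)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise UndefinedAUCError("AUC undefined: labels contain a single class")
    ranks = rankdata(scores)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _auc_rows(rank_matrix: np.ndarray, pos_mask: np.ndarray, n1: int, n0: int) -> np.ndarray:
    return (rank_matrix[:, pos_mask].sum(axis=1) - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def perm_test_auc_diff(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    labels: np.ndarray,
    n_iter: int = 100_000,
    seed: int = 0,
    chunk: int = 256,
) -> float:
    """Two-sided paired sign-flip permutation test of AUC(a) - AUC(b).

    Each iteration swaps (a_i, b_i) independently per participant with
    probability 1/2 and recomputes the AUC difference; the p-value counts
    permuted |differences| at least as large as the observed one, with
    add-one smoothing.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels)
    if a.shape != b.shape or a.shape != y.shape:
        raise InvalidParameterError("scores_a, scores_b, labels must be aligned")
    if n_iter < 1:
        raise InvalidParameterError("n_iter must be >= 1")
    obs = abs(auc(a, y) - auc(b, y))
    pos = y == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    rng = np.random.default_rng(seed)
    extreme = 0
    done = 0
    while done < n_iter:
        m = min(chunk, n_iter - done)
        flips = rng.random((m, a.size)) < 0.5
        A = np.where(flips, b, a)
        B = np.where(flips, a, b)
        auc_a = _auc_rows(rankdata(A, axis=1), pos, n1, n0)
        auc_b = _auc_rows(rankdata(B, axis=1), pos, n1, n0)
        extreme += int(np.sum(np.abs(auc_a - auc_b) >= obs - _EPS))
        done += m
    return (extreme + 1) / (n_iter + 1)


def perm_test_auc_vs_chance(
    scores: np.ndarray,
    labels: np.ndarray,
    n_iter: int = 100_000,
    seed: int = 0,
    chunk: int = 5000,
) -> float:
    """One-sided (greater) label-permutation test of an AUC against 0.5.

    Labels are reshuffled each iteration and the AUC recomputed; since the
    score ranks are fixed, each permuted AUC is the rank-sum of a random
    case subset.  Add-one smoothed.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise InvalidParameterError("scores and labels must be aligned")
    if n_iter < 1:
        raise InvalidParameterError("n_iter must be >= 1")
    obs = auc(s, y)
    n = s.size
    n1 = int((y == 1).sum())
    n0 = n - n1
    ranks = rankdata(s)
    rng = np.random.default_rng(seed)
    extreme = 0
    done = 0
    base = n1 * (n1 + 1) / 2.0
    while done < n_iter:
        m = min(chunk, n_iter - done)
        u = rng.random((m, n))
        idx = np.argpartition(u, n1 - 1, axis=1)[:, :n1]
        perm_auc = (ranks[idx].sum(axis=1) - base) / (n1 * n0)
        extreme += int(np.sum(perm_auc >= obs - _EPS))
        done += m
    return (extreme + 1) / (n_iter + 1)


def bh_fdr(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Returns (rejected flags, adjusted p-values).  Rejects all p <= p_(k*)
    where k* = max{k : p_(k) <= k * alpha / m}; adjusted p-values are the
    monotone (cummin from the largest rank) step-up quantities.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    rejected, adjusted, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return rejected, adjusted


def cross_validated_ridge(
    X: np.ndarray,
    labels: np.ndarray,
    folds: FoldAssignment,
    penalty: float = 1.0,
) -> np.ndarray:
    """Out-of-fold ridge-logistic probabilities (used for demographics models)."""
    y = np.asarray(labels)
    preds = np.full(y.size, np.nan)
    for f in range(folds.k):
        train, test = folds.train_test(f)
        if len(np.unique(y[train])) < 2:
            continue
        model = fit_demographics_ridge(X[train], y[train], penalty=penalty)
        preds[test] = model.predict_proba(X[test])
    return preds


def cross_validated_scores(
    topic_scores: np.ndarray,
    gram_matrix,
    demographics: np.ndarray,
    labels: np.ndarray,
    folds: FoldAssignment,
    *,
    gram_names: list[str] | None = None,
    k_grams: int = 500,
    n_estimators: int = 1000,
    ridge_penalty: float = 1.0,
    seed: int = 0,
) -> CVScores:
    """Out-of-fold predictions for the three models.

    Per fold: select the top ``k_grams`` grams on the training rows only,
    fit the language trees on [topic scores | selected gram frequencies] and
    the ridge on demographics, ensemble the two with training-AUC weights,
    and store held-out predictions.  Folds whose training labels are
    single-class are skipped (recorded; their test predictions stay NaN).
    """
    y = np.asarray(labels)
    n = y.size
    out = CVScores(
        p_language=np.full(n, np.nan),
        p_demographics=np.full(n, np.nan),
        p_combined=np.full(n, np.nan),
    )
    dense_grams = gram_matrix.toarray() if sp.issparse(gram_matrix) else np.asarray(gram_matrix)
    for f in range(folds.k):
        train, test = folds.train_test(f)
        if len(np.unique(y[train])) < 2:
            out.skipped_folds.append(f)
            continue
        sel = fwer_select(gram_matrix[train], y[train], k=k_grams, gram_names=gram_names)
        sel.fold = f
        X_lang_train = np.hstack([topic_scores[train], dense_grams[np.ix_(train, sel.indices)]])
        X_lang_test = np.hstack([topic_scores[test], dense_grams[np.ix_(test, sel.indices)]])
        lang = fit_language_trees(X_lang_train, y[train], n_estimators=n_estimators, seed=seed + f)
        demo = fit_demographics_ridge(demographics[train], y[train], penalty=ridge_penalty)
        p_lang = lang.predict_proba(X_lang_test)
        p_demo = demo.predict_proba(demographics[test])
        out.p_language[test] = p_lang
        out.p_demographics[test] = p_demo
        out.p_combined[test] = ensemble_predict(p_lang, p_demo, lang.train_auc, demo.train_auc)
        out.train_aucs.append((lang.train_auc, demo.train_auc))
        out.selections.append(sel)
    return out
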