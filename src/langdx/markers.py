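"""Per-topic condition markers: three-AUC scans, quartile risk ratios, heatmap data.

A topic is a candidate marker for a condition when adding it to a
demographics-only logistic model improves out-of-sample AUC.  The scan
compares, per topic: (1) the AUC of the raw topic usage score alone, (2) the
cross-validated AUC of ridge logistic over age/sex/race, and (3) the
cross-validated AUC of the same model plus the topic; significance of
(3) vs (2) comes from the paired sign-flip permutation test, BH-corrected
across topics within the condition.

The quartile ratio translates a marker into plain risk terms: participants
are split into quartiles of the topic score, and the ratio of the
maximum-likelihood case proportions in the top versus bottom quartile is
reported with a percentile bootstrap CI (resampling within each quartile).
A bottom quartile with zero cases yields a ratio of +inf with a finite lower
bound, which is how strong markers in small cohorts present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .encoding import TopicModel, top_words
from .errors import DegenerateLabelsError, InvalidParameterError
from .evaluation import (
    FoldAssignment,
    auc,
    bh_fdr,
    cross_validated_ridge,
    perm_test_auc_diff,
    stratified_kfold,
)

__all__ = [
    "MarkerResult",
    "QuartileRatio",
    "topic_marker_scan",
    "quartile_ratio",
    "topic_expression_matrix",
    "export_wordclouds",
]


@dataclass
class MarkerResult:
    condition: str
    topic: int
    auc_topic_alone: float
    auc_demo: float
    auc_demo_plus_topic: float
    p_value: float
    adjusted_p: float
    direction: int  # +1 if cases use the topic more than controls
    degenerate: bool = False


@dataclass
class QuartileRatio:
    condition: str | None
    topic: int | None
    ratio: float  # may be +inf when the bottom quartile has no cases
    ci_low: float
    ci_high: float  # may be +inf
    cases_top: int
    cases_bottom: int
    n_top: int
    n_bottom: int


def topic_marker_scan(
    topic_scores: np.ndarray,
    demographics: np.ndarray,
    labels: np.ndarray,
    n_iter: int = 100_000,
    seed: int = 0,
    *,
    k: int = 10,
    ridge_penalty: float = 1.0,
    alpha: float = 0.05,
    condition: str = "condition",
) -> list[MarkerResult]:
    """Scan every topic for incremental predictive value over demographics.

    The demographics-only cross-validated predictions are computed once and
    shared; each topic then gets its own demographics+topic cross-validated
    ridge fit on the same folds.  Constant (degenerate) topics are flagged
    with AUC 0.5 and p 1.0.  BH adjustment runs across the topics of this
    condition.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("labels contain a single class")
    S = np.asarray(topic_scores, dtype=float)
    folds = stratified_kfold(y, k=k, seed=seed)
    p_demo = cross_validated_ridge(demographics, y, folds, penalty=ridge_penalty)
    ok = ~np.isnan(p_demo)
    auc_demo = auc(p_demo[ok], y[ok])

    results: list[MarkerResult] = []
    pvals = np.ones(S.shape[1])
    for t in range(S.shape[1]):
        s = S[:, t]
        cases_mean = s[y == 1].mean()
        controls_mean = s[y == 0].mean()
        direction = 1 if cases_mean >= controls_mean else -1
        if np.ptp(s) == 0:
            results.append(
                MarkerResult(condition, t, 0.5, auc_demo, auc_demo, 1.0, 1.0, direction, True)
            )
            continue
        X = np.column_stack([demographics, s])
        p_dt = cross_validated_ridge(X, y, folds, penalty=ridge_penalty)
        both = ok & ~np.isnan(p_dt)
        p = perm_test_auc_diff(
            p_dt[both], p_demo[both], y[both], n_iter=n_iter, seed=seed + 7919 * (t + 1)
        )
        pvals[t] = p
        results.append(
            MarkerResult(
                condition,
                t,
                auc(s, y),
                auc_demo,
                auc(p_dt[both], y[both]),
                p,
                np.nan,
                direction,
            )
        )
    _, adjusted = bh_fdr(pvals, alpha=alpha)
    for r, q in zip(results, adjusted):
        r.adjusted_p = float(q)
    return results


def _quantile_with_infinities(values: np.ndarray, q: float) -> float:
    """Linear-interpolation quantile that tolerates +inf entries."""
    v = np.sort(values)
    pos = q * (v.size - 1)
    lo, hi = v[int(np.floor(pos))], v[int(np.ceil(pos))]
    if np.isinf(lo):
        return float(lo)
    if np.isinf(hi):
        return float(hi) if pos > np.floor(pos) else float(lo)
    return float(lo + (pos - np.floor(pos)) * (hi - lo))


def _quartile_groups(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Bottom- and top-quartile index arrays; ties broken by stable input order."""
    order = np.argsort(scores, kind="stable")
    groups = np.array_split(order, 4)
    return groups[0], groups[3]


def quartile_ratio(
    topic_scores_vector: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 10_000,
    seed: int = 0,
    *,
    condition: str | None = None,
    topic: int | None = None,
) -> QuartileRatio:
    """Top- vs bottom-quartile condition risk ratio with a bootstrap 95% CI.

    The point estimate divides the maximum-likelihood case proportions of the
    two quartiles.  Bootstrap resamples draw labels within each (fixed)
    quartile; a resample with a zero-case bottom quartile contributes +inf,
    and the upper bound is reported as +inf when the 97.5th percentile is
    infinite (a rare condition concentrated in the top quartile therefore
    presents as "ratio r, CI [finite, inf]").  When the observed bottom
    quartile has no cases at all the ratio is +inf and pure resampling is
    degenerate, so the bottom rate is continuity-corrected to 1/(n+1) for the
    CI, which then keeps a finite lower bound.
    """
    s = np.asarray(topic_scores_vector, dtype=float)
    y = np.asarray(labels)
    if s.size != y.size:
        raise InvalidParameterError("scores and labels must be aligned")
    if s.size < 8:
        raise InvalidParameterError("need at least 8 participants for quartiles")
    bottom, top = _quartile_groups(s)
    k_top = int(y[top].sum())
    k_bot = int(y[bottom].sum())
    n_top, n_bot = top.size, bottom.size
    if k_top == 0 and k_bot == 0:
        raise DegenerateLabelsError("no cases in either extreme quartile; ratio undefined")
    ratio = np.inf if k_bot == 0 else (k_top / n_top) / (k_bot / n_bot)

    # resampling 0/1 labels within a fixed quartile == binomial draw of the case count
    rng = np.random.default_rng(seed)
    bt = rng.binomial(n_top, k_top / n_top, size=n_boot) / n_top
    # a zero-case bottom quartile is degenerate under pure resampling (every
    # resample is infinite); use the add-one rate as a continuity correction
    p_bot = k_bot / n_bot if k_bot > 0 else 1.0 / (n_bot + 1)
    bb = rng.binomial(n_bot, p_bot, size=n_boot) / n_bot
    with np.errstate(divide="ignore", invalid="ignore"):
        boots = np.where(bb == 0, np.where(bt > 0, np.inf, np.nan), bt / bb)
    boots = boots[~np.isnan(boots)]  # both-zero resamples carry no ratio information
    lo = _quantile_with_infinities(boots, 0.025)
    hi = _quantile_with_infinities(boots, 0.975)
    return QuartileRatio(
        condition=condition,
        topic=topic,
        ratio=float(ratio),
        ci_low=float(lo),
        ci_high=float(hi),
        cases_top=k_top,
        cases_bottom=k_bot,
        n_top=n_top,
        n_bottom=n_bot,
    )


def topic_expression_matrix(
    marker_results: dict[str, list[MarkerResult]],
) -> tuple[pd.DataFrame, list[str]]:
    """Signed condition x topic matrix of marker strength, rows clustered.

    Entry = direction * (auc_topic_alone - 0.5), so values lie in
    [-0.5, 0.5]: positive means cases use the topic more.  Rows (conditions)
    are ordered by average-linkage hierarchical clustering on Euclidean
    distance; conditions are sorted by name before clustering so the
    dendrogram does not depend on input order.
    """
    if not marker_results:
        raise InvalidParameterError("no marker results supplied")
    conditions = sorted(marker_results)
    n_topics = len(marker_results[conditions[0]])
    rows = []
    for c in conditions:
        res = marker_results[c]
        if len(res) != n_topics:
            raise InvalidParameterError(f"condition {c!r} has an incomplete topic scan")
        rows.append([r.direction * (r.auc_topic_alone - 0.5) for r in sorted(res, key=lambda r: r.topic)])
    M = pd.DataFrame(rows, index=conditions, columns=[f"topic_{t}" for t in range(n_topics)])
    if len(conditions) > 2:
        Z = linkage(M.to_numpy(), method="average", metric="euclidean")
        order = [conditions[i] for i in leaves_list(Z)]
    else:
        order = conditions
    return M.loc[order], order


def export_wordclouds(
    model: TopicModel,
    marker_results: dict[str, list[MarkerResult]],
    top_k_topics: int = 3,
    alpha: float = 0.05,
    n_words: int = 15,
) -> dict[str, list[dict]]:
    """Word-cloud data: per condition, the strongest BH-passing marker topics.

    For each condition the ``top_k_topics`` topics with the highest
    demographics+topic AUC among those passing BH at ``alpha`` are exported
    with their top words and rank-proportional sizes.
    """
    out: dict[str, list[dict]] = {}
    for condition, results in marker_results.items():
        passing = [r for r in results if r.adjusted_p <= alpha and not r.degenerate]
        passing.sort(key=lambda r: (-r.auc_demo_plus_topic, r.topic))
        entries = []
        for r in passing[:top_k_topics]:
            words = top_words(model, r.topic, n=n_words)
            entries.append(
                {
                    "topic": r.topic,
                    "auc_demo_plus_topic": r.auc_demo_plus_topic,
                    "direction": r.direction,
                    "adjusted_p": r.adjusted_p,
                    "words": [
                        {"word": w, "probability": p, "size": size} for w, p, size in words
                    ],
                }
            )
        out[condition] = entries
    return out
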