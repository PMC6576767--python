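"""Model/Results layer tying the pipeline together.

Two model classes mirror the study's two questions.  ``ConditionPredictability``
asks: per condition, how well do (1) language, (2) demographics, and (3) their
AUC-weighted ensemble predict the diagnosis under stratified 10-fold
cross-validation, and are the differences significant under Monte-Carlo
permutation tests with BH FDR control across conditions?  ``TopicMarkerScan``
asks: which single topics add out-of-sample predictive value over
demographics, and how large is the top-versus-bottom-quartile risk ratio for
the strongest markers?

Both follow the familiar fit() -> Results pattern: build the model from data,
call ``fit()``, and read estimates, p-values, and ``summary()`` off the
Results object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoding import NGramFrequencies, TopicModel, TopicScores
from .errors import InvalidParameterError
from .evaluation import (
    EvalResult,
    auc,
    bh_fdr,
    cross_validated_scores,
    perm_test_auc_diff,
    perm_test_auc_vs_chance,
    stratified_kfold,
)
from .io import ConditionPanel
from .markers import (
    MarkerResult,
    QuartileRatio,
    export_wordclouds,
    quartile_ratio,
    topic_expression_matrix,
    topic_marker_scan,
)
from .synthetic import encode_demographics

__all__ = [
    "ConditionPredictability",
    "PredictabilityResults",
    "TopicMarkerScan",
    "MarkerScanResults",
]


def _as_panel(panel) -> ConditionPanel:
    if isinstance(panel, ConditionPanel):
        return panel
    if isinstance(panel, pd.DataFrame):
        return ConditionPanel(participant_ids=list(panel.index), labels=panel)
    raise InvalidParameterError("panel must be a ConditionPanel or labels DataFrame")


def _condition_rows(
    panel: ConditionPanel, demographics: pd.DataFrame, condition: str
) -> np.ndarray:
    """Row mask honouring the condition's sex restriction (if any)."""
    mask = np.ones(len(panel.participant_ids), dtype=bool)
    sex = panel.sex_restrictions.get(condition)
    if sex is not None:
        mask &= (demographics["sex"] == sex).to_numpy()
    return mask


@dataclass
class PredictabilityResults:
    """Per-condition AUCs for the three models with permutation significance."""

    results: list[EvalResult]
    model: "ConditionPredictability" = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "condition": r.condition,
                    "n_cases": r.n_cases,
                    "n": r.n_total,
                    "auc_language": r.auc_language,
                    "auc_demographics": r.auc_demographics,
                    "auc_combined": r.auc_combined,
                    "p_lang_vs_demo": r.p_lang_vs_demo,
                    "p_combined_vs_demo": r.p_combined_vs_demo,
                    "p_lang_vs_chance": r.p_lang_vs_chance,
                    "q_lang_vs_demo": r.q_lang_vs_demo,
                    "q_combined_vs_demo": r.q_combined_vs_demo,
                    "q_lang_vs_chance": r.q_lang_vs_chance,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            "Condition predictability (stratified CV, AUC)",
            "=" * 46,
            df.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
            "",
            "q_*: Benjamini-Hochberg adjusted across conditions per comparison family.",
        ]
        return "\n".join(lines)

    def plot_comparison(self, ax=None):
        """Grouped bars of the three AUCs per condition."""
        import matplotlib.pyplot as plt

        df = self.to_frame()
        df = df.assign(gain=df.auc_language - df.auc_demographics).sort_values(
            "gain", ascending=False
        )
        if ax is None:
            _, ax = plt.subplots(figsize=(max(6, 0.6 * len(df)), 4))
        x = np.arange(len(df))
        for i, (col, label) in enumerate(
            [
                ("auc_language", "Language alone"),
                ("auc_demographics", "Demographics alone"),
                ("auc_combined", "Demographics & language"),
            ]
        ):
            ax.bar(x + (i - 1) * 0.27, df[col], width=0.25, label=label)
        ax.axhline(0.5, color="grey", lw=0.8, ls="--")
        ax.set_xticks(x)
        ax.set_xticklabels(df.condition, rotation=45, ha="right")
        ax.set_ylabel("cross-validated AUC")
        ax.legend()
        return ax


class ConditionPredictability:
    """Three-model predictability comparison over a condition panel.

    Parameters
    ----------
    topic_scores : TopicScores or array (participants x topics)
    gram_freqs : NGramFrequencies (candidate unigram/bigram frequencies)
    demographics : DataFrame with participant_id, age, sex, race
    panel : ConditionPanel or binary labels DataFrame
    """

    def __init__(
        self,
        topic_scores,
        gram_freqs: NGramFrequencies,
        demographics: pd.DataFrame,
        panel,
        *,
        min_cases: int = 30,
        cv_folds: int = 10,
        k_grams: int = 500,
        n_estimators: int = 1000,
        ridge_penalty: float = 1.0,
        n_perm: int = 100_000,
        alpha: float = 0.05,
        seed: int = 0,
    ) -> None:
        self.topic_scores = (
            topic_scores.matrix if isinstance(topic_scores, TopicScores) else np.asarray(topic_scores)
        )
        self.gram_freqs = gram_freqs
        self.demographics = demographics.reset_index(drop=True)
        self.panel = _as_panel(panel)
        self.min_cases = min_cases
        self.cv_folds = cv_folds
        self.k_grams = k_grams
        self.n_estimators = n_estimators
        self.ridge_penalty = ridge_penalty
        self.n_perm = n_perm
        self.alpha = alpha
        self.seed = seed
        if self.topic_scores.shape[0] != len(self.panel.participant_ids):
            raise InvalidParameterError("topic scores and panel row counts differ")

    def fit(self) -> PredictabilityResults:
        X_demo_all, _ = encode_demographics(self.demographics)
        results: list[EvalResult] = []
        for ci, condition in enumerate(self.panel.conditions):
            rows = _condition_rows(self.panel, self.demographics, condition)
            y = self.panel.labels[condition].to_numpy()[rows]
            n_cases = int(y.sum())
            if n_cases < self.min_cases or (y == 0).sum() < self.min_cases:
                warnings.warn(
                    f"condition {condition!r}: below {self.min_cases} cases/controls; skipped"
                )
                continue
            folds = stratified_kfold(y, k=self.cv_folds, seed=self.seed + 11 * ci)
            cv = cross_validated_scores(
                self.topic_scores[rows],
                self.gram_freqs.matrix[rows],
                X_demo_all[rows],
                y,
                folds,
                gram_names=self.gram_freqs.vocabulary,
                k_grams=self.k_grams,
                n_estimators=self.n_estimators,
                ridge_penalty=self.ridge_penalty,
                seed=self.seed + 101 * ci,
            )
            ok = ~np.isnan(cv.p_language)
            base = self.seed + 1009 * (ci + 1)
            results.append(
                EvalResult(
                    condition=condition,
                    n_cases=n_cases,
                    n_total=int(y.size),
                    auc_language=auc(cv.p_language[ok], y[ok]),
                    auc_demographics=auc(cv.p_demographics[ok], y[ok]),
                    auc_combined=auc(cv.p_combined[ok], y[ok]),
                    p_lang_vs_demo=perm_test_auc_diff(
                        cv.p_language[ok], cv.p_demographics[ok], y[ok],
                        n_iter=self.n_perm, seed=base,
                    ),
                    p_combined_vs_demo=perm_test_auc_diff(
                        cv.p_combined[ok], cv.p_demographics[ok], y[ok],
                        n_iter=self.n_perm, seed=base + 1,
                    ),
                    p_lang_vs_chance=perm_test_auc_vs_chance(
                        cv.p_language[ok], y[ok], n_iter=self.n_perm, seed=base + 2
                    ),
                )
            )
        # BH families: one per comparison type, across conditions
        if results:
            for attr, qattr in [
                ("p_lang_vs_demo", "q_lang_vs_demo"),
                ("p_combined_vs_demo", "q_combined_vs_demo"),
                ("p_lang_vs_chance", "q_lang_vs_chance"),
            ]:
                _, adj = bh_fdr([getattr(r, attr) for r in results], alpha=self.alpha)
                for r, q in zip(results, adj):
                    setattr(r, qattr, float(q))
        return PredictabilityResults(results=results, model=self)


@dataclass
class MarkerScanResults:
    """Per-topic marker scans for every condition, plus derived artifacts."""

    results: dict[str, list[MarkerResult]]
    model: "TopicMarkerScan" = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for condition, res in self.results.items():
            for r in res:
                rows.append(
                    {
                        "condition": condition,
                        "topic": r.topic,
                        "auc_topic_alone": r.auc_topic_alone,
                        "auc_demo": r.auc_demo,
                        "auc_demo_plus_topic": r.auc_demo_plus_topic,
                        "p_value": r.p_value,
                        "adjusted_p": r.adjusted_p,
                        "direction": r.direction,
                        "degenerate": r.degenerate,
                    }
                )
        return pd.DataFrame(rows)

    def expression_matrix(self) -> tuple[pd.DataFrame, list[str]]:
        return topic_expression_matrix(self.results)

    def quartile_ratio(self, condition: str, topic: int) -> QuartileRatio:
        m = self.model
        rows = _condition_rows(m.panel, m.demographics, condition)
        return quartile_ratio(
            m.topic_scores[rows, topic],
            m.panel.labels[condition].to_numpy()[rows],
            n_boot=m.n_boot,
            seed=m.seed + 31 * topic,
            condition=condition,
            topic=topic,
        )

    def wordclouds(self, model: TopicModel, top_k_topics: int = 3) -> dict:
        return export_wordclouds(
            model, self.results, top_k_topics=top_k_topics, alpha=self.model.alpha
        )

    def summary(self, alpha: float | None = None) -> str:
        alpha = self.model.alpha if alpha is None else alpha
        df = self.to_frame()
        sig = df[df.adjusted_p <= alpha]
        lines = [
            "Topic marker scan",
            "=" * 46,
            f"{len(df)} condition x topic tests; "
            f"{len(sig)} pass BH at {alpha:g}",
        ]
        if len(sig):
            lines.append(
                sig.sort_values(["condition", "adjusted_p"]).to_string(
                    index=False, float_format=lambda v: f"{v:.4f}"
                )
            )
        return "\n".join(lines)

    def plot_heatmap(self, ax=None):
        """Fig-3-style signed topic-expression heatmap (blue = used more by cases)."""
        import matplotlib.pyplot as plt

        M, _ = self.expression_matrix()
        if ax is None:
            _, ax = plt.subplots(figsize=(10, max(2, 0.4 * len(M))))
        im = ax.imshow(M.to_numpy(), aspect="auto", cmap="coolwarm_r", vmin=-0.5, vmax=0.5)
        ax.set_yticks(range(len(M)))
        ax.set_yticklabels(M.index)
        ax.set_xlabel("topic")
        plt.colorbar(im, ax=ax, label="direction x (AUC - 0.5)")
        return ax


class TopicMarkerScan:
    """Per-topic three-AUC marker scan over a condition panel."""

    def __init__(
        self,
        topic_scores,
        demographics: pd.DataFrame,
        panel,
        *,
        min_cases: int = 30,
        cv_folds: int = 10,
        ridge_penalty: float = 1.0,
        n_perm: int = 100_000,
        n_boot: int = 10_000,
        alpha: float = 0.05,
        seed: int = 0,
    ) -> None:
        self.topic_scores = (
            topic_scores.matrix if isinstance(topic_scores, TopicScores) else np.asarray(topic_scores)
        )
        self.demographics = demographics.reset_index(drop=True)
        self.panel = _as_panel(panel)
        self.min_cases = min_cases
        self.cv_folds = cv_folds
        self.ridge_penalty = ridge_penalty
        self.n_perm = n_perm
        self.n_boot = n_boot
        self.alpha = alpha
        self.seed = seed

    def fit(self) -> MarkerScanResults:
        X_demo_all, _ = encode_demographics(self.demographics)
        out: dict[str, list[MarkerResult]] = {}
        for ci, condition in enumerate(self.panel.conditions):
            rows = _condition_rows(self.panel, self.demographics, condition)
            y = self.panel.labels[condition].to_numpy()[rows]
            if y.sum() < self.min_cases or (y == 0).sum() < self.min_cases:
                warnings.warn(
                    f"condition {condition!r}: below {self.min_cases} cases/controls; skipped"
                )
                continue
            out[condition] = topic_marker_scan(
                self.topic_scores[rows],
                X_demo_all[rows],
                y,
                n_iter=self.n_perm,
                seed=self.seed + 211 * ci,
                k=self.cv_folds,
                ridge_penalty=self.ridge_penalty,
                alpha=self.alpha,
                condition=condition,
            )
        return MarkerScanResults(results=out, model=self)
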