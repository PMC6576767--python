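"""End-to-end pipeline: filter -> encode -> evaluate -> markers -> artifacts.

``run_pipeline`` drives the whole analysis from a :class:`~langdx.io.RunConfig`
and writes deterministic result tables plus a machine-readable manifest
(package version, parameters, seeds, input checksums).  Two runs with an
identical config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .encoding import (
    extract_ngrams,
    filter_min_words,
    fit_lda,
    score_topics,
    top_words,
    unigram_frequencies,
)
from .errors import LangdxError
from .io import ConditionPanel, RunConfig, build_condition_panel, read_demographics, read_posts
from .models import ConditionPredictability, TopicMarkerScan
from .synthetic import ConditionEffect, GeneratorConfig, simulate_study

logger = logging.getLogger("langdx")

__all__ = ["run_pipeline"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _generator_config(block: dict, seed: int) -> GeneratorConfig:
    block = dict(block)
    effects = [
        ConditionEffect(
            name=e["name"],
            intercept=e.get("intercept", 0.0),
            topic_coefs=np.asarray(e["topic_coefs"], float) if e.get("topic_coefs") is not None else None,
            demo_coefs=np.asarray(e["demo_coefs"], float) if e.get("demo_coefs") is not None else None,
        )
        for e in block.pop("condition_effects", [])
    ] or None
    if effects is not None:
        block["condition_effects"] = effects
    block.setdefault("seed", seed)
    return GeneratorConfig(**block)


def _load_inputs(config: RunConfig):
    manifest_inputs = {}
    if config.simulate is not None:
        gen = _generator_config(config.simulate, config.seed)
        study = simulate_study(gen)
        corpus, demographics = study.corpus, study.demographics
        panel = ConditionPanel(
            participant_ids=list(study.labels.index),
            labels=study.labels,
            sex_restrictions=dict(config.sex_restrictions),
        )
        manifest_inputs["simulate"] = {
            k: (v if not isinstance(v, list) else "...") for k, v in config.simulate.items()
        }
    else:
        corpus = read_posts(config.posts_path)
        demographics = read_demographics(config.demographics_path)
        panel = build_condition_panel(
            config.diagnoses_path,
            config.mapping_path,
            min_cases=config.min_cases,
            sex_restrictions=config.sex_restrictions,
        )
        for key in ("posts_path", "demographics_path", "diagnoses_path", "mapping_path"):
            p = getattr(config, key)
            if p:
                manifest_inputs[key] = {"path": str(p), "sha256": _sha256(Path(p))}
    return corpus, demographics, panel, manifest_inputs


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis; returns the output directory.

    Artifacts: ``eval_results.csv`` (per-condition model comparison),
    ``marker_results.csv``, ``quartile_ratios.csv``, ``expression_matrix.csv``,
    ``wordclouds.json``, ``topic_model_top_words.json``, ``manifest.json``.
    Any stage failure aborts with a stage-tagged message; artifacts written
    before the failure are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage = "load"
    try:
        corpus, demographics, panel, manifest_inputs = _load_inputs(config)
        logger.info("loaded %d participants (%.1fs)", len(corpus), time.time() - t0)

        stage = "filter"
        corpus = filter_min_words(corpus, config.min_words)
        if config.min_posts:
            corpus = [c for c in corpus if len([p for p in c.posts if p]) >= config.min_posts]
        kept = {c.participant_id for c in corpus}
        row_keep = [pid in kept for pid in panel.participant_ids]
        panel = ConditionPanel(
            participant_ids=[p for p in panel.participant_ids if p in kept],
            labels=panel.labels.loc[row_keep],
            sex_restrictions=panel.sex_restrictions,
        )
        order = {pid: i for i, pid in enumerate(panel.participant_ids)}
        corpus = sorted(corpus, key=lambda c: order.get(c.participant_id, len(order)))
        demographics = (
            demographics.set_index("participant_id").loc[panel.participant_ids].reset_index()
        )
        logger.info("cohort after filters: %d participants", len(corpus))

        stage = "encode"
        grams = extract_ngrams(corpus, max_vocab=config.max_vocab)
        lda = fit_lda(
            corpus, n_topics=config.n_topics, max_iter=config.lda_max_iter, seed=config.seed
        )
        scores = score_topics(lda, unigram_frequencies(corpus, lda.vocabulary))

        stage = "evaluate"
        pred = ConditionPredictability(
            scores, grams, demographics, panel,
            min_cases=config.min_cases, cv_folds=config.cv_folds,
            k_grams=config.k_grams, n_estimators=config.n_estimators,
            ridge_penalty=config.ridge_penalty, n_perm=config.n_perm,
            alpha=config.alpha, seed=config.seed,
        ).fit()
        eval_df = pred.to_frame()
        eval_df.to_csv(out / "eval_results.csv", index=False)

        stage = "markers"
        scan = TopicMarkerScan(
            scores, demographics, panel,
            min_cases=config.min_cases, cv_folds=config.cv_folds,
            ridge_penalty=config.ridge_penalty, n_perm=config.n_perm,
            n_boot=config.n_boot, alpha=config.alpha, seed=config.seed,
        ).fit()
        scan.to_frame().to_csv(out / "marker_results.csv", index=False)
        if scan.results:
            M, row_order = scan.expression_matrix()
            M.to_csv(out / "expression_matrix.csv")
            ratios = []
            for condition, res in scan.results.items():
                best = [r for r in res if not r.degenerate]
                best.sort(key=lambda r: (-r.auc_demo_plus_topic, r.topic))
                for r in best[: config.top_k_topics]:
                    q = scan.quartile_ratio(condition, r.topic)
                    ratios.append(dataclasses.asdict(q))
            pd.DataFrame(ratios).to_csv(out / "quartile_ratios.csv", index=False)
            clouds = scan.wordclouds(lda, top_k_topics=config.top_k_topics)
            with open(out / "wordclouds.json", "w", encoding="utf-8") as fh:
                json.dump(clouds, fh, indent=2)

        stage = "report"
        with open(out / "topic_model_top_words.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    str(t): [w for w, _, _ in top_words(lda, t, 15)]
                    for t in range(lda.n_topics)
                },
                fh,
                indent=2,
            )
        config_dict = config.to_dict()
        manifest = {
            "package": "langdx",
            "version": __version__,
            "seed": config.seed,
            "parameters": config_dict,
            "inputs": manifest_inputs,
            "config_hash": hashlib.sha256(
                json.dumps(
                    {k: v for k, v in config_dict.items() if k != "out_dir"},
                    sort_keys=True,
                    default=str,
                ).encode()
            ).hexdigest(),
            "n_participants": len(corpus),
            "conditions": list(panel.conditions),
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        logger.info("pipeline finished in %.1fs", time.time() - t0)
        return out
    except LangdxError as exc:
        raise LangdxError(f"[stage: {stage}] {exc}") from exc
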