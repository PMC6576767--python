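"""Readers, writers, condition grouping, and run configuration.

All tables are UTF-8 comma-separated with RFC-4180 quoting (pandas
defaults); posts travel as JSONL with one object per post.  Diagnoses may
arrive either as a pre-grouped binary matrix or as long-format ICD-9 codes
plus a user-supplied code-to-category mapping (the canonical grouping being
the Elixhauser Comorbidity Index plus locally prevalent additions; the exact
code lists are the user's responsibility).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .encoding import ParticipantCorpus, tokenize
from .errors import InvalidParameterError, SchemaError

logger = logging.getLogger("langdx")

__all__ = [
    "ConditionPanel",
    "RunConfig",
    "read_posts",
    "write_posts",
    "read_demographics",
    "build_condition_panel",
]


@dataclass
class ConditionPanel:
    """Binary condition labels with prevalence filters and sex restrictions."""

    participant_ids: list[str]
    labels: pd.DataFrame  # participants x conditions, 0/1
    sex_restrictions: dict[str, str] = field(default_factory=dict)  # condition -> "female"|"male"

    @property
    def conditions(self) -> list[str]:
        return list(self.labels.columns)

    def case_counts(self) -> pd.Series:
        return self.labels.sum(axis=0)


def read_posts(path: str | Path) -> list[ParticipantCorpus]:
    """Read posts (JSONL objects or CSV rows with participant_id, text).

    Posts are grouped per participant in first-appearance order and
    tokenized; malformed JSONL lines are counted and logged, not fatal.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = {"participant_id", "text"} - set(df.columns)
        if missing:
            raise SchemaError(f"posts CSV missing columns: {sorted(missing)}")
        records = list(zip(df["participant_id"], df["text"]))
    else:
        bad = 0
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                try:
                    obj = json.loads(line)
                    records.append((str(obj["participant_id"]), str(obj["text"])))
                except (json.JSONDecodeError, KeyError, TypeError):
                    bad += 1
        if bad:
            logger.warning("read_posts: skipped %d malformed JSONL line(s)", bad)
    by_id: dict[str, ParticipantCorpus] = {}
    for pid, text in records:
        if pid not in by_id:
            by_id[pid] = ParticipantCorpus(participant_id=pid, posts=[])
        by_id[pid].posts.append(tokenize(text))
    return list(by_id.values())


def write_posts(corpus: list[ParticipantCorpus], path: str | Path) -> None:
    """Write one JSONL object per post (tokens joined by single spaces)."""
    with open(path, "w", encoding="utf-8") as fh:
        for part in corpus:
            for post in part.posts:
                fh.write(
                    json.dumps(
                        {"participant_id": part.participant_id, "text": " ".join(post)},
                        ensure_ascii=False,
                    )
                    + "\n"
                )


def read_demographics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"participant_id", "age", "sex", "race"} - set(df.columns)
    if missing:
        raise SchemaError(f"demographics CSV missing columns: {sorted(missing)}")
    df["participant_id"] = df["participant_id"].astype(str)
    return df


def _load_code_mapping(mapping_path: str | Path) -> list[tuple[str, str, bool]]:
    """(code-or-prefix, category, is_prefix) triples from a mapping CSV.

    A code ending in ``x`` (e.g. ``250.x`` or ``V22x``) matches any code
    starting with the part before the ``x``.
    """
    mp = pd.read_csv(mapping_path, dtype=str)
    missing = {"code", "category"} - set(mp.columns)
    if missing:
        raise SchemaError(f"mapping CSV missing columns: {sorted(missing)}")
    rules = []
    for code, cat in zip(mp["code"], mp["category"]):
        code = code.strip()
        if code.lower().endswith("x"):
            rules.append((code[:-1].rstrip("."), cat, True))
        else:
            rules.append((code, cat, False))
    return rules


def build_condition_panel(
    diagnoses_path: str | Path,
    mapping_path: str | Path | None = None,
    min_cases: int = 30,
    sex_restrictions: dict[str, str] | None = None,
    strict: bool = False,
) -> ConditionPanel:
    """Build the binary condition panel from diagnoses, applying prevalence filters.

    Two input shapes are accepted: a binary matrix CSV (participant_id plus
    one 0/1 column per condition category), or a long CSV with columns
    (participant_id, code) combined with a code-to-category mapping.  A
    participant is positive for a category if any of their codes maps to it.
    Categories with fewer than ``min_cases`` cases are dropped (logged).
    Unmapped codes are counted and logged (raised in strict mode).
    """
    df = pd.read_csv(diagnoses_path, dtype=str)
    if "participant_id" not in df.columns:
        raise SchemaError("diagnoses CSV must have a participant_id column")
    df["participant_id"] = df["participant_id"].astype(str)
    if "code" in df.columns:
        if mapping_path is None:
            raise SchemaError("long-format diagnoses require a code->category mapping")
        rules = _load_code_mapping(mapping_path)
        ids = list(dict.fromkeys(df["participant_id"]))
        categories = list(dict.fromkeys(cat for _, cat, _ in rules))
        labels = pd.DataFrame(0, index=ids, columns=categories, dtype=int)
        unmapped = 0
        for pid, code in zip(df["participant_id"], df["code"]):
            code = str(code).strip()
            hit = False
            for pat, cat, is_prefix in rules:
                if (is_prefix and code.startswith(pat)) or (not is_prefix and code == pat):
                    labels.loc[pid, cat] = 1
                    hit = True
            if not hit:
                unmapped += 1
        if unmapped:
            msg = f"build_condition_panel: {unmapped} code occurrence(s) had no mapping"
            if strict:
                raise SchemaError(msg)
            logger.warning(msg)
    else:
        labels = df.set_index("participant_id").astype(int)
        bad = ~labels.isin([0, 1]).all()
        if bad.any():
            raise SchemaError(f"non-binary label columns: {list(labels.columns[bad])}")
    counts = labels.sum(axis=0)
    dropped = list(counts.index[counts < min_cases])
    if dropped:
        logger.info(
            "build_condition_panel: dropping %d condition(s) below %d cases: %s",
            len(dropped), min_cases, dropped,
        )
    labels = labels.drop(columns=dropped)
    return ConditionPanel(
        participant_ids=list(labels.index),
        labels=labels,
        sex_restrictions=dict(sex_restrictions or {}),
    )


@dataclass
class RunConfig:
    """Schema-validated configuration for a full pipeline run.

    Every source of randomness derives from ``seed``; two runs with an equal
    config produce identical outputs.
    """

    seed: int
    out_dir: str = "results"
    # inputs: either real files ...
    posts_path: str | None = None
    demographics_path: str | None = None
    diagnoses_path: str | None = None
    mapping_path: str | None = None
    # ... or a synthetic study
    simulate: dict | None = None
    # cohort filters
    min_words: int = 500
    min_posts: int | None = None
    min_cases: int = 30
    sex_restrictions: dict = field(default_factory=dict)
    # encoding
    max_vocab: int = 20_000
    n_topics: int = 200
    lda_max_iter: int = 100
    # models
    k_grams: int = 500
    n_estimators: int = 1000
    ridge_penalty: float = 1.0
    cv_folds: int = 10
    # inference
    n_perm: int = 100_000
    n_boot: int = 10_000
    alpha: float = 0.05
    top_k_topics: int = 3

    def __post_init__(self) -> None:
        if self.seed is None or not isinstance(self.seed, (int, np.integer)):
            raise InvalidParameterError("config must provide an integer seed")
        if self.simulate is None and self.posts_path is None:
            raise InvalidParameterError("config needs posts_path or a simulate block")
        for name in ("max_vocab", "n_topics", "k_grams", "n_estimators", "cv_folds",
                     "n_perm", "n_boot"):
            if getattr(self, name) < 1:
                raise InvalidParameterError(f"{name} must be >= 1")
        if not 0 < self.alpha < 1:
            raise InvalidParameterError("alpha must lie in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) if path.suffix in {".yml", ".yaml"} else json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in data:
            raise InvalidParameterError("config must provide an integer seed")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
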