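"""Synthetic study generator with known ground truth.

Emulates the structure of a cohort study linking per-participant social-media
language to binary condition labels: each participant writes posts whose
words come from a Dirichlet-multinomial topic mixture, carries demographics
(age, sex, race), and receives condition labels from a logistic model with
planted topic and demographic effects.  All generator choices are
artifact-level modelling assumptions — the real study data are private and
their generative process unknown — and are documented in the methods note.

Defaults follow the study conditions exercised by the test-bed: 1,000
participants with 600 words each over a 20-topic, 500-word vocabulary, Table
1-style demographics (76% female; race mix dominated by one category; ages
18-65), and one condition with a strong planted coefficient (+3) on a single
topic and no demographic effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoding import ParticipantCorpus
from .errors import InvalidParameterError

__all__ = [
    "ConditionEffect",
    "GeneratorConfig",
    "GroundTruth",
    "SimulatedStudy",
    "generate_topic_word_matrix",
    "generate_corpus",
    "generate_demographics",
    "encode_demographics",
    "assign_conditions",
    "simulate_study",
]

RACE_CATEGORIES = ("black", "white", "asian", "other")


@dataclass
class ConditionEffect:
    """Logistic-model coefficients planting one condition's signal.

    P(y=1) = logistic(intercept + topic_coefs . theta + demo_coefs . x) where
    theta is the participant's true topic mixture and x the encoded
    demographics (age/10, female indicator, race one-hot less the reference).
    """

    name: str
    intercept: float = 0.0
    topic_coefs: np.ndarray | None = None  # length n_topics_true (None = zeros)
    demo_coefs: np.ndarray | None = None  # length n_demo_features (None = zeros)


def _default_effects() -> list[ConditionEffect]:
    coefs = np.zeros(20)
    coefs[0] = 3.0
    return [ConditionEffect("condition_a", intercept=-1.5, topic_coefs=coefs)]


@dataclass
class GeneratorConfig:
    n_participants: int = 1000
    vocab_size: int = 500
    n_topics_true: int = 20
    words_per_participant: int | tuple = 600  # int or ("lognormal", mu, sigma)
    topic_concentration: float = 0.05
    mixture_concentration: float = 0.05
    posts_per_participant: int = 30
    age_range: tuple[float, float] = (18.0, 65.0)
    female_proportion: float = 0.76
    race_proportions: dict = field(
        default_factory=lambda: {"black": 0.71, "white": 0.23, "asian": 0.02, "other": 0.04}
    )
    condition_effects: list[ConditionEffect] = field(default_factory=_default_effects)
    realistic_text: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_participants", "vocab_size", "n_topics_true", "posts_per_participant"):
            if getattr(self, name) < 1:
                raise InvalidParameterError(f"{name} must be >= 1")
        if self.vocab_size < 2:
            raise InvalidParameterError("vocab_size must be >= 2")
        if self.vocab_size < self.n_topics_true:
            raise InvalidParameterError("vocab_size must be >= n_topics_true")
        if self.topic_concentration <= 0 or self.mixture_concentration <= 0:
            raise InvalidParameterError("Dirichlet concentrations must be > 0")
        if isinstance(self.words_per_participant, int):
            if self.words_per_participant < 1:
                raise InvalidParameterError("words_per_participant must be >= 1")
        else:
            kind = self.words_per_participant[0]
            if kind != "lognormal":
                raise InvalidParameterError(
                    "words_per_participant must be an int or ('lognormal', mu, sigma)"
                )
        if not 0.0 <= self.female_proportion <= 1.0:
            raise InvalidParameterError("female_proportion must lie in [0, 1]")
        total = sum(self.race_proportions.values())
        if abs(total - 1.0) > 1e-9 or any(p < 0 for p in self.race_proportions.values()):
            raise InvalidParameterError("race_proportions must be >= 0 and sum to 1")
        for eff in self.condition_effects:
            if eff.topic_coefs is not None and len(eff.topic_coefs) != self.n_topics_true:
                raise InvalidParameterError(
                    f"condition {eff.name!r}: topic_coefs length "
                    f"{len(eff.topic_coefs)} != n_topics_true {self.n_topics_true}"
                )

    @property
    def n_demo_features(self) -> int:
        return 2 + len(self.race_proportions) - 1


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    topic_word: np.ndarray  # n_topics_true x vocab_size, rows sum to 1
    theta: np.ndarray  # n_participants x n_topics_true, rows sum to 1
    condition_effects: list[ConditionEffect] = field(default_factory=list)
    condition_probs: pd.DataFrame | None = None  # realized P(y=1) per participant


@dataclass
class SimulatedStudy:
    corpus: list[ParticipantCorpus]
    demographics: pd.DataFrame
    labels: pd.DataFrame  # participants x conditions, 0/1
    ground_truth: GroundTruth


def generate_topic_word_matrix(
    n_topics: int, vocab_size: int, concentration: float, seed: int
) -> np.ndarray:
    """Draw each topic's word distribution from a symmetric Dirichlet."""
    if concentration <= 0:
        raise InvalidParameterError("concentration must be > 0")
    if n_topics < 1 or vocab_size < n_topics:
        raise InvalidParameterError("need n_topics >= 1 and vocab_size >= n_topics")
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.full(vocab_size, concentration), size=n_topics)


def _token_strings(vocab_size: int) -> np.ndarray:
    width = max(4, len(str(vocab_size - 1)))
    return np.array([f"w{i:0{width}d}" for i in range(vocab_size)])


def generate_corpus(config: GeneratorConfig) -> tuple[list[ParticipantCorpus], GroundTruth]:
    """Generate every participant's posts plus the generating ground truth.

    Per participant: theta ~ Dirichlet(mixture_concentration), each word's
    topic ~ Categorical(theta), word ~ Categorical(topic row); words are
    partitioned uniformly at random into ``posts_per_participant`` posts.
    Deterministic given (config, config.seed).
    """
    rng = np.random.default_rng(config.seed)
    K, V = config.n_topics_true, config.vocab_size
    topic_word = generate_topic_word_matrix(
        K, V, config.topic_concentration, int(rng.integers(2**31))
    )
    theta = rng.dirichlet(np.full(K, config.mixture_concentration), size=config.n_participants)
    tokens = _token_strings(V)

    if isinstance(config.words_per_participant, int):
        n_words = np.full(config.n_participants, config.words_per_participant)
    else:
        _, mu, sigma = config.words_per_participant
        n_words = np.maximum(1, rng.lognormal(mu, sigma, config.n_participants).astype(int))

    corpus: list[ParticipantCorpus] = []
    for i in range(config.n_participants):
        topic_counts = rng.multinomial(n_words[i], theta[i])
        word_ids = np.concatenate(
            [
                np.repeat(np.arange(V), rng.multinomial(c, topic_word[k]))
                for k, c in enumerate(topic_counts)
                if c > 0
            ]
        )
        rng.shuffle(word_ids)
        post_of = rng.integers(0, config.posts_per_participant, size=word_ids.size)
        toks = tokens[word_ids]
        if config.realistic_text:
            bang = rng.random(word_ids.size) < 0.05
            toks = np.where(bang, np.char.add(toks, "!"), toks)
        posts = [toks[post_of == p].tolist() for p in range(config.posts_per_participant)]
        corpus.append(ParticipantCorpus(participant_id=f"p{i:05d}", posts=posts))
    return corpus, GroundTruth(topic_word=topic_word, theta=theta)


def generate_demographics(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw age (uniform over the configured range), sex, and race."""
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n = config.n_participants
    races = list(config.race_proportions)
    probs = np.array([config.race_proportions[r] for r in races])
    return pd.DataFrame(
        {
            "participant_id": [f"p{i:05d}" for i in range(n)],
            "age": rng.uniform(*config.age_range, size=n).round(1),
            "sex": np.where(rng.random(n) < config.female_proportion, "female", "male"),
            "race": rng.choice(races, size=n, p=probs),
        }
    )


def encode_demographics(
    demographics: pd.DataFrame, reference_race: str | None = None
) -> tuple[np.ndarray, list[str]]:
    """Numeric design matrix: age/10, female indicator, race one-hot less reference.

    The reference race defaults to the most common category (dropped to avoid
    collinearity).  Age is divided by 10 so planted coefficients are per
    decade; model-side standardization happens inside the ridge fit.
    """
    races = demographics["race"].value_counts()
    if reference_race is None:
        reference_race = races.index[0]
    cols = [r for r in sorted(races.index) if r != reference_race]
    X = np.column_stack(
        [
            demographics["age"].to_numpy(dtype=float) / 10.0,
            (demographics["sex"] == "female").to_numpy(dtype=float),
        ]
        + [(demographics["race"] == r).to_numpy(dtype=float) for r in cols]
    )
    return X, ["age_decades", "female"] + [f"race_{r}" for r in cols]


def assign_conditions(
    theta: np.ndarray,
    demographics: pd.DataFrame,
    effects: list[ConditionEffect],
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw condition labels from the planted logistic model.

    Returns (labels, probabilities), both participants x conditions.  Labels
    are drawn by comparing one uniform per participant-condition against the
    logistic probability, so raising an intercept (same seed) can only turn
    0s into 1s — realized prevalence is monotone in the intercept.
    """
    n, k_true = theta.shape
    X_demo, _ = encode_demographics(demographics)
    rng = np.random.default_rng(seed)
    labels = {}
    probs = {}
    for eff in effects:
        tc = np.zeros(k_true) if eff.topic_coefs is None else np.asarray(eff.topic_coefs, float)
        if tc.shape != (k_true,):
            raise InvalidParameterError(
                f"condition {eff.name!r}: topic_coefs length {tc.size} != {k_true}"
            )
        dc = (
            np.zeros(X_demo.shape[1])
            if eff.demo_coefs is None
            else np.asarray(eff.demo_coefs, float)
        )
        if dc.shape != (X_demo.shape[1],):
            raise InvalidParameterError(
                f"condition {eff.name!r}: demo_coefs length {dc.size} != {X_demo.shape[1]}"
            )
        eta = eff.intercept + theta @ tc + X_demo @ dc
        p = 1.0 / (1.0 + np.exp(-eta))
        u = rng.random(n)
        labels[eff.name] = (u < p).astype(int)
        probs[eff.name] = p
    ids = demographics["participant_id"].tolist()
    return (
        pd.DataFrame(labels, index=ids),
        pd.DataFrame(probs, index=ids),
    )


def simulate_study(config: GeneratorConfig) -> SimulatedStudy:
    """Generate corpus, demographics, and labels in one deterministic call."""
    corpus, truth = generate_corpus(config)
    demographics = generate_demographics(config)
    labels, probs = assign_conditions(
        truth.theta, demographics, config.condition_effects, config.seed + 2
    )
    truth.condition_effects = config.condition_effects
    truth.condition_probs = probs
    return SimulatedStudy(
        corpus=corpus, demographics=demographics, labels=labels, ground_truth=truth
    )
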