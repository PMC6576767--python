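"""Patient language encoding: tokenization, n-gram frequencies, topics, topic scores.

Each participant's posts are reduced to (i) relative frequencies of the most
frequent unigrams and bigrams across the cohort and (ii) usage scores for
latent topics fit by LDA.  The topic usage score is

    score(topic, participant) = sum_w p(topic | w) * p(w | participant)

where ``p(topic | w)`` is the word-level topic posterior obtained from the
fitted topic-word distributions by Bayes' rule, and ``p(w | participant)`` is
the participant's relative unigram frequency.  With complete vocabulary
coverage each participant's scores form a probability vector over topics.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import LatentDirichletAllocation

from .errors import EmptyCorpusError, InvalidParameterError

__all__ = [
    "ParticipantCorpus",
    "NGramFrequencies",
    "TopicModel",
    "TopicScores",
    "tokenize",
    "filter_min_words",
    "extract_ngrams",
    "unigram_frequencies",
    "fit_lda",
    "score_topics",
    "top_words",
]

# --------------------------------------------------------------------------
# tokenization
# --------------------------------------------------------------------------

_EMOTICON = r"""[<>]?[:;=8][\-o'^]?[)\](\[dDpP/\\|@}{*3]"""
_TOKEN_RE = re.compile(
    r"(?P<url>https?://\S+|www\.\S+)"
    r"|(?P<handle>@\w+)"
    rf"|(?P<emoticon>{_EMOTICON}|<3)"
    r"|(?P<word>[^\W_]+(?:['’_-][^\W_]+)*)"
    r"|(?P<punct>(?P<pc>[^\w\s])(?P=pc)*)",
    re.UNICODE,
)


def tokenize(text: str) -> list[str]:
    """Split raw post text into lowercased tokens.

    URLs and @-handles are collapsed to the placeholders ``<url>`` and
    ``<user>``; common emoticons survive as single tokens; runs of one
    repeated punctuation character form one token.  Total function: any
    unicode string is accepted and the empty string yields ``[]``.
    """
    tokens: list[str] = []
    for m in _TOKEN_RE.finditer(text.lower()):
        if m.lastgroup == "url":
            tokens.append("<url>")
        elif m.lastgroup == "handle":
            tokens.append("<user>")
        else:
            tokens.append(m.group(0))
    return tokens


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass
class ParticipantCorpus:
    """All posts of one participant, already tokenized."""

    participant_id: str
    posts: list[list[str]] = field(default_factory=list)

    @property
    def total_words(self) -> int:
        return sum(len(p) for p in self.posts)

    def iter_tokens(self):
        for post in self.posts:
            yield from post


@dataclass
class NGramFrequencies:
    """Relative frequencies of grams per participant.

    ``matrix[i, j]`` is participant *i*'s count of gram *j* divided by the
    participant's total number of grams *of that order* (unigram counts over
    unigram totals, bigram counts over bigram totals).
    """

    vocabulary: list[str]
    orders: np.ndarray  # 1 for unigrams, 2 for bigrams
    matrix: sp.csr_matrix  # participants x vocabulary
    participant_ids: list[str]

    @property
    def n_participants(self) -> int:
        return self.matrix.shape[0]


@dataclass
class TopicModel:
    """LDA topic-word distributions and the derived word-level posteriors."""

    vocabulary: list[str]
    phi: np.ndarray  # n_topics x vocab, p(word | topic)
    topic_prior: np.ndarray  # n_topics, p(topic)
    topic_given_word: np.ndarray  # vocab x n_topics, p(topic | word)

    @property
    def n_topics(self) -> int:
        return self.phi.shape[0]

    @property
    def word_index(self) -> dict[str, int]:
        return {w: i for i, w in enumerate(self.vocabulary)}


@dataclass
class TopicScores:
    """Per-participant topic usage scores (rows sum to in-vocabulary mass)."""

    matrix: np.ndarray  # participants x n_topics
    participant_ids: list[str]


# --------------------------------------------------------------------------
# corpus filters and gram extraction
# --------------------------------------------------------------------------


def filter_min_words(
    corpus: list[ParticipantCorpus], min_words: int = 500
) -> list[ParticipantCorpus]:
    """Keep participants with at least ``min_words`` tokens, preserving order.

    The inclusive reading (>= 500) of the adequacy threshold is used; pass a
    different ``min_words`` to change the cutoff.
    """
    if min_words < 0:
        raise InvalidParameterError("min_words must be >= 0")
    return [c for c in corpus if c.total_words >= min_words]


def _count_grams(participant: ParticipantCorpus) -> tuple[Counter, Counter]:
    uni: Counter = Counter()
    bi: Counter = Counter()
    for post in participant.posts:
        uni.update(post)
        # bigrams never span post boundaries
        bi.update(f"{a} {b}" for a, b in zip(post, post[1:]))
    return uni, bi


def extract_ngrams(
    corpus: list[ParticipantCorpus], max_vocab: int | None = 20_000
) -> NGramFrequencies:
    """Count unigrams and bigrams and keep the ``max_vocab`` most frequent.

    Both orders are pooled into one ranking by total corpus count; ties break
    lexicographically.  Relative frequencies are normalized per order within
    each participant.  ``max_vocab=None`` keeps every gram.
    """
    if not corpus:
        raise EmptyCorpusError("corpus is empty")
    per_uni: list[Counter] = []
    per_bi: list[Counter] = []
    total: Counter = Counter()
    for part in corpus:
        uni, bi = _count_grams(part)
        per_uni.append(uni)
        per_bi.append(bi)
        total.update(uni)
        total.update(bi)
    if not total:
        raise EmptyCorpusError("corpus contains zero words")

    ranked = sorted(total.items(), key=lambda kv: (-kv[1], kv[0]))
    if max_vocab is not None:
        ranked = ranked[:max_vocab]
    vocabulary = [g for g, _ in ranked]
    index = {g: j for j, g in enumerate(vocabulary)}
    orders = np.array([2 if " " in g else 1 for g in vocabulary], dtype=np.int8)

    rows, cols, vals = [], [], []
    for i, (uni, bi) in enumerate(zip(per_uni, per_bi)):
        n_uni = sum(uni.values())
        n_bi = sum(bi.values())
        for counter, denom in ((uni, n_uni), (bi, n_bi)):
            if denom == 0:
                continue
            for gram, c in counter.items():
                j = index.get(gram)
                if j is not None:
                    rows.append(i)
                    cols.append(j)
                    vals.append(c / denom)
    matrix = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(corpus), len(vocabulary)), dtype=float
    )
    return NGramFrequencies(
        vocabulary=vocabulary,
        orders=orders,
        matrix=matrix,
        participant_ids=[c.participant_id for c in corpus],
    )


def unigram_frequencies(
    corpus: list[ParticipantCorpus], vocabulary: list[str] | None = None
) -> NGramFrequencies:
    """Relative unigram frequencies p(word | participant) over ``vocabulary``.

    With ``vocabulary=None`` the full corpus unigram vocabulary (sorted) is
    used, so every row sums to exactly 1.
    """
    if not corpus:
        raise EmptyCorpusError("corpus is empty")
    counters = []
    seen: set[str] = set()
    for part in corpus:
        uni: Counter = Counter()
        for post in part.posts:
            uni.update(post)
        counters.append(uni)
        seen.update(uni)
    if vocabulary is None:
        vocabulary = sorted(seen)
    index = {w: j for j, w in enumerate(vocabulary)}
    rows, cols, vals = [], [], []
    for i, uni in enumerate(counters):
        n = sum(uni.values())
        if n == 0:
            continue
        for w, c in uni.items():
            j = index.get(w)
            if j is not None:
                rows.append(i)
                cols.append(j)
                vals.append(c / n)
    matrix = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(corpus), len(vocabulary)), dtype=float
    )
    return NGramFrequencies(
        vocabulary=list(vocabulary),
        orders=np.ones(len(vocabulary), dtype=np.int8),
        matrix=matrix,
        participant_ids=[c.participant_id for c in corpus],
    )


# --------------------------------------------------------------------------
# topic model
# --------------------------------------------------------------------------


def fit_lda(
    corpus: list[ParticipantCorpus],
    n_topics: int = 200,
    *,
    doc_topic_prior: float | None = None,
    topic_word_prior: float = 0.01,
    max_iter: int = 100,
    evaluate_every: int = 5,
    seed: int = 0,
) -> TopicModel:
    """Fit an LDA topic model on the corpus unigrams.

    One document per participant.  ``doc_topic_prior`` defaults to
    ``min(1, 50 / n_topics)``, ``topic_word_prior`` to 0.01.  Batch
    variational inference runs until the perplexity change (checked every
    ``evaluate_every`` passes) falls below sklearn's tolerance or ``max_iter``
    passes are exhausted.  The topic prior
    p(topic) is the corpus-wide expected topic proportion (document topic
    distributions weighted by document length) and p(topic | word) follows by
    Bayes' rule from phi and the prior.  Fixed ``seed`` gives a reproducible
    model.
    """
    if not corpus:
        raise EmptyCorpusError("corpus is empty")
    if n_topics < 1:
        raise InvalidParameterError("n_topics must be >= 1")
    freqs = unigram_frequencies(corpus)
    vocabulary = freqs.vocabulary
    if n_topics > len(vocabulary):
        raise InvalidParameterError(
            f"n_topics={n_topics} exceeds distinct vocabulary size {len(vocabulary)}"
        )
    # integer count matrix over the unigram vocabulary
    index = {w: j for j, w in enumerate(vocabulary)}
    rows, cols, vals = [], [], []
    for i, part in enumerate(corpus):
        uni = Counter(part.iter_tokens())
        for w, c in uni.items():
            rows.append(i)
            cols.append(index[w])
            vals.append(c)
    counts = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(corpus), len(vocabulary)), dtype=np.float64
    )

    if n_topics == 1:
        # single-topic degeneracy: phi is the corpus unigram distribution
        total = np.asarray(counts.sum(axis=0)).ravel()
        phi = (total / total.sum())[None, :]
        prior = np.array([1.0])
        tgw = np.ones((len(vocabulary), 1))
        return TopicModel(vocabulary, phi, prior, tgw)

    if doc_topic_prior is None:
        doc_topic_prior = min(1.0, 50.0 / n_topics)
    lda = LatentDirichletAllocation(
        n_components=n_topics,
        doc_topic_prior=doc_topic_prior,
        topic_word_prior=topic_word_prior,
        max_iter=max_iter,
        evaluate_every=evaluate_every,
        learning_method="batch",
        random_state=seed,
    )
    doc_topic = lda.fit_transform(counts)
    phi = lda.components_ / lda.components_.sum(axis=1, keepdims=True)

    doc_lengths = np.asarray(counts.sum(axis=1)).ravel()
    weighted = doc_topic * doc_lengths[:, None]
    prior = weighted.sum(axis=0)
    prior = prior / prior.sum()

    joint = phi.T * prior[None, :]  # vocab x topics, p(w|t) p(t)
    tgw = joint / joint.sum(axis=1, keepdims=True)
    return TopicModel(vocabulary, phi, prior, tgw)


def score_topics(model: TopicModel, unigram_freqs: NGramFrequencies) -> TopicScores:
    """Topic usage scores: sum over words of p(topic | word) p(word | participant).

    Words outside the model vocabulary contribute nothing, so each row sums to
    the participant's in-vocabulary probability mass (1 with full coverage).
    Participants with zero in-vocabulary mass get an all-zero row and a
    warning.
    """
    widx = model.word_index
    cols_in_model = np.array(
        [widx.get(w, -1) for w in unigram_freqs.vocabulary], dtype=int
    )
    keep = cols_in_model >= 0
    F = unigram_freqs.matrix[:, np.flatnonzero(keep)]
    T = model.topic_given_word[cols_in_model[keep], :]
    scores = np.asarray(F @ T)
    empty = np.flatnonzero(np.asarray(F.sum(axis=1)).ravel() == 0)
    if empty.size:
        ids = [unigram_freqs.participant_ids[i] for i in empty[:5]]
        warnings.warn(
            f"{empty.size} participant(s) have no in-vocabulary words "
            f"(e.g. {ids}); their topic scores are all zero."
        )
    return TopicScores(matrix=scores, participant_ids=list(unigram_freqs.participant_ids))


def top_words(model: TopicModel, topic: int, n: int = 15) -> list[tuple[str, float, float]]:
    """Top-``n`` words of a topic by p(word | topic), with rank-proportional sizes.

    Returns (word, probability, size) triples sorted by descending
    probability, ties broken lexicographically; size decreases linearly with
    rank, the rank-1 word having size 1.  If ``n`` exceeds the vocabulary all
    words are returned.
    """
    if not 0 <= topic < model.n_topics:
        raise InvalidParameterError(f"topic index {topic} out of range")
    row = model.phi[topic]
    order = sorted(range(len(row)), key=lambda j: (-row[j], model.vocabulary[j]))
    order = order[: min(n, len(order))]
    m = len(order)
    return [
        (model.vocabulary[j], float(row[j]), (m - r) / m)
        for r, j in enumerate(order)
    ]
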