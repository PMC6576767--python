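"""Language encoding: tokenizer, gram counting, LDA contracts, topic scores."""

import warnings

import numpy as np
import pytest

from langdx.encoding import (
    ParticipantCorpus,
    extract_ngrams,
    filter_min_words,
    fit_lda,
    score_topics,
    tokenize,
    top_words,
    unigram_frequencies,
)
from langdx.errors import EmptyCorpusError, InvalidParameterError
from langdx.synthetic import GeneratorConfig, generate_corpus


class TestTokenize:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("", []),
            ("Sick of this!", ["sick", "of", "this", "!"]),
            ("so happy :) today", ["so", "happy", ":)", "today"]),
            ("see https://x.co/a and @friend", ["see", "<url>", "and", "<user>"]),
            ("wait... what?!", ["wait", "...", "what", "?", "!"]),
            ("i'm don't gonna-go", ["i'm", "don't", "gonna-go"]),
        ],
    )
    def test_examples(self, text, expected):
        assert tokenize(text) == expected

    def test_case_insensitive(self):
        assert tokenize("I'm OK") == tokenize("i'm ok")


class TestFilters:
    def test_min_words_boundary_is_inclusive(self):
        corpus = [
            ParticipantCorpus("a", [["w"] * 499]),
            ParticipantCorpus("b", [["w"] * 500]),
            ParticipantCorpus("c", [["w"] * 501]),
        ]
        kept = filter_min_words(corpus, 500)
        assert [c.participant_id for c in kept] == ["b", "c"]

    def test_zero_threshold_is_identity_and_empty_ok(self):
        corpus = [ParticipantCorpus("a", [[]])]
        assert filter_min_words(corpus, 0) == corpus
        assert filter_min_words([], 500) == []


class TestExtractNgrams:
    def test_hand_counts_single_participant(self):
        corpus = [ParticipantCorpus("p", [["a", "b", "a"]])]
        f = extract_ngrams(corpus, max_vocab=None)
        freqs = dict(zip(f.vocabulary, f.matrix.toarray()[0]))
        assert freqs["a"] == pytest.approx(2 / 3)
        assert freqs["b"] == pytest.approx(1 / 3)
        assert freqs["a b"] == pytest.approx(1 / 2)
        assert freqs["b a"] == pytest.approx(1 / 2)

    def test_bigrams_do_not_span_posts(self):
        corpus = [ParticipantCorpus("p", [["a", "b"], ["c", "d"]])]
        f = extract_ngrams(corpus, max_vocab=None)
        bigrams = {g for g in f.vocabulary if " " in g}
        assert bigrams == {"a b", "c d"}

    def test_max_vocab_one_keeps_most_frequent(self):
        corpus = [ParticipantCorpus("p", [["x", "x", "y"]])]
        f = extract_ngrams(corpus, max_vocab=1)
        assert f.vocabulary == ["x"]

    def test_per_order_normalization(self, tiny_corpus):
        f = extract_ngrams(tiny_corpus, max_vocab=None)
        M = f.matrix.toarray()
        uni = f.orders == 1
        assert np.allclose(M[:, uni].sum(axis=1), 1.0, atol=1e-9)
        assert (M[:, ~uni].sum(axis=1) <= 1 + 1e-9).all()

    def test_empty_corpus_rejected(self):
        with pytest.raises(EmptyCorpusError):
            extract_ngrams([])
        with pytest.raises(EmptyCorpusError):
            extract_ngrams([ParticipantCorpus("p", [[]])])


class TestFitLda:
    def test_single_topic_degeneracy(self, tiny_corpus):
        model = fit_lda(tiny_corpus, n_topics=1, seed=0)
        # phi equals the pooled corpus unigram distribution
        # counts: a:3, b:4, c:2, d:1 over 10 tokens
        expected = {"a": 0.3, "b": 0.4, "c": 0.2, "d": 0.1}
        for w, p in zip(model.vocabulary, model.phi[0]):
            assert p == pytest.approx(expected[w])
        assert np.allclose(model.topic_given_word, 1.0)

    def test_bayes_rows_normalized(self, tiny_corpus):
        model = fit_lda(tiny_corpus, n_topics=3, max_iter=10, seed=1)
        assert np.allclose(model.phi.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(model.topic_given_word.sum(axis=1), 1.0, atol=1e-9)
        assert model.topic_prior.sum() == pytest.approx(1.0, abs=1e-9)

    def test_too_many_topics_rejected(self, tiny_corpus):
        with pytest.raises(InvalidParameterError):
            fit_lda(tiny_corpus, n_topics=10, seed=0)

    def test_seed_reproducibility(self, tiny_corpus):
        a = fit_lda(tiny_corpus, n_topics=2, max_iter=10, seed=5)
        b = fit_lda(tiny_corpus, n_topics=2, max_iter=10, seed=5)
        assert np.array_equal(a.phi, b.phi)

    def test_recovers_well_separated_topics(self):
        """Parameter recovery: greedy TV matching of fitted to true topics."""
        cfg = GeneratorConfig(
            n_participants=300, vocab_size=100, n_topics_true=5,
            words_per_participant=400, posts_per_participant=1,
            topic_concentration=0.01, condition_effects=[], seed=21,
        )
        corpus, truth = generate_corpus(cfg)
        model = fit_lda(corpus, n_topics=5, max_iter=50, seed=0)
        # embed fitted phi over the full generator vocabulary
        width = max(4, len(str(cfg.vocab_size - 1)))
        col = {f"w{i:0{width}d}": i for i in range(cfg.vocab_size)}
        phi = np.zeros((5, cfg.vocab_size))
        for j, w in enumerate(model.vocabulary):
            phi[:, col[w]] = model.phi[:, j]
        tv = 0.5 * np.abs(phi[:, None, :] - truth.topic_word[None, :, :]).sum(axis=2)
        matched, used, dists = set(), set(), []
        for _ in range(5):  # greedy best-pair matching
            best = None
            for i in range(5):
                for j in range(5):
                    if i in matched or j in used:
                        continue
                    if best is None or tv[i, j] < best[0]:
                        best = (tv[i, j], i, j)
            dists.append(best[0])
            matched.add(best[1])
            used.add(best[2])
        assert np.mean(dists) < 0.2


class TestScoreTopics:
    def test_hand_arithmetic(self):
        from langdx.encoding import NGramFrequencies, TopicModel
        import scipy.sparse as sp

        model = TopicModel(
            vocabulary=["u", "v"],
            phi=np.array([[0.5, 0.5], [0.5, 0.5]]),  # unused by scoring
            topic_prior=np.array([0.5, 0.5]),
            topic_given_word=np.array([[0.9, 0.1], [0.2, 0.8]]),
        )
        freqs = NGramFrequencies(
            vocabulary=["u", "v"],
            orders=np.ones(2, dtype=np.int8),
            matrix=sp.csr_matrix(np.array([[0.5, 0.5]])),
            participant_ids=["p"],
        )
        scores = score_topics(model, freqs)
        assert np.allclose(scores.matrix, [[0.55, 0.45]], atol=1e-12)

    def test_matches_brute_force_double_loop(self, tiny_corpus):
        model = fit_lda(tiny_corpus, n_topics=2, max_iter=10, seed=2)
        freqs = unigram_frequencies(tiny_corpus, model.vocabulary)
        scores = score_topics(model, freqs)
        F = freqs.matrix.toarray()
        brute = np.zeros_like(scores.matrix)
        for i in range(F.shape[0]):
            for t in range(model.n_topics):
                for j in range(len(model.vocabulary)):
                    brute[i, t] += model.topic_given_word[j, t] * F[i, j]
        assert np.abs(scores.matrix - brute).max() < 1e-12

    def test_single_topic_scores_equal_coverage_mass(self, tiny_corpus):
        model = fit_lda(tiny_corpus, n_topics=1, seed=0)
        freqs = unigram_frequencies(tiny_corpus, model.vocabulary)
        scores = score_topics(model, freqs)
        assert np.allclose(scores.matrix, 1.0, atol=1e-9)

    def test_out_of_vocabulary_participant_warns_zero_row(self):
        corpus = [
            ParticipantCorpus("in", [["a", "b"]]),
            ParticipantCorpus("out", [["z", "z"]]),
        ]
        model = fit_lda([corpus[0]], n_topics=1, seed=0)
        freqs = unigram_frequencies(corpus)
        with pytest.warns(UserWarning, match="no in-vocabulary"):
            scores = score_topics(model, freqs)
        assert scores.matrix[1].sum() == 0.0
        assert scores.matrix[0].sum() == pytest.approx(1.0)


class TestTopWords:
    def _uniform_model(self, words):
        from langdx.encoding import TopicModel

        v = len(words)
        return TopicModel(
            vocabulary=list(words),
            phi=np.full((1, v), 1.0 / v),
            topic_prior=np.array([1.0]),
            topic_given_word=np.ones((v, 1)),
        )

    def test_dominant_word_ranked_first(self):
        from langdx.encoding import TopicModel

        model = TopicModel(
            vocabulary=["x", "y", "z"],
            phi=np.array([[0.05, 0.9, 0.05]]),
            topic_prior=np.array([1.0]),
            topic_given_word=np.ones((3, 1)),
        )
        out = top_words(model, 0, n=3)
        assert out[0][0] == "y"
        sizes = [s for _, _, s in out]
        assert sizes == sorted(sizes, reverse=True) and sizes[0] == 1.0

    def test_ties_break_lexicographically(self):
        out = top_words(self._uniform_model(["pear", "apple", "mango"]), 0, n=3)
        assert [w for w, _, _ in out] == ["apple", "mango", "pear"]

    def test_n_larger_than_vocab_clamps(self):
        out = top_words(self._uniform_model(list("abcde")), 0, n=15)
        assert len(out) == 5
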