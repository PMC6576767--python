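import warnings

import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from langdx.encoding import ParticipantCorpus
from langdx.synthetic import ConditionEffect, GeneratorConfig, simulate_study


@pytest.fixture
def tiny_corpus():
    """Three hand-built participants with known counts."""
    return [
        ParticipantCorpus("alice", [["a", "b", "a"]]),
        ParticipantCorpus("bob", [["a", "b"], ["c", "d"]]),
        ParticipantCorpus("carol", [["b", "b", "c"]]),
    ]


@pytest.fixture(scope="session")
def planted_study():
    """Small synthetic study with a strong planted effect on topic 0."""
    coefs = np.zeros(5)
    coefs[0] = 8.0
    cfg = GeneratorConfig(
        n_participants=300,
        vocab_size=100,
        n_topics_true=5,
        words_per_participant=300,
        posts_per_participant=5,
        topic_concentration=0.01,
        condition_effects=[ConditionEffect("planted", intercept=-1.2, topic_coefs=coefs)],
        seed=7,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cfg, simulate_study(cfg)
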