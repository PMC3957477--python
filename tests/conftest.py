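import numpy as np
import pytest

from cisclust import (
    Background0,
    MaskedSequence,
    build_scoring_matrix,
    consensus_pwm,
    score_distribution,
)

# Probe printed in the source methods; anchor core TGATTAAT at [14, 22),
# Meis core TGACAG at [1, 7), edge-to-edge gap 7.
MEIS_II_PROBE = "ATGACAGCTCGGAATGATTAATGGCCCAAATA"


@pytest.fixture(scope="session")
def uniform_bg():
    return Background0.uniform()


@pytest.fixture(scope="session")
def anchor_cm():
    return consensus_pwm("TGATTAAT", 97, motif_id="anchor")


@pytest.fixture(scope="session")
def meis_cm():
    return consensus_pwm("TGACAG", 97, motif_id="meis")


@pytest.fixture(scope="session")
def anchor_scan(uniform_bg, anchor_cm):
    sm = build_scoring_matrix(anchor_cm, uniform_bg)
    return sm, score_distribution(sm, uniform_bg)


@pytest.fixture(scope="session")
def meis_scan(uniform_bg, meis_cm):
    sm = build_scoring_matrix(meis_cm, uniform_bg)
    return sm, score_distribution(sm, uniform_bg)


@pytest.fixture
def probe_seq():
    return MaskedSequence("meis_ii_probe", MEIS_II_PROBE)


def enumerate_words(sm, bg):
    """Exhaustive oracle: exact score and probability of every 4^w word."""
    w = sm.width
    idx = np.indices((4,) * w).reshape(w, -1)
    scores = sm.scores[np.arange(w)[:, None], idx].sum(axis=0)
    probs = np.prod(bg.as_array()[idx], axis=0)
    return scores, probs


def exact_pvalue(scores, probs, s):
    return float(probs[scores >= s - 1e-12].sum())


def random_count_matrix(rng, width, motif_id="rand", low=1, high=30, pseudocount=0.25):
    from cisclust import CountMatrix

    counts = rng.integers(low, high, size=(width, 4)).astype(float)
    return CountMatrix(motif_id, counts, pseudocount)


def random_sequence(rng, length):
    return MaskedSequence("rand", "".join("ACGT"[i] for i in rng.integers(0, 4, length)))
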