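import numpy as np
import pytest

import graphser as g


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_corpus():
    """3 speakers x 2 well-separated emotions x 3 utterances, in memory."""
    profiles = {k: g.SEPARABLE5[k] for k in ("angry", "neutral")}
    table, utterances = g.generate_corpus(3, profiles, 3, rate_hz=16000, seed=11)
    return table, utterances


@pytest.fixture(scope="session")
def tiny_features(tiny_corpus):
    _, utterances = tiny_corpus
    return g.extract_features(utterances)


def brute_force_visibility(series):
    """Direct triple-loop evaluation of the visibility criterion."""
    x = np.asarray(series, dtype=float)
    n = x.size
    a = np.zeros((n, n), dtype=np.int8)
    for i in range(n):
        for j in range(i + 1, n):
            visible = True
            for k in range(i + 1, j):
                if not x[k] < x[i] + (x[j] - x[i]) * (k - i) / (j - i):
                    visible = False
                    break
            if visible:
                a[i, j] = a[j, i] = 1
    return a
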