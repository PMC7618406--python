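"""Shared fixtures: planted synthetic worlds and heavyweight model fits.

Session-scoped fixtures hold the expensive artifacts (a trained embedding
on the planted-topic corpus, the large 2PL recovery fit) so that unit,
property and acceptance tests reuse a single computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from semspace.cooccurrence import build_cooccurrence
from semspace.corpus import Corpus, Document, build_vocabulary
from semspace.glove import train_glove
from semspace.irt import BinaryResponseMatrix, fit_2pl
from semspace.synthetic import WorldSpec, generate_corpus


def cooccurrence_oracle(docs_tokens, vocab, window, weighting="inverse_distance"):
    """Exhaustive enumeration of in-window pairs (independent of the
    vectorized scan): O(n * window) nested loops on a dense matrix."""
    idx = {w: i for i, w in enumerate(vocab)}
    n = len(vocab)
    X = np.zeros((n, n))
    for tokens in docs_tokens:
        for i in range(len(tokens)):
            for d in range(1, window + 1):
                j = i + d
                if j >= len(tokens):
                    break
                a, b = tokens[i], tokens[j]
                if a in idx and b in idx:
                    w = 1.0 / d if weighting == "inverse_distance" else 1.0
                    ia, ib = idx[a], idx[b]
                    X[ia, ib] += w
                    if ia != ib:
                        X[ib, ia] += w
    return X


def make_corpus(texts: list[str]) -> Corpus:
    return Corpus(
        [Document(f"d{i}", t.split()) for i, t in enumerate(texts)], "math"
    )


@pytest.fixture(scope="session")
def planted_world():
    """Planted 5-topic corpus (200 topic words, ~2e5 tokens) with truth."""
    world = WorldSpec(
        n_topics=5, words_per_topic=40, n_docs=2000, doc_length=100, seed=1
    )
    corpus, truth = generate_corpus(world)
    vocab = [e.word for e in build_vocabulary(corpus, min_count=5)]
    X = build_cooccurrence(corpus, vocab, window=15)
    return {"world": world, "corpus": corpus, "truth": truth, "vocab": vocab, "X": X}


@pytest.fixture(scope="session")
def planted_embedding(planted_world):
    """25-dimensional embedding trained on the planted corpus."""
    return train_glove(planted_world["X"], dim=25, seed=0)


def topic_cosine_separation(emb, truth, vocab) -> float:
    """Mean intra-topic minus mean inter-topic cosine similarity."""
    topics: dict[int, list[str]] = {}
    for w in vocab:
        if w in truth.topic_of and not w.startswith("shapectx"):
            topics.setdefault(truth.topic_of[w], []).append(w)
    intra, inter = [], []
    keys = sorted(topics)
    units = {}
    for t in keys:
        V = emb.subset(topics[t])
        units[t] = V / np.linalg.norm(V, axis=1, keepdims=True)
    for ti in keys:
        C = units[ti] @ units[ti].T
        intra.extend(C[np.triu_indices(C.shape[0], k=1)].tolist())
        for tj in keys:
            if tj > ti:
                inter.extend((units[ti] @ units[tj].T).ravel().tolist())
    return float(np.mean(intra) - np.mean(inter))


@pytest.fixture(scope="session")
def irt_recovery():
    """2PL parameter-recovery simulation: 1000 participants x 100 items,
    a ~ U(0.5, 2.5), b ~ U(-2, 2), theta ~ N(0, 1)."""
    rng = np.random.default_rng(7)
    n_p, n_i = 1000, 100
    a = rng.uniform(0.5, 2.5, n_i)
    b = rng.uniform(-2.0, 2.0, n_i)
    theta = rng.normal(0.0, 1.0, n_p)
    P = 1.0 / (1.0 + np.exp(-a[None, :] * (theta[:, None] - b[None, :])))
    Y = (rng.random((n_p, n_i)) < P).astype(float)
    R = BinaryResponseMatrix(
        [f"p{i}" for i in range(n_p)], [f"it{j}" for j in range(n_i)], Y
    )
    fit = fit_2pl(R, seed=0)
    return {"a": a, "b": b, "theta": theta, "responses": R, "fit": fit}
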