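"""Windowed, distance-weighted word cooccurrence matrices.

Two vocabulary words cooccur when they appear within ``window`` token
positions of one another inside the same document.  Each unordered pair
occurrence at distance ``d`` contributes weight ``1/d`` (inverse-distance
weighting, the usual choice for log-bilinear embedding models) or ``1``
(uniform) to both the (i, j) and (j, i) cells; same-word pairs accumulate
on the diagonal once per occurrence.  Windows never cross document
boundaries, and tokens outside the vocabulary are skipped (they still
occupy positions, so they count toward the distance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .corpus import Corpus

__all__ = ["CooccurrenceMatrix", "build_cooccurrence"]


@dataclass
class CooccurrenceMatrix:
    """Symmetric sparse cooccurrence statistics over an ordered vocabulary."""

    vocab: list[str]
    X: sp.csr_matrix
    window: int
    weighting: str = "inverse_distance"
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {w: i for i, w in enumerate(self.vocab)}

    @property
    def nnz(self) -> int:
        return self.X.nnz

    def value(self, word_i: str, word_j: str) -> float:
        return float(self.X[self.index[word_i], self.index[word_j]])


def build_cooccurrence(
    corpus: Corpus,
    vocab: list[str],
    window: int = 15,
    weighting: str = "inverse_distance",
) -> CooccurrenceMatrix:
    """Scan a corpus and accumulate the windowed cooccurrence matrix.

    Parameters
    ----------
    corpus : lemmatized corpus to scan
    vocab : ordered vocabulary; tokens outside it are skipped
    window : maximal token distance (inclusive) for a pair to count
    weighting : ``inverse_distance`` (weight 1/d) or ``uniform`` (weight 1)
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not vocab:
        raise ValueError("vocab must be non-empty")
    if weighting not in ("inverse_distance", "uniform"):
        raise ValueError(f"unknown weighting {weighting!r}")
    index = {w: i for i, w in enumerate(vocab)}
    n = len(vocab)

    # Flatten all documents with a document index so the vectorized
    # offset scan can mask pairs that straddle a boundary.
    ids = np.empty(corpus.token_count, dtype=np.int64)
    doc_of = np.empty(corpus.token_count, dtype=np.int64)
    pos = 0
    for k, doc in enumerate(corpus.documents):
        for t in doc.tokens:
            ids[pos] = index.get(t, -1)
            doc_of[pos] = k
            pos += 1

    rows, cols, vals = [], [], []
    for d in range(1, window + 1):
        if d >= len(ids):
            break
        a, b = ids[:-d], ids[d:]
        ok = (a >= 0) & (b >= 0) & (doc_of[:-d] == doc_of[d:])
        if not ok.any():
            continue
        w = 1.0 / d if weighting == "inverse_distance" else 1.0
        rows.append(a[ok])
        cols.append(b[ok])
        vals.append(np.full(int(ok.sum()), w))

    if rows:
        i = np.concatenate(rows)
        j = np.concatenate(cols)
        v = np.concatenate(vals)
        S = sp.coo_matrix((v, (i, j)), shape=(n, n)).tocsr()
    else:
        S = sp.csr_matrix((n, n))
    X = (S + S.T).tolil()
    # Same-word pairs are counted once per occurrence, not doubled.
    X.setdiag(S.diagonal())
    return CooccurrenceMatrix(list(vocab), X.tocsr(), window, weighting)
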