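"""Plain-text I/O for corpora, vocabularies, embeddings and trial tables.

All tabular formats are UTF-8 TSV with a header row; embeddings use the
standard word-vector text dialect (one line per word: ``word v1 ... vd``,
optionally preceded by an ``N d`` header line).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cooccurrence import CooccurrenceMatrix
from .corpus import Corpus, Document, VocabularyEntry, vocabulary_frame
from .glove import EmbeddingSet

__all__ = [
    "save_corpus_lines",
    "load_corpus_lines",
    "save_vocabulary",
    "load_vocabulary",
    "save_embeddings",
    "load_embeddings",
    "save_cooccurrence",
    "load_cooccurrence",
    "save_table",
    "load_table",
]


def save_corpus_lines(corpus: Corpus, path: str | Path) -> None:
    """One document per line, tokens space-separated."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc in corpus.documents:
            fh.write(" ".join(doc.tokens) + "\n")


def load_corpus_lines(
    path: str | Path, variant: str = "math", label: str | None = None
) -> Corpus:
    docs = []
    with open(path, encoding="utf-8") as fh:
        for k, line in enumerate(fh):
            tokens = line.split()
            if tokens:
                docs.append(Document(doc_id=f"doc{k}", tokens=tokens, label=label))
    return Corpus(docs, variant)


def save_vocabulary(entries: list[VocabularyEntry], path: str | Path) -> None:
    vocabulary_frame(entries).to_csv(path, sep="\t", index=False)


def load_vocabulary(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_embeddings(
    emb: EmbeddingSet, path: str | Path, header: bool = False
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"{len(emb.vocab)} {emb.dim}\n")
        for i, w in enumerate(emb.vocab):
            vec = " ".join(f"{x:.6g}" for x in emb.vectors[i])
            fh.write(f"{w} {vec}\n")


def load_embeddings(
    path: str | Path, corpus_variant: str = "math", seed: int = 0
) -> EmbeddingSet:
    words, rows = [], []
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().split()
        if len(first) == 2 and all(tok.isdigit() for tok in first):
            pass  # "N d" header line
        elif first:
            words.append(first[0])
            rows.append([float(x) for x in first[1:]])
        for line in fh:
            parts = line.split()
            if parts:
                words.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
    vectors = np.asarray(rows, dtype=float)
    return EmbeddingSet(
        vocab=words,
        vectors=vectors,
        biases=np.zeros(len(words)),
        dim=vectors.shape[1],
        corpus_variant=corpus_variant,
        seed=seed,
    )


def save_cooccurrence(X: CooccurrenceMatrix, path: str | Path) -> None:
    """Triplet TSV (word_i, word_j, weight) of the nonzero entries."""
    coo = X.X.tocoo()
    df = pd.DataFrame(
        {
            "word_i": [X.vocab[i] for i in coo.row],
            "word_j": [X.vocab[j] for j in coo.col],
            "weight": coo.data,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def load_cooccurrence(
    path: str | Path, window: int, weighting: str = "inverse_distance"
) -> CooccurrenceMatrix:
    import scipy.sparse as sp

    df = pd.read_csv(path, sep="\t")
    vocab = sorted(set(df["word_i"]) | set(df["word_j"]))
    index = {w: i for i, w in enumerate(vocab)}
    X = sp.coo_matrix(
        (
            df["weight"],
            ([index[w] for w in df["word_i"]], [index[w] for w in df["word_j"]]),
        ),
        shape=(len(vocab), len(vocab)),
    ).tocsr()
    return CooccurrenceMatrix(vocab, X, window, weighting)


def save_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
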