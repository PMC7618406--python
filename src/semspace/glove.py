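"""GloVe-style embeddings trained on a cooccurrence matrix.

The model fits word vectors ``w_i``, context vectors ``w̃_j`` and biases to
the log cooccurrence counts by weighted least squares, minimising

    sum over nonzero X_ij of  f(X_ij) (w_i·w̃_j + b_i + b̃_j − log X_ij)^2

with the saturating weight f(x) = (x/x_max)^alpha for x < x_max, else 1.
Optimisation is deterministic mini-batch AdaGrad: the nonzero entries are
shuffled in a fixed order derived from the seed and updates within a batch
are scatter-added, so repeated runs with the same seed give bit-identical
vectors.  The exported vector for a word is w_i + w̃_i.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator

from .cooccurrence import CooccurrenceMatrix

__all__ = [
    "EmbeddingSet",
    "GloVe",
    "train_glove",
    "train_constrained",
    "dimensionality_sweep",
    "DEFAULT_HYPER",
]

#: Training hyperparameter defaults (the standard choices for this model
#: family; only window size and dimensionality are study design choices).
DEFAULT_HYPER: dict = {
    "x_max": 100.0,
    "alpha": 0.75,
    "learning_rate": 0.05,
    "epochs": 50,
}


@dataclass
class EmbeddingSet:
    """Word -> d-dimensional vector map for one corpus variant.

    ``missing`` flags vocabulary words that carried no cooccurrence
    information during training (e.g. absent from an alternate corpus);
    their vectors are zero and must be excluded from similarity analyses.
    """

    vocab: list[str]
    vectors: np.ndarray  # (n_words, dim)
    biases: np.ndarray  # (n_words,) main + context bias sum
    dim: int
    corpus_variant: str = "math"
    seed: int = 0
    missing: frozenset[str] = frozenset()
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {w: i for i, w in enumerate(self.vocab)}
        if self.vectors.shape != (len(self.vocab), self.dim):
            raise ValueError("vectors shape inconsistent with vocab/dim")
        if not np.isfinite(self.vectors).all():
            raise ValueError("non-finite vectors")

    def vector(self, word: str) -> np.ndarray:
        return self.vectors[self.index[word]]

    def __contains__(self, word: str) -> bool:
        return word in self.index and word not in self.missing

    def subset(self, words: list[str]) -> np.ndarray:
        return self.vectors[[self.index[w] for w in words]]


class GloVe(BaseEstimator):
    """Weighted least-squares log-bilinear embedding estimator.

    Parameters
    ----------
    n_components : embedding dimensionality
    x_max, alpha : saturation point and exponent of the loss weight f
    learning_rate : AdaGrad base step size
    n_epochs : full passes over the nonzero cooccurrence entries
    batch_size : entries per deterministic mini-batch
    random_state : seed for initialisation and shuffling

    Attributes
    ----------
    vectors_ : (n_words, n_components) exported vectors, w + w̃
    biases_ : (n_words,) summed main and context biases
    loss_history_ : mean weighted squared error per epoch
    vocab_ : ordered vocabulary
    """

    def __init__(
        self,
        n_components: int = 50,
        x_max: float = 100.0,
        alpha: float = 0.75,
        learning_rate: float = 0.05,
        n_epochs: int = 50,
        batch_size: int = 1024,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.x_max = x_max
        self.alpha = alpha
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.batch_size = batch_size
        self.random_state = random_state

    def fit(self, X: CooccurrenceMatrix | sp.spmatrix, y=None) -> "GloVe":
        if isinstance(X, CooccurrenceMatrix):
            vocab = list(X.vocab)
            M = X.X.tocoo()
        else:
            M = sp.coo_matrix(X)
            vocab = [str(i) for i in range(M.shape[0])]
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        mask = M.data > 0
        ii = M.row[mask].astype(np.int64)
        jj = M.col[mask].astype(np.int64)
        xv = M.data[mask].astype(np.float64)
        if xv.size == 0:
            raise ValueError("cooccurrence matrix has no positive entry")

        n, d = len(vocab), self.n_components
        rng = np.random.default_rng(self.random_state)
        scale = 0.5 / d
        W = rng.uniform(-scale, scale, size=(n, d))
        Wc = rng.uniform(-scale, scale, size=(n, d))
        b = np.zeros(n)
        bc = np.zeros(n)
        # AdaGrad accumulators start at 1 so the first step is <= lr |g|
        Gw = np.ones((n, d))
        Gwc = np.ones((n, d))
        Gb = np.ones(n)
        Gbc = np.ones(n)

        logx = np.log(xv)
        f = np.minimum((xv / self.x_max) ** self.alpha, 1.0)
        lr = self.learning_rate
        nnz = xv.size
        losses = []
        for _epoch in range(self.n_epochs):
            order = rng.permutation(nnz)
            total = 0.0
            for start in range(0, nnz, self.batch_size):
                sel = order[start : start + self.batch_size]
                i, j = ii[sel], jj[sel]
                wi, wj = W[i], Wc[j]
                diff = np.einsum("ij,ij->i", wi, wj) + b[i] + bc[j] - logx[sel]
                fb = f[sel]
                total += 0.5 * float(np.sum(fb * diff * diff))
                g = fb * diff
                gw = g[:, None] * wj
                gwc = g[:, None] * wi
                # AdaGrad with accumulator values frozen at batch start;
                # scatter-adds make duplicate indices within a batch safe.
                np.add.at(W, i, -lr * gw / np.sqrt(Gw[i]))
                np.add.at(Wc, j, -lr * gwc / np.sqrt(Gwc[j]))
                np.add.at(b, i, -lr * g / np.sqrt(Gb[i]))
                np.add.at(bc, j, -lr * g / np.sqrt(Gbc[j]))
                np.add.at(Gw, i, gw * gw)
                np.add.at(Gwc, j, gwc * gwc)
                np.add.at(Gb, i, g * g)
                np.add.at(Gbc, j, g * g)
            if not np.isfinite(total):
                raise RuntimeError("training diverged: non-finite loss")
            losses.append(total / nnz)

        self.vocab_ = vocab
        self.vectors_ = W + Wc
        self.biases_ = b + bc
        self.loss_history_ = np.asarray(losses)
        self.n_features_in_ = n
        return self

    def embedding_set(
        self, corpus_variant: str = "math", missing: frozenset[str] = frozenset()
    ) -> EmbeddingSet:
        return EmbeddingSet(
            vocab=list(self.vocab_),
            vectors=self.vectors_.copy(),
            biases=self.biases_.copy(),
            dim=self.n_components,
            corpus_variant=corpus_variant,
            seed=self.random_state,
            missing=missing,
        )


def _make_estimator(dim: int, hyper: dict | None, seed: int) -> GloVe:
    h = dict(DEFAULT_HYPER)
    if hyper:
        h.update(hyper)
    return GloVe(
        n_components=dim,
        x_max=h["x_max"],
        alpha=h["alpha"],
        learning_rate=h["learning_rate"],
        n_epochs=h["epochs"],
        random_state=seed,
    )


def train_glove(
    X: CooccurrenceMatrix,
    dim: int = 50,
    hyper: dict | None = None,
    seed: int = 0,
    corpus_variant: str = "math",
) -> EmbeddingSet:
    """Train embeddings of dimensionality ``dim`` on a cooccurrence matrix."""
    est = _make_estimator(dim, hyper, seed).fit(X)
    out = est.embedding_set(corpus_variant)
    out.loss_history = est.loss_history_  # type: ignore[attr-defined]
    return out


def train_constrained(
    X_alt: CooccurrenceMatrix,
    vocab: list[str],
    dim: int = 50,
    hyper: dict | None = None,
    seed: int = 0,
    corpus_variant: str = "nonmath",
) -> EmbeddingSet:
    """Train on an alternate corpus while imposing an external vocabulary.

    Words of ``vocab`` with no cooccurrence mass in ``X_alt`` receive a
    flagged zero vector (``missing``) and must be excluded downstream.
    """
    alt_index = X_alt.index
    present = [w for w in vocab if w in alt_index]
    if not present:
        raise ValueError("imposed vocabulary shares no word with the corpus")
    rowsel = np.array([alt_index[w] for w in present])
    sub = X_alt.X[rowsel][:, rowsel]
    # Drop words whose restricted rows are empty: no information at all.
    rowmass = np.asarray(abs(sub).sum(axis=1)).ravel()
    keep = rowmass > 0
    trained_words = [w for w, k in zip(present, keep) if k]
    if not trained_words:
        raise ValueError("no imposed-vocabulary word has cooccurrence mass")
    sub = sub[keep][:, keep]
    subX = CooccurrenceMatrix(trained_words, sub.tocsr(), X_alt.window, X_alt.weighting)
    est = _make_estimator(dim, hyper, seed).fit(subX)
    vectors = np.zeros((len(vocab), dim))
    biases = np.zeros(len(vocab))
    tr_index = {w: i for i, w in enumerate(trained_words)}
    missing = []
    for i, w in enumerate(vocab):
        if w in tr_index:
            vectors[i] = est.vectors_[tr_index[w]]
            biases[i] = est.biases_[tr_index[w]]
        else:
            missing.append(w)
    if missing:
        warnings.warn(
            f"{len(missing)} imposed-vocabulary words absent from the "
            "alternate corpus; flagged as missing"
        )
    return EmbeddingSet(
        vocab=list(vocab),
        vectors=vectors,
        biases=biases,
        dim=dim,
        corpus_variant=corpus_variant,
        seed=seed,
        missing=frozenset(missing),
    )


def default_dimension_grid() -> list[int]:
    """Dimensionality sweep grid: 1..50 plus 100..500 in steps of 50."""
    return list(range(1, 51)) + list(range(100, 501, 50))


def dimensionality_sweep(
    X: CooccurrenceMatrix,
    dims: list[int],
    hyper: dict | None = None,
    seed: int = 0,
    corpus_variant: str = "math",
) -> dict[int, EmbeddingSet]:
    """Train one embedding set per requested dimensionality.

    Each dimensionality uses the base seed offset by its index so sweeps
    are reproducible but not trivially correlated.  Failures for a single
    dimensionality are reported and do not abort the rest of the sweep.
    """
    if not dims:
        raise ValueError("dims must be non-empty")
    out: dict[int, EmbeddingSet] = {}
    for k, dim in enumerate(dims):
        try:
            out[dim] = train_glove(
                X, dim=dim, hyper=hyper, seed=seed + k, corpus_variant=corpus_variant
            )
        except (ValueError, RuntimeError) as exc:  # pragma: no cover - rare
            warnings.warn(f"dimensionality {dim} failed: {exc}")
    return out
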