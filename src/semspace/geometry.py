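"""Geometric probes of the embedding space.

These operations examine whether the embedding geometry carries
interpretable structure: principal-component projections (e.g. number
words ordering by log magnitude along PC1), projections onto an anchor
axis joining two reference words (e.g. "one" to "billion"), consistency
of analogy offset vectors, a global cluster map (spectral clustering with
elbow-selected k, 2-d layout, Voronoi cells around projected centers),
and within- versus between-domain similarity contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats as ss
from scipy.spatial import QhullError, Voronoi
from sklearn.base import BaseEstimator
from sklearn.cluster import SpectralClustering
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .glove import EmbeddingSet
from .similarity import cosine

__all__ = [
    "Projection1D",
    "SemanticMap",
    "pca_project",
    "axis_project",
    "analogy_offsets",
    "SemanticMapper",
    "semantic_map",
    "domain_contrast",
]


@dataclass
class Projection1D:
    """Scalar coordinates of words along a one-dimensional basis."""

    coordinates: dict[str, float]
    basis: str
    sign_convention: tuple[str, str] | None = None


@dataclass
class SemanticMap:
    """A clustered 2-d layout of the embedding space."""

    words: list[str]
    cluster_id: np.ndarray
    k: int
    coords2d: np.ndarray  # (n_words, 2)
    centers2d: np.ndarray  # (k, 2)
    voronoi_cells: list | None
    dispersion_curve: dict[int, float]
    seed: int


def _as_matrix(vectors, words: list[str] | None = None):
    """Accept an EmbeddingSet or a word->vector mapping; return (words, V)."""
    if isinstance(vectors, EmbeddingSet):
        if words is None:
            words = [w for w in vectors.vocab if w in vectors]
        missing = [w for w in words if w not in vectors]
        if missing:
            raise KeyError(f"words without embeddings: {missing[:5]}")
        return list(words), vectors.subset(list(words))
    mapping = dict(vectors)
    if words is None:
        words = list(mapping)
    missing = [w for w in words if w not in mapping]
    if missing:
        raise KeyError(f"words without embeddings: {missing[:5]}")
    return list(words), np.asarray([mapping[w] for w in words], dtype=float)


def pca_project(
    vectors,
    words: list[str] | None = None,
    n_components: int = 2,
    sign_ref: tuple[str, str] | None = None,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Mean-centered principal-component coordinates of a word subset.

    Components come in decreasing explained-variance order.  If
    ``sign_ref = (w_lo, w_hi)`` is given, each component's sign is set so
    that ``w_lo`` has the smaller coordinate, making plots reproducible.

    Returns ``(words, coords, explained_variance_ratio)``.
    """
    words, V = _as_matrix(vectors, words)
    if len(words) < n_components + 1:
        raise ValueError("need more points than components")
    pca = PCA(n_components=n_components, random_state=0)
    coords = pca.fit_transform(V)
    if sign_ref is not None:
        ia, ib = words.index(sign_ref[0]), words.index(sign_ref[1])
        for c in range(n_components):
            if coords[ia, c] > coords[ib, c]:
                coords[:, c] *= -1.0
    return words, coords, pca.explained_variance_ratio_


def axis_project(
    vectors, anchor_a: str, anchor_b: str, targets: list[str]
) -> Projection1D:
    """Project words onto the unit axis from ``anchor_a`` to ``anchor_b``.

    The coordinate of a word w is ``t(w) = <v_w - v_a, d>`` with d the
    unit direction ``(v_b - v_a)/||v_b - v_a||``, so t(a) = 0 and
    t(b) = ||v_b - v_a||.  Invariant under global translation,
    equivariant under global scaling.
    """
    names, V = _as_matrix(vectors, [anchor_a, anchor_b] + list(targets))
    va, vb = V[0], V[1]
    diff = vb - va
    norm = np.linalg.norm(diff)
    if norm == 0:
        raise ValueError("anchors have identical embeddings")
    d = diff / norm
    coords = {w: float(np.dot(V[i] - va, d)) for i, w in enumerate(names)}
    return Projection1D(
        coordinates=coords,
        basis=f"anchor_axis({anchor_a},{anchor_b})",
        sign_convention=(anchor_a, anchor_b),
    )


def analogy_offsets(
    vectors, pairs: list[tuple[str, str]]
) -> tuple[np.ndarray, float]:
    """Offset vectors target - source per pair, and their consistency.

    Consistency is the mean pairwise cosine similarity between offsets:
    1 for a perfect parallelogram structure, about 0 for unrelated
    offsets in high dimension.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 analogy pairs")
    sources = [p[0] for p in pairs]
    targets = [p[1] for p in pairs]
    names, V = _as_matrix(vectors, sources + targets)
    n = len(pairs)
    offsets = V[n:] - V[:n]
    sims = [
        cosine(offsets[i], offsets[j]) for i in range(n) for j in range(i + 1, n)
    ]
    return offsets, float(np.mean(sims))


class SemanticMapper(BaseEstimator):
    """Cluster map estimator: spectral clustering + elbow + 2-d layout.

    Spectral clustering runs once per k over ``k_range`` on a cosine
    affinity (clipped at zero); k* maximises the discrete second
    difference of the within-cluster dispersion curve (the elbow).  All
    vectors and the k* cluster centers are then embedded jointly in 2-d
    with t-SNE, and Voronoi cells are computed around the projected
    centers (requires at least 4 centers; otherwise cells are omitted
    with a warning).

    Attributes
    ----------
    labels_ : cluster assignment per word
    k_ : selected number of clusters
    coords2d_, centers2d_ : 2-d layout of points and cluster centers
    voronoi_cells_ : scipy Voronoi region vertex arrays per cluster, or None
    dispersion_ : within-cluster dispersion per candidate k
    """

    def __init__(
        self,
        k_range: tuple[int, int] = (2, 100),
        perplexity: float = 30.0,
        random_state: int = 0,
    ):
        self.k_range = k_range
        self.perplexity = perplexity
        self.random_state = random_state

    def fit(self, X, y=None) -> "SemanticMapper":
        V = np.asarray(X, dtype=float)
        n = V.shape[0]
        lo = max(2, self.k_range[0])
        hi = min(self.k_range[1], n - 1)
        if (lo, hi) != tuple(self.k_range):
            warnings.warn(f"k_range clipped to [{lo}, {hi}]")
        if hi < lo:
            raise ValueError("k_range admits no valid k")
        norms = np.linalg.norm(V, axis=1)
        safe = np.where(norms == 0, 1.0, norms)
        U = V / safe[:, None]
        affinity = np.clip(U @ U.T, 0.0, None)
        np.fill_diagonal(affinity, 1.0)

        labels_per_k: dict[int, np.ndarray] = {}
        dispersion: dict[int, float] = {}
        for k in range(lo, hi + 1):
            sc = SpectralClustering(
                n_clusters=k,
                affinity="precomputed",
                random_state=self.random_state,
                assign_labels="kmeans",
                n_init=10,
            )
            labels = sc.fit_predict(affinity)
            labels_per_k[k] = labels
            w = 0.0
            for c in np.unique(labels):
                pts = V[labels == c]
                w += float(((pts - pts.mean(axis=0)) ** 2).sum())
            dispersion[k] = w

        ks = sorted(dispersion)
        if len(ks) >= 3:
            second = {
                ks[i]: dispersion[ks[i - 1]] - 2 * dispersion[ks[i]] + dispersion[ks[i + 1]]
                for i in range(1, len(ks) - 1)
            }
            k_star = max(second, key=lambda k: (second[k], -k))
        else:
            warnings.warn("k_range too narrow for the elbow rule; using smallest k")
            k_star = ks[0]
        labels = labels_per_k[k_star]
        centers = np.vstack(
            [V[labels == c].mean(axis=0) for c in range(k_star)]
        )

        stacked = np.vstack([V, centers])
        perp = min(self.perplexity, max(2.0, (stacked.shape[0] - 1) / 3.0))
        tsne = TSNE(
            n_components=2,
            perplexity=perp,
            random_state=self.random_state,
            init="pca",
        )
        coords = tsne.fit_transform(stacked)
        self.labels_ = labels
        self.k_ = int(k_star)
        self.coords2d_ = coords[:n]
        self.centers2d_ = coords[n:]
        self.dispersion_ = dispersion
        self.voronoi_cells_ = self._voronoi_cells(self.centers2d_)
        self.n_features_in_ = V.shape[1]
        return self

    @staticmethod
    def _voronoi_cells(centers: np.ndarray):
        if centers.shape[0] < 4:
            warnings.warn("fewer than 4 cluster centers: Voronoi cells omitted")
            return None
        try:
            vor = Voronoi(centers)
        except QhullError:  # pragma: no cover - degenerate geometry
            warnings.warn("degenerate center configuration: Voronoi cells omitted")
            return None
        cells = []
        for c in range(centers.shape[0]):
            region = vor.regions[vor.point_region[c]]
            if -1 in region or not region:
                cells.append(None)  # unbounded cell
            else:
                cells.append(vor.vertices[region])
        return cells


def semantic_map(
    vectors,
    words: list[str] | None = None,
    k_range: tuple[int, int] = (2, 100),
    seed: int = 0,
    perplexity: float = 30.0,
) -> SemanticMap:
    """Build a :class:`SemanticMap` for a word subset (see SemanticMapper)."""
    words, V = _as_matrix(vectors, words)
    est = SemanticMapper(k_range=k_range, perplexity=perplexity, random_state=seed).fit(V)
    return SemanticMap(
        words=words,
        cluster_id=est.labels_,
        k=est.k_,
        coords2d=est.coords2d_,
        centers2d=est.centers2d_,
        voronoi_cells=est.voronoi_cells_,
        dispersion_curve=est.dispersion_,
        seed=seed,
    )


def domain_contrast(
    vectors, domain_labels: dict[str, str], domains: tuple[str, str]
) -> dict:
    """Within- versus between-domain cosine similarity contrast.

    Intra-domain similarities pool the unordered within-domain pairs of
    both domains; inter-domain similarities are all cross-domain pairs.
    Returns the group moments and a pooled two-sample t statistic with
    ``df = n_intra + n_inter - 2``.
    """
    da, db = domains
    words_a = [w for w, d in domain_labels.items() if d == da]
    words_b = [w for w, d in domain_labels.items() if d == db]
    if len(words_a) < 2 or len(words_b) < 2:
        raise ValueError("each domain needs at least 2 words")
    _, Va = _as_matrix(vectors, words_a)
    _, Vb = _as_matrix(vectors, words_b)

    def _pair_cosines(V):
        out = []
        for i in range(V.shape[0]):
            for j in range(i + 1, V.shape[0]):
                out.append(cosine(V[i], V[j]))
        return out

    intra = np.array(_pair_cosines(Va) + _pair_cosines(Vb))
    inter = np.array(
        [cosine(u, v) for u in Va for v in Vb]
    )
    df = intra.size + inter.size - 2
    if intra.std(ddof=1) == 0 and inter.std(ddof=1) == 0:
        raise ValueError("t statistic undefined: zero variance in both groups")
    t, p = ss.ttest_ind(intra, inter, equal_var=True)
    return {
        "intra_mean": float(intra.mean()),
        "intra_sd": float(intra.std(ddof=1)),
        "inter_mean": float(inter.mean()),
        "inter_sd": float(inter.std(ddof=1)),
        "t": float(t),
        "df": int(df),
        "p": float(p),
        "n_intra": int(intra.size),
        "n_inter": int(inter.size),
    }
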