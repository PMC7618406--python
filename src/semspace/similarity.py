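"""Comparison of embedding-predicted similarity with human ratings.

This module covers the behavioral analysis chain: stratified pair
selection from an embedding space, aggregation of per-trial similarity
ratings, rank-based correlation and regression, leave-one-out noise
ceiling (the upper bound on explainable variance), AIC model comparison,
category contrasts, and per-group (word grade / participant education)
breakdowns across corpus variants.

Trial tables are plain pandas DataFrames:

- similarity trials: columns ``participant_id, word_a, word_b, rating``
  (optionally ``category, grade_group``), ratings real in [0, 5];
- familiarity trials: columns ``participant_id, word, rating``, integer
  ratings in 0..8;
- participants: ``participant_id, education, self_assessment, age_band,
  sex`` with education drawn from :data:`semspace.corpus.EDUCATION_LEVELS`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as ss
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .corpus import GRADE_GROUPS
from .glove import EmbeddingSet

__all__ = [
    "PAIR_CATEGORIES",
    "WordPair",
    "CorrelationResult",
    "RegressionResult",
    "ModelComparison",
    "cosine",
    "euclidean",
    "pair_key",
    "select_pairs",
    "mean_grade_similarity",
    "aggregate_ratings",
    "rank_transform",
    "spearman",
    "RankGLM",
    "fit_rank_glm",
    "noise_ceiling",
    "compare_models_aic",
    "category_contrast",
    "percentile_bin",
    "fit_by_group",
]

#: Fixed reporting order of the stratified pair categories.
PAIR_CATEGORIES: tuple[str, ...] = ("close", "mean", "orthogonal", "opposite")


@dataclass
class WordPair:
    """A selected word pair with its predicted cosine and design category."""

    word_a: str
    word_b: str
    grade_group: str
    category: str
    predicted_cosine: float

    @property
    def key(self) -> tuple[str, str]:
        return pair_key(self.word_a, self.word_b)


@dataclass
class CorrelationResult:
    """A rank correlation with its sample size and significance."""

    r_s: float
    n: int
    p: float

    @property
    def r_squared(self) -> float:
        return self.r_s**2


@dataclass
class RegressionResult:
    """A rank-OLS fit: per-term coefficients plus fit statistics."""

    coefficients: dict[str, tuple[float, float, float]]  # name -> (beta, t, p)
    r_squared: float
    f_statistic: float
    f_pvalue: float
    df_model: int
    df_resid: int
    aic: float
    nobs: int
    response: np.ndarray = field(repr=False, default=None)


@dataclass
class ModelComparison:
    """Relative evidence for a set of models on the same response."""

    aic: dict[str, float]
    delta_aic: dict[str, float]
    p: dict[str, float]
    preferred: str


def pair_key(word_a: str, word_b: str) -> tuple[str, str]:
    """Canonical unordered key for a word pair."""
    return (word_a, word_b) if word_a <= word_b else (word_b, word_a)


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity ⟨u,v⟩ / (‖u‖·‖v‖), in [-1, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("dimension mismatch")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine undefined for a zero vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def euclidean(u: np.ndarray, v: np.ndarray) -> float:
    """Euclidean distance sqrt(sum (u_i - v_i)^2)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("dimension mismatch")
    return float(np.linalg.norm(u - v))


def _cosine_matrix(V: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(V, axis=1)
    if (norms == 0).any():
        raise ValueError("zero vector in embedding subset")
    U = V / norms[:, None]
    return np.clip(U @ U.T, -1.0, 1.0)


def mean_grade_similarity(
    embeddings: EmbeddingSet, words: list[str]
) -> tuple[float, float, int]:
    """Moments of cosine similarity over all unordered same-group pairs.

    Returns ``(mu, sigma, n_pairs)`` where sigma is the population
    standard deviation over the pair list.
    """
    words = [w for w in words if w in embeddings]
    if len(words) < 2:
        raise ValueError("need at least 2 embedded words in the group")
    C = _cosine_matrix(embeddings.subset(words))
    iu = np.triu_indices(len(words), k=1)
    vals = C[iu]
    return float(vals.mean()), float(vals.std()), int(vals.size)


def select_pairs(
    embeddings: EmbeddingSet,
    word_groups: pd.DataFrame,
    k_per_category: int = 3,
) -> list[WordPair]:
    """Stratified pair selection from the embedding space.

    For each target word, among the candidates sharing its grade group,
    select the ``k`` words of maximal cosine (category ``close``), minimal
    cosine (``opposite``), minimal \\|cosine\\| (``orthogonal``) and cosine
    closest to the group's mean pairwise cosine (``mean``).  Pairs are
    deduplicated across targets on the unordered key; the
    first-encountered category is kept and collisions are logged.

    Parameters
    ----------
    embeddings : embedding set providing the vectors
    word_groups : DataFrame with columns ``word`` and ``grade_group``
    k_per_category : pairs per target and category (default 3)
    """
    if k_per_category < 1:
        raise ValueError("k_per_category must be >= 1")
    seen: dict[tuple[str, str], WordPair] = {}
    n_collisions = 0
    for group, sub in word_groups.groupby("grade_group", sort=False):
        words = [w for w in sub["word"] if w in embeddings]
        if len(words) < 2:
            continue
        if len(words) < 4 * k_per_category + 1:
            warnings.warn(
                f"grade group {group!r} has only {len(words)} embedded words; "
                "selecting as many pairs as available"
            )
        C = _cosine_matrix(embeddings.subset(words))
        iu = np.triu_indices(len(words), k=1)
        mu = float(C[iu].mean())
        for ti, target in enumerate(words):
            cand = [(c, words[ci]) for ci, c in enumerate(C[ti]) if ci != ti]
            crit = {
                "close": sorted(cand, key=lambda cw: (-cw[0], cw[1])),
                "opposite": sorted(cand, key=lambda cw: (cw[0], cw[1])),
                "orthogonal": sorted(cand, key=lambda cw: (abs(cw[0]), cw[1])),
                "mean": sorted(cand, key=lambda cw: (abs(cw[0] - mu), cw[1])),
            }
            for category in PAIR_CATEGORIES:
                for c, other in crit[category][:k_per_category]:
                    pair = WordPair(target, other, group, category, float(c))
                    if pair.key in seen:
                        n_collisions += 1
                        continue
                    seen[pair.key] = pair
    if n_collisions:
        warnings.warn(f"{n_collisions} duplicate pair selections merged")
    return list(seen.values())


def aggregate_ratings(trials: pd.DataFrame) -> pd.DataFrame:
    """Average ratings per unordered word pair over all trials.

    Returns a DataFrame indexed by the canonical pair key with columns
    ``mean_rating`` and ``n_trials``; the grand mean over trials is kept
    in ``df.attrs['grand_mean']`` (the mean of means differs from it when
    trial counts differ across pairs).
    """
    if trials.empty:
        return pd.DataFrame(columns=["mean_rating", "n_trials"])
    keys = [pair_key(a, b) for a, b in zip(trials["word_a"], trials["word_b"])]
    df = trials.assign(_key=keys)
    agg = df.groupby("_key")["rating"].agg(["mean", "count"])
    agg.columns = ["mean_rating", "n_trials"]
    agg.index.name = "pair"
    agg.attrs["grand_mean"] = float(trials["rating"].mean())
    return agg


def rank_transform(values) -> np.ndarray:
    """Ranks 1..n with mean ranks assigned to ties."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot rank an empty sequence")
    if not np.isfinite(values).all():
        raise ValueError("non-finite values cannot be ranked")
    return ss.rankdata(values, method="average")


def spearman(x, y) -> CorrelationResult:
    """Spearman rank-order correlation with a two-sided t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    rx, ry = rank_transform(x), rank_transform(y)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("correlation undefined: zero rank variance")
    r, p = ss.spearmanr(x, y)
    return CorrelationResult(r_s=float(r), n=int(x.size), p=float(p))


class RankGLM(BaseEstimator):
    """Ordinary least squares on rank-transformed variables.

    Every predictor and the response are rank-transformed (mean-rank
    ties); interaction terms are products of main-effect ranks, themselves
    re-ranked for scale comparability; an intercept is added explicitly.

    Attributes
    ----------
    result_ : :class:`RegressionResult`
    sm_result_ : the underlying statsmodels OLS results object
    terms_ : design term names in fit order
    """

    def __init__(self, interactions: bool = True):
        self.interactions = interactions

    def fit(self, X: pd.DataFrame, y) -> "RankGLM":
        y = np.asarray(y, dtype=float)
        names = list(X.columns)
        mains = {c: rank_transform(X[c].to_numpy()) for c in names}
        design: dict[str, np.ndarray] = dict(mains)
        if self.interactions:
            from itertools import combinations

            for r in range(2, len(names) + 1):
                for combo in combinations(names, r):
                    prod = np.prod([mains[c] for c in combo], axis=0)
                    design[":".join(combo)] = rank_transform(prod)
        terms = list(design)
        Xmat = np.column_stack([design[t] for t in terms])
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), Xmat])) < (
            Xmat.shape[1] + 1
        ):
            culprits = _collinear_terms(Xmat, terms)
            raise ValueError(f"rank-deficient design; collinear terms: {culprits}")
        yr = rank_transform(y)
        exog = sm.add_constant(
            pd.DataFrame(Xmat, columns=terms), prepend=True, has_constant="add"
        )
        res = sm.OLS(yr, exog).fit()
        coeffs = {
            term: (float(res.params[term]), float(res.tvalues[term]), float(res.pvalues[term]))
            for term in exog.columns
        }
        self.sm_result_ = res
        self.terms_ = terms
        self.result_ = RegressionResult(
            coefficients=coeffs,
            r_squared=float(res.rsquared),
            f_statistic=float(res.fvalue),
            f_pvalue=float(res.f_pvalue),
            df_model=int(res.df_model),
            df_resid=int(res.df_resid),
            aic=float(res.aic),
            nobs=int(res.nobs),
            response=yr,
        )
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:  # pragma: no cover - thin
        raise NotImplementedError(
            "rank OLS is descriptive: ranks are sample-relative, so "
            "out-of-sample prediction is not defined"
        )


def _collinear_terms(Xmat: np.ndarray, terms: list[str]) -> list[str]:
    """Name terms involved in exact collinearity (for error messages)."""
    bad = []
    for k in range(Xmat.shape[1]):
        others = np.delete(Xmat, k, axis=1)
        base = np.column_stack([np.ones(Xmat.shape[0]), others])
        if np.linalg.matrix_rank(np.column_stack([base, Xmat[:, k]])) == np.linalg.matrix_rank(base):
            bad.append(terms[k])
    return bad


def fit_rank_glm(
    table: pd.DataFrame,
    response: str,
    predictors: list[str],
    interactions: bool = True,
) -> RegressionResult:
    """Rank-OLS of ``response`` on ``predictors`` and their interactions."""
    est = RankGLM(interactions=interactions).fit(table[predictors], table[response])
    return est.result_


def noise_ceiling(
    trials: pd.DataFrame,
    grouping: pd.Series | dict | None = None,
    min_shared: int = 3,
) -> float | dict[str, float]:
    """Leave-one-out estimate of the explainable variance in ratings.

    For each participant, their ratings are correlated (Pearson) with the
    leave-one-out mean rating of every pair they share with at least one
    other participant; the squared correlations are averaged.  With
    ``grouping`` (participant_id -> subgroup label), subgroup ceilings are
    returned: each member is still referenced against the leave-one-out
    mean over *all* participants, since subgroup overlap alone can be too
    sparse.

    Participants sharing fewer than ``min_shared`` pairs with the rest of
    the panel are skipped with a warning.
    """
    keys = [pair_key(a, b) for a, b in zip(trials["word_a"], trials["word_b"])]
    df = trials.assign(_key=keys)
    wide = df.pivot_table(
        index="participant_id", columns="_key", values="rating", aggfunc="mean"
    )
    vals = wide.to_numpy()
    seen = ~np.isnan(vals)
    col_sum = np.nansum(vals, axis=0)
    col_n = seen.sum(axis=0)

    r2 = {}
    n_skipped = 0
    for pi, pid in enumerate(wide.index):
        mask = seen[pi] & (col_n >= 2)
        if mask.sum() < min_shared:
            n_skipped += 1
            continue
        own = vals[pi, mask]
        loo = (col_sum[mask] - own) / (col_n[mask] - 1)
        if own.std() == 0 or loo.std() == 0:
            n_skipped += 1
            continue
        r = np.corrcoef(own, loo)[0, 1]
        r2[pid] = r * r
    if n_skipped:
        warnings.warn(
            f"{n_skipped} participants skipped (insufficient overlap or "
            "constant ratings)"
        )
    if not r2:
        raise ValueError("no participant had enough shared pairs")
    if grouping is None:
        return float(np.mean(list(r2.values())))
    grouping = dict(grouping)
    out: dict[str, float] = {}
    for g in sorted(set(grouping.values()), key=str):
        members = [v for pid, v in r2.items() if grouping.get(pid) == g]
        if members:
            out[g] = float(np.mean(members))
    return out


def compare_models_aic(fits: dict[str, RegressionResult]) -> ModelComparison:
    """Akaike comparison of fits sharing the same response vector.

    ΔAIC_i = AIC_i − AIC_min and the associated evidence probability is
    p_i = exp(−ΔAIC_i / 2); the preferred model has ΔAIC = 0, p = 1.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    names = list(fits)
    ref = fits[names[0]].response
    for name in names[1:]:
        other = fits[name].response
        if ref is None or other is None or len(ref) != len(other) or not np.allclose(ref, other):
            raise ValueError("fits must share an identical response vector")
    aic = {name: float(fits[name].aic) for name in names}
    amin = min(aic.values())
    delta = {name: a - amin for name, a in aic.items()}
    p = {name: math.exp(-d / 2.0) for name, d in delta.items()}
    preferred = min(names, key=lambda nm: (aic[nm], nm))
    return ModelComparison(aic=aic, delta_aic=delta, p=p, preferred=preferred)


def _dunn_tests(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's post-hoc z tests on pooled ranks, Bonferroni-adjusted."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    ranks = rank_transform(pooled)
    n_total = pooled.size
    mean_rank = {}
    start = 0
    for g in names:
        k = groups[g].size
        mean_rank[g] = ranks[start : start + k].mean()
        start += k
    # tie correction on the pooled sample
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    m = len(names) * (len(names) - 1) // 2
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            gi, gj = names[i], names[j]
            se = math.sqrt(var_base * (1.0 / groups[gi].size + 1.0 / groups[gj].size))
            z = (mean_rank[gi] - mean_rank[gj]) / se
            p = 2.0 * ss.norm.sf(abs(z))
            rows.append(
                {
                    "group_a": gi,
                    "group_b": gj,
                    "z": z,
                    "p_raw": p,
                    "p_adjusted": min(1.0, p * m),
                }
            )
    return pd.DataFrame(rows)


def category_contrast(trials: pd.DataFrame) -> dict:
    """Omnibus and pairwise contrasts of ratings across pair categories.

    Returns category means (fixed order close, mean, orthogonal,
    opposite), the Kruskal-Wallis H and p, and Dunn's pairwise z tests
    with Bonferroni adjustment.
    """
    groups: dict[str, np.ndarray] = {}
    for cat in PAIR_CATEGORIES:
        vals = trials.loc[trials["category"] == cat, "rating"].to_numpy(dtype=float)
        if vals.size < 2:
            warnings.warn(f"category {cat!r} has fewer than 2 trials; excluded")
            continue
        groups[cat] = vals
    if len(groups) < 2:
        raise ValueError("need at least 2 populated categories")
    means = {cat: float(v.mean()) for cat, v in groups.items()}
    all_same = len({v for g in groups.values() for v in g.tolist()}) == 1
    if all_same:
        H, p = 0.0, 1.0
    else:
        H, p = ss.kruskal(*groups.values())
    return {
        "means": means,
        "H": float(H),
        "p": float(p),
        "n": int(sum(v.size for v in groups.values())),
        "dunn": _dunn_tests(groups),
    }


def percentile_bin(x, y, n_bins: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Equal-count binning of (x, y) along sorted x; per-bin means.

    The remainder when ``len(x)`` is not divisible by ``n_bins`` is spread
    over the first bins.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < n_bins:
        raise ValueError("fewer points than bins")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    xb = [chunk.mean() for chunk in np.array_split(xs, n_bins)]
    yb = [chunk.mean() for chunk in np.array_split(ys, n_bins)]
    return np.asarray(xb), np.asarray(yb)


def fit_by_group(
    trials: pd.DataFrame,
    embeddings: dict[str, EmbeddingSet],
    grouping: str = "grade_group",
    participants: pd.DataFrame | None = None,
    min_pairs: int = 3,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-group correlation of mean rating with embedding cosine, for each
    corpus variant, plus a monotone-trend test per variant.

    ``grouping`` is ``"grade_group"`` (pairs grouped by the word grade at
    selection) or ``"education"`` (trials grouped by participant
    education, requiring ``participants``).  The trend statistic is the
    Spearman correlation of the group's rank order with its within-group
    r_s.
    """
    if grouping == "education":
        if participants is None:
            raise ValueError("education grouping requires the participants table")
        edu = participants.set_index("participant_id")["education"]
        trials = trials.assign(_group=trials["participant_id"].map(edu))
        from .corpus import EDUCATION_LEVELS as ORDER
    elif grouping == "grade_group":
        trials = trials.assign(_group=trials["grade_group"])
        ORDER = GRADE_GROUPS
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    rows = []
    groups_present = [g for g in ORDER if g in set(trials["_group"])]
    for g in groups_present:
        sub = trials[trials["_group"] == g]
        agg = aggregate_ratings(sub)
        for variant, emb in embeddings.items():
            sims, ratings = [], []
            for (wa, wb), mean_rating in agg["mean_rating"].items():
                if wa in emb and wb in emb:
                    sims.append(cosine(emb.vector(wa), emb.vector(wb)))
                    ratings.append(mean_rating)
            if len(sims) < min_pairs:
                warnings.warn(f"group {g!r} / variant {variant!r} omitted (<{min_pairs} pairs)")
                continue
            try:
                res = spearman(ratings, sims)
            except ValueError:
                warnings.warn(f"group {g!r} / variant {variant!r}: correlation undefined")
                continue
            rows.append(
                {"group": g, "variant": variant, "r_s": res.r_s, "n": res.n, "p": res.p}
            )
    table = pd.DataFrame(rows)
    trends: dict[str, float] = {}
    for variant in embeddings:
        sub = table[table["variant"] == variant]
        if len(sub) < 3 or sub["r_s"].nunique() == 1:
            warnings.warn(f"trend test degenerate for variant {variant!r}")
            trends[variant] = float("nan")
            continue
        gr = [groups_present.index(g) for g in sub["group"]]
        trends[variant] = spearman(gr, sub["r_s"].to_numpy()).r_s
    return table, trends
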