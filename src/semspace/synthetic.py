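"""Synthetic corpora and behavioral data with known ground truth.

Every stage of the analysis pipeline is testable by parameter recovery on
data from this module:

- :func:`generate_corpus` plants topical word clusters (with a
  configurable cross-topic leakage), a log-magnitude gradient among
  number words, and analogy quadruples (number-shape pairs sharing
  context), and returns the generative pairwise similarity as ground
  truth;
- :func:`generate_participants` samples education levels (defaults follow
  the skewed distribution typical of online math-interested panels) and
  links a latent ability to education with calibrated noise;
- :func:`generate_familiarity` produces graded 0-8 ratings from an
  ordered-threshold (graded response) model, so that downstream
  dichotomization at >=4 recovers the planted 2PL difficulty;
- :func:`generate_similarity` maps a true cosine through a convex
  monotone link onto the 0-5 rating scale and adds calibrated noise.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as ss

from .corpus import (
    Corpus,
    Document,
    EDUCATION_LEVELS,
    EDUCATION_TO_GROUP,
    GRADE_GROUPS,
)

__all__ = [
    "WorldSpec",
    "BehaviorSpec",
    "GroundTruth",
    "generate_corpus",
    "generate_participants",
    "make_item_bank",
    "generate_familiarity",
    "generate_similarity",
    "calibrate_similarity_noise",
    "convex_link",
    "planted_magnitude_vectors",
    "planted_offset_quadruples",
    "DEFAULT_EDUCATION_PROBS",
]

#: Education distribution defaults: proportions observed in a large online
#: panel recruited through social media (heavily skewed toward the
#: university-educated).
DEFAULT_EDUCATION_PROBS: tuple[float, ...] = tuple(
    np.array([4, 8, 232, 58, 170, 199, 122, 304, 133], dtype=float)
    / 1230.0
)

#: Ordered cut-points of the 9-level familiarity scale on the latent
#: logistic metric; the 4th cut-point sits at zero so that the known /
#: unknown dichotomization boundary coincides with the planted difficulty.
DEFAULT_CUTPOINTS: tuple[float, ...] = (-3.0, -2.0, -1.0, 0.0, 1.0, 2.0, 3.0, 4.0)


@dataclass
class WorldSpec:
    """Parameters of the synthetic world behind a corpus."""

    n_topics: int = 5
    words_per_topic: int = 40
    n_number_words: int = 12
    n_quadruples: int = 4
    n_docs: int = 2000
    doc_length: int = 100
    topic_mixing: float = 0.1
    number_doc_share: float = 0.15
    analogy_doc_share: float = 0.05
    vocab_cap: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.topic_mixing <= 1.0:
            raise ValueError("topic_mixing must lie in [0, 1]")


@dataclass
class BehaviorSpec:
    """Parameters of the simulated participant panel and rating process."""

    n_participants: int = 300
    education_probs: tuple[float, ...] = DEFAULT_EDUCATION_PROBS
    ability_slope: float = 1.0
    sigma_theta: float = 0.9
    self_assessment_target: float = 0.55
    cutpoints: tuple[float, ...] = DEFAULT_CUTPOINTS
    n_familiarity_words: int = 50
    pairs_per_group: int = 20
    gamma: float = 2.0
    noise_sd: float = 0.8
    participant_offset_sd: float = 0.0
    attention: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.education_probs, dtype=float)
        if probs.size != len(EDUCATION_LEVELS):
            raise ValueError("education_probs must have 9 entries")
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("education_probs must sum to 1")
        cps = np.asarray(self.cutpoints)
        if not (np.diff(cps) > 0).all():
            raise ValueError("cut-points must be strictly increasing")


@dataclass
class GroundTruth:
    """Generative structure of a synthetic corpus."""

    words: list[str]
    features: np.ndarray  # (n_words, n_latent) latent feature vectors
    topic_of: dict[str, int]
    log_magnitude: dict[str, float]
    quadruples: list[tuple[str, str]]  # (number word, shape word)
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {w: i for i, w in enumerate(self.words)}

    def similarity(self, word_a: str, word_b: str) -> float:
        u = self.features[self.index[word_a]]
        v = self.features[self.index[word_b]]
        return float(
            np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        )

    def similarity_matrix(self, words: list[str] | None = None) -> np.ndarray:
        words = words or self.words
        V = self.features[[self.index[w] for w in words]]
        norms = np.linalg.norm(V, axis=1)
        U = V / norms[:, None]
        return np.clip(U @ U.T, -1.0, 1.0)


def _latent_features(spec: WorldSpec, words, topic_of, log_mag, quadruples):
    """Latent vectors whose cosines define the planted similarity."""
    n_mag = 8
    n_latent = spec.n_topics + n_mag + 2  # + number domain + shape domain
    feats = np.zeros((len(words), n_latent))
    mags = [log_mag[w] for w in log_mag]
    lo, hi = (min(mags), max(mags)) if mags else (0.0, 1.0)
    centers = np.linspace(lo, hi, n_mag)
    width = (hi - lo) / n_mag + 1e-9

    def bumps(m):
        return np.exp(-0.5 * ((m - centers) / width) ** 2)

    shape_of = {s: n for n, s in quadruples}
    for i, w in enumerate(words):
        if w in log_mag:
            feats[i, spec.n_topics + n_mag] = 1.0
            feats[i, spec.n_topics : spec.n_topics + n_mag] = bumps(log_mag[w])
        elif w in shape_of:
            feats[i, spec.n_topics + n_mag + 1] = 1.0
            feats[i, spec.n_topics : spec.n_topics + n_mag] = 0.8 * bumps(
                log_mag[shape_of[w]]
            )
        else:
            t = topic_of[w]
            feats[i, : spec.n_topics] = spec.topic_mixing / spec.n_topics
            feats[i, t] += 1.0 - spec.topic_mixing
    return feats


def generate_corpus(spec: WorldSpec) -> tuple[Corpus, GroundTruth]:
    """Generate a corpus with planted topical and magnitude structure.

    Documents sample a topic and draw words mostly within-topic (leakage
    controlled by ``topic_mixing``); number documents center on a
    magnitude and draw magnitude-neighbouring number words; analogy
    documents pair each number with its shape word amid shared context.
    """
    rng = np.random.default_rng(spec.seed)
    topic_words = [
        [f"t{t}w{j}" for j in range(spec.words_per_topic)]
        for t in range(spec.n_topics)
    ]
    number_words = [f"num{i}" for i in range(spec.n_number_words)]
    n_quad = min(spec.n_quadruples, spec.n_number_words)
    shape_words = [f"shape{i}" for i in range(n_quad)]
    ctx_words = [f"shapectx{j}" for j in range(4)] if n_quad else []
    words = [w for ws in topic_words for w in ws] + number_words + shape_words + ctx_words
    if len(words) > spec.vocab_cap:
        raise ValueError("world vocabulary exceeds the configured cap")

    topic_of = {w: t for t, ws in enumerate(topic_words) for w in ws}
    for w in ctx_words:  # context words live in topic 0's neighbourhood
        topic_of[w] = 0
    # quasi-logarithmic magnitudes: successive numbers roughly double
    log_mag = {w: 0.3 * i for i, w in enumerate(number_words)}
    quadruples = [(number_words[i], shape_words[i]) for i in range(n_quad)]

    docs: list[Document] = []
    all_topic = [w for ws in topic_words for w in ws]
    p_num = spec.number_doc_share if number_words else 0.0
    p_ana = spec.analogy_doc_share if quadruples else 0.0
    for d in range(spec.n_docs):
        u = rng.random()
        if u < p_num:
            c = rng.integers(spec.n_number_words)
            weights = np.exp(-np.abs(np.arange(spec.n_number_words) - c) / 1.0)
            weights /= weights.sum()
            tokens = list(rng.choice(number_words, size=spec.doc_length, p=weights))
        elif u < p_num + p_ana:
            q = rng.integers(len(quadruples))
            num, shape = quadruples[q]
            pool = [num, shape] + ctx_words
            tokens = list(rng.choice(pool, size=spec.doc_length))
        else:
            t = int(rng.integers(spec.n_topics))
            tokens = []
            leak = rng.random(spec.doc_length) < spec.topic_mixing
            for k in range(spec.doc_length):
                pool = all_topic if leak[k] else topic_words[t]
                tokens.append(pool[rng.integers(len(pool))])
        docs.append(Document(doc_id=f"doc{d}", tokens=tokens, label="math"))

    truth = GroundTruth(
        words=words,
        features=_latent_features(spec, words, topic_of, log_mag, quadruples),
        topic_of=topic_of,
        log_magnitude=log_mag,
        quadruples=quadruples,
    )
    return Corpus(docs, "math"), truth


def _calibrate_self_noise(probs, slope, sigma_theta, target, n=20_000, seed=12345):
    """Binary-search the self-assessment noise sd to hit the target
    Spearman correlation between self-assessment and education."""
    rng = np.random.default_rng(seed)
    edu = rng.choice(len(probs), size=n, p=probs)
    edu_z = (edu - edu.mean()) / (edu.std() + 1e-12)
    theta = slope * edu_z + rng.normal(0, sigma_theta, n)
    extra = rng.normal(0, 1, n)

    def corr_at(sigma):
        return ss.spearmanr(theta + sigma * extra, edu).statistic

    if corr_at(0.0) < target:
        warnings.warn(
            "ability link too noisy to reach the self-assessment target; "
            "using zero extra noise"
        )
        return 0.0
    lo, hi = 0.0, 20.0
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        if corr_at(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_participants(spec: BehaviorSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample a participant panel with education-linked latent ability.

    Returns the participants table (participant_id, education,
    self_assessment, age_band, sex, theta) and the true ability vector.
    Self-assessment (1-10) is a discretized noisy readout of ability,
    calibrated so that Spearman(self-assessment, education) matches
    ``self_assessment_target``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants
    probs = np.asarray(spec.education_probs)
    if n == 0:
        return (
            pd.DataFrame(
                columns=[
                    "participant_id",
                    "education",
                    "self_assessment",
                    "age_band",
                    "sex",
                    "theta",
                ]
            ),
            np.empty(0),
        )
    edu_idx = rng.choice(len(EDUCATION_LEVELS), size=n, p=probs)
    edu_z = (edu_idx - edu_idx.mean()) / (edu_idx.std() + 1e-12)
    theta = spec.ability_slope * edu_z + rng.normal(0, spec.sigma_theta, n)
    sigma_self = _calibrate_self_noise(
        probs, spec.ability_slope, spec.sigma_theta, spec.self_assessment_target
    )
    self_latent = theta + sigma_self * rng.normal(0, 1, n)
    # deciles of the latent readout -> 1..10 scale
    qs = np.quantile(self_latent, np.linspace(0.1, 0.9, 9))
    self_assessment = 1 + np.searchsorted(qs, self_latent)
    df = pd.DataFrame(
        {
            "participant_id": [f"p{i:05d}" for i in range(n)],
            "education": [EDUCATION_LEVELS[i] for i in edu_idx],
            "education_rank": edu_idx,
            "self_assessment": self_assessment,
            "age_band": rng.choice(["18-25", "25-40", "40-60", ">60"], size=n),
            "sex": rng.choice(["female", "male"], size=n),
            "theta": theta,
        }
    )
    return df, theta


def make_item_bank(
    words: list[str],
    seed: int = 0,
    a_range: tuple[float, float] = (0.5, 2.5),
    b_range: tuple[float, float] = (-2.0, 2.0),
    grades: dict[str, int] | None = None,
    grade_slope: float = 0.8,
    logfreqs: dict[str, float] | None = None,
    freq_slope: float = 0.4,
    b_noise: float = 0.3,
) -> pd.DataFrame:
    """True item parameters for the familiarity generator.

    Discriminations are a ~ U(a_range).  Difficulties are b ~ U(b_range)
    by default; with ``grades`` (and optionally ``logfreqs``) they are
    instead planted as ``b = grade_slope * grade_z - freq_slope *
    logfreq_z + noise`` so that familiarity decreases with word grade and
    increases with corpus frequency.
    """
    rng = np.random.default_rng(seed)
    a = rng.uniform(*a_range, len(words))
    if grades is None:
        b = rng.uniform(*b_range, len(words))
    else:
        g = np.array([grades[w] for w in words], dtype=float)
        b = grade_slope * (g - g.mean()) / (g.std() + 1e-12)
        if logfreqs is not None:
            f = np.array([logfreqs[w] for w in words], dtype=float)
            b = b - freq_slope * (f - f.mean()) / (f.std() + 1e-12)
        b = b + rng.normal(0, b_noise, len(words))
    return pd.DataFrame({"word": words, "a": a, "b": b})


def generate_familiarity(
    participants: pd.DataFrame,
    items: pd.DataFrame,
    cutpoints: tuple[float, ...] = DEFAULT_CUTPOINTS,
    n_words: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Graded familiarity ratings from an ordered-threshold model.

    Each participant rates ``n_words`` randomly assigned words; the
    latent response is ``a (theta - b)`` plus standard logistic noise and
    the rating is the number of cut-points it exceeds (0..8).
    """
    cps = np.asarray(cutpoints, dtype=float)
    if not (np.diff(cps) > 0).all():
        raise ValueError("cut-points must be strictly increasing")
    rng = np.random.default_rng(seed)
    words = items["word"].to_numpy()
    a = items["a"].to_numpy()
    b = items["b"].to_numpy()
    if (a <= 0).any():
        raise ValueError("item discriminations must be positive")
    take = min(n_words, len(words))
    rows = []
    for pid, theta in zip(participants["participant_id"], participants["theta"]):
        sel = rng.choice(len(words), size=take, replace=False)
        z = a[sel] * (theta - b[sel]) + rng.logistic(0, 1, take)
        ratings = (z[:, None] > cps[None, :]).sum(axis=1)
        for w, r in zip(words[sel], ratings):
            rows.append((pid, w, int(r)))
    return pd.DataFrame(rows, columns=["participant_id", "word", "rating"])


def convex_link(
    s, gamma: float = 2.0, scale: float = 5.0, floor: float = 0.0
) -> np.ndarray:
    """Convex monotone map from true cosine to the 0-5 rating scale.

    Default ``g(s) = scale * max(s, 0)^gamma`` (convex on [0, 1] for
    gamma > 1, flat below 0).  A ``floor`` in (0, 1) mixes in a weak
    linear component over [-1, 1], ``floor * scale * (s + 1)/2``, keeping
    the map convex but strictly monotone over the whole cosine range so
    that opposite pairs land below orthogonal ones in expectation.
    """
    s = np.asarray(s, dtype=float)
    g = np.clip(s, 0.0, None) ** gamma
    return scale * ((1.0 - floor) * g + floor * (s + 1.0) / 2.0)


def calibrate_similarity_noise(pair_values, target_ceiling: float) -> float:
    """Noise sd such that the explainable-variance ceiling of ratings
    ``value + N(0, sd)`` equals ``target_ceiling``:
    ``sd = sqrt(var(values) (1 - c) / c)``."""
    if not 0.0 < target_ceiling < 1.0:
        raise ValueError("target ceiling must lie in (0, 1)")
    v = float(np.var(np.asarray(pair_values, dtype=float)))
    return float(np.sqrt(v * (1.0 - target_ceiling) / target_ceiling))


def generate_similarity(
    participants: pd.DataFrame,
    pairs: pd.DataFrame,
    gamma: float = 2.0,
    noise_sd: float = 0.8,
    participant_offset_sd: float = 0.0,
    pairs_per_group: int = 20,
    attention: float = 0.0,
    tracking: float = 0.0,
    floor: float = 0.0,
    assign: str = "design",
    clip: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Similarity trials: a convex transform of true cosine plus noise.

    ``pairs`` needs columns ``word_a, word_b, grade_group, true_cosine``
    (optionally ``category`` and ``alt_cosine``).  Under
    ``assign='design'`` each participant sees ``pairs_per_group`` pairs
    from every grade group at or below their education level;
    ``assign='all'`` shows every pair to everyone.

    Two ability-linked mechanisms can be planted: with ``attention > 0``
    the per-trial noise shrinks for high-ability participants
    (``sd * exp(-attention * theta_z)``); with ``tracking > 0`` (and an
    ``alt_cosine`` column) each participant rates a blend
    ``w * true + (1 - w) * alt`` with ``w = clip(0.5 + tracking *
    theta_z, 0, 1)``, so only educated raters track the primary
    similarity structure.  ``floor`` is forwarded to :func:`convex_link`.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if assign not in ("design", "all"):
        raise ValueError("assign must be 'design' or 'all'")
    rng = np.random.default_rng(seed)
    has_cat = "category" in pairs.columns
    theta = participants["theta"].to_numpy() if "theta" in participants else np.zeros(len(participants))
    theta_z = (theta - theta.mean()) / (theta.std() + 1e-12) if len(theta) > 1 else theta
    group_order = {g: i for i, g in enumerate(GRADE_GROUPS)}
    by_group = {g: sub.reset_index(drop=True) for g, sub in pairs.groupby("grade_group")}

    frames = []
    for k, row in enumerate(participants.itertuples(index=False)):
        offset = rng.normal(0, participant_offset_sd) if participant_offset_sd else 0.0
        sd = noise_sd * np.exp(-attention * theta_z[k])
        if assign == "all":
            shown = pairs
        else:
            ceiling = group_order[EDUCATION_TO_GROUP[row.education]]
            parts = []
            for g, sub in by_group.items():
                if group_order[g] <= ceiling:
                    take = min(pairs_per_group, len(sub))
                    parts.append(sub.iloc[rng.choice(len(sub), take, replace=False)])
            if not parts:
                continue
            shown = pd.concat(parts)
        s_true = shown["true_cosine"].to_numpy()
        if tracking > 0.0 and "alt_cosine" in shown.columns:
            w = float(np.clip(0.5 + tracking * theta_z[k], 0.0, 1.0))
            s_true = w * s_true + (1.0 - w) * shown["alt_cosine"].to_numpy()
        g_of_s = convex_link(s_true, gamma=gamma, floor=floor)
        rating = g_of_s + offset + rng.normal(0, sd, len(shown))
        if clip:
            rating = np.clip(rating, 0.0, 5.0)
        frame = pd.DataFrame(
            {
                "participant_id": row.participant_id,
                "word_a": shown["word_a"].to_numpy(),
                "word_b": shown["word_b"].to_numpy(),
                "grade_group": shown["grade_group"].to_numpy(),
                "rating": rating,
            }
        )
        if has_cat:
            frame.insert(4, "category", shown["category"].to_numpy())
        frames.append(frame)
    if not frames:
        cols = ["participant_id", "word_a", "word_b", "grade_group", "rating"]
        if has_cat:
            cols.insert(4, "category")
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)


def planted_magnitude_vectors(
    n: int = 22, dim: int = 50, noise_sd: float = 0.05, seed: int = 0
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Vectors carrying a planted log-magnitude direction.

    Word i sits at ``log10(magnitude_i)`` along a fixed random unit
    direction plus isotropic noise; magnitudes are log-spaced from 1 to
    1000.  Returns (words, vectors, log magnitudes).
    """
    rng = np.random.default_rng(seed)
    mags = np.logspace(0, 3, n)
    logm = np.log10(mags)
    direction = rng.normal(size=dim)
    direction /= np.linalg.norm(direction)
    V = logm[:, None] * direction[None, :] + rng.normal(0, noise_sd, (n, dim))
    words = [f"num{i}" for i in range(n)]
    return words, V, logm


def planted_offset_quadruples(
    n_pairs: int = 6,
    dim: int = 50,
    noise_sd: float = 0.1,
    offset_norm: float = 3.0,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], list[tuple[str, str]]]:
    """Source/target vector pairs sharing one offset, plus per-pair noise.

    Returns a word->vector mapping and the (source, target) pair list.
    """
    rng = np.random.default_rng(seed)
    offset = rng.normal(size=dim)
    offset *= offset_norm / np.linalg.norm(offset)
    vectors: dict[str, np.ndarray] = {}
    pairs = []
    for i in range(n_pairs):
        src = rng.normal(size=dim)
        tgt = src + offset + rng.normal(0, noise_sd, dim)
        vectors[f"src{i}"] = src
        vectors[f"tgt{i}"] = tgt
        pairs.append((f"src{i}", f"tgt{i}"))
    return vectors, pairs
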