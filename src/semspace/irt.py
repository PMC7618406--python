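"""Two-parameter logistic (2PL) item response theory for familiarity data.

Familiarity ratings on the 0-8 scale are dichotomized into unknown
(ratings 0-3) versus known (ratings 4-8).  The probability that a
participant with latent ability θ knows item i is modeled as

    T_i(1 | θ) = 1 / (1 + exp(-a_i (θ - b_i)))

with discrimination a_i > 0 and difficulty b_i.  Items are estimated by
marginal maximum likelihood via EM with fixed Gaussian quadrature over a
standard-normal ability prior; abilities are scored by their posterior
mean (EAP).  Curation drops items with extreme discrimination (above the
9th decile) or difficulty (outside the central 95%), mirroring the fact
that very skewed response patterns are not identifiable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as ss
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .similarity import CorrelationResult, spearman

__all__ = [
    "BinaryResponseMatrix",
    "IRTItem",
    "IRTFit",
    "dichotomize",
    "p_correct_2pl",
    "TwoPL",
    "fit_2pl",
    "curate_items",
    "select_discriminative_subset",
    "irt_descriptive_concordance",
]


@dataclass
class BinaryResponseMatrix:
    """Participants x items responses in {0, 1}, NaN where unobserved."""

    participants: list
    items: list[str]
    data: np.ndarray  # float array, entries 0.0 / 1.0 / NaN

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (len(self.participants), len(self.items)):
            raise ValueError("data shape inconsistent with labels")

    def degenerate_items(self) -> list[str]:
        """Items whose observed responses are all 0 or all 1."""
        out = []
        for j, item in enumerate(self.items):
            col = self.data[:, j]
            obs = col[~np.isnan(col)]
            if obs.size == 0 or obs.min() == obs.max():
                out.append(item)
        return out


@dataclass
class IRTItem:
    item_id: str
    a: float
    b: float
    se_a: float = float("nan")
    se_b: float = float("nan")
    convergence_flag: bool = True


@dataclass
class IRTFit:
    items: list[IRTItem]
    abilities: dict
    ability_se: dict = field(default_factory=dict)
    log_likelihood: float = float("nan")
    n_iterations: int = 0
    ll_history: np.ndarray = field(default_factory=lambda: np.empty(0))
    excluded_items: list[str] = field(default_factory=list)

    def item_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item_id": [it.item_id for it in self.items],
                "a": [it.a for it in self.items],
                "b": [it.b for it in self.items],
                "se_a": [it.se_a for it in self.items],
                "se_b": [it.se_b for it in self.items],
                "converged": [it.convergence_flag for it in self.items],
            }
        )


def dichotomize(trials: pd.DataFrame, threshold: int = 3) -> BinaryResponseMatrix:
    """Binarize familiarity trials: rating <= threshold -> 0, else 1.

    ``trials`` has columns ``participant_id, word, rating`` with integer
    ratings in 0..8; unobserved participant-word cells stay missing.
    """
    ratings = trials["rating"].to_numpy()
    if ((ratings < 0) | (ratings > 8)).any():
        raise ValueError("familiarity ratings must lie in 0..8")
    wide = trials.pivot_table(
        index="participant_id", columns="word", values="rating", aggfunc="last"
    )
    data = wide.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        binary = np.where(np.isnan(data), np.nan, (data > threshold).astype(float))
    return BinaryResponseMatrix(
        participants=list(wide.index), items=list(wide.columns), data=binary
    )


def p_correct_2pl(theta, a, b):
    """2PL response probability 1 / (1 + exp(-a (theta - b)))."""
    a = np.asarray(a, dtype=float)
    if (a <= 0).any() if a.ndim else a <= 0:
        raise ValueError("discrimination a must be positive")
    z = a * (np.asarray(theta, dtype=float) - np.asarray(b, dtype=float))
    return 1.0 / (1.0 + np.exp(-z))


class TwoPL(BaseEstimator):
    """Marginal maximum-likelihood 2PL estimator (EM, fixed quadrature).

    Parameters
    ----------
    n_quadrature : nodes of the fixed grid over the ability prior
    theta_range : grid end points
    tol : max absolute parameter change declaring convergence
    max_iter : EM iteration cap
    a_bounds : admissible discrimination interval; estimates pinned at a
        bound have their convergence flag cleared (Heywood-type cases)
    newton_steps : Newton iterations per item per M-step (with
        step-halving, so the expected complete-data likelihood never
        decreases and EM monotonicity is preserved)

    Attributes
    ----------
    discrimination_, difficulty_ : (n_items,) estimates
    se_a_, se_b_ : delta-method standard errors
    abilities_, ability_se_ : (n_participants,) EAP scores and posterior sd
    log_likelihood_, ll_history_ : marginal log-likelihood trace
    converged_items_ : per-item convergence flags
    n_iter_ : EM iterations run
    """

    def __init__(
        self,
        n_quadrature: int = 61,
        theta_range: tuple[float, float] = (-6.0, 6.0),
        tol: float = 1e-5,
        max_iter: int = 500,
        a_bounds: tuple[float, float] = (0.05, 10.0),
        newton_steps: int = 5,
        random_state: int = 0,
    ):
        self.n_quadrature = n_quadrature
        self.theta_range = theta_range
        self.tol = tol
        self.max_iter = max_iter
        self.a_bounds = a_bounds
        self.newton_steps = newton_steps
        self.random_state = random_state

    def fit(self, X, y=None) -> "TwoPL":
        if isinstance(X, BinaryResponseMatrix):
            data = X.data
        else:
            data = np.asarray(X, dtype=float)
        n_p, n_i = data.shape
        if n_p < 2 or n_i < 2:
            raise ValueError("need at least 2 participants and 2 items")
        obs = ~np.isnan(data)
        Y = np.where(obs, data, 0.0)
        M = obs.astype(float)

        nodes = np.linspace(*self.theta_range, self.n_quadrature)
        logw = ss.norm.logpdf(nodes)
        logw -= logsumexp(logw)

        # moment-based warm start
        p_obs = np.clip(Y.sum(0) / np.maximum(M.sum(0), 1.0), 0.02, 0.98)
        a = np.ones(n_i)
        b = -ss.norm.ppf(p_obs)
        ll_history = []
        lo, hi = self.a_bounds
        for it in range(1, self.max_iter + 1):
            # E-step: participant posteriors over the quadrature grid
            z = a[None, :] * (nodes[:, None] - b[None, :])  # (Q, I)
            logP = -np.logaddexp(0.0, -z)
            log1mP = -np.logaddexp(0.0, z)
            L = Y @ logP.T + (M - Y) @ log1mP.T  # (N, Q)
            L += logw[None, :]
            lse = logsumexp(L, axis=1)
            post = np.exp(L - lse[:, None])
            ll = float(lse.sum())
            ll_history.append(ll)

            n_q = post.T @ M  # (Q, I) expected exposure
            r_q = post.T @ Y  # (Q, I) expected endorsements

            a_new, b_new = self._m_step(nodes, n_q, r_q, a, b)
            delta = max(np.abs(a_new - a).max(), np.abs(b_new - b).max())
            a, b = a_new, b_new
            if delta < self.tol:
                break

        a = np.clip(a, lo, hi)
        pinned = (a <= lo) | (a >= hi)
        if delta < self.tol:
            self.converged_items_ = ~pinned
        else:  # EM hit max_iter: nothing is certified converged
            self.converged_items_ = np.zeros(n_i, dtype=bool)

        # final E-step quantities for scoring and SEs
        z = a[None, :] * (nodes[:, None] - b[None, :])
        logP = -np.logaddexp(0.0, -z)
        log1mP = -np.logaddexp(0.0, z)
        L = Y @ logP.T + (M - Y) @ log1mP.T + logw[None, :]
        lse = logsumexp(L, axis=1)
        post = np.exp(L - lse[:, None])
        self.log_likelihood_ = float(lse.sum())
        self.abilities_ = post @ nodes
        second = post @ nodes**2
        self.ability_se_ = np.sqrt(np.maximum(second - self.abilities_**2, 0.0))

        n_q = post.T @ M
        self.se_a_, self.se_b_ = self._standard_errors(nodes, n_q, a, b)
        self.discrimination_ = a
        self.difficulty_ = b
        self.ll_history_ = np.asarray(ll_history)
        self.n_iter_ = it
        return self

    def _m_step(self, nodes, n_q, r_q, a, b):
        """Per-item Newton updates of (slope, intercept) on the expected
        complete-data likelihood, with step-halving to guarantee ascent."""
        lo, hi = self.a_bounds
        a_new = a.copy()
        b_new = b.copy()
        for j in range(a.size):
            slope, inter = a[j], -a[j] * b[j]
            nj, rj = n_q[:, j], r_q[:, j]

            def objective(s, c):
                zz = s * nodes + c
                return float(np.sum(rj * (-np.logaddexp(0.0, -zz)) + (nj - rj) * (-np.logaddexp(0.0, zz))))

            cur = objective(slope, inter)
            for _ in range(self.newton_steps):
                zz = slope * nodes + inter
                p = 1.0 / (1.0 + np.exp(-zz))
                w = nj * p * (1 - p)
                resid = rj - nj * p
                g = np.array([np.sum(resid * nodes), np.sum(resid)])
                H = np.array(
                    [
                        [np.sum(w * nodes * nodes), np.sum(w * nodes)],
                        [np.sum(w * nodes), np.sum(w)],
                    ]
                )
                H[0, 0] += 1e-10
                H[1, 1] += 1e-10
                try:
                    step = np.linalg.solve(H, g)
                except np.linalg.LinAlgError:  # pragma: no cover - degenerate
                    break
                t = 1.0
                for _half in range(20):
                    s_try = slope + t * step[0]
                    c_try = inter + t * step[1]
                    if lo <= s_try <= hi and objective(s_try, c_try) >= cur:
                        slope, inter = s_try, c_try
                        cur = objective(slope, inter)
                        break
                    t *= 0.5
                else:
                    break
            a_new[j] = slope
            b_new[j] = -inter / slope
        return a_new, b_new

    def _standard_errors(self, nodes, n_q, a, b):
        """Delta-method SEs from the expected (slope, intercept) information."""
        se_a = np.full(a.size, np.nan)
        se_b = np.full(a.size, np.nan)
        for j in range(a.size):
            zz = a[j] * (nodes - b[j])
            p = 1.0 / (1.0 + np.exp(-zz))
            w = n_q[:, j] * p * (1 - p)
            H = np.array(
                [
                    [np.sum(w * nodes * nodes), np.sum(w * nodes)],
                    [np.sum(w * nodes), np.sum(w)],
                ]
            )
            try:
                cov_sc = np.linalg.inv(H)
            except np.linalg.LinAlgError:  # pragma: no cover
                continue
            # (a, b) = (s, -c/s) with c = -a b:
            # db/ds = c/s^2 = -b/a, db/dc = -1/s = -1/a
            J = np.array([[1.0, 0.0], [-b[j] / a[j], -1.0 / a[j]]])
            cov_ab = J @ cov_sc @ J.T
            if cov_ab[0, 0] >= 0 and cov_ab[1, 1] >= 0:
                se_a[j] = np.sqrt(cov_ab[0, 0])
                se_b[j] = np.sqrt(cov_ab[1, 1])
        return se_a, se_b


def fit_2pl(
    responses: BinaryResponseMatrix,
    config: dict | None = None,
    seed: int = 0,
) -> IRTFit:
    """Fit the 2PL model, excluding degenerate (all-0 / all-1) items first."""
    degenerate = responses.degenerate_items()
    if degenerate:
        warnings.warn(
            f"{len(degenerate)} degenerate items excluded before fitting: "
            "responses skewed entirely toward one value"
        )
    keep = [j for j, item in enumerate(responses.items) if item not in set(degenerate)]
    if len(keep) < 2:
        raise ValueError("fewer than 2 non-degenerate items")
    items = [responses.items[j] for j in keep]
    data = responses.data[:, keep]
    cfg = dict(
        n_quadrature=61, theta_range=(-6.0, 6.0), tol=1e-5, max_iter=500
    )
    if config:
        cfg.update(config)
    est = TwoPL(random_state=seed, **cfg).fit(data)
    fitted = [
        IRTItem(
            item_id=item,
            a=float(est.discrimination_[k]),
            b=float(est.difficulty_[k]),
            se_a=float(est.se_a_[k]),
            se_b=float(est.se_b_[k]),
            convergence_flag=bool(est.converged_items_[k]),
        )
        for k, item in enumerate(items)
    ]
    abilities = dict(zip(responses.participants, est.abilities_.tolist()))
    ability_se = dict(zip(responses.participants, est.ability_se_.tolist()))
    return IRTFit(
        items=fitted,
        abilities=abilities,
        ability_se=ability_se,
        log_likelihood=est.log_likelihood_,
        n_iterations=est.n_iter_,
        ll_history=est.ll_history_,
        excluded_items=degenerate,
    )


def curate_items(fit: IRTFit) -> list[IRTItem]:
    """Retain the first nine deciles of discrimination and, among the
    survivors, the central 95% of difficulty (2.5th-97.5th percentiles).

    Percentiles use linear interpolation; items tied with the cut value
    are retained.  Fewer than 20 items triggers a warning but the rules
    still apply.
    """
    if len(fit.items) < 20:
        warnings.warn("fewer than 20 items: percentile curation is coarse")
    a_vals = np.array([it.a for it in fit.items])
    a_cut = np.percentile(a_vals, 90)
    survivors = [it for it in fit.items if it.a <= a_cut]
    b_vals = np.array([it.b for it in survivors])
    b_lo, b_hi = np.percentile(b_vals, [2.5, 97.5])
    return [it for it in survivors if b_lo <= it.b <= b_hi]


def select_discriminative_subset(
    items: list[IRTItem], n: int = 80, difficulty_bins: int = 4
) -> list[IRTItem]:
    """Pick ``n`` high-discrimination items covering the difficulty range.

    Difficulty is stratified into ``difficulty_bins`` equal-count strata;
    within each stratum the highest-discrimination items are taken,
    proportionally to stratum size (largest-remainder allocation).
    Deterministic given input order; ties break on item_id.
    """
    if n >= len(items):
        if n > len(items):
            warnings.warn("requested more items than available; returning all")
        return list(items)
    order = np.argsort([it.b for it in items], kind="stable")
    strata = np.array_split(order, difficulty_bins)
    sizes = np.array([len(s) for s in strata], dtype=float)
    quota = sizes / sizes.sum() * n
    alloc = np.floor(quota).astype(int)
    remainder = quota - alloc
    for k in np.argsort(-remainder, kind="stable")[: n - alloc.sum()]:
        alloc[k] += 1
    chosen: list[IRTItem] = []
    for stratum, take in zip(strata, alloc):
        members = sorted(
            (items[i] for i in stratum), key=lambda it: (-it.a, it.item_id)
        )
        chosen.extend(members[: int(take)])
    return chosen


def irt_descriptive_concordance(
    fit: IRTFit,
    familiarity_means: dict[str, float],
    word_grades: dict[str, float],
    word_logfreqs: dict[str, float],
    participant_education: dict,
) -> dict[str, CorrelationResult]:
    """Spearman concordance of IRT estimates with descriptive measures.

    Returns correlations of (−b, mean familiarity), (b, grade),
    (b, log frequency) and (θ, education).  Mismatched keys are an error.
    """
    item_ids = [it.item_id for it in fit.items]
    for name, table in (
        ("familiarity_means", familiarity_means),
        ("word_grades", word_grades),
        ("word_logfreqs", word_logfreqs),
    ):
        missing = [w for w in item_ids if w not in table]
        if missing:
            raise KeyError(f"{name} lacks items: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    missing_p = [p for p in fit.abilities if p not in participant_education]
    if missing_p:
        raise KeyError(f"participant_education lacks: {missing_p[:5]}")
    b = np.array([it.b for it in fit.items])
    fam = np.array([familiarity_means[w] for w in item_ids])
    grade = np.array([word_grades[w] for w in item_ids])
    lf = np.array([word_logfreqs[w] for w in item_ids])
    pids = list(fit.abilities)
    theta = np.array([fit.abilities[p] for p in pids])
    edu = np.array([participant_education[p] for p in pids])
    return {
        "difficulty_vs_familiarity": spearman(-b, fam),
        "difficulty_vs_grade": spearman(b, grade),
        "difficulty_vs_logfreq": spearman(b, lf),
        "ability_vs_education": spearman(theta, edu),
    }
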