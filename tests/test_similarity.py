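"""Similarity metrics, pair selection, rank statistics and noise ceiling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from semspace.glove import EmbeddingSet
from semspace.similarity import (
    PAIR_CATEGORIES,
    aggregate_ratings,
    category_contrast,
    compare_models_aic,
    cosine,
    euclidean,
    fit_by_group,
    fit_rank_glm,
    mean_grade_similarity,
    noise_ceiling,
    pair_key,
    percentile_bin,
    rank_transform,
    select_pairs,
    spearman,
)


def _embedding(words, vectors):
    V = np.asarray(vectors, dtype=float)
    return EmbeddingSet(
        vocab=list(words), vectors=V, biases=np.zeros(len(words)), dim=V.shape[1]
    )


class TestMetrics:
    def test_cosine_closed_forms(self):
        u = np.array([2.0, 1.0, -3.0])
        assert cosine(u, u) == pytest.approx(1.0)
        assert cosine([1, 0], [0, 1]) == pytest.approx(0.0)
        assert cosine([1, 1], [1, 0]) == pytest.approx(math.sqrt(2) / 2)

    def test_cosine_errors(self):
        with pytest.raises(ValueError):
            cosine([0.0, 0.0], [1.0, 0.0])
        with pytest.raises(ValueError):
            cosine([1.0], [1.0, 0.0])

    def test_euclidean_closed_forms(self):
        assert euclidean([1, 2], [1, 2]) == 0.0
        assert euclidean([0, 0], [3, 4]) == pytest.approx(5.0)
        with pytest.raises(ValueError):
            euclidean([1], [1, 2])

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=-5, max_value=5, allow_nan=False), min_size=2, max_size=8
        ),
        st.lists(
            st.floats(min_value=-5, max_value=5, allow_nan=False), min_size=2, max_size=8
        ),
    )
    def test_unit_norm_identity(self, u, v):
        n = min(len(u), len(v))
        u, v = np.array(u[:n]), np.array(v[:n])
        if np.linalg.norm(u) < 1e-6 or np.linalg.norm(v) < 1e-6:
            return
        u /= np.linalg.norm(u)
        v /= np.linalg.norm(v)
        # on unit vectors: euclidean^2 = 2 - 2 cosine
        assert euclidean(u, v) ** 2 == pytest.approx(2 - 2 * cosine(u, v), abs=1e-9)


def select_pairs_oracle(emb, word_groups, k):
    """Brute force: enumerate every candidate pair per target, sort per
    criterion with the lexicographic tie rule, dedup on unordered keys."""
    chosen = {}
    for group in word_groups["grade_group"].unique():
        words = list(word_groups.loc[word_groups["grade_group"] == group, "word"])
        if len(words) < 2:
            continue
        cos = {
            (a, b): cosine(emb.vector(a), emb.vector(b))
            for i, a in enumerate(words)
            for b in words[i + 1 :]
        }
        mu = np.mean(list(cos.values()))

        def sim(a, b):
            return cos[(a, b)] if (a, b) in cos else cos[(b, a)]

        for target in words:
            cands = [(sim(target, o), o) for o in words if o != target]
            ranked = {
                "close": sorted(cands, key=lambda cw: (-cw[0], cw[1])),
                "opposite": sorted(cands, key=lambda cw: (cw[0], cw[1])),
                "orthogonal": sorted(cands, key=lambda cw: (abs(cw[0]), cw[1])),
                "mean": sorted(cands, key=lambda cw: (abs(cw[0] - mu), cw[1])),
            }
            for cat in PAIR_CATEGORIES:
                picked = ranked[cat][:k]
                assert len(picked) == min(k, len(cands))  # 4k raw per target
                for c, other in picked:
                    key = pair_key(target, other)
                    if key not in chosen:
                        chosen[key] = (cat, c, group)
    return chosen


class TestSelectPairs:
    @pytest.mark.parametrize("n_words,k,seed", [(5, 1, 0), (20, 2, 1), (50, 3, 2)])
    def test_matches_bruteforce_oracle(self, n_words, k, seed):
        rng = np.random.default_rng(seed)
        words = [f"w{i:02d}" for i in range(n_words)]
        emb = _embedding(words, rng.normal(size=(n_words, 8)))
        groups = pd.DataFrame(
            {"word": words, "grade_group": ["primary" if i % 2 else "bachelor" for i in range(n_words)]}
        )
        with pytest.warns(UserWarning):
            pairs = select_pairs(emb, groups, k_per_category=k)
        got = {p.key: (p.category, p.predicted_cosine, p.grade_group) for p in pairs}
        expected = select_pairs_oracle(emb, groups, k)
        assert set(got) == set(expected)
        for key in got:
            assert got[key][0] == expected[key][0]
            assert got[key][1] == pytest.approx(expected[key][1])

    def test_pairs_stay_within_grade_group(self):
        rng = np.random.default_rng(3)
        words = [f"w{i}" for i in range(30)]
        emb = _embedding(words, rng.normal(size=(30, 6)))
        groups = pd.DataFrame(
            {"word": words, "grade_group": [f"g{i % 3}" for i in range(30)]}
        )
        g_of = dict(zip(groups["word"], groups["grade_group"]))
        for p in select_pairs(emb, groups, k_per_category=2):
            assert g_of[p.word_a] == g_of[p.word_b] == p.grade_group


class TestMeanGradeSimilarity:
    def test_identical_vectors(self):
        emb = _embedding(["a", "b", "c"], [[1, 2], [1, 2], [1, 2]])
        mu, sigma, n = mean_grade_similarity(emb, ["a", "b", "c"])
        assert (mu, sigma, n) == (pytest.approx(1.0), pytest.approx(0.0), 3)

    def test_two_orthogonal(self):
        emb = _embedding(["a", "b"], [[1, 0], [0, 1]])
        mu, _, n = mean_grade_similarity(emb, ["a", "b"])
        assert mu == pytest.approx(0.0) and n == 1

    def test_matches_pair_enumeration(self):
        rng = np.random.default_rng(5)
        words = [f"w{i}" for i in range(6)]
        V = rng.normal(size=(6, 4))
        emb = _embedding(words, V)
        vals = [
            cosine(V[i], V[j]) for i in range(6) for j in range(i + 1, 6)
        ]
        mu, sigma, n = mean_grade_similarity(emb, words)
        assert mu == pytest.approx(np.mean(vals))
        assert sigma == pytest.approx(np.std(vals))
        assert n == 15

    def test_singleton_group_rejected(self):
        emb = _embedding(["a"], [[1.0, 0.0]])
        with pytest.raises(ValueError):
            mean_grade_similarity(emb, ["a"])


class TestAggregate:
    def test_mean_per_pair_and_grand_mean(self):
        trials = pd.DataFrame(
            {
                "participant_id": ["p1", "p2", "p1", "p1"],
                "word_a": ["a", "b", "x", "x"],
                "word_b": ["b", "a", "y", "y"],
                "rating": [2.0, 4.0, 5.0, 5.0],
            }
        )
        agg = aggregate_ratings(trials)
        assert agg.loc[[("a", "b")], "mean_rating"].iloc[0] == pytest.approx(3.0)
        assert agg.loc[[("x", "y")], "n_trials"].iloc[0] == 2
        # mean of means (4.0) differs from the grand mean over trials
        assert agg.attrs["grand_mean"] == pytest.approx(4.0)
        assert agg["mean_rating"].mean() == pytest.approx(4.0)

    def test_single_trial_is_itself(self):
        trials = pd.DataFrame(
            {"participant_id": ["p"], "word_a": ["u"], "word_b": ["v"], "rating": [1.5]}
        )
        assert aggregate_ratings(trials)["mean_rating"].iloc[0] == 1.5


class TestRanks:
    def test_mean_rank_ties(self):
        assert rank_transform([10, 20, 20, 30]).tolist() == [1.0, 2.5, 2.5, 4.0]

    def test_strictly_increasing_is_identity(self):
        assert rank_transform([3, 7, 9, 22]).tolist() == [1, 2, 3, 4]

    def test_all_equal(self):
        assert rank_transform([5, 5, 5]).tolist() == [2.0, 2.0, 2.0]

    def test_spearman_monotone_extremes(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman(x, [v**3 for v in x]).r_s == pytest.approx(1.0)
        assert spearman(x, [-v for v in x]).r_s == pytest.approx(-1.0)

    def test_spearman_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=40)
        y = rng.normal(size=40) + 0.5 * x
        res = spearman(x, y)
        rx, ry = rank_transform(x), rank_transform(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert res.r_s == pytest.approx(expected, abs=1e-12)
        assert res.r_squared == pytest.approx(res.r_s**2)

    def test_zero_variance_signaled(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])


class TestRankGLM:
    def test_recovers_planted_signs(self):
        rng = np.random.default_rng(2)
        n = 3000
        edu = rng.integers(0, 9, n).astype(float)
        grade = rng.integers(0, 5, n).astype(float)
        lf = rng.normal(2, 0.5, n)
        y = 0.7 * edu - 0.9 * grade + 0.4 * lf + rng.normal(0, 1.5, n)
        tab = pd.DataFrame({"y": y, "education": edu, "grade": grade, "logfreq": lf})
        mains = fit_rank_glm(
            tab, "y", ["education", "grade", "logfreq"], interactions=False
        )
        assert mains.coefficients["education"][0] > 0
        assert mains.coefficients["grade"][0] < 0
        assert mains.coefficients["logfreq"][0] > 0
        assert all(
            mains.coefficients[c][2] < 1e-4
            for c in ("education", "grade", "logfreq")
        )
        # with the full interaction design the dominant effects keep their
        # signs and significance (interactions share the weaker one's rank
        # variance, so only sign is asserted for it)
        res = fit_rank_glm(tab, "y", ["education", "grade", "logfreq"])
        assert res.coefficients["education"][0] > 0
        assert res.coefficients["grade"][0] < 0
        assert res.df_resid == res.nobs - len(res.coefficients)
        assert res.coefficients["education"][2] < 1e-4
        assert res.coefficients["grade"][2] < 1e-4

    def test_duplicated_predictor_rejected(self):
        rng = np.random.default_rng(4)
        tab = pd.DataFrame({"y": rng.normal(size=50), "x1": rng.normal(size=50)})
        tab["x2"] = tab["x1"]
        with pytest.raises(ValueError, match="collinear"):
            fit_rank_glm(tab, "y", ["x1", "x2"], interactions=False)


class TestNoiseCeiling:
    @staticmethod
    def _trials(matrix, pids=None):
        n_p, n_q = matrix.shape
        pids = pids or [f"p{i}" for i in range(n_p)]
        rows = []
        for i, pid in enumerate(pids):
            for j in range(n_q):
                if not np.isnan(matrix[i, j]):
                    rows.append((pid, f"a{j}", f"b{j}", matrix[i, j]))
        return pd.DataFrame(rows, columns=["participant_id", "word_a", "word_b", "rating"])

    def test_identical_raters_hit_one(self):
        base = np.linspace(0, 5, 20)
        M = np.tile(base, (5, 1))
        assert noise_ceiling(self._trials(M)) == pytest.approx(1.0)

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(0)
        M = rng.normal(size=(200, 500))
        assert abs(noise_ceiling(self._trials(M))) < 0.02

    def test_additive_model_matches_analytic_value(self):
        # ratings = shared signal + noise with variance ratio 1:1; the
        # leave-one-out ceiling converges to V/(V + sigma^2/(n-1))-adjusted
        # product, approximately 0.5 at 200 raters
        rng = np.random.default_rng(1)
        n_p, n_q = 200, 500
        signal = rng.normal(0, 1, n_q)
        M = signal[None, :] + rng.normal(0, 1, (n_p, n_q))
        est = noise_ceiling(self._trials(M))
        expected = 1.0 / (1.0 + 1.0) * 1.0 / (1.0 + 1.0 / (n_p - 1))
        assert est == pytest.approx(expected, abs=0.05)

    def test_invariant_to_participant_order(self):
        rng = np.random.default_rng(3)
        signal = rng.normal(size=50)
        M = signal[None, :] + rng.normal(0, 1, (10, 50))
        t1 = self._trials(M)
        t2 = t1.sample(frac=1.0, random_state=7).reset_index(drop=True)
        assert noise_ceiling(t1) == pytest.approx(noise_ceiling(t2))

    def test_subgroups_use_full_panel_reference(self):
        rng = np.random.default_rng(4)
        signal = rng.normal(size=80)
        M = signal[None, :] + rng.normal(0, 0.5, (20, 80))
        trials = self._trials(M)
        grouping = {f"p{i}": ("lo" if i < 10 else "hi") for i in range(20)}
        out = noise_ceiling(trials, grouping=grouping)
        assert set(out) == {"lo", "hi"}
        assert all(0 < v <= 1 for v in out.values())


class TestAIC:
    @staticmethod
    def _fit(y, x):
        return fit_rank_glm(
            pd.DataFrame({"y": y, "x": x}), "y", ["x"], interactions=False
        )

    def test_identical_fits_tie_at_one(self):
        rng = np.random.default_rng(0)
        y, x = rng.normal(size=30), rng.normal(size=30)
        comp = compare_models_aic({"m1": self._fit(y, x), "m2": self._fit(y, x)})
        assert comp.delta_aic == {"m1": 0.0, "m2": 0.0}
        assert comp.p["m1"] == comp.p["m2"] == 1.0

    def test_delta_two_gives_exp_minus_one(self):
        rng = np.random.default_rng(1)
        y, x = rng.normal(size=30), rng.normal(size=30)
        fit = self._fit(y, x)
        from dataclasses import replace

        shifted = replace(fit, aic=fit.aic + 2.0)
        comp = compare_models_aic({"base": fit, "worse": shifted})
        assert comp.p["worse"] == pytest.approx(math.exp(-1.0))
        assert comp.preferred == "base"

    def test_large_delta_is_decisive(self):
        assert math.exp(-734.31 / 2) < 0.001

    def test_differing_responses_rejected(self):
        rng = np.random.default_rng(2)
        f1 = self._fit(rng.normal(size=30), rng.normal(size=30))
        f2 = self._fit(rng.normal(size=31), rng.normal(size=31))
        with pytest.raises(ValueError):
            compare_models_aic({"a": f1, "b": f2})


class TestCategoryContrast:
    @staticmethod
    def _trials(means, n=300, sd=0.5, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for cat, m in means.items():
            for v in rng.normal(m, sd, n):
                rows.append((cat, v))
        return pd.DataFrame(rows, columns=["category", "rating"])

    def test_planted_ordering_all_pairwise_significant(self):
        means = {"close": 3.2, "mean": 2.7, "orthogonal": 2.2, "opposite": 1.7}
        out = category_contrast(self._trials(means))
        assert (
            out["means"]["close"]
            > out["means"]["mean"]
            > out["means"]["orthogonal"]
            > out["means"]["opposite"]
        )
        assert out["p"] < 0.001
        assert (out["dunn"]["p_adjusted"] < 0.05).all()

    def test_null_omnibus_calibrated(self):
        rng = np.random.default_rng(5)
        hits = 0
        reps = 400
        for _ in range(reps):
            df = pd.DataFrame(
                {
                    "category": np.repeat(list(PAIR_CATEGORIES), 30),
                    "rating": rng.normal(size=120),
                }
            )
            if category_contrast(df)["p"] < 0.05:
                hits += 1
        assert abs(hits / reps - 0.05) < 0.03

    def test_all_ties_give_zero_h(self):
        df = pd.DataFrame(
            {"category": ["close"] * 5 + ["mean"] * 5, "rating": [2.0] * 10}
        )
        out = category_contrast(df)
        assert out["H"] == 0.0


class TestPercentileBin:
    def test_identity_when_bins_equal_points(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=100), rng.normal(size=100)
        xb, yb = percentile_bin(x, y, n_bins=100)
        order = np.argsort(x, kind="stable")
        assert np.allclose(xb, x[order])
        assert np.allclose(yb, y[order])

    def test_two_bins_are_half_means(self):
        x = np.array([4.0, 1.0, 3.0, 2.0])
        y = np.array([40.0, 10.0, 30.0, 20.0])
        xb, yb = percentile_bin(x, y, 2)
        assert xb.tolist() == [1.5, 3.5]
        assert yb.tolist() == [15.0, 35.0]

    def test_validation(self):
        with pytest.raises(ValueError):
            percentile_bin([1, 2], [1, 2], 0)
        with pytest.raises(ValueError):
            percentile_bin([1], [1], 2)


class TestFitByGroup:
    def test_planted_variant_dominates_in_every_group(self):
        rng = np.random.default_rng(6)
        n_words = 40
        words = [f"w{i}" for i in range(n_words)]
        V_math = rng.normal(size=(n_words, 10))
        V_non = rng.normal(size=(n_words, 10))
        emb = {
            "math": _embedding(words, V_math),
            "nonmath": _embedding(words, V_non),
        }
        rows = []
        for g in ("primary", "bachelor"):
            for _ in range(60):
                i, j = rng.choice(n_words, 2, replace=False)
                s = cosine(V_math[i], V_math[j])
                for p in range(3):
                    rows.append(
                        (f"p{p}", words[i], words[j], g, 2.5 + 2 * s + rng.normal(0, 0.2))
                    )
        trials = pd.DataFrame(
            rows, columns=["participant_id", "word_a", "word_b", "grade_group", "rating"]
        )
        table, _ = fit_by_group(trials, emb, grouping="grade_group")
        piv = table.pivot(index="group", columns="variant", values="r_s")
        assert (piv["math"] > piv["nonmath"]).all()

    def test_single_group_trend_degenerate(self):
        rng = np.random.default_rng(7)
        words = [f"w{i}" for i in range(10)]
        V = rng.normal(size=(10, 5))
        emb = {"math": _embedding(words, V)}
        rows = [
            ("p0", words[i], words[j], "primary", rng.uniform(0, 5))
            for i in range(10)
            for j in range(i + 1, 10)
        ]
        trials = pd.DataFrame(
            rows, columns=["participant_id", "word_a", "word_b", "grade_group", "rating"]
        )
        with pytest.warns(UserWarning, match="degenerate"):
            _, trends = fit_by_group(trials, emb, grouping="grade_group")
        assert math.isnan(trends["math"])
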