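"""Dichotomization, 2PL estimation, curation and subset selection."""

import numpy as np
import pandas as pd
import pytest

from semspace.irt import (
    BinaryResponseMatrix,
    IRTFit,
    IRTItem,
    curate_items,
    dichotomize,
    fit_2pl,
    irt_descriptive_concordance,
    p_correct_2pl,
    select_discriminative_subset,
)


class TestDichotomize:
    @pytest.mark.parametrize("rating,expected", [(0, 0), (3, 0), (4, 1), (8, 1)])
    def test_boundary_inclusive(self, rating, expected):
        trials = pd.DataFrame(
            {"participant_id": ["p"], "word": ["w"], "rating": [rating]}
        )
        R = dichotomize(trials)
        assert R.data[0, 0] == expected

    def test_missing_cells_preserved(self):
        trials = pd.DataFrame(
            {
                "participant_id": ["p1", "p1", "p2"],
                "word": ["u", "v", "u"],
                "rating": [5, 2, 7],
            }
        )
        R = dichotomize(trials)
        assert np.isnan(R.data).sum() == 1

    def test_out_of_range_rejected(self):
        trials = pd.DataFrame({"participant_id": ["p"], "word": ["w"], "rating": [9]})
        with pytest.raises(ValueError):
            dichotomize(trials)


class TestResponseCurve:
    def test_half_probability_at_difficulty(self):
        assert p_correct_2pl(0.7, 1.3, 0.7) == pytest.approx(0.5)

    def test_closed_form(self):
        assert p_correct_2pl(2.0, 1.0, 0.0) == pytest.approx(1 / (1 + np.exp(-2)))

    def test_saturates_for_large_discrimination(self):
        assert p_correct_2pl(1.0, 50.0, 0.0) > 0.999

    def test_monotone_in_ability(self):
        thetas = np.linspace(-4, 4, 30)
        p = p_correct_2pl(thetas, 1.5, 0.3)
        assert (np.diff(p) > 0).all()

    def test_nonpositive_discrimination_rejected(self):
        with pytest.raises(ValueError):
            p_correct_2pl(0.0, -1.0, 0.0)


class TestFit:
    def test_parameter_recovery(self, irt_recovery):
        a, b, fit = irt_recovery["a"], irt_recovery["b"], irt_recovery["fit"]
        kept = [
            j
            for j, item in enumerate(irt_recovery["responses"].items)
            if item not in set(fit.excluded_items)
        ]
        a_hat = np.array([it.a for it in fit.items])
        b_hat = np.array([it.b for it in fit.items])
        assert np.corrcoef(b[kept], b_hat)[0, 1] >= 0.95
        assert np.corrcoef(a[kept], a_hat)[0, 1] >= 0.85

    def test_marginal_likelihood_monotone(self, irt_recovery):
        ll = irt_recovery["fit"].ll_history
        assert (np.diff(ll) >= -1e-8).all()

    def test_ability_recovery(self, irt_recovery):
        fit = irt_recovery["fit"]
        theta_hat = [fit.abilities[p] for p in irt_recovery["responses"].participants]
        assert np.corrcoef(irt_recovery["theta"], theta_hat)[0, 1] > 0.9

    def test_degenerate_item_excluded(self):
        rng = np.random.default_rng(0)
        data = (rng.random((50, 3)) < 0.5).astype(float)
        data[:, 1] = 1.0  # answered 1 by everyone: not identifiable
        R = BinaryResponseMatrix([f"p{i}" for i in range(50)], ["u", "v", "w"], data)
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fit_2pl(R)
        assert fit.excluded_items == ["v"]
        assert [it.item_id for it in fit.items] == ["u", "w"]

    def test_minimal_checkerboard_runs(self):
        data = np.array([[1.0, 0.0], [0.0, 1.0]])
        R = BinaryResponseMatrix(["p0", "p1"], ["i0", "i1"], data)
        fit = fit_2pl(R, config={"max_iter": 50})
        assert len(fit.items) == 2
        assert np.isfinite([it.a for it in fit.items]).all()

    def test_scale_indeterminacy_resolved_by_prior(self):
        # (a, b, theta) and (2a, b/2, theta/2) give identical response
        # probabilities; with common uniform draws the fits coincide
        rng = np.random.default_rng(3)
        n_p, n_i = 400, 30
        a = rng.uniform(0.8, 1.6, n_i)
        b = rng.uniform(-1, 1, n_i)
        theta = rng.normal(0, 1, n_p)
        U = rng.random((n_p, n_i))
        P1 = 1 / (1 + np.exp(-a[None] * (theta[:, None] - b[None])))
        P2 = 1 / (1 + np.exp(-(2 * a[None]) * (theta[:, None] / 2 - b[None] / 2)))
        assert np.allclose(P1, P2)
        f1 = fit_2pl(
            BinaryResponseMatrix(list(range(n_p)), [f"i{j}" for j in range(n_i)], (U < P1).astype(float))
        )
        f2 = fit_2pl(
            BinaryResponseMatrix(list(range(n_p)), [f"i{j}" for j in range(n_i)], (U < P2).astype(float))
        )
        p_hat1 = np.array(
            [p_correct_2pl(0.5, it.a, it.b) for it in f1.items]
        )
        p_hat2 = np.array(
            [p_correct_2pl(0.5, it.a, it.b) for it in f2.items]
        )
        assert np.abs(p_hat1 - p_hat2).max() < 1e-3


class TestCuration:
    @staticmethod
    def _fit(a_vals, b_vals):
        items = [
            IRTItem(item_id=f"i{k}", a=float(a), b=float(b))
            for k, (a, b) in enumerate(zip(a_vals, b_vals))
        ]
        return IRTFit(items=items, abilities={})

    def test_top_discrimination_decile_dropped(self):
        a = np.linspace(0.5, 2.5, 10)
        with pytest.warns(UserWarning):
            kept = curate_items(self._fit(a, np.zeros(10)))
        assert len(kept) == 9
        assert max(it.a for it in kept) < 2.5

    def test_difficulty_tails_dropped(self):
        b = np.linspace(-2, 2, 40)  # symmetric
        rng = np.random.default_rng(0)
        a = rng.uniform(0.5, 1.0, 40)
        kept = curate_items(self._fit(a, b))
        kept_b = sorted(it.b for it in kept)
        # decile rule drops the largest-a items; among survivors exactly
        # the extreme low and high difficulties are trimmed
        surviving = sorted(
            it.b for it in self._fit(a, b).items if it.a <= np.percentile(a, 90)
        )
        assert kept_b == surviving[1:-1]

    def test_identical_parameters_all_retained(self):
        kept = curate_items(self._fit(np.ones(25), np.zeros(25)))
        assert len(kept) == 25


class TestSubset:
    def test_top_discrimination_per_difficulty_half(self):
        a = [0.5, 2.0, 1.0, 1.5, 0.6, 2.2, 1.1, 0.9]
        b = [-2, -1.5, -1, -0.5, 0.5, 1, 1.5, 2]
        items = [IRTItem(f"i{k}", a[k], b[k]) for k in range(8)]
        out = select_discriminative_subset(items, n=4, difficulty_bins=2)
        ids = {it.item_id for it in out}
        # low-b half: i0..i3, top a are i1 (2.0), i3 (1.5); high-b half: i5 (2.2), i6 (1.1)
        assert ids == {"i1", "i3", "i5", "i6"}

    def test_requesting_all_returns_identity(self):
        items = [IRTItem(f"i{k}", 1.0 + k * 0.1, 0.0) for k in range(5)]
        assert select_discriminative_subset(items, n=5) == items

    def test_selected_minimum_discrimination_above_median(self, irt_recovery):
        fit = irt_recovery["fit"]
        curated = curate_items(fit)
        subset = select_discriminative_subset(curated, n=30)
        all_a = np.array([it.a for it in curated])
        assert min(it.a for it in subset) >= np.median(all_a)


class TestConcordance:
    @staticmethod
    def _fit_with(b_by_item, abilities):
        items = [IRTItem(w, 1.0, b) for w, b in b_by_item.items()]
        return IRTFit(items=items, abilities=abilities)

    def test_planted_grade_link_recovered(self):
        rng = np.random.default_rng(1)
        grades = {f"w{i}": i % 6 for i in range(60)}
        b = {w: 0.6 * g + rng.normal(0, 0.3) for w, g in grades.items()}
        fam = {w: 5 - b[w] + rng.normal(0, 0.2) for w in grades}
        lf = {w: rng.normal(2, 0.5) for w in grades}
        edu = {f"p{i}": i % 9 for i in range(40)}
        theta = {p: 0.5 * e + rng.normal(0, 0.6) for p, e in edu.items()}
        out = irt_descriptive_concordance(self._fit_with(b, theta), fam, grades, lf, edu)
        assert out["difficulty_vs_grade"].r_s > 0
        assert out["difficulty_vs_familiarity"].r_s > 0.8
        assert out["ability_vs_education"].r_s >= 0.5  # planted link ~0.6

    def test_constant_grade_signaled(self):
        b = {f"w{i}": float(i) for i in range(10)}
        fam = {w: 1.0 + i for i, w in enumerate(b)}
        grades = {w: 3 for w in b}
        lf = {w: float(i) for i, w in enumerate(b)}
        edu = {"p0": 1, "p1": 2, "p2": 3}
        theta = {"p0": 0.1, "p1": 0.2, "p2": 0.3}
        with pytest.raises(ValueError):
            irt_descriptive_concordance(self._fit_with(b, theta), fam, grades, lf, edu)

    def test_mismatched_keys_rejected(self):
        fit = self._fit_with({"w0": 0.0, "w1": 1.0}, {"p0": 0.0})
        with pytest.raises(KeyError, match="w1"):
            irt_descriptive_concordance(fit, {"w0": 1.0}, {"w0": 1, "w1": 2}, {"w0": 1.0, "w1": 2.0}, {"p0": 3})
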