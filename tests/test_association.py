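"""Cytokine group scores, timepoint deltas, rank correlation, persistence AUC, OLS."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cartprofiler.association import (
    cytokine_group_scores,
    pearson_regression,
    persistence_auc,
    spearman_assoc,
    timepoint_deltas,
)
from cartprofiler.datasets import CohortConfig, CorrelateSet, DonorSpec, generate_correlates


def _cset(cyto_rows, grouping, persistence=None):
    cytokines = pd.DataFrame(cyto_rows, columns=["patient", "cytokine", "timepoint", "concentration"])
    persistence = persistence if persistence is not None else pd.DataFrame(
        {"patient": ["p1", "p1"], "day": [0.0, 28.0], "level": [1.0, 1.0]}
    )
    metrics = pd.DataFrame({"patient": cytokines["patient"].unique()}).set_index("patient")
    return CorrelateSet(cytokines=cytokines, grouping=grouping, persistence=persistence, product_metrics=metrics)


def _brute_spearman(x, y):
    """Midrank Spearman: Pearson correlation of midranks, computed by hand."""

    def midrank(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        sv = np.asarray(v)[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = midrank(x), midrank(y)
    rx, ry = rx - rx.mean(), ry - ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


class TestGroupScores:
    def test_single_member_group_is_the_cytokine(self):
        cset = _cset([("p1", "IL-6", "pre", 7.5)], {"IL-6": "inflammatory"})
        scores = cytokine_group_scores(cset)
        assert scores["score"].iloc[0] == 7.5

    def test_two_members_average(self):
        rows = [("p1", "IL-6", "pre", 2.0), ("p1", "TNF-a", "pre", 4.0)]
        cset = _cset(rows, {"IL-6": "g", "TNF-a": "g"})
        assert cytokine_group_scores(cset)["score"].iloc[0] == 3.0

    def test_permutation_invariant_within_group(self):
        rows = [("p1", c, "pre", v) for c, v in [("a", 1.0), ("b", 5.0), ("c", 9.0)]]
        g = {"a": "g", "b": "g", "c": "g"}
        s1 = cytokine_group_scores(_cset(rows, g))["score"].iloc[0]
        s2 = cytokine_group_scores(_cset(rows[::-1], g))["score"].iloc[0]
        assert s1 == s2

    def test_empty_group_rejected(self):
        cset = _cset([("p1", "IL-6", "pre", 1.0)], {"IL-6": "g"})
        cset.grouping["ghost-cytokine"] = "empty-group"
        with pytest.raises(ValueError, match="empty-group"):
            cytokine_group_scores(cset)


class TestDeltas:
    def _scores(self, vals):
        return pd.DataFrame(
            [("p1", "g", tp, v) for tp, v in vals.items()],
            columns=["patient", "group", "timepoint", "score"],
        )

    def test_equal_values_zero_delta(self):
        d = timepoint_deltas(self._scores({"pre": 3.0, "wk1": 3.0, "wk4": 3.0}))
        assert np.allclose(d.to_numpy(), 0.0)

    def test_later_minus_earlier(self):
        d = timepoint_deltas(self._scores({"pre": 1.0, "wk1": 5.0, "wk4": 2.0}))
        assert d["pre->wk1"].iloc[0] == 4.0

    def test_telescoping(self):
        d = timepoint_deltas(self._scores({"pre": 1.0, "wk1": 6.0, "wk4": 4.0}))
        assert d["pre->wk4"].iloc[0] == pytest.approx(d["pre->wk1"].iloc[0] + d["wk1->wk4"].iloc[0])

    def test_missing_timepoint_nan_with_warning(self):
        with pytest.warns(UserWarning, match="missing"):
            d = timepoint_deltas(self._scores({"pre": 1.0, "wk1": 2.0}))
        assert np.isnan(d["pre->wk4"].iloc[0])


class TestSpearman:
    def _frames(self, x, y):
        patients = [f"p{i}" for i in range(len(x))]
        metrics = pd.DataFrame({"m": x}, index=patients)
        deltas = pd.DataFrame({"d": y}, index=pd.MultiIndex.from_product([patients, ["g"]], names=["patient", "group"]))
        return metrics, deltas

    def test_monotone_pair_is_plus_one_reversed_minus_one(self):
        m, d = self._frames([1, 2, 3, 4], [10, 20, 30, 40])
        assert spearman_assoc(m, d).iloc[0, 0] == pytest.approx(1.0)
        m, d = self._frames([1, 2, 3, 4], [40, 30, 20, 10])
        assert spearman_assoc(m, d).iloc[0, 0] == pytest.approx(-1.0)

    def test_matches_brute_force_midranks_with_ties(self, rng):
        x = rng.integers(0, 5, size=10).astype(float)  # ties guaranteed
        y = rng.integers(0, 5, size=10).astype(float)
        m, d = self._frames(x, y)
        assert spearman_assoc(m, d).iloc[0, 0] == pytest.approx(_brute_spearman(x, y), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.random(10)
        y = rng.random(10)
        m1, d1 = self._frames(x, y)
        m2, d2 = self._frames(np.exp(5 * x), y**3)
        assert spearman_assoc(m1, d1).iloc[0, 0] == pytest.approx(spearman_assoc(m2, d2).iloc[0, 0])

    def test_constant_vector_nan(self):
        m, d = self._frames([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        assert np.isnan(spearman_assoc(m, d).iloc[0, 0])

    def test_planted_factor_recovered_in_95_percent_of_simulations(self):
        """Positive latent link between cluster abundance and cytokine response
        recovered (rho > 0) in >= 95% of 200 simulations at n = 10 patients."""
        donors = [DonorSpec(f"d{i}") for i in range(10)]
        hits = 0
        n_sim = 200
        for s in range(n_sim):
            cohort = CohortConfig(donors=donors, events_per_sample=10, seed=s)
            cset = generate_correlates(cohort, group_effects={"inflammatory": 20.0}, noise_sd=1.0, seed=s)
            deltas = timepoint_deltas(cytokine_group_scores(cset))
            rho = spearman_assoc(cset.product_metrics, deltas)
            if rho.loc["cluster_abundance", ("inflammatory", "pre->wk1")] > 0:
                hits += 1
        assert hits / n_sim >= 0.95


class TestPersistenceAUC:
    def test_constant_over_28_days(self):
        curve = pd.DataFrame({"patient": ["p"] * 5, "day": [0, 0.125, 7, 14, 28], "level": [3.0] * 5})
        assert persistence_auc(curve)["p"] == pytest.approx(84.0)

    def test_linear_ramp_triangle(self):
        curve = pd.DataFrame({"patient": ["p", "p"], "day": [0.0, 10.0], "level": [0.0, 6.0]})
        assert persistence_auc(curve)["p"] == pytest.approx(30.0)

    def test_additive_over_adjacent_intervals(self):
        full = pd.DataFrame({"patient": ["p"] * 3, "day": [0.0, 7.0, 28.0], "level": [1.0, 5.0, 2.0]})
        left = full.iloc[:2]
        right = full.iloc[1:]
        assert persistence_auc(full)["p"] == pytest.approx(
            persistence_auc(left)["p"] + persistence_auc(right)["p"]
        )

    def test_matches_fine_grid_quadrature(self):
        days = np.array([0.0, 0.125, 7.0, 14.0, 28.0])
        levels = np.array([0.0, 40.0, 100.0, 55.0, 20.0])
        curve = pd.DataFrame({"patient": "p", "day": days, "level": levels})
        fine_t = np.linspace(0, 28, 200_001)
        fine_y = np.interp(fine_t, days, levels)
        assert persistence_auc(curve)["p"] == pytest.approx(np.trapezoid(fine_y, fine_t), abs=1e-6)

    def test_unordered_timepoints_rejected(self):
        curve = pd.DataFrame({"patient": ["p"] * 3, "day": [0.0, 14.0, 7.0], "level": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="increasing"):
            persistence_auc(curve)


class TestPearsonRegression:
    def test_exact_linear_relation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = pearson_regression(x, 2 * x)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(0.0)

    def test_antisymmetric_under_negation(self, rng):
        x, y = rng.random(20), rng.random(20)
        assert pearson_regression(x, y).r == pytest.approx(-pearson_regression(x, -y).r)

    def test_null_relationship_ci_covers_zero(self, rng):
        x = rng.normal(size=1000)
        y = rng.normal(size=1000)
        res = pearson_regression(x, y)
        assert abs(res.r) < 0.1
        assert res.slope_ci[0] < 0 < res.slope_ci[1]
        assert not res.significant or res.p < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_slope_ci_matches_t_formula(self, rng):
        x, y = rng.random(15), rng.random(15)
        res = pearson_regression(x, y)
        lin = stats.linregress(x, y)
        t = stats.t.ppf(0.975, 13)
        assert res.slope_ci == pytest.approx((lin.slope - t * lin.stderr, lin.slope + t * lin.stderr))
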