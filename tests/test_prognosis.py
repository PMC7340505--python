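"""Abundance, cut points, Cox models, Kaplan-Meier, diversity."""

import numpy as np
import pandas as pd
import pytest

from cytorisk.clustering import ClusterResult
from cytorisk.io import CohortManifest, ValidationError
from cytorisk.prognosis import (
    FitError,
    abundance_table,
    assign_high_low,
    classify_prognostic,
    cox_multivariate,
    cox_univariate,
    cut_point,
    diversity_association,
    iqr_cut_point,
    kaplan_meier,
    prognostic_report,
)

# abundance vector whose quartiles (linear interpolation) are exactly
# 0.67 and 3.36, reproducing the worked cut point of 2.69
WORKED_ABUNDANCES = [0.10, 0.67, 1.50, 3.36, 9.00]


class TestAbundance:
    def test_simple_tally(self):
        labels = np.array([3] * 25 + [1] * 75)
        clusters = ClusterResult(labels=labels, k=3, seed=0)
        pids = np.repeat("P1", 100)
        tab = abundance_table(clusters, pids)
        assert tab.loc["P1", 3] == pytest.approx(25.0)
        assert tab.loc["P1", 1] == pytest.approx(75.0)
        assert tab.loc["P1", 2] == 0.0

    def test_rows_sum_to_100_and_match_brute_force(self, rng):
        labels = rng.integers(1, 6, size=500)
        pids = rng.choice(["A", "B", "C"], size=500)
        tab = abundance_table(ClusterResult(labels=labels, k=5, seed=0), pids)
        np.testing.assert_allclose(tab.sum(axis=1), 100.0)
        for p in "ABC":
            for c in range(1, 6):
                expect = 100 * np.sum((pids == p) & (labels == c)) / np.sum(pids == p)
                assert tab.loc[p, c] == pytest.approx(expect)


class TestCutPoints:
    def test_worked_iqr_example(self):
        assert iqr_cut_point(WORKED_ABUNDANCES) == pytest.approx(2.69)

    def test_constant_vector(self):
        assert iqr_cut_point([5.0] * 8) == 0.0

    def test_matches_independent_quantiles(self, rng):
        a = rng.uniform(0, 30, size=40)
        q1, q3 = np.percentile(a, [25, 75])
        assert iqr_cut_point(a) == pytest.approx(q3 - q1)

    def test_minimum_cohort_size(self):
        with pytest.raises(ValidationError):
            iqr_cut_point([1.0, 2.0, 3.0])

    def test_alternative_rules(self, rng):
        a = rng.uniform(0, 30, size=40)
        assert cut_point(a, "tertile") == pytest.approx(np.quantile(a, 2 / 3))
        assert cut_point(a, "quartile") == pytest.approx(np.quantile(a, 0.75))
        with pytest.raises(ValidationError):
            cut_point(a, "median-ish")

    def test_high_low_boundary(self):
        grp = assign_high_low([2.69, 2.70, 0.5], 2.69)
        assert list(grp) == ["low", "high", "low"]  # boundary value is low
        assert list(assign_high_low([0.0, 0.0], 0.0)) == ["low", "low"]

    def test_high_low_monotone(self, rng):
        a = rng.uniform(0, 10, size=30)
        cut = 4.0
        grp = assign_high_low(a, cut)
        bumped = assign_high_low(a + 0.5, cut)
        # raising abundance never moves a patient high -> low
        assert not np.any((grp == "high") & (bumped == "low"))


def _grid_search_cox_beta(x, times, events, grid=None):
    """Brute-force maximiser of the Cox partial likelihood (no ties)."""
    grid = grid if grid is not None else np.arange(-5, 5, 1e-4)
    order = np.argsort(times)
    x, times, events = x[order], times[order], events[order]
    best_beta, best_ll = None, -np.inf
    for b in grid:
        risk = np.exp(b * x)
        ll = 0.0
        for i in range(len(x)):
            if events[i]:
                ll += b * x[i] - np.log(risk[i:].sum())
        if ll > best_ll:
            best_ll, best_beta = ll, b
    return best_beta


class TestCoxUnivariate:
    def test_null_case(self, rng):
        t = rng.exponential(100, size=400)
        grp = np.array(["high", "low"] * 200)
        hr, ci, p = cox_univariate(grp, t, np.ones(400, int))
        assert 0.8 < hr < 1.25
        assert p > 0.05
        assert ci[0] < 1 < ci[1]

    def test_exponential_rate_ratio_two(self, rng):
        n = 500
        t_high = rng.exponential(50, size=n)  # rate 2x the low group
        t_low = rng.exponential(100, size=n)
        grp = np.array(["high"] * n + ["low"] * n)
        hr, ci, p = cox_univariate(
            grp, np.concatenate([t_high, t_low]), np.ones(2 * n, int)
        )
        assert 1.8 <= hr <= 2.2
        assert p < 1e-6

    def test_four_subject_toy_matches_grid_search(self):
        times = np.array([2.0, 5.0, 11.0, 13.0])
        events = np.array([1, 1, 1, 0])
        grp = np.array(["high", "low", "high", "low"])
        hr, _, _ = cox_univariate(grp, times, events)
        x = (grp == "high").astype(float)
        beta_star = _grid_search_cox_beta(x, times, events)
        assert np.log(hr) == pytest.approx(beta_star, abs=1e-3)

    def test_group_swap_gives_reciprocal_hr(self, rng):
        t = np.concatenate([rng.exponential(40, 60), rng.exponential(90, 60)])
        e = np.ones(120, int)
        grp = np.array(["high"] * 60 + ["low"] * 60)
        swapped = np.where(grp == "high", "low", "high")
        hr1, _, p1 = cox_univariate(grp, t, e)
        hr2, _, p2 = cox_univariate(swapped, t, e)
        assert hr1 == pytest.approx(1 / hr2, rel=1e-6)
        assert p1 == pytest.approx(p2, rel=1e-6)

    def test_error_conditions(self):
        with pytest.raises(FitError, match="events"):
            cox_univariate(["high", "low"], [1.0, 2.0], [0, 0])
        with pytest.raises(FitError, match="nonempty"):
            cox_univariate(["high", "high"], [1.0, 2.0], [1, 1])


class TestClassify:
    @pytest.mark.parametrize(
        "hr,p,expect",
        [(2.0, 0.01, "negative"), (0.5, 0.01, "positive"), (2.0, 0.20, "NS"),
         (1.0, 0.01, "NS")],
    )
    def test_directions(self, hr, p, expect):
        assert classify_prognostic(hr, p) == expect

    def test_invalid_hr(self):
        with pytest.raises(ValidationError):
            classify_prognostic(-1.0, 0.01)


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(10, size=200)
        curves = kaplan_meier(t, np.ones(200, int))
        df = curves["all"]
        for time, s in zip(df["time"][1:], df["survival"][1:]):
            assert s == pytest.approx(np.mean(t > time), abs=1e-9)

    def test_all_censored_is_flat_one(self):
        curves = kaplan_meier([5.0, 8.0, 2.0], [0, 0, 0])
        assert np.all(curves["all"]["survival"] == 1.0)

    def test_textbook_product_limit(self):
        # events at 6, 13, 31 with censorings at 10 and 16:
        # S = 4/5 at t=6, 4/5 * 2/3 at t=13, 0 at t=31
        t = np.array([6.0, 10.0, 13.0, 16.0, 31.0])
        e = np.array([1, 0, 1, 0, 1])
        df = kaplan_meier(t, e)["all"].set_index("time")["survival"]
        assert df.loc[6.0] == pytest.approx(4 / 5)
        assert df.loc[13.0] == pytest.approx(4 / 5 * 2 / 3)
        assert df.loc[31.0] == pytest.approx(0.0)


class TestCoxMultivariate:
    def test_reduces_to_univariate_for_single_binary(self, rng):
        t = np.concatenate([rng.exponential(40, 80), rng.exponential(100, 80)])
        e = np.ones(160, int)
        x = np.array([1.0] * 80 + [0.0] * 80)
        df = pd.DataFrame({"T": t, "E": e, "high": x})
        m = cox_multivariate(df, "T", "E", ["high"])
        grp = np.where(x == 1, "high", "low")
        hr_uni, _, p_uni = cox_univariate(grp, t, e)
        assert m.summary.loc["high", "HR"] == pytest.approx(hr_uni, rel=1e-6)
        assert m.summary.loc["high", "p"] == pytest.approx(p_uni, rel=1e-6)
        # HR = exp(coef) exactly
        np.testing.assert_allclose(
            m.summary["HR"], np.exp(m.summary["coef"]), rtol=1e-12
        )

    def test_per_percent_effect_recovery(self, rng):
        """Abundance with true log-HR 0.07/percent: the CI covers HR 1.07
        in >= 90% of simulations at n = 300."""
        hits = 0
        n_sim = 20
        for s in range(n_sim):
            r = np.random.default_rng(1000 + s)
            abund = r.uniform(0, 30, size=300)
            age = r.normal(60, 8, size=300)
            rate = 0.002 * np.exp(0.07 * abund)
            t = r.exponential(1 / rate)
            df = pd.DataFrame(
                {"T": t, "E": 1, "abundance": abund, "Age": age}
            )
            m = cox_multivariate(df, "T", "E", ["abundance", "Age"])
            lo = m.summary.loc["abundance", "ci_low"]
            hi = m.summary.loc["abundance", "ci_high"]
            hits += lo <= np.exp(0.07) <= hi
        assert hits >= 0.9 * n_sim

    def test_constant_covariate_dropped(self, rng):
        df = pd.DataFrame(
            {
                "T": rng.exponential(50, 60),
                "E": 1,
                "x": rng.normal(size=60),
                "zero": 0.0,
            }
        )
        with pytest.warns(UserWarning, match="constant"):
            m = cox_multivariate(df, "T", "E", ["x", "zero"])
        assert m.dropped == ["zero"]
        assert "zero" not in m.summary.index

    def test_collinear_covariates_rejected(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame(
            {"T": rng.exponential(50, 50), "E": 1, "a": x, "b": 2 * x + 1}
        )
        with pytest.raises(FitError, match="collinear"):
            cox_multivariate(df, "T", "E", ["a", "b"])

    def test_schoenfeld_check_reported(self, rng):
        df = pd.DataFrame(
            {
                "T": rng.exponential(50, 100),
                "E": rng.integers(0, 2, 100),
                "x": rng.normal(size=100),
            }
        )
        df.loc[0, "E"] = 1  # guarantee at least one event
        m = cox_multivariate(df, "T", "E", ["x"], check_ph=True)
        assert m.ph_check is not None
        assert "x" in m.ph_check.index
        assert 0 <= float(m.ph_check.loc["x"]) <= 1


class TestDiversity:
    def test_constant_counts_undefined(self):
        ab = pd.DataFrame(np.full((6, 3), 20.0))
        with pytest.warns(UserWarning, match="constant"):
            rho, p = diversity_association(ab, np.arange(6) + 1.0)
        assert np.isnan(rho)

    def test_perfect_rank_alignment(self):
        # patient i has exactly i+1 clusters above 1%
        n = 8
        ab = np.full((n, n), 0.5)
        for i in range(n):
            ab[i, : i + 1] = 5.0
        rho, p = diversity_association(pd.DataFrame(ab), np.arange(n, dtype=float))
        assert rho == pytest.approx(1.0)

    def test_matches_manual_rank_correlation(self, rng):
        ab = pd.DataFrame(rng.uniform(0, 10, size=(20, 6)))
        t = rng.exponential(100, size=20)
        rho, _ = diversity_association(ab, t)
        counts = (ab > 1.0).sum(axis=1).to_numpy()
        rk = pd.Series(counts).rank().to_numpy()
        rt = pd.Series(t).rank().to_numpy()
        manual = np.corrcoef(rk, rt)[0, 1]
        assert rho == pytest.approx(manual, abs=1e-10)


class TestPrognosticReport:
    def test_report_on_constructed_cohort(self, rng):
        # cluster 1 abundance drives hazard; cluster 2 is noise
        n = 28
        a1 = rng.uniform(0, 40, size=n)
        a2 = rng.uniform(0, 40, size=n)
        rest = 100 - a1 - a2
        ab = pd.DataFrame(
            {1: a1, 2: a2, 3: rest}, index=[f"P{i:02d}" for i in range(n)]
        )
        rate = 0.002 * np.exp(0.1 * a1)
        man = CohortManifest(
            pd.DataFrame(
                {
                    "patient_id": ab.index,
                    "os_time": rng.exponential(1 / rate),
                    "os_event": 1,
                }
            )
        )
        rep = prognostic_report(ab, man)
        assert rep.table.loc[1, "direction"] == "negative"
        assert rep.table.loc[1, "HR"] > 1
        grp = rep.groups[1]
        assert set(grp.unique()) == {"high", "low"}
        assert rep.table.loc[1, "n_high"] + rep.table.loc[1, "n_low"] == n
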