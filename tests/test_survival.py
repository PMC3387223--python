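import itertools

import numpy as np
import pandas as pd
import pytest

from lungmeth.dataio import ValidationError
from lungmeth.survival import (
    cox_fit,
    cox_score_test,
    cox_wilcoxon_screen,
    discretize_beta,
    discretize_beta_array,
    exclude_early_deaths,
    kaplan_meier,
    km_curves,
    km_screen,
    logrank_test,
    wilcoxon_rank_sum,
)


def make_sheet(times, events, prefix="P"):
    ids = [f"{prefix}{i}" for i in range(len(times))]
    return pd.DataFrame(
        {
            "tissue": "tumor",
            "histology": "SCC",
            "survival_months": times,
            "event": [bool(e) for e in events],
            "pack_years": np.nan,
            "smoker": None,
            "replicate_group": None,
        },
        index=pd.Index(ids, name="sample_id"),
    )


class TestExclusion:
    def test_up_to_one_month_removed(self):
        sheet = make_sheet([0.5, 1.0, 1.1, 30.0], [1, 1, 0, 0])
        out, n = exclude_early_deaths(sheet)
        assert n == 2
        assert list(out.index) == ["P2", "P3"]

    def test_no_early_deaths_unchanged(self):
        sheet = make_sheet([5.0, 30.0], [1, 0])
        out, n = exclude_early_deaths(sheet)
        assert n == 0 and len(out) == 2

    def test_empty_sheet(self):
        sheet = make_sheet([], [])
        out, n = exclude_early_deaths(sheet)
        assert n == 0 and len(out) == 0


class TestDiscretize:
    @pytest.mark.parametrize(
        "beta, group",
        [(0.10, "low"), (0.50, "medium"), (0.90, "high"),
         (0.0, "low"), (0.25, "medium"), (0.75, "high"), (1.0, "high")],
    )
    def test_group_bounds(self, beta, group):
        assert discretize_beta(beta) == group

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            discretize_beta(1.2)
        with pytest.raises(ValidationError):
            discretize_beta_array(np.array([0.5, -0.1]))

    def test_array_agrees_with_scalar(self, rng):
        b = rng.random(50)
        names = ["low", "medium", "high"]
        assert [names[c] for c in discretize_beta_array(b)] == [
            discretize_beta(v) for v in b
        ]


def km_oracle(times, events):
    """Brute-force product-limit: walk event times, multiply survival."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    out = {}
    s = 1.0
    for t in sorted(set(times[events])):
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & events)
        s *= 1 - d / at_risk
        out[t] = s
    return out


class TestKaplanMeier:
    def test_all_censored_survival_stays_one(self):
        km = kaplan_meier([3, 5, 8], [0, 0, 0])
        assert km.empty  # no event times, S == 1 throughout

    def test_three_events_product_limit(self):
        km = kaplan_meier([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(km["survival"], [2 / 3, 1 / 3, 0.0])

    def test_single_subject_event(self):
        km = kaplan_meier([5.0], [1])
        assert km["survival"].iloc[0] == 0.0

    def test_censored_at_event_time_stays_at_risk(self):
        # event and censoring tied at t=2: the censored subject counts in the
        # risk set of that event
        km = kaplan_meier([2, 2, 3], [1, 0, 1])
        np.testing.assert_allclose(km["survival"], [2 / 3, 0.0])

    def test_matches_oracle_on_random_small_datasets(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            n = rng.integers(1, 11)
            times = rng.integers(1, 8, size=n).astype(float)
            events = rng.random(n) < 0.7
            if not events.any():
                continue
            km = kaplan_meier(times, events)
            oracle = km_oracle(times, events)
            assert dict(zip(km["time"], km["survival"])) == pytest.approx(oracle)

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        times = rng.exponential(20, 40)
        events = rng.random(40) < 0.7
        km = kaplan_meier(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for t, s in zip(km["time"], km["survival"]):
            assert s == pytest.approx(float(kmf.predict(t)), abs=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            kaplan_meier([], [])


def logrank_2x2_oracle(times, events, groups):
    """Per-event-time 2x2 tabulation for the two-group log-rank."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    groups = np.asarray(groups)
    g0 = np.unique(groups)[0]
    o_minus_e, var = 0.0, 0.0
    for t in sorted(set(times[events])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = np.sum(at_risk & (groups == g0))
        d = np.sum((times == t) & events)
        d1 = np.sum((times == t) & events & (groups == g0))
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_identical_groups_are_null(self):
        times = [1, 2, 3, 1, 2, 3]
        events = [1, 1, 1, 1, 1, 1]
        res = logrank_test(times, events, ["a"] * 3 + ["b"] * 3)
        assert res["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_toy_two_group_oracle(self):
        times = [1, 2, 3, 4, 5, 6]
        events = [1] * 6
        groups = ["a"] * 3 + ["b"] * 3
        res = logrank_test(times, events, groups)
        assert res["chi2"] == pytest.approx(
            logrank_2x2_oracle(times, events, groups), abs=1e-12
        )

    def test_matches_oracle_on_random_data(self, rng):
        for _ in range(25):
            n = rng.integers(6, 30)
            times = np.round(rng.exponential(10, n), 1)
            events = rng.random(n) < 0.8
            groups = rng.integers(0, 2, n)
            if len(np.unique(groups)) < 2 or not events.any():
                continue
            res = logrank_test(times, events, groups)
            assert res["chi2"] == pytest.approx(
                logrank_2x2_oracle(times, events, groups), abs=1e-9
            )

    def test_matches_lifelines_multigroup(self, rng):
        from lifelines.statistics import multivariate_logrank_test

        times = rng.exponential(15, 60)
        events = rng.random(60) < 0.7
        groups = rng.integers(0, 3, 60)
        res = logrank_test(times, events, groups)
        ref = multivariate_logrank_test(times, groups, events)
        assert res["chi2"] == pytest.approx(ref.test_statistic, abs=1e-8)
        assert res["p"] == pytest.approx(ref.p_value, abs=1e-10)

    def test_label_permutation_invariance(self, rng):
        times = rng.exponential(10, 20)
        events = rng.random(20) < 0.7
        groups = rng.integers(0, 2, 20)
        relabeled = np.where(groups == 0, "z", "a")
        a = logrank_test(times, events, groups)
        b = logrank_test(times, events, relabeled)
        assert a["chi2"] == pytest.approx(b["chi2"], abs=1e-12)

    def test_pre_event_censoring_leaves_statistic(self, rng):
        times = np.array([5.0, 6, 7, 8, 9, 10])
        events = np.ones(6, bool)
        groups = np.array([0, 1, 0, 1, 0, 1])
        base = logrank_test(times, events, groups)
        aug = logrank_test(
            np.append(times, 1.0), np.append(events, False), np.append(groups, 0)
        )
        assert aug["chi2"] == pytest.approx(base["chi2"], abs=1e-12)

    def test_time_unit_invariance(self, rng):
        times = rng.exponential(10, 30)
        events = rng.random(30) < 0.6
        groups = rng.integers(0, 2, 30)
        a = logrank_test(times, events, groups)
        b = logrank_test(times * 12.0, events, groups)
        assert a["chi2"] == pytest.approx(b["chi2"], abs=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test([1, 2], [1, 1], ["a", "a"])


class TestCox:
    def test_constant_covariate_flagged_degenerate(self):
        res = cox_fit([1, 2, 3, 4], [1, 1, 1, 0], [2.0, 2.0, 2.0, 2.0])
        assert not res.converged

    def test_score_test_equals_logrank_without_ties(self, rng):
        for _ in range(10):
            n = 30
            times = rng.exponential(10, n)  # continuous: no ties
            events = rng.random(n) < 0.8
            x = rng.integers(0, 2, n).astype(float)
            if len(np.unique(x)) < 2 or events.sum() < 2:
                continue
            score = cox_score_test(times, events, x)
            lr = logrank_test(times, events, x)
            assert score["chi2"] == pytest.approx(lr["chi2"], rel=1e-9)

    def test_matches_lifelines_on_tie_free_data(self, rng):
        from lifelines import CoxPHFitter

        n = 80
        x = rng.normal(size=n)
        times = rng.exponential(1.0 / np.exp(0.5 * x))
        events = rng.random(n) < 0.8
        res = cox_fit(times, events, x)
        df = pd.DataFrame({"T": times, "E": events, "x": x})
        ref = CoxPHFitter().fit(df, "T", "E")
        assert res.beta == pytest.approx(float(ref.params_["x"]), abs=1e-5)
        assert res.se == pytest.approx(float(ref.standard_errors_["x"]), abs=1e-5)

    def test_hazard_ratio_recovery(self):
        # unit-variance covariate, true hazard ratio 2 per unit, n = 200
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            x = rng.normal(size=200)
            times = rng.exponential(1.0 / (0.05 * 2.0**x))
            censor = rng.exponential(60, 200)
            obs = np.minimum(times, censor)
            events = times <= censor
            res = cox_fit(obs, events, x)
            if res.converged and 1.6 <= np.exp(res.beta) <= 2.5:
                hits += 1
        assert hits >= 90

    def test_time_unit_invariance(self, rng):
        times = rng.exponential(10, 40)
        events = rng.random(40) < 0.7
        x = rng.normal(size=40)
        a = cox_fit(times, events, x)
        b = cox_fit(times * 7.0, events, x)
        assert a.beta == pytest.approx(b.beta, abs=1e-8)


def wilcoxon_enumeration_oracle(x, y):
    """Two-sided exact p by enumerating every group-1 subset of the pooled
    ranks."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = np.argsort(np.argsort(pooled)) + 1
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = [
        sum(comb) - n1 * (n1 + 1) / 2
        for comb in itertools.combinations(range(1, len(pooled) + 1), n1)
    ]
    us = np.array(us)
    lo = np.mean(us <= u_obs)
    hi = np.mean(us >= u_obs)
    return min(1.0, 2 * min(lo, hi))


class TestWilcoxon:
    def test_separated_groups_exact_p(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res["exact"]
        assert res["p"] == pytest.approx(0.1)  # 2 * 1/20

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(20):
            n1, n2 = rng.integers(2, 7), rng.integers(2, 8)
            x = rng.normal(size=n1)
            y = rng.normal(0.5, 1, size=n2)
            res = wilcoxon_rank_sum(x, y)
            assert res["exact"]
            assert res["p"] == pytest.approx(
                wilcoxon_enumeration_oracle(x, y), abs=1e-12
            )

    def test_matches_scipy_exact(self, rng):
        from scipy.stats import mannwhitneyu

        x = rng.normal(size=6)
        y = rng.normal(size=8)
        res = wilcoxon_rank_sum(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert res["p"] == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_and_normal_agree_at_n8(self, rng):
        # the continuity-corrected normal approximation evaluated on the same
        # tie-free data stays within 0.02 of the exact p
        from scipy.stats import norm

        for _ in range(10):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            exact = wilcoxon_rank_sum(x, y)["p"]
            ranks = pd.Series(np.concatenate([x, y])).rank().to_numpy()
            u = ranks[:8].sum() - 8 * 9 / 2
            mu, sigma = 32.0, np.sqrt(8 * 8 * 17 / 12)
            z = (abs(u - mu) - 0.5) / sigma
            approx_p = 2 * norm.sf(max(z, 0))
            assert abs(exact - approx_p) < 0.02

    def test_equal_groups_large_p(self, rng):
        x = rng.normal(size=30)
        res = wilcoxon_rank_sum(x, rng.permutation(x))
        assert res["p"] > 0.5

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_rank_sum([], [1.0])


class TestScreens:
    def _beta_for_sizes(self, sizes, ids):
        vals = np.concatenate(
            [np.full(sizes[0], 0.1), np.full(sizes[1], 0.5), np.full(sizes[2], 0.9)]
        )
        noise = np.linspace(0, 0.04, len(vals))  # keep within bins, break ties
        return pd.DataFrame([vals + noise], index=["cgA"], columns=ids)

    def test_group_size_rule(self, rng):
        times = rng.exponential(30, 46) + 2
        sheet = make_sheet(times, rng.random(46) < 0.7)
        skipped = self._beta_for_sizes((4, 30, 12), sheet.index)
        assert len(km_screen(skipped, sheet)) == 0
        tested = self._beta_for_sizes((6, 30, 10), sheet.index)
        out = km_screen(tested, sheet)
        assert list(out.index) == ["cgA"]
        assert (out.loc["cgA", ["n_low", "n_medium", "n_high"]] == [6, 30, 10]).all()

    def test_two_populated_groups_suffice(self, rng):
        times = rng.exponential(30, 40) + 2
        sheet = make_sheet(times, rng.random(40) < 0.7)
        beta = self._beta_for_sizes((0, 30, 10), sheet.index)
        out = km_screen(beta, sheet)
        assert len(out) == 1

    def test_km_screen_empty_warns(self, rng):
        times = rng.exponential(30, 10) + 2
        sheet = make_sheet(times, np.ones(10))
        beta = pd.DataFrame([np.full(10, 0.5)], index=["cgA"], columns=sheet.index)
        # single populated group -> skipped -> empty result
        with pytest.warns(UserWarning, match="group-size"):
            out = km_screen(beta, sheet)
        assert out.empty

    def test_short_stratum_includes_24_months(self):
        times = [24.0, 10, 5, 70, 80, 90, 3, 15, 65, 75]
        events = [1, 1, 1, 0, 0, 1, 1, 1, 0, 0]
        sheet = make_sheet(times, events)
        beta = pd.DataFrame(
            [np.linspace(0.1, 0.9, 10)], index=["cgA"], columns=sheet.index
        )
        out = cox_wilcoxon_screen(beta, sheet)
        assert out.loc["cgA", "n_short"] == 5  # the 24.0-month death included

    def test_censored_short_survivor_not_in_short_stratum(self):
        times = [10.0, 12, 5, 70, 80, 90, 3, 15, 65, 75]
        events = [0, 1, 1, 0, 0, 1, 1, 1, 0, 0]  # first patient censored at 10
        sheet = make_sheet(times, events)
        beta = pd.DataFrame(
            [np.linspace(0.1, 0.9, 10)], index=["cgA"], columns=sheet.index
        )
        out = cox_wilcoxon_screen(beta, sheet)
        assert out.loc["cgA", "n_short"] == 4

    def test_small_stratum_rejected(self):
        sheet = make_sheet([5.0, 70, 80, 90], [1, 0, 0, 0])
        beta = pd.DataFrame([[0.1, 0.5, 0.6, 0.9]], index=["cgA"], columns=sheet.index)
        with pytest.raises(ValidationError, match="strata"):
            cox_wilcoxon_screen(beta, sheet)

    def test_planted_hazard_cpg_called_by_cox_wilcoxon(self):
        """The planted prognostic CpG (default hazard: e^1 per methylation
        group step) is called with the poor-survival group hypermethylated in
        most simulated cohorts."""
        from lungmeth import dataio, normalization
        from lungmeth.synthetic import SimulationConfig, simulate_dataset

        hits = usable = 0
        for seed in range(50):
            ds = simulate_dataset(SimulationConfig(seed=700 + seed))
            sheet = dataio.drop_duplicate_replicates(ds.sheet)
            qn = normalization.quantile_normalize(ds.beta[list(sheet.index)])
            sheet2, _ = exclude_early_deaths(sheet)
            prog = ds.truth.probes.query("prognostic").index
            try:
                cw = cox_wilcoxon_screen(qn.loc[prog], sheet2)
            except ValidationError:
                continue  # a stratum came out too small in this cohort
            usable += 1
            row = cw.iloc[0]
            hits += bool(row["combined_call"]) and row["delta_short_long"] > 0
        assert usable >= 35
        assert hits / usable >= 0.8

    def test_km_curves_step_export(self, default_qn, default_sheet, default_dataset):
        sheet, _ = exclude_early_deaths(default_sheet)
        prog = default_dataset.truth.probes.query("prognostic").index[0]
        curves = km_curves(default_qn.loc[prog], sheet)
        assert {"group", "time", "survival"} <= set(curves.columns)
        assert curves["survival"].between(0, 1).all()
        # survival is non-increasing within each group
        for _, grp in curves.groupby("group"):
            assert (np.diff(grp["survival"]) <= 1e-12).all()
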