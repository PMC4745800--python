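"""Median dichotomization, Cox treatment models, KM/log-rank and the screen."""

import numpy as np
import pandas as pd
import pytest

from rppamet import (
    ClinicalTable,
    DegenerateDataError,
    ExpressionMatrix,
    Metagene,
    cox_treatment_hr,
    dichotomize_at_median,
    interaction_test,
    km_logrank,
    screen,
    screen_report,
    forest_table,
)


def _clinical(time, event, arm, index=None, **covs):
    n = len(time)
    index = index or [f"s{i}" for i in range(n)]
    return ClinicalTable(pd.DataFrame(
        {"time": time, "event": event, "arm": arm, **covs},
        index=pd.Index(index, name="sample_id")))


def _sim_clinical(rng, n=300, log_hr=0.0, cens_frac=0.0, score=None,
                  interaction=0.0):
    arm = np.array(["treated", "control"])[rng.integers(0, 2, n)]
    treated = (arm == "treated").astype(float)
    z = np.zeros(n) if score is None else score
    lam = 0.05 * np.exp(treated * log_hr + treated * z * interaction)
    t = rng.exponential(1 / lam)
    if cens_frac > 0:
        c = rng.exponential(1 / (0.05 * cens_frac / (1 - cens_frac)), n)
        event = (t <= c).astype(int)
        t = np.minimum(t, c)
    else:
        event = np.ones(n, dtype=int)
    return _clinical(t, event, arm)


class TestDichotomize:
    def test_even_split(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        part = dichotomize_at_median(s)
        labels = part.to_series()
        assert list(labels[["a", "b"]]) == ["low", "low"]
        assert list(labels[["c", "d"]]) == ["high", "high"]

    def test_odd_n_median_sample_goes_low(self):
        s = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        assert dichotomize_at_median(s).to_series()["b"] == "low"

    def test_heavy_ties_at_median_all_low(self):
        s = pd.Series([1.0] * 6 + [9.0] * 4, index=[f"s{i}" for i in range(10)])
        labels = dichotomize_at_median(s).to_series()
        assert (labels[:6] == "low").all() and (labels[6:] == "high").all()

    def test_constant_scores_rejected(self):
        with pytest.raises(DegenerateDataError):
            dichotomize_at_median(pd.Series([2.0, 2.0, 2.0]))


class TestCoxTreatment:
    def test_all_censored_errors(self):
        clin = _clinical([1.0, 2.0, 3.0, 4.0], [0, 0, 0, 0],
                         ["treated", "control"] * 2)
        with pytest.raises(DegenerateDataError, match="events"):
            cox_treatment_hr(clin)

    def test_single_arm_errors(self):
        clin = _clinical([1.0, 2.0, 3.0], [1, 1, 1], ["treated"] * 3)
        with pytest.raises(DegenerateDataError, match="arms"):
            cox_treatment_hr(clin)

    def test_relabeling_arms_inverts_hr(self, rng):
        clin = _sim_clinical(rng, n=250, log_hr=np.log(0.5))
        res = cox_treatment_hr(clin)
        swapped = clin.data.copy()
        swapped["arm"] = np.where(swapped["arm"] == "treated", "control", "treated")
        res_sw = cox_treatment_hr(ClinicalTable(swapped))
        assert res_sw.hr == pytest.approx(1 / res.hr, rel=1e-6)
        assert res_sw.p == pytest.approx(res.p, rel=1e-6)

    def test_null_hr_near_one(self, rng):
        res = cox_treatment_hr(_sim_clinical(rng, n=2000, log_hr=0.0))
        assert res.ci_lo < 1.0 < res.ci_hi

    def test_covariate_adjustment_runs(self, rng):
        clin = _sim_clinical(rng, n=200, log_hr=np.log(0.7))
        df = clin.data.copy()
        df["grade"] = rng.choice(["g1", "g2", "g3"], len(df))
        res = cox_treatment_hr(ClinicalTable(df), covariates=["grade"])
        assert res.converged and np.isfinite(res.hr)

    def test_monotone_likelihood_flagged_not_raised(self):
        # all treated events early, all control censored late: no exception
        clin = _clinical([1.0, 1.5, 2.0, 30.0, 31.0, 32.0], [1, 1, 1, 0, 0, 1],
                         ["treated"] * 3 + ["control"] * 3)
        res = cox_treatment_hr(clin)
        if not res.converged:
            assert res.ci_hi == np.inf and res.ci_lo == 0.0


class TestInteraction:
    def test_constant_score_rejected(self, rng):
        clin = _sim_clinical(rng, n=50)
        with pytest.raises(DegenerateDataError, match="constant"):
            interaction_test(clin, pd.Series(1.0, index=clin.data.index))

    def test_planted_interaction_detected(self, rng):
        z = rng.standard_normal(400)
        clin = _sim_clinical(rng, n=400, score=z, interaction=1.0)
        p = interaction_test(clin, pd.Series(z, index=clin.data.index))
        assert p < 0.01

    def test_no_interaction_large_p_mostly(self, rng):
        ps = []
        for _ in range(30):
            z = rng.standard_normal(200)
            clin = _sim_clinical(rng, n=200, score=z, interaction=0.0)
            ps.append(interaction_test(clin, pd.Series(z, index=clin.data.index)))
        assert np.mean(np.array(ps) < 0.05) <= 0.2

    def test_score_scaling_leaves_continuous_p_unchanged(self, rng):
        z = rng.standard_normal(300)
        clin = _sim_clinical(rng, n=300, score=z, interaction=0.8)
        s = pd.Series(z, index=clin.data.index)
        p1 = interaction_test(clin, s)
        p2 = interaction_test(clin, s * 37.0)
        assert p1 == pytest.approx(p2, rel=1e-5)


class TestKmLogrank:
    def test_identical_groups_agree(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0] * 2
        events = [1, 0, 1, 1, 0] * 2
        clin = _clinical(times, events, ["treated", "control"] * 5)
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=clin.data.index)
        # same survival data in both groups
        clin.data.iloc[5:, 0] = clin.data.iloc[:5, 0].to_numpy()
        clin.data.iloc[5:, 1] = clin.data.iloc[:5, 1].to_numpy()
        curves, chi2, p = km_logrank(groups, clin)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_complete_separation_tiny_p(self, rng):
        t_a = rng.uniform(1, 2, 50)
        t_b = rng.uniform(10, 20, 50)
        clin = _clinical(np.r_[t_a, t_b], np.ones(100, int),
                         ["treated", "control"] * 50)
        groups = pd.Series(["a"] * 50 + ["b"] * 50, index=clin.data.index)
        curves, chi2, p = km_logrank(groups, clin)
        assert p < 1e-10
        assert set(curves) == {"a", "b"}
        # survival curves are non-increasing step functions from 1.0
        for c in curves.values():
            assert c["survival"].iloc[0] == 1.0
            assert (np.diff(c["survival"]) <= 1e-12).all()

    def test_hazard_ratio_two_power(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            t_a = r.exponential(1 / 0.10, 500)
            t_b = r.exponential(1 / 0.05, 500)
            clin = _clinical(np.r_[t_a, t_b], np.ones(1000, int),
                             ["treated", "control"] * 500)
            groups = pd.Series(["a"] * 500 + ["b"] * 500, index=clin.data.index)
            if km_logrank(groups, clin)[2] < 0.001:
                hits += 1
        assert hits >= 19

    def test_single_group_rejected(self):
        clin = _clinical([1.0, 2.0], [1, 1], ["treated", "control"])
        with pytest.raises(DegenerateDataError):
            km_logrank(pd.Series(["a", "a"], index=clin.data.index), clin)


class TestScreen:
    def test_empty_metagene_list_is_empty_result(self, small_cohorts):
        derivation, _ = small_cohorts
        assert screen([], derivation.expr, derivation.clinical) == []

    def test_scaling_scores_leaves_dichotomous_screen_identical(self, small_cohorts):
        derivation, _ = small_cohorts
        mg = {name: dict(m) for name, m in derivation.truth.true_members.items()}
        name = derivation.truth.interaction_protein
        base = Metagene(name, mg[name])
        res1 = screen([base], derivation.expr, derivation.clinical)
        scaled_expr = ExpressionMatrix(derivation.expr.data * 5.0)
        res2 = screen([base], scaled_expr, derivation.clinical)
        assert res1[0].p_interaction_dichotomous == pytest.approx(
            res2[0].p_interaction_dichotomous, rel=1e-6)
        assert res1[0].hr_low.hr == pytest.approx(res2[0].hr_low.hr, rel=1e-6)

    def test_planted_metagene_flagged_with_small_q(self, small_cohorts):
        derivation, _ = small_cohorts
        truth = derivation.truth
        mgs = [Metagene(n, dict(m)) for n, m in truth.true_members.items()]
        results = screen(mgs, derivation.expr, derivation.clinical,
                         covariates=["age"])
        rep = screen_report(results)
        assert rep.index[0] == truth.interaction_protein
        assert rep["q_interaction"].iloc[0] < 0.05

    def test_per_stratum_hrs_mirror_planted_benefit_pattern(self, small_cohorts):
        derivation, _ = small_cohorts
        truth = derivation.truth
        mg = Metagene(truth.interaction_protein,
                      dict(truth.true_members[truth.interaction_protein]))
        res = screen([mg], derivation.expr, derivation.clinical)[0]
        # benefit concentrated in the score-low stratum, absent in the high
        assert res.hr_low.hr < res.hr_high.hr

    def test_forest_table_consistent_with_results(self, small_cohorts):
        derivation, _ = small_cohorts
        truth = derivation.truth
        mgs = [Metagene(n, dict(m)) for n, m in truth.true_members.items()]
        results = screen(mgs, derivation.expr, derivation.clinical)
        ft = forest_table(results)
        assert set(ft["stratum"]) == {"low", "high"}
        for r in results:
            row = ft[(ft["metagene"] == r.metagene_name) & (ft["stratum"] == "low")]
            assert row["hr"].iloc[0] == pytest.approx(r.hr_low.hr)
            assert (row["ci_lo"].iloc[0] <= row["hr"].iloc[0] <= row["ci_hi"].iloc[0])

    def test_subgroup_restriction(self, small_cohorts):
        derivation, _ = small_cohorts
        truth = derivation.truth
        df = derivation.clinical.data.copy()
        df["er"] = ["pos", "neg"] * (len(df) // 2)
        clin = ClinicalTable(df)
        mg = Metagene(truth.interaction_protein,
                      dict(truth.true_members[truth.interaction_protein]))
        full = screen([mg], derivation.expr, clin)[0]
        sub = screen([mg], derivation.expr, clin, subgroup=("er", "neg"))[0]
        assert sum(sub.n_per_cell.values()) == len(df) // 2
        assert sum(full.n_per_cell.values()) == len(df)
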