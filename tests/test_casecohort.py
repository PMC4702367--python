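"""Risk sets, coefficient models and the pseudo-partial likelihood."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from tvcc import (
    CaseCohort,
    ConfigurationError,
    ConstantCoefficient,
    CustomBasisCoefficient,
    LinearCoefficient,
    PeriodGrid,
    SeparationError,
    StepCoefficient,
    build_risk_sets,
    evaluate_beta,
)

from conftest import make_subjects


def synthetic_cohort(n=300, seed=0, with_entry=True):
    """Small synthetic cohort-style case-control table: continuous event and
    censoring ages, Bernoulli exposure, one covariate."""
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n)
    z = rng.normal(size=n)
    entry = rng.uniform(0, 3, n) if with_entry else np.zeros(n)
    # exponential event times modulated by x and z, censored administratively
    rate = 0.05 * np.exp(-0.7 * x + 0.4 * z)
    event = entry + rng.exponential(1 / rate, n)
    censor = entry + rng.uniform(5, 25, n)
    is_case = event < censor
    index = np.where(is_case, event, censor)
    df = make_subjects([
        (f"s{i}", int(is_case[i]), entry[i], index[i], int(x[i]), 0.0, "a")
        for i in range(n)
    ])
    df["z1"] = z
    return df


class TestCoefficientModels:
    def test_step_evaluates_period_log_hr(self, grid):
        coef = np.log([0.25, 0.34, 0.46, 0.62])
        model = StepCoefficient(grid)
        assert evaluate_beta(model, 2.0, coef) == pytest.approx(np.log(0.25))
        assert evaluate_beta(model, 17.5, coef) == pytest.approx(np.log(0.62))

    def test_linear_and_constant(self):
        assert evaluate_beta(LinearCoefficient(), 10.0, [-1.5, 0.07]) == pytest.approx(-0.8)
        assert evaluate_beta(ConstantCoefficient(), 3.3, [0.0]) == 0.0

    def test_step_outside_grid_errors(self, grid):
        from tvcc import PeriodAssignmentError
        with pytest.raises(PeriodAssignmentError):
            evaluate_beta(StepCoefficient(grid), 25.0, np.zeros(4))

    def test_custom_basis_matches_linear(self):
        cb = CustomBasisCoefficient([lambda t: np.ones_like(t), lambda t: t])
        t = np.array([0.0, 3.0, 11.0])
        np.testing.assert_allclose(cb.basis(t), LinearCoefficient().basis(t))


class TestRiskSets:
    def test_membership_inequalities(self):
        subj = make_subjects([
            ("case", 1, 0.0, 3.0, 1, 0.0, "a"),
            ("c1", 0, 0.0, 14.0, 0, np.nan, "a"),   # at risk at t=3
            ("c2", 0, 0.0, 2.0, 0, np.nan, "a"),    # index before the event
            ("c3", 0, 4.0, 10.0, 0, np.nan, "a"),   # enters after the event
        ])
        (rs,) = build_risk_sets(subj)
        members = set(subj.loc[rs.member_rows, "id"])
        assert members == {"case", "c1"}

    def test_control_at_risk_at_own_index_time(self):
        # right-closed at-risk convention: T_I = t_j still counts
        subj = make_subjects([
            ("case", 1, 0.0, 5.0, 1, 0.0, "a"),
            ("c1", 0, 0.0, 5.0, 0, np.nan, "a"),
        ])
        (rs,) = build_risk_sets(subj)
        assert rs.member_rows.size == 2

    def test_stratification_can_empty_the_comparison_set(self, caplog):
        subj = make_subjects([
            ("case", 1, 0.0, 3.0, 1, 0.0, "A"),
            ("c1", 0, 0.0, 14.0, 0, np.nan, "B"),
        ])
        with caplog.at_level("WARNING", logger="tvcc.casecohort"):
            (rs,) = build_risk_sets(subj, stratified=True)
        assert rs.member_rows.size == 1
        assert any("only the case" in m for m in caplog.messages)

    def test_breslow_ties_give_identical_risk_sets(self):
        rows = [("case1", 1, 0.0, 7.0, 1, 0.0, "a"),
                ("case2", 1, 0.0, 7.0, 0, np.nan, "a")]
        rows += [(f"c{i}", 0, 0.0, 10.0, i % 2, 0.0 if i % 2 else np.nan, "a")
                 for i in range(5)]
        sets = build_risk_sets(make_subjects(rows))
        assert len(sets) == 2
        assert all(rs.member_rows.size == 6 for rs in sets)

    def test_cases_do_not_enter_other_risk_sets_by_default(self):
        subj = make_subjects([
            ("early", 1, 0.0, 3.0, 1, 0.0, "a"),
            ("late", 1, 0.0, 8.0, 0, np.nan, "a"),
            ("c1", 0, 0.0, 9.0, 1, 0.0, "a"),
        ])
        early, late = build_risk_sets(subj)
        assert early.member_rows.size == 2     # the late case is excluded
        withf = build_risk_sets(subj, include_case_followup=True)
        assert withf[0].member_rows.size == 3  # ... unless in the subcohort


class TestPseudoPartialLikelihood:
    def test_symmetric_risk_set_is_coin_flip(self):
        subj = make_subjects([
            ("case", 1, 0.0, 3.0, 1, 0.0, "a"),
            ("c1", 0, 0.0, 10.0, 1, 0.0, "a"),
        ])
        model = CaseCohort(subj, ConstantCoefficient())
        for beta in (-2.0, 0.0, 1.5):
            assert model.loglik([beta]) == pytest.approx(np.log(0.5))

    def test_single_contrast_closed_form_and_separation(self):
        subj = make_subjects([
            ("case", 1, 0.0, 3.0, 1, 0.0, "a"),
            ("c1", 0, 0.0, 10.0, 0, np.nan, "a"),
        ])
        model = CaseCohort(subj, ConstantCoefficient())
        for b in (-1.0, 0.0, 2.0):
            assert model.loglik([b]) == pytest.approx(b - np.logaddexp(0.0, b))
        with pytest.raises(SeparationError):
            model.fit()

    def test_brute_force_toy(self):
        """Likelihood, score and Hessian match an explicit term-by-term
        evaluation over the three risk sets."""
        subj = make_subjects([
            ("i1", 1, 0.0, 2.0, 1, 0.0, "a"),
            ("i2", 1, 0.0, 5.5, 0, np.nan, "a"),
            ("i3", 1, 0.0, 8.0, 1, 0.0, "a"),
            ("k1", 0, 0.0, 9.0, 1, 0.0, "a"),
            ("k2", 0, 0.0, 6.0, 0, np.nan, "a"),
            ("k3", 0, 3.0, 12.0, 1, 0.0, "a"),
            ("k4", 0, 0.0, 1.5, 0, np.nan, "a"),
        ])
        subj["z1"] = [0.3, -0.2, 1.1, 0.0, 0.4, -0.5, 0.8]
        grid = PeriodGrid((0, 5, 10))
        model = CaseCohort(subj, StepCoefficient(grid), time_axis="t")
        theta = np.array([-0.9, -0.2, 0.35])  # beta1, beta2, gamma

        def eta(row, t):
            x = subj.loc[row, "exposure"]
            b = theta[0] if t < 5 else theta[1]
            return b * x + theta[2] * subj.loc[row, "z1"]

        expected = 0.0
        at_risk = lambda r, t: (subj.loc[r, "is_case"] == 0
                                and subj.loc[r, "entry_time"] < t <= subj.loc[r, "index_time"])
        for case_row in (0, 1, 2):
            t = subj.loc[case_row, "index_time"]
            members = [case_row] + [r for r in range(len(subj)) if at_risk(r, t)]
            denom = sum(np.exp(eta(r, t)) for r in members)
            expected += eta(case_row, t) - np.log(denom)

        ll, score, hess = model.objective(theta)
        assert ll == pytest.approx(expected, abs=1e-12)
        # analytic score and Hessian against numerical differentiation
        eps = 1e-6
        for j in range(3):
            d = np.zeros(3); d[j] = eps
            num = (model.loglik(theta + d) - model.loglik(theta - d)) / (2 * eps)
            assert score[j] == pytest.approx(num, abs=1e-6)
            num_h = (model.objective(theta + d)[1] - model.objective(theta - d)[1]) / (2 * eps)
            np.testing.assert_allclose(hess[:, j], num_h, atol=1e-5)

    def test_time_varying_exposure_status(self):
        """A member unexposed at t_j contributes exp(gamma'z) only; exposed
        members use their own time since exposure."""
        subj = make_subjects([
            ("case", 1, 0.0, 6.0, 1, 1.0, "a"),   # exposed at age 1 -> u = 5
            ("c1", 0, 0.0, 10.0, 1, 8.0, "a"),    # not yet exposed at t=6
            ("c2", 0, 0.0, 10.0, 1, 4.0, "a"),    # exposed, u = 2
        ])
        grid = PeriodGrid((0, 4, 8))
        model = CaseCohort(subj, StepCoefficient(grid), time_axis="u")
        b = np.array([-1.0, -0.4])
        # case: u=5 -> beta2; c1: x(6)=0 -> 0; c2: u=2 -> beta1
        expected = b[1] - np.log(np.exp(b[1]) + 1.0 + np.exp(b[0]))
        assert model.loglik(b) == pytest.approx(expected, abs=1e-12)


class TestFitEquivalences:
    def test_full_cohort_limit_matches_cox_partial_likelihood(self):
        """With cases at risk over (T_E, T_I] the fit equals a standard Cox
        model with left truncation (independent lifelines oracle)."""
        subj = synthetic_cohort(n=300, seed=3)
        model = CaseCohort(subj, ConstantCoefficient(), include_case_followup=True,
                           time_axis="t")
        res = model.fit()
        df = pd.DataFrame({
            "start": subj["entry_time"], "stop": subj["index_time"],
            "event": subj["is_case"], "x": subj["exposure"], "z1": subj["z1"],
        })
        cph = CoxPHFitter()
        cph.fit(df, duration_col="stop", event_col="event", entry_col="start",
                fit_options={"precision": 1e-11})
        assert res.params["x"] == pytest.approx(cph.params_["x"], abs=1e-6)
        assert res.params["z1"] == pytest.approx(cph.params_["z1"], abs=1e-6)
        assert res.bse["x"] == pytest.approx(cph.standard_errors_["x"], rel=1e-5)
        assert res.llf == pytest.approx(cph.log_likelihood_, abs=1e-5)

    def test_default_mode_matches_cox_with_case_entry_shift(self):
        """Cases entering only at their own event time equals the standard-
        software recipe: shift each case's entry to just before its event."""
        subj = synthetic_cohort(n=250, seed=9)
        res = CaseCohort(subj, ConstantCoefficient(), time_axis="t").fit()
        eps = 1e-9
        start = np.where(subj["is_case"] == 1, subj["index_time"] - eps,
                         subj["entry_time"])
        df = pd.DataFrame({
            "start": start, "stop": subj["index_time"], "event": subj["is_case"],
            "x": subj["exposure"], "z1": subj["z1"],
        })
        cph = CoxPHFitter()
        cph.fit(df, duration_col="stop", event_col="event", entry_col="start",
                fit_options={"precision": 1e-11})
        assert res.params["x"] == pytest.approx(cph.params_["x"], abs=1e-6)
        assert res.params["z1"] == pytest.approx(cph.params_["z1"], abs=1e-6)

    def test_robust_close_to_model_when_one_risk_set_per_subject(self):
        """Disjoint strata with one case each: every subject enters exactly
        one risk set, so the sandwich agrees with the inverse information up
        to a small-sample factor."""
        rng = np.random.default_rng(4)
        rows = []
        for s in range(60):
            rows.append((f"case{s}", 1, 0.0, rng.uniform(1, 9), int(rng.random() < 0.4),
                         0.0, f"st{s}"))
            for j in range(3):
                rows.append((f"c{s}_{j}", 0, 0.0, 10.0, int(rng.random() < 0.6),
                             0.0, f"st{s}"))
        res = CaseCohort(make_subjects(rows), ConstantCoefficient(),
                         stratified=True, time_axis="t").fit()
        ratio = res.robust_bse["x"] / res.bse["x"]
        assert 0.8 < ratio < 1.2

    def test_constant_beta_recovered_within_mc_error(self):
        subj = synthetic_cohort(n=2000, seed=12)
        res = CaseCohort(subj, ConstantCoefficient(), include_case_followup=True,
                         time_axis="t").fit()
        assert abs(res.params["x"] - (-0.7)) < 2.5 * res.bse["x"]
        assert abs(res.params["z1"] - 0.4) < 2.5 * res.bse["z1"]

    def test_step_fit_on_constant_data_is_mutually_compatible(self):
        """Per-period estimates of a step model fitted to constant-effect
        data agree with the constant fit within their SEs."""
        subj = synthetic_cohort(n=2000, seed=21)
        const = CaseCohort(subj, ConstantCoefficient(), time_axis="t").fit()
        grid = PeriodGrid((0, 7, 14, 30))
        step = CaseCohort(subj, StepCoefficient(grid), time_axis="t").fit()
        for name in step.beta_params.index:
            z = (step.params[name] - const.params["x"]) / step.robust_bse[name]
            assert abs(z) < 3

    def test_no_cases_errors(self):
        subj = make_subjects([("c1", 0, 0.0, 10.0, 1, 0.0, "a")])
        with pytest.raises(ConfigurationError):
            CaseCohort(subj, ConstantCoefficient())


@pytest.fixture(scope="module")
def study_sample(midsize_config):
    from tvcc import simulate_case_control
    return simulate_case_control(midsize_config, seed=31)


class TestStudyScaleProperties:

    def test_score_is_centred_at_the_generating_parameters(self, study_sample):
        """The pseudo-partial-likelihood score at the true step coefficients
        is within Monte-Carlo error of zero (its variance is approximately
        the observed information)."""
        subjects, truth = study_sample
        grid = PeriodGrid((0, 5, 10, 15, 20))
        model = CaseCohort(subjects, StepCoefficient(grid), stratified=True,
                           time_axis="t")
        theta = np.array(list(truth["log_hr_schedule"].values()))
        _, score, hess = model.objective(theta)
        sd = np.sqrt(np.diag(-hess))
        assert np.all(np.abs(score) < 3.5 * sd)

    def test_fine_grid_logistic_approaches_case_cohort(self, study_sample):
        """With short periods and few cases per period the reused-control
        logistic fit (definition i) approaches the case-cohort step fit:
        per-period estimates agree well within their joint uncertainty."""
        from tvcc import LogisticSpec, PeriodLogistic

        subjects, _ = study_sample
        fine = PeriodGrid(np.arange(0, 20.1, 2.5))
        log_res = PeriodLogistic(subjects, fine, definition="i",
                                 spec=LogisticSpec(robust_se=True)).fit()
        cc_res = CaseCohort(subjects, StepCoefficient(fine), time_axis="t").fit()
        for l, label in enumerate(fine.labels):
            d = log_res.params[f"x:{label}"] - cc_res.params[f"x:{label}"]
            joint = np.hypot(log_res.bse[f"x:{label}"],
                             cc_res.robust_bse[f"x:{label}"])
            assert abs(d) < 2 * joint, label

    def test_linear_waning_trend_is_recovered(self, study_sample):
        """A linear beta(t) fitted to step-waning data picks up the rising
        trend (positive slope) and evaluates smoothly with delta-method SEs."""
        subjects, _ = study_sample
        res = CaseCohort(subjects, LinearCoefficient(), stratified=True,
                         time_axis="t").fit()
        assert res.converged
        b0, b1 = res.beta_params
        assert b1 > 0  # efficacy wanes: log HR rises with age
        curve = res.beta_at([2.0, 10.0, 18.0], robust=True)
        assert np.all(np.isfinite(curve["se"]))
        assert curve["log_hr"].is_monotonic_increasing
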