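"""Mixed-model estimation, oracles and trajectory projections."""

import numpy as np
import pandas as pd
import pytest

import stepbandit as sb
from stepbandit.cohort import SimConfig, generate_cohort, simulate_step_log
from stepbandit.lmm import (
    DEFAULT_HORIZON,
    StepTrajectoryLMM,
    StepTrajectoryResults,
    fit_lmm,
    subgroup_fit,
)


def _simulated_log(seed=0, n=30, n_days=60, sigma_b2=4e6, residual_sd=1500.0):
    per = n // 3
    cfg = SimConfig(
        n_participants=n,
        arm_sizes=(n - 2 * per, per, per),
        n_days=n_days,
        sigma_b2=sigma_b2,
        residual_sd=residual_sd,
        missing_days_mean={"control": 5.0, "random": 4.0, "adaptive": 3.0},
    )
    rng = np.random.default_rng(seed)
    return simulate_step_log(generate_cohort(cfg, rng), n_days, rng)


class TestEstimation:
    def test_gls_with_zero_variance_ratio_is_exactly_ols(self):
        log = _simulated_log(seed=1)
        model = StepTrajectoryLMM.from_step_log(log)
        res = model.fit(gamma=0.0)
        beta_ols, *_ = np.linalg.lstsq(model.X, model.y, rcond=None)
        assert np.allclose(res.params.to_numpy(), beta_ols, atol=1e-8)

    def test_data_without_person_variance_collapses_to_ols(self):
        # seed chosen so the REML profile hits the zero-variance boundary
        # (about half of zero-variance replicates do; the rest estimate a
        # small positive variance and GLS shrinks accordingly)
        log = _simulated_log(seed=1, sigma_b2=0.0)
        model = StepTrajectoryLMM.from_step_log(log)
        res = model.fit()
        assert res.sigma_b2 == pytest.approx(0.0, abs=1e-3)
        beta_ols, *_ = np.linalg.lstsq(model.X, model.y, rcond=None)
        rel = np.abs(res.params.to_numpy() - beta_ols) / np.abs(beta_ols)
        assert rel.max() < 1e-6

    def test_perfectly_flat_arms_fit_exactly(self):
        rows = []
        for pid, (arm, level) in enumerate(
            [("adaptive", 3000)] * 3 + [("control", 3500)] * 3
        ):
            for day in range(10):
                rows.append((f"P{pid}", day, level, arm))
        log = pd.DataFrame(rows, columns=["participant_id", "day", "steps", "arm"])
        res = fit_lmm(log)
        assert res.arm_slope("adaptive") == pytest.approx(0.0, abs=1e-6)
        assert res.arm_slope("control") == pytest.approx(0.0, abs=1e-6)
        assert res.params["control"] == pytest.approx(500.0, abs=1e-6)
        assert res.sigma_e2 < 1e-6

    def test_matches_statsmodels_mixedlm(self):
        """Independent REML implementation agrees with statsmodels."""
        import statsmodels.formula.api as smf

        log = _simulated_log(seed=3)
        obs = log[log.observed]
        res = fit_lmm(log)
        sm_fit = smf.mixedlm(
            "steps ~ C(arm, Treatment('adaptive'))*day",
            obs,
            groups=obs["participant_id"],
        ).fit(reml=True)
        ours = res.params
        theirs = {
            "intercept": sm_fit.params["Intercept"],
            "control": sm_fit.params["C(arm, Treatment('adaptive'))[T.control]"],
            "random": sm_fit.params["C(arm, Treatment('adaptive'))[T.random]"],
            "day": sm_fit.params["day"],
            "control:day": sm_fit.params["C(arm, Treatment('adaptive'))[T.control]:day"],
            "random:day": sm_fit.params["C(arm, Treatment('adaptive'))[T.random]:day"],
        }
        for name, value in theirs.items():
            assert ours[name] == pytest.approx(value, rel=1e-3, abs=1e-3)
        assert res.sigma_e2 == pytest.approx(sm_fit.scale, rel=1e-2)
        assert res.sigma_b2 == pytest.approx(
            float(sm_fit.cov_re.iloc[0, 0]), rel=2e-2
        )
        assert res.bse["day"] == pytest.approx(sm_fit.bse["day"], rel=1e-2)

    def test_likelihood_ratio_of_nested_models_nonnegative(self):
        for seed in (0, 5, 9):
            log = _simulated_log(seed=seed, n=18, n_days=30)
            obs = log[log.observed]
            full = StepTrajectoryLMM(obs).fit(method="ml")
            reduced = StepTrajectoryLMM(obs, include_interactions=False).fit(method="ml")
            assert full.llf >= reduced.llf - 1e-6

    def test_preconditions_and_errors(self):
        log = _simulated_log(seed=2)
        one_day = log[log.day == 0]
        with pytest.raises(ValueError, match=">=2"):
            StepTrajectoryLMM(one_day)
        with pytest.raises(ValueError, match="arm"):
            StepTrajectoryLMM(log.assign(arm="placebo"))
        res = fit_lmm(log)
        with pytest.raises(ValueError, match="unknown arm"):
            res.arm_baseline("placebo")
        with pytest.raises(ValueError, match="method"):
            StepTrajectoryLMM.from_step_log(log).fit(method="mcmc")


REFERENCE_COEFS = dict(
    intercept=3196.79,
    control=283.32,
    random=500.92,
    day=3.61,
    control_day=-2.80,
    random_day=-3.26,
)


@pytest.fixture(scope="module")
def res():
    return StepTrajectoryResults.from_fixed_effects(**REFERENCE_COEFS)


class TestProjections:
    """Derived trajectory quantities from a fixed coefficient table."""

    def test_arm_baselines(self, res):
        assert res.arm_baseline("adaptive") == pytest.approx(3196.79)
        assert round(res.arm_baseline("control")) == 3480
        assert round(res.arm_baseline("random")) == 3698

    def test_arm_slopes(self, res):
        assert res.arm_slope("adaptive") == pytest.approx(3.61)
        assert res.arm_slope("control") == pytest.approx(0.81)
        assert res.arm_slope("random") == pytest.approx(0.35)

    def test_horizon_gains(self, res):
        assert round(res.project_gain("adaptive")) == 606
        assert round(res.project_gain("control")) == 136
        assert round(res.project_gain("random")) == 59
        with pytest.raises(ValueError, match="horizon"):
            res.project_gain("adaptive", horizon=0)

    def test_percent_changes(self, res):
        assert round(res.percent_change("adaptive")) == 19
        assert round(res.percent_change("control"), 1) == 3.9
        assert round(res.percent_change("random"), 1) == 1.6

    def test_web_like_subsample_arithmetic(self):
        web = StepTrajectoryResults.from_fixed_effects(intercept=3156.0, day=2.3)
        assert round(web.percent_change("adaptive"), 1) == 12.2

    def test_identities_hold_for_fitted_models(self):
        res = fit_lmm(_simulated_log(seed=6))
        for arm in ("adaptive", "control", "random"):
            gain = res.project_gain(arm, DEFAULT_HORIZON)
            assert gain == res.arm_slope(arm) * DEFAULT_HORIZON
            assert res.percent_change(arm) == 100.0 * gain / res.arm_baseline(arm)
        table = res.projection_table()
        assert list(table.columns) == [
            "arm", "baseline", "slope", "horizon", "gain", "percent",
        ]
        assert len(table) == 3

    def test_zero_baseline_percent_is_undefined(self):
        res = StepTrajectoryResults.from_fixed_effects(intercept=0.0, day=1.0)
        with pytest.raises(ValueError, match="baseline"):
            res.percent_change("adaptive")

    def test_zero_slope_projects_zero_gain(self):
        res = StepTrajectoryResults.from_fixed_effects(intercept=3000.0)
        assert res.project_gain("adaptive") == 0.0


class TestSubgroups:
    def test_single_group_matches_full_fit(self):
        log = _simulated_log(seed=4).assign(recruitment_source="web")
        sub = subgroup_fit(log)
        assert set(sub) == {"web"}
        pd.testing.assert_series_equal(sub["web"].params, fit_lmm(log).params)

    def test_swapped_labels_swap_outputs(self):
        log = _simulated_log(seed=5, n=36)
        ids = sorted(log.participant_id.unique())
        first_half = set(ids[: len(ids) // 2])
        labels = log.participant_id.isin(first_half).map({True: "clinic", False: "web"})
        sub = subgroup_fit(log.assign(recruitment_source=labels))
        swapped = subgroup_fit(
            log.assign(
                recruitment_source=labels.map({"clinic": "web", "web": "clinic"})
            )
        )
        pd.testing.assert_series_equal(sub["clinic"].params, swapped["web"].params)
        pd.testing.assert_series_equal(sub["web"].params, swapped["clinic"].params)

    def test_degenerate_group_fails_alone(self):
        log = _simulated_log(seed=8)
        keep = sorted(log.participant_id.unique())[0]
        labels = np.where(log.participant_id == keep, "clinic", "web")
        sub = subgroup_fit(log.assign(recruitment_source=labels))
        assert isinstance(sub["clinic"], Exception)
        assert isinstance(sub["web"], StepTrajectoryResults)


def test_summary_mentions_key_quantities():
    res = fit_lmm(_simulated_log(seed=10))
    text = res.summary()
    assert "Random-intercept" in text
    assert "sigma_b^2" in text
    assert "baseline" in text
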