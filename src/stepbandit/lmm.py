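"""Random-intercept linear mixed model for daily step trajectories.

Model
-----
For participant *i* on study day *t* (0-167, so the intercept is the day-1
mean) with observed count :math:`y_{it}`:

.. math::

    y_{it} = \\beta_0 + \\beta_C C_i + \\beta_R R_i
             + (\\beta_d + \\beta_{Cd} C_i + \\beta_{Rd} R_i)\\, t
             + b_i + \\varepsilon_{it}

where :math:`C_i, R_i` indicate the control and random arms (adaptive is the
reference), :math:`b_i \\sim N(0, \\sigma_b^2)` is the person-level random
intercept and :math:`\\varepsilon_{it} \\sim N(0, \\sigma_e^2)` iid. Only
observed days enter the likelihood (transmission gaps are complete-case).

Estimation is REML (ML available) by profiling the likelihood over the
variance ratio :math:`\\gamma = \\sigma_b^2/\\sigma_e^2`: for each candidate
``gamma`` the fixed effects are the closed-form GLS solution, the residual
variance has a closed form, and the one-dimensional profile objective is
minimised numerically. Uncertainty is Wald (normal approximation), matching
the symmetric intervals the model is usually reported with.

``StepTrajectoryResults`` also derives the trajectory projections used to
summarise arms: day-1 baseline, daily slope, the gain over a horizon of 168
days, and the percent change relative to baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import optimize, stats

DEFAULT_HORIZON = 168
PARAM_NAMES = ("intercept", "control", "random", "day", "control:day", "random:day")
_ARM_SET = ("adaptive", "control", "random")


class RankError(np.linalg.LinAlgError):
    """The fixed-effects design is singular."""


class ConvergenceError(RuntimeError):
    """The profile-likelihood optimisation failed; carries the trace."""

    def __init__(self, message: str, trace: list | None = None):
        self.trace = trace or []
        super().__init__(message)


class StepTrajectoryLMM:
    """Model object; build from a long-format step log and call :meth:`fit`.

    Parameters
    ----------
    data:
        Long-format frame with columns ``participant_id``, ``day``,
        ``steps`` and ``arm`` (values adaptive/control/random). Rows are
        expected to be observed days only; use :meth:`from_step_log` to
        filter on an ``observed`` column.
    """

    def __init__(self, data: pd.DataFrame, include_interactions: bool = True):
        required = {"participant_id", "day", "steps", "arm"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"step log missing columns: {sorted(missing)}")
        arms = set(data["arm"].unique())
        unknown = arms - set(_ARM_SET)
        if unknown:
            raise ValueError(f"unknown arm labels: {sorted(unknown)}")
        counts = data.groupby(["arm", "participant_id"])["day"].nunique()
        for arm in arms:
            per_person = counts.loc[arm]
            if len(per_person) < 2 or (per_person < 2).any():
                raise ValueError(
                    f"arm {arm!r} needs >=2 participants with >=2 observed days"
                )
        self.include_interactions = include_interactions
        self.data = data.reset_index(drop=True)
        day = self.data["day"].to_numpy(dtype=float)
        control = (self.data["arm"] == "control").to_numpy(dtype=float)
        randarm = (self.data["arm"] == "random").to_numpy(dtype=float)
        X = np.column_stack(
            [
                np.ones(len(day)),
                control,
                randarm,
                day,
                control * day,
                randarm * day,
            ]
        )
        keep = [0, 3]
        if control.any():
            keep += [1, 4] if include_interactions else [1]
        if randarm.any():
            keep += [2, 5] if include_interactions else [2]
        keep = sorted(keep)
        self.param_names = tuple(PARAM_NAMES[j] for j in keep)
        self.X = X[:, keep]
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise RankError("fixed-effects design matrix is rank deficient")
        self.y = self.data["steps"].to_numpy(dtype=float)
        codes, self.group_labels = pd.factorize(self.data["participant_id"])
        self.groups = codes
        self.n_groups = len(self.group_labels)

    @classmethod
    def from_step_log(cls, step_log: pd.DataFrame) -> "StepTrajectoryLMM":
        """Build from a log that may carry unobserved rows (dropped here)."""
        df = step_log
        if "observed" in df.columns:
            df = df[df["observed"].astype(bool)]
        return cls(df)

    # -- profile likelihood machinery --------------------------------------

    def _sufficient_stats(self):
        X, y, g = self.X, self.y, self.groups
        p = X.shape[1]
        XtX = X.T @ X
        Xty = X.T @ y
        yty = float(y @ y)
        n_i = np.bincount(g, minlength=self.n_groups).astype(float)
        S = np.zeros((self.n_groups, p))
        for j in range(p):
            S[:, j] = np.bincount(g, weights=X[:, j], minlength=self.n_groups)
        t = np.bincount(g, weights=y, minlength=self.n_groups)
        return XtX, Xty, yty, n_i, S, t

    def _profile(self, gamma: float, stats_tuple, reml: bool):
        """Profile -2 log-likelihood (up to a constant) at a variance ratio."""
        XtX, Xty, yty, n_i, S, t = stats_tuple
        N, p = self.X.shape
        c = gamma / (1.0 + gamma * n_i)
        A = XtX - (S * c[:, None]).T @ S
        b = Xty - S.T @ (c * t)
        q = yty - float(c @ t**2)
        beta = np.linalg.solve(A, b)
        rss = max(q - float(beta @ b), 1e-12)
        logdet_ratio = float(np.sum(np.log1p(gamma * n_i)))
        if reml:
            sign, logdet_A = np.linalg.slogdet(A)
            if sign <= 0:
                raise RankError("X' V^-1 X not positive definite")
            obj = (N - p) * np.log(rss) + logdet_ratio + logdet_A
            sigma_e2 = rss / (N - p)
        else:
            obj = N * np.log(rss) + logdet_ratio
            sigma_e2 = rss / N
        return obj, beta, sigma_e2, A, rss

    def fit(
        self,
        method: str = "reml",
        gamma: float | None = None,
    ) -> "StepTrajectoryResults":
        """Fit the model.

        Parameters
        ----------
        method:
            ``"reml"`` (default) or ``"ml"`` (for likelihood-ratio tests of
            nested fixed-effect structures).
        gamma:
            Fix the variance ratio sigma_b^2/sigma_e^2 instead of profiling
            it; ``gamma=0`` makes the GLS solution collapse to OLS exactly.
        """
        if method not in ("reml", "ml"):
            raise ValueError("method must be 'reml' or 'ml'")
        reml = method == "reml"
        suff = self._sufficient_stats()
        trace: list[tuple[float, float]] = []

        def objective(log_gamma: float) -> float:
            val = self._profile(np.exp(log_gamma), suff, reml)[0]
            trace.append((float(np.exp(log_gamma)), float(val)))
            return val

        if gamma is None:
            grid = np.linspace(np.log(1e-8), np.log(1e8), 41)
            vals = np.array([objective(lg) for lg in grid])
            j = int(np.argmin(vals))
            lo = grid[max(j - 1, 0)]
            hi = grid[min(j + 1, len(grid) - 1)]
            res = optimize.minimize_scalar(
                objective, bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-10},
            )
            if not res.success:
                raise ConvergenceError("profile optimisation failed", trace)
            gamma_hat = float(np.exp(res.x))
            # A boundary solution at the grid floor means "no intercept
            # variance"; snap to the exact OLS limit.
            obj_zero = self._profile(0.0, suff, reml)[0]
            if obj_zero <= res.fun:
                gamma_hat = 0.0
        else:
            if gamma < 0:
                raise ValueError("gamma must be >= 0")
            gamma_hat = float(gamma)

        obj, beta, sigma_e2, A, rss = self._profile(gamma_hat, suff, reml)
        cov = sigma_e2 * np.linalg.inv(A)
        N, p = self.X.shape
        n_i = np.bincount(self.groups, minlength=self.n_groups).astype(float)
        logdet_ratio = float(np.sum(np.log1p(gamma_hat * n_i)))
        sign, logdet_A = np.linalg.slogdet(A)
        if reml:
            llf = -0.5 * (
                (N - p) * np.log(2 * np.pi * sigma_e2)
                + logdet_ratio
                + (logdet_A - p * np.log(sigma_e2))
                + rss / sigma_e2
            )
        else:
            llf = -0.5 * (
                N * np.log(2 * np.pi * sigma_e2) + logdet_ratio + rss / sigma_e2
            )
        return StepTrajectoryResults(
            model=self,
            params=pd.Series(beta, index=list(self.param_names)),
            cov_params=pd.DataFrame(
                cov, index=list(self.param_names), columns=list(self.param_names)
            ),
            sigma_b2=gamma_hat * sigma_e2,
            sigma_e2=sigma_e2,
            llf=float(llf),
            method=method,
            converged=True,
            nobs=N,
            n_groups=self.n_groups,
        )


@dataclass
class StepTrajectoryResults:
    """Estimates, uncertainty and trajectory projections for a fitted model."""

    params: pd.Series
    cov_params: pd.DataFrame | None = None
    sigma_b2: float = np.nan
    sigma_e2: float = np.nan
    llf: float = np.nan
    method: str = "reml"
    converged: bool = True
    nobs: int = 0
    n_groups: int = 0
    model: StepTrajectoryLMM | None = None

    @classmethod
    def from_fixed_effects(
        cls,
        intercept: float,
        control: float = 0.0,
        random: float = 0.0,
        day: float = 0.0,
        control_day: float = 0.0,
        random_day: float = 0.0,
    ) -> "StepTrajectoryResults":
        """Build a results object from a published-style coefficient table.

        Useful for reproducing derived quantities (baselines, slopes,
        projections) by pure arithmetic when only the coefficients are
        available; uncertainty fields are NaN.
        """
        params = pd.Series(
            [intercept, control, random, day, control_day, random_day],
            index=list(PARAM_NAMES),
        )
        return cls(params=params)

    # -- uncertainty -------------------------------------------------------

    def _get(self, name: str) -> float:
        return float(self.params.get(name, 0.0))

    @property
    def bse(self) -> pd.Series:
        if self.cov_params is None:
            return pd.Series(np.nan, index=self.params.index)
        return pd.Series(
            np.sqrt(np.diag(self.cov_params.to_numpy())), index=self.params.index
        )

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.bse
        return pd.Series(
            2 * stats.norm.sf(np.abs(z.to_numpy())), index=self.params.index
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Wald confidence intervals (normal approximation)."""
        zcrit = stats.norm.ppf(1 - alpha / 2)
        lo = self.params - zcrit * self.bse
        hi = self.params + zcrit * self.bse
        return pd.DataFrame({"ci_low": lo, "ci_high": hi})

    # -- trajectory projections -------------------------------------------

    def arm_baseline(self, arm: str) -> float:
        """Model-implied day-1 mean step count for an arm (steps)."""
        if arm == "adaptive":
            return self._get("intercept")
        if arm == "control":
            return self._get("intercept") + self._get("control")
        if arm == "random":
            return self._get("intercept") + self._get("random")
        raise ValueError(f"unknown arm {arm!r}")

    def arm_slope(self, arm: str) -> float:
        """Daily rate of change in mean steps for an arm (steps/day)."""
        if arm == "adaptive":
            return self._get("day")
        if arm == "control":
            return self._get("day") + self._get("control:day")
        if arm == "random":
            return self._get("day") + self._get("random:day")
        raise ValueError(f"unknown arm {arm!r}")

    def project_gain(self, arm: str, horizon: int = DEFAULT_HORIZON) -> float:
        """Cumulative change in daily steps over the horizon: slope x days."""
        if horizon <= 0:
            raise ValueError("horizon must be positive")
        return self.arm_slope(arm) * horizon

    def percent_change(self, arm: str, horizon: int = DEFAULT_HORIZON) -> float:
        """Percent change of daily steps over the horizon vs the baseline."""
        baseline = self.arm_baseline(arm)
        if baseline == 0:
            raise ValueError(f"arm {arm!r} baseline is zero; percent undefined")
        return 100.0 * self.project_gain(arm, horizon) / baseline

    def projection_table(self, horizon: int = DEFAULT_HORIZON) -> pd.DataFrame:
        """Per-arm baseline, slope, horizon gain and percent change."""
        rows = []
        for arm in _ARM_SET:
            rows.append(
                {
                    "arm": arm,
                    "baseline": self.arm_baseline(arm),
                    "slope": self.arm_slope(arm),
                    "horizon": horizon,
                    "gain": self.project_gain(arm, horizon),
                    "percent": self.percent_change(arm, horizon),
                }
            )
        return pd.DataFrame(rows)

    # -- reporting ---------------------------------------------------------

    def coef_table(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "parameter": self.params.index,
                "estimate": self.params.to_numpy(),
                "se": self.bse.to_numpy(),
                "ci_low": ci["ci_low"].to_numpy(),
                "ci_high": ci["ci_high"].to_numpy(),
                "p_value": self.pvalues.to_numpy(),
            }
        )

    def summary(self) -> str:
        lines = [
            "Random-intercept linear mixed model of daily step count",
            f"method: {self.method.upper()}    observations: {self.nobs}"
            f"    participants: {self.n_groups}",
            f"sigma_b^2 (between-person): {self.sigma_b2:,.2f}"
            f"    sigma_e^2 (residual): {self.sigma_e2:,.2f}",
            f"log-likelihood: {self.llf:.2f}    converged: {self.converged}",
            "",
            f"{'parameter':<14}{'estimate':>12}{'se':>10}{'ci_low':>12}"
            f"{'ci_high':>12}{'p':>9}",
        ]
        ci = self.conf_int()
        for name in self.params.index:
            lines.append(
                f"{name:<14}{self.params[name]:>12.2f}{self.bse[name]:>10.2f}"
                f"{ci.loc[name, 'ci_low']:>12.2f}{ci.loc[name, 'ci_high']:>12.2f}"
                f"{self.pvalues[name]:>9.3g}"
            )
        lines.append("")
        lines.append("Projected trajectories (horizon 168 days):")
        proj = self.projection_table()
        for _, r in proj.iterrows():
            lines.append(
                f"  {r['arm']:<9} baseline {r['baseline']:>7.0f}  "
                f"slope {r['slope']:>6.2f}/day  gain {r['gain']:>6.0f}  "
                f"change {r['percent']:>5.1f}%"
            )
        return "\n".join(lines)

    def plot_trajectories(self, horizon: int = DEFAULT_HORIZON, ax=None):
        """Fitted mean step trajectory per arm over the horizon."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        days = np.arange(horizon)
        for arm in _ARM_SET:
            ax.plot(
                days,
                self.arm_baseline(arm) + self.arm_slope(arm) * days,
                label=arm,
            )
        ax.set_xlabel("study day")
        ax.set_ylabel("expected daily steps")
        ax.legend()
        return ax


# -- spec-surface convenience wrappers -------------------------------------


def fit_lmm(step_log: pd.DataFrame, method: str = "reml") -> StepTrajectoryResults:
    """Fit the trajectory model to a long-format step log (observed rows)."""
    return StepTrajectoryLMM.from_step_log(step_log).fit(method=method)


def arm_baseline(fit: StepTrajectoryResults, arm: str) -> float:
    return fit.arm_baseline(arm)


def arm_slope(fit: StepTrajectoryResults, arm: str) -> float:
    return fit.arm_slope(arm)


def project_gain(
    fit: StepTrajectoryResults, arm: str, horizon: int = DEFAULT_HORIZON
) -> float:
    return fit.project_gain(arm, horizon)


def percent_change(
    fit: StepTrajectoryResults, arm: str, horizon: int = DEFAULT_HORIZON
) -> float:
    return fit.percent_change(arm, horizon)


def subgroup_fit(
    step_log: pd.DataFrame,
    grouping: str = "recruitment_source",
    method: str = "reml",
) -> dict[str, StepTrajectoryResults | Exception]:
    """Independent fits of the same model per subgroup.

    Degenerate groups (too few participants, singular design) yield the
    raised exception as their entry so the other groups still come back.
    """
    if grouping not in step_log.columns:
        raise ValueError(f"grouping column {grouping!r} not in step log")
    groups = step_log[grouping].unique()
    if len(groups) < 1:
        raise ValueError("no groups present")
    out: dict[str, StepTrajectoryResults | Exception] = {}
    for g in sorted(groups):
        sub = step_log[step_log[grouping] == g]
        try:
            out[str(g)] = fit_lmm(sub, method=method)
        except (ValueError, np.linalg.LinAlgError, RuntimeError) as exc:
            out[str(g)] = exc
    return out
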