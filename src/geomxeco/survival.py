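"""Score-stratified survival analysis.

A cohort carrying a per-sample signature score (e.g. an ssGSEA CAF-state
score) is dichotomized at an empirical quantile of the score (default the
75th percentile, type-7 linear interpolation; ties at the cutoff go to the
low group), compared by Kaplan-Meier curves with a two-group log-rank test,
and summarized by a Cox proportional-hazards ratio (Efron tie handling)
with a Wald confidence interval, optionally adjusted for clinical
covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    required = {"time_months", "event", "score"}
    if missing := required - set(cohort.columns):
        raise ValueError(f"cohort missing columns: {sorted(missing)}")
    if (cohort["time_months"].to_numpy(float) <= 0).any():
        raise ValueError("times must be positive")
    if not set(cohort["event"].unique()) <= {0, 1}:
        raise ValueError("event flags must be 0/1")
    return cohort


@dataclass
class StratifiedCohort:
    data: pd.DataFrame            # cohort + 'group' column in {'high','low'}
    quantile: float
    cutoff: float

    @property
    def n_high(self) -> int:
        return int((self.data["group"] == "high").sum())

    @property
    def n_low(self) -> int:
        return int((self.data["group"] == "low").sum())


@dataclass
class KMResult:
    curves: dict[str, pd.DataFrame]   # group -> survival function table
    chi2: float
    p: float
    unstable: bool = False


@dataclass
class CoxResult:
    hr: float
    ci_low: float
    ci_high: float
    p: float
    coef: float
    n_events: int
    covariate_hrs: dict[str, float] = field(default_factory=dict)


def dichotomize_at_quantile(cohort: pd.DataFrame, q: float = 0.75) -> StratifiedCohort:
    """Split a cohort into high/low groups at the empirical q-quantile of score.

    The quantile uses the type-7 (linear interpolation) convention; samples
    strictly above the cutoff are 'high', ties at the cutoff go to 'low'.
    """
    validate_cohort(cohort)
    if not 0 < q < 1:
        raise ValueError("quantile must lie in (0, 1)")
    if len(cohort) < 8:
        raise ValueError("need >= 8 samples")
    scores = cohort["score"].to_numpy(float)
    if np.allclose(scores, scores[0]):
        raise ValueError("all scores identical; cannot stratify")
    cutoff = float(np.quantile(scores, q))  # numpy default = type-7
    data = cohort.copy()
    data["group"] = np.where(scores > cutoff, "high", "low")
    return StratifiedCohort(data=data, quantile=q, cutoff=cutoff)


def km_logrank(strat: StratifiedCohort) -> KMResult:
    """Kaplan-Meier curves per group and the two-group log-rank test (1 df)."""
    data = strat.data
    curves = {}
    unstable = False
    for grp in ("low", "high"):
        sub = data[data["group"] == grp]
        if sub.empty:
            raise ValueError(f"group {grp!r} is empty")
        if sub["event"].sum() == 0:
            unstable = True
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time_months"], sub["event"], label=grp)
        curves[grp] = kmf.survival_function_
    hi = data[data["group"] == "high"]
    lo = data[data["group"] == "low"]
    res = logrank_test(hi["time_months"], lo["time_months"],
                       event_observed_A=hi["event"], event_observed_B=lo["event"])
    return KMResult(curves=curves, chi2=float(res.test_statistic),
                    p=float(res.p_value), unstable=unstable)


def cox_hr(strat: StratifiedCohort, covariates: list[str] | None = None,
           min_events: int = 10) -> CoxResult:
    """Cox proportional-hazards ratio of high vs low score group.

    Efron tie handling (the lifelines default). With ``covariates`` the
    model adjusts for the named cohort columns (multivariable mode).
    Non-convergence propagates as an error with lifelines' diagnostics.
    """
    data = strat.data
    n_events = int(data["event"].sum())
    if n_events < min_events:
        raise ValueError(f"need >= {min_events} events, got {n_events}")
    cols = ["time_months", "event"]
    df = pd.DataFrame({"time_months": data["time_months"],
                       "event": data["event"],
                       "group_high": (data["group"] == "high").astype(float)})
    for cov in covariates or []:
        if cov not in data.columns:
            raise ValueError(f"covariate {cov!r} not in cohort")
        df[cov] = pd.to_numeric(data[cov])
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time_months", event_col="event")
    summ = cph.summary.loc["group_high"]
    cov_hrs = {c: float(np.exp(cph.summary.loc[c, "coef"]))
               for c in (covariates or [])}
    return CoxResult(hr=float(np.exp(summ["coef"])),
                     ci_low=float(np.exp(summ["coef lower 95%"])),
                     ci_high=float(np.exp(summ["coef upper 95%"])),
                     p=float(summ["p"]), coef=float(summ["coef"]),
                     n_events=n_events, covariate_hrs=cov_hrs)
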