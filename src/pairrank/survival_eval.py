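"""Survival evaluation of a risk score: cutoff choice and group comparison.

The cutoff is chosen on the training cohort by a time-dependent ROC at a
fixed horizon (cumulative cases / dynamic controls): cases are subjects
with an event by the horizon, controls are subjects still event-free past
it, and censoring before the horizon is handled by inverse-probability
weighting with a Kaplan-Meier estimate of the censoring distribution.
Group comparisons use the product-limit estimator, the log-rank test and
Cox proportional-hazards models with Wald confidence intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

from .errors import FitError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class TimeDependentROC:
    """ROC at a survival horizon, with the Youden-optimal cutoff.

    ``thresholds`` ascend; a subject is called high-risk when its score is
    strictly above the threshold, so ``sensitivity`` is non-increasing and
    ``specificity`` non-decreasing along the array.
    """

    horizon: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    optimal_cutoff: float
    optimal_sens: float
    optimal_spec: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def _censoring_survival(time: np.ndarray, event: np.ndarray):
    """Kaplan-Meier estimate of the censoring survival function G(t)."""
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=1 - event)
    return kmf


def td_roc(scores: pd.Series, surv: pd.DataFrame, horizon: float) -> TimeDependentROC:
    """Cumulative/dynamic time-dependent ROC with KM censoring weights.

    Cases (event time <= horizon, event observed) are weighted by the
    inverse censoring survival just before their event time; controls
    (observed time > horizon) enter unweighted. The AUC is the trapezoid
    over the (1 - specificity, sensitivity) curve; the optimal cutoff
    maximizes the Youden index, ties resolved toward the lower cutoff so
    the high-risk group is larger.
    """
    common = scores.index.intersection(surv.index)
    if len(common) == 0:
        raise ValidationError("scores and survival table share no samples")
    x = scores.loc[common].to_numpy(dtype=float)
    time = surv.loc[common, "time"].to_numpy(dtype=float)
    event = surv.loc[common, "status"].to_numpy(dtype=int)

    is_case = (event == 1) & (time <= horizon)
    is_control = time > horizon
    if not is_case.any():
        raise ValidationError(f"no events before horizon {horizon}")
    if not is_control.any():
        raise ValidationError(f"no subjects at risk past horizon {horizon}")

    G = _censoring_survival(time, event)
    # left limit of G at each case's event time
    g_at = G.survival_function_at_times(np.maximum(time[is_case] - 1e-9, 0.0))
    g_vals = np.asarray(g_at, dtype=float)
    g_vals[g_vals <= 0] = np.nan
    weights = 1.0 / g_vals
    if np.isnan(weights).any():
        weights = np.where(np.isnan(weights), np.nanmax(weights), weights)

    thresholds = np.unique(x)
    case_x = x[is_case]
    control_x = x[is_control]
    w_total = weights.sum()
    n_control = is_control.sum()
    sens = np.array(
        [weights[case_x > c].sum() / w_total for c in thresholds]
    )
    spec = np.array([(control_x <= c).sum() / n_control for c in thresholds])

    fpr = np.concatenate(([1.0], 1.0 - spec, [0.0]))
    tpr = np.concatenate(([1.0], sens, [0.0]))
    auc = float(np.trapezoid(tpr[::-1], fpr[::-1]))

    youden = sens + spec - 1.0
    best = int(np.flatnonzero(youden == youden.max())[0])
    return TimeDependentROC(
        horizon=float(horizon),
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        optimal_cutoff=float(thresholds[best]),
        optimal_sens=float(sens[best]),
        optimal_spec=float(spec[best]),
    )


def km_curve(surv: pd.DataFrame, groups: pd.Series) -> dict[str, pd.DataFrame]:
    """Product-limit survival curve per group.

    Returns, per group, a step function as a DataFrame with columns
    ``time`` and ``survival`` (starting from S(0) = 1).
    """
    groups = groups.loc[surv.index]
    curves: dict[str, pd.DataFrame] = {}
    for g in pd.unique(groups):
        sub = surv.loc[groups == g]
        if sub.empty:
            raise ValidationError(f"group {g!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["status"])
        sf = kmf.survival_function_
        curves[str(g)] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float),
             "survival": sf.iloc[:, 0].to_numpy(dtype=float)}
        )
    return curves


def logrank_test(surv: pd.DataFrame, groups: pd.Series) -> tuple[float, float]:
    """Log-rank chi-square statistic and p-value comparing survival by group."""
    groups = groups.loc[surv.index]
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValidationError("log-rank test needs at least 2 groups")
    if surv["status"].sum() < 1:
        raise ValidationError("log-rank test needs at least 1 event")
    res = multivariate_logrank_test(surv["time"], groups, surv["status"])
    return float(res.test_statistic), float(res.p_value)


def logrank_observed_minus_expected(
    surv: pd.DataFrame, groups: pd.Series, group: str
) -> float:
    """O - E of the log-rank tally for one group; positive means more events
    than expected under equal hazards (the group fares worse)."""
    groups = groups.loc[surv.index]
    time = surv["time"].to_numpy(dtype=float)
    event = surv["status"].to_numpy(dtype=int)
    in_group = (groups == group).to_numpy()
    o_minus_e = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        d = int(((time == t) & (event == 1)).sum())
        d_g = int(((time == t) & (event == 1) & in_group).sum())
        o_minus_e += d_g - d * (at_risk & in_group).sum() / at_risk.sum()
    return float(o_minus_e)


def _prepare_covariates(df: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Encode categorical covariates as 0/1 dummies (first level reference)."""
    out = df[["time", "status"]].copy()
    for cov in covariates:
        col = df[cov]
        if pd.api.types.is_numeric_dtype(col):
            out[cov] = col.astype(float)
        else:
            cat = col.astype("category")
            if set(cat.cat.categories) == {"low", "high"}:
                # report high vs low, the risk-group convention
                cat = cat.cat.reorder_categories(["low", "high"])
            dummies = pd.get_dummies(cat, prefix=cov,
                                     drop_first=True, dtype=float)
            # missing values propagate as NaN rather than a silent 0 row
            dummies[col.isna()] = np.nan
            out = out.join(dummies)
    return out


def cox_models(
    surv: pd.DataFrame,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Univariate and multivariate Cox reports over clinical covariates.

    Returns one row per (model, covariate term): hazard ratio, Wald 95% CI
    and p-value. Rows with a missing value of the relevant covariate are
    dropped per model. Non-convergence is reported per covariate with NaN
    estimates rather than aborting the whole report.
    """
    if covariates is None:
        covariates = [c for c in surv.columns if c not in ("time", "status")]
    if not covariates:
        raise ValidationError("no covariates to model")
    n_events = int(surv["status"].sum())
    if n_events < 10 * 1:
        warnings.warn(
            f"only {n_events} events; hazard-ratio estimates may be unstable",
            stacklevel=2,
        )
    rows = []

    def _fit(frame: pd.DataFrame, model_name: str) -> None:
        frame = frame.dropna()
        try:
            cph = CoxPHFitter()
            cph.fit(frame, duration_col="time", event_col="status")
        except (ConvergenceError, ValueError) as exc:
            for term in frame.columns.drop(["time", "status"]):
                rows.append(
                    {"model": model_name, "term": term, "hazard_ratio": np.nan,
                     "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan,
                     "note": f"fit failed: {exc}"}
                )
            return
        summary = cph.summary
        for term in summary.index:
            rows.append(
                {
                    "model": model_name,
                    "term": term,
                    "hazard_ratio": float(summary.loc[term, "exp(coef)"]),
                    "ci_low": float(summary.loc[term, "exp(coef) lower 95%"]),
                    "ci_high": float(summary.loc[term, "exp(coef) upper 95%"]),
                    "p_value": float(summary.loc[term, "p"]),
                    "note": "",
                }
            )

    for cov in covariates:
        _fit(_prepare_covariates(surv, [cov]), "univariate")
    if len(covariates) > 1:
        _fit(_prepare_covariates(surv, covariates), "multivariate")
    report = pd.DataFrame(rows)
    if report.empty:
        raise FitError("no Cox model could be fitted")
    return report
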