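"""Replicability of population inferences on synthetic data.

The inferential task is a logistic regression on the core variables with a
flagged *parameter of interest*.  The model is fitted on the real data and
on each synthetic replicate; replicate estimates are pooled with multiple-
imputation-style combining rules, and the combined estimate is compared
with the real one through four agreement metrics:

* decision agreement — same direction and same significance status;
* estimate agreement — synthetic estimate inside the real 95% CI;
* standardized difference — difference consistent with no difference;
* CI overlap — proportion of overlap between the two 95% CIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import Cohort
from .generators import SyntheticEnsemble

__all__ = [
    "EstimateCI",
    "ReplicabilityResult",
    "EstimateFailure",
    "fit_logistic_estimate",
    "combine_estimates",
    "replicability_metrics",
    "ensemble_replicability",
]


class EstimateFailure(RuntimeError):
    """Logistic fit failed (non-convergence or complete separation)."""


@dataclass
class EstimateCI:
    """A point estimate with standard error and two-sided confidence interval."""

    estimate: float
    standard_error: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    df: float | None = None  # None = normal reference

    def __post_init__(self) -> None:
        if self.standard_error < 0:
            raise ValueError("standard error must be nonnegative")
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("estimate must lie inside its confidence interval")

    @property
    def significant(self) -> bool:
        """True when the CI excludes zero."""
        return self.ci_low > 0 or self.ci_high < 0


@dataclass
class ReplicabilityResult:
    decision_agreement: int
    estimate_agreement: int
    standardized_difference_agreement: int
    ci_overlap: float


def _design(cohort: Cohort, predictors: list[str], poi: str):
    """Complete-case design matrix: dummies for categoricals, floats else.

    Returns (X DataFrame with constant, y vector, poi column name).
    """
    df = cohort.records
    outcome = cohort.outcome_name
    out_meta = cohort.meta_for(outcome)
    positive = (out_meta.categories or sorted(df[outcome].dropna().astype(str).unique()))[-1]

    cols = {}
    poi_col = poi
    for name in predictors:
        m = cohort.meta_for(name)
        col = df[name]
        if m.vtype == "continuous":
            cols[name] = pd.to_numeric(col, errors="coerce")
        else:
            s = col.astype(object).astype(str).where(col.notna(), np.nan)
            levels = sorted(v for v in s.dropna().unique())
            for lv in levels[1:]:  # drop-first coding
                cols[f"{name}[{lv}]"] = (s == lv).astype(float).where(s.notna(), np.nan)
            if name == poi:
                if len(levels) != 2:
                    raise EstimateFailure(
                        f"parameter of interest {poi!r} must be continuous or binary"
                    )
                poi_col = f"{name}[{levels[1]}]"
    X = pd.DataFrame(cols)
    y = (df[outcome].astype(object).astype(str) == positive).astype(float)
    keep = X.notna().all(axis=1) & df[outcome].notna()
    X, y = X.loc[keep], y.loc[keep]
    X = sm.add_constant(X, has_constant="add")
    return X, y, poi_col


def fit_logistic_estimate(
    cohort: Cohort,
    outcome: str | None = None,
    predictors: list[str] | None = None,
    parameter_of_interest: str | None = None,
    alpha: float = 0.05,
) -> EstimateCI:
    """Maximum-likelihood logistic fit; Wald SE and CI for the flagged coefficient.

    Complete cases only; categorical predictors are dummy-coded (first level
    as reference).  Non-convergence and complete separation raise
    :class:`EstimateFailure` so callers can record the replicate as missing.
    """
    predictors = predictors or cohort.core_predictor_names
    poi = parameter_of_interest or cohort.parameter_of_interest or predictors[0]
    if poi not in predictors:
        raise ValueError("parameter of interest must be among the predictors")
    X, y, poi_col = _design(cohort, predictors, poi)
    uniq = np.unique(y)
    if len(uniq) < 2:
        raise EstimateFailure("outcome is constant; logistic model undefined")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
            model = sm.Logit(y, X)
            res = model.fit(disp=0, maxiter=200)
    except (sm.tools.sm_exceptions.PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise EstimateFailure(f"logistic fit failed: {exc}") from exc
    except Warning as exc:
        raise EstimateFailure(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise EstimateFailure("logistic fit did not converge")
    est = float(res.params[poi_col])
    se = float(res.bse[poi_col])
    if not np.isfinite(est) or not np.isfinite(se) or se > 1e4:
        raise EstimateFailure("degenerate estimate (likely separation)")
    z = stats.norm.ppf(1 - alpha / 2)
    return EstimateCI(est, se, est - z * se, est + z * se, alpha=alpha)


def combine_estimates(
    estimates: list[EstimateCI], alpha: float = 0.05, rule: str = "partial"
) -> EstimateCI:
    """Pool replicate estimates with multiple-imputation-style combining rules.

    With m replicate estimates q_i and squared standard errors se_i^2:
    qbar = mean(q_i), wbar = mean(se_i^2), b = sample variance of q_i.
    The default ("partial") total variance is T = wbar + b/m, which is
    never negative; the fully-synthetic alternative T = (1 + 1/m) b - wbar
    (floored at wbar) is available via ``rule="full"``.  The interval uses a
    t reference with Barnard–Rubin-style degrees of freedom
    nu = (m - 1) (1 + wbar / (b/m))^2, infinite when b = 0.
    """
    if not estimates:
        raise ValueError("need at least one estimate to combine")
    m = len(estimates)
    q = np.array([e.estimate for e in estimates], dtype=float)
    w = np.array([e.standard_error**2 for e in estimates], dtype=float)
    qbar = float(q.mean())
    wbar = float(w.mean())
    b = float(q.var(ddof=1)) if m > 1 else 0.0
    if rule == "partial":
        T = wbar + b / m
    elif rule == "full":
        T = max((1.0 + 1.0 / m) * b - wbar, wbar)
    else:
        raise ValueError("rule must be 'partial' or 'full'")
    se = float(np.sqrt(T))
    if b > 0:
        df = (m - 1) * (1.0 + wbar / (b / m)) ** 2
        q_crit = stats.t.ppf(1 - alpha / 2, df)
    else:
        df = None
        q_crit = stats.norm.ppf(1 - alpha / 2)
    return EstimateCI(qbar, se, qbar - q_crit * se, qbar + q_crit * se, alpha=alpha, df=df)


def replicability_metrics(real: EstimateCI, synthetic: EstimateCI) -> ReplicabilityResult:
    """The four agreement metrics comparing a combined synthetic estimate to real."""
    if real.alpha != synthetic.alpha:
        raise ValueError("real and synthetic intervals must use the same alpha")
    if real.ci_high == real.ci_low:
        raise ValueError("zero-width real confidence interval")

    same_sign = np.sign(synthetic.estimate) == np.sign(real.estimate)
    decision = int(bool(same_sign and (synthetic.significant == real.significant)))

    estimate = int(real.ci_low <= synthetic.estimate <= real.ci_high)

    denom = np.sqrt(synthetic.standard_error**2 + real.standard_error**2)
    z_crit = stats.norm.ppf(1 - real.alpha / 2)
    if denom == 0:
        std_diff = int(synthetic.estimate == real.estimate)
    else:
        std_diff = int(abs(synthetic.estimate - real.estimate) / denom <= z_crit)

    inter = min(real.ci_high, synthetic.ci_high) - max(real.ci_low, synthetic.ci_low)
    if synthetic.ci_high == synthetic.ci_low:
        overlap = 0.0 if inter < 0 else 1.0 if inter >= 0 and estimate else 0.0
    else:
        overlap = max(
            0.0,
            0.5
            * (
                inter / (real.ci_high - real.ci_low)
                + inter / (synthetic.ci_high - synthetic.ci_low)
            ),
        )
    return ReplicabilityResult(
        decision_agreement=decision,
        estimate_agreement=estimate,
        standardized_difference_agreement=std_diff,
        ci_overlap=float(overlap),
    )


def ensemble_replicability(
    real: Cohort,
    ensemble: SyntheticEnsemble,
    alpha: float = 0.05,
    rule: str = "partial",
) -> tuple[ReplicabilityResult, EstimateCI, EstimateCI, int]:
    """Fit real + per-replicate estimates, combine, and compare.

    Returns (metrics, real estimate, combined synthetic estimate, number of
    replicates that produced a usable estimate).  Replicates whose fit fails
    (separation, constant outcome) are dropped with a warning.
    """
    real_est = fit_logistic_estimate(real, alpha=alpha)
    rep_estimates: list[EstimateCI] = []
    for i, rep in enumerate(ensemble.replicates):
        rep_cohort = Cohort(records=rep.records, meta=list(real.meta), dataset_id=rep.dataset_id)
        try:
            rep_estimates.append(fit_logistic_estimate(rep_cohort, alpha=alpha))
        except EstimateFailure as exc:
            warnings.warn(f"replicate {i}: {exc}; recorded as missing", stacklevel=2)
    if not rep_estimates:
        raise EstimateFailure("no synthetic replicate produced a usable estimate")
    combined = combine_estimates(rep_estimates, alpha=alpha, rule=rule)
    return replicability_metrics(real_est, combined), real_est, combined, len(rep_estimates)
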