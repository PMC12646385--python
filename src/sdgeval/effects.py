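"""Mixed-effects meta-analysis of evaluation metrics.

For each generator and metric, the fixed effect of the number of adjunct
variables k on the metric is estimated with the medical dataset as a
random component (random intercept *and* random slope):

    value ~ 1 + k + (1 + k | dataset)

Continuous metrics (cluster fidelity, TSTR AUROC, CI overlap, membership
relative F1) use a linear mixed model; the binary agreement metrics
(estimate / decision / standardized-difference agreement) use a binomial
GLMM with logit link, and the fixed effect is reported as an odds ratio.

Confidence intervals for the linear fixed effect use the likelihood
profile (by response shifting), falling back to Wald intervals when
profiling fails; the interval method actually used is recorded in the
output.  The binomial GLMM is fitted by variational Bayes and reports
Wald-style intervals from the posterior standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "EffectEstimate",
    "fit_metric_effect",
    "effect_table",
    "metric_family",
    "aggregate_replicates",
    "extrapolate_metric_change",
    "BINARY_METRICS",
]

#: Metrics modelled with the binomial-logit family (values in {0, 1}).
BINARY_METRICS = {
    "estimate_agreement",
    "decision_agreement",
    "standardized_difference_agreement",
}


@dataclass
class EffectEstimate:
    metric_name: str
    generator_id: str
    family: str  # "linear" | "binomial_logit"
    fixed_effect: float  # coefficient (linear) or odds ratio (binomial)
    ci_low: float
    ci_high: float
    p_value: float
    ci_method: str  # "profile" | "wald" | "vb_wald"
    p_method: str = "wald_z"
    n_obs: int = 0
    n_datasets: int = 0
    notes: str = ""

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def metric_family(metric_name: str) -> str:
    return "binomial_logit" if metric_name in BINARY_METRICS else "linear"


def aggregate_replicates(metric_table: pd.DataFrame) -> pd.DataFrame:
    """Variant-level analysis table: replicate means for continuous metrics.

    Binary agreement metrics are already variant-level (one combined
    comparison per variant) and pass through unchanged.  A ``variant_id``
    column, when present, keeps variants with the same adjunct count k
    distinct during aggregation.
    """
    df = metric_table.copy()
    keys = ["dataset_id", "generator_id", "k_adjunct", "metric_name"]
    if "variant_id" in df.columns:
        keys.insert(3, "variant_id")
    binary = df["metric_name"].isin(BINARY_METRICS)
    cont = df.loc[~binary].groupby(keys, as_index=False)["value"].mean()
    return pd.concat([cont, df.loc[binary, keys + ["value"]]], ignore_index=True)


def extrapolate_metric_change(fixed_effect: float, n_variables: int) -> float:
    """Projected change in a linearly modelled metric after adding
    ``n_variables`` adjunct variables at the estimated per-variable effect."""
    return float(fixed_effect * n_variables)


# ---------------------------------------------------------------------------
# linear mixed model


def _fit_linear_mixed(y: np.ndarray, k: np.ndarray, groups: np.ndarray):
    import statsmodels.formula.api as smf

    data = pd.DataFrame({"value": y, "k_adjunct": k, "dataset_id": groups})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "value ~ k_adjunct", data, groups=data["dataset_id"], re_formula="~k_adjunct"
        )
        res = None
        for method, free in (
            ("bfgs", None), ("powell", None), ("lbfgs", None),
            # singular unstructured fits: refit with independent intercept/slope
            ("bfgs", sm_free_struct()), ("powell", sm_free_struct()),
        ):
            try:
                cand = model.fit(reml=False, method=method, free=free)
            except Exception:  # noqa: BLE001 - try the next optimiser
                continue
            if cand.converged and np.all(np.isfinite(cand.bse_fe)):
                res = cand
                break
            if res is None:
                res = cand  # keep the best-effort fit as a last resort
        if res is None:
            raise RuntimeError("linear mixed model failed to fit")
    return res


def sm_free_struct():
    """Variance-components structure with uncorrelated intercept and slope."""
    from statsmodels.regression.mixed_linear_model import MixedLMParams

    return MixedLMParams.from_components(
        fe_params=np.ones(2), cov_re=np.eye(2)
    )


def _profile_ci_linear(
    y: np.ndarray, k: np.ndarray, groups: np.ndarray, beta_hat: float, llf_hat: float,
    se: float, alpha: float = 0.05,
):
    """Profile-likelihood CI by response shifting.

    Fixing the slope at beta0 is equivalent to fitting
    (y - beta0 * k) ~ 1 + (1 + k | dataset); the profile bound solves
    2 * (llf_hat - llf(beta0)) = chi2_{1, 1-alpha}.
    """
    import statsmodels.formula.api as smf

    crit = stats.chi2.ppf(1 - alpha, 1) / 2.0

    def profile_llf(beta0: float) -> float:
        data = pd.DataFrame(
            {"value": y - beta0 * k, "k_adjunct": k, "dataset_id": groups}
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                "value ~ 1", data, groups=data["dataset_id"], re_formula="~k_adjunct"
            )
            res = model.fit(reml=False, method="bfgs")
        return float(res.llf)

    def gap(beta0: float) -> float:
        return (llf_hat - profile_llf(beta0)) - crit

    bounds = []
    for direction in (-1.0, 1.0):
        lo, hi = 0.0, 2.0
        while gap(beta_hat + direction * hi * max(se, 1e-12)) < 0 and hi < 64:
            hi *= 2
        step = max(se, 1e-12)
        b = optimize.brentq(
            lambda t: gap(beta_hat + direction * t * step), lo, hi, xtol=1e-4
        )
        bounds.append(beta_hat + direction * b * step)
    return min(bounds), max(bounds)


def _fit_linear(
    sub: pd.DataFrame, metric_name: str, generator_id: str, ci_method: str
) -> EffectEstimate:
    y = sub["value"].to_numpy(dtype=float)
    k = sub["k_adjunct"].to_numpy(dtype=float)
    groups = sub["dataset_id"].to_numpy()
    res = _fit_linear_mixed(y, k, groups)
    beta = float(res.fe_params["k_adjunct"])
    se = float(res.bse_fe["k_adjunct"])
    # between-within t reference: the slope varies at the dataset level, so
    # its effective degrees of freedom are tied to the number of datasets,
    # not the number of observations (small-sample approximation in place
    # of a Satterthwaite computation, which the backend does not provide)
    df_bw = max(len(np.unique(groups)) - 2, 1)
    t_stat = beta / se if se > 0 else np.inf * np.sign(beta)
    p = float(2 * stats.t.sf(abs(t_stat), df_bw))
    used = "wald"
    t_crit = float(stats.t.ppf(0.975, df_bw))
    lo, hi = beta - t_crit * se, beta + t_crit * se
    if ci_method == "profile":
        try:
            lo, hi = _profile_ci_linear(y, k, groups, beta, float(res.llf), se)
            used = "profile"
        except Exception:
            used = "wald"
    return EffectEstimate(
        metric_name=metric_name,
        generator_id=generator_id,
        family="linear",
        fixed_effect=beta,
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=p,
        ci_method=used,
        p_method="t_between_within",
        n_obs=len(sub),
        n_datasets=sub["dataset_id"].nunique(),
    )


# ---------------------------------------------------------------------------
# binomial GLMM (variational Bayes)


def _fit_binomial(
    sub: pd.DataFrame, metric_name: str, generator_id: str
) -> EffectEstimate:
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    data = sub.copy()
    data["value"] = data["value"].astype(float)
    if data["value"].nunique() < 2:
        raise ValueError(f"metric {metric_name!r} is constant; no effect estimable")
    vc_formulas = {
        "intercept": "0 + C(dataset_id)",
        "slope": "0 + C(dataset_id):k_adjunct",
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = BinomialBayesMixedGLM.from_formula(
            "value ~ k_adjunct", vc_formulas, data
        )
        res = model.fit_vb()
    names = list(model.exog_names)
    i = names.index("k_adjunct")
    coef = float(res.fe_mean[i])
    sd = float(res.fe_sd[i])
    z = coef / sd if sd > 0 else np.inf * np.sign(coef)
    p = float(2 * stats.norm.sf(abs(z)))
    zc = 1.959963984540054
    return EffectEstimate(
        metric_name=metric_name,
        generator_id=generator_id,
        family="binomial_logit",
        fixed_effect=float(np.exp(coef)),
        ci_low=float(np.exp(coef - zc * sd)),
        ci_high=float(np.exp(coef + zc * sd)),
        p_value=p,
        ci_method="vb_wald",
        p_method="vb_wald_z",
        n_obs=len(sub),
        n_datasets=sub["dataset_id"].nunique(),
        notes="odds ratio; variational-Bayes posterior",
    )


def fit_metric_effect(
    metric_table: pd.DataFrame,
    metric_name: str,
    generator_id: str,
    family: str | None = None,
    ci_method: str = "profile",
    aggregate: bool = True,
) -> EffectEstimate:
    """Fixed effect of the adjunct count on one metric for one generator.

    ``metric_table`` is the long-format table (dataset_id, generator_id,
    k_adjunct, metric_name, replicate, value).  Requires at least two
    distinct datasets so the random effects are identifiable.
    """
    df = aggregate_replicates(metric_table) if aggregate else metric_table
    sub = df[(df["metric_name"] == metric_name) & (df["generator_id"] == generator_id)]
    if sub.empty:
        raise ValueError(f"no rows for metric {metric_name!r} / generator {generator_id!r}")
    if sub["dataset_id"].nunique() < 2:
        raise ValueError(
            "random effects need at least two datasets; "
            "fit a fixed-effects-only model for single-dataset tables"
        )
    if sub["value"].nunique() < 2:
        raise ValueError(f"metric {metric_name!r} is constant; no effect estimable")
    family = family or metric_family(metric_name)
    if family == "linear":
        return _fit_linear(sub, metric_name, generator_id, ci_method)
    if family == "binomial_logit":
        return _fit_binomial(sub, metric_name, generator_id)
    raise ValueError(f"unknown family {family!r}")


def effect_table(
    metric_table: pd.DataFrame, ci_method: str = "wald"
) -> pd.DataFrame:
    """One row per (generator, metric): fixed effect, CI, p, significance.

    Rows are ordered generator-major.  Cells that cannot be fitted (constant
    metric, single dataset) are recorded with NaN effect and a note.
    """
    rows = []
    generators = sorted(metric_table["generator_id"].unique())
    for gen in generators:
        metrics = sorted(
            metric_table.loc[metric_table["generator_id"] == gen, "metric_name"].unique()
        )
        for met in metrics:
            try:
                est = fit_metric_effect(metric_table, met, gen, ci_method=ci_method)
                rows.append(
                    {
                        "generator_id": gen,
                        "metric_name": met,
                        "family": est.family,
                        "fixed_effect": est.fixed_effect,
                        "ci_low": est.ci_low,
                        "ci_high": est.ci_high,
                        "p_value": est.p_value,
                        "significant": est.significant,
                        "ci_method": est.ci_method,
                        "notes": est.notes,
                    }
                )
            except Exception as exc:  # noqa: BLE001 - table rendering must not die
                rows.append(
                    {
                        "generator_id": gen,
                        "metric_name": met,
                        "family": metric_family(met),
                        "fixed_effect": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "p_value": np.nan,
                        "significant": False,
                        "ci_method": "",
                        "notes": f"not fitted: {exc}",
                    }
                )
    return pd.DataFrame(rows)
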