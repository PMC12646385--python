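"""Simulation of cross-sectional medical-style cohorts with known ground truth.

Real high-dimensional health datasets (registry, discharge, survey data)
are access-restricted, so the pipeline is exercised on simulated cohorts
that reproduce their stated structural features: a handful of *core*
predictors driving a binary outcome of configurable (possibly extreme)
prevalence, a pool of *adjunct* variables that are either independent of
the core, noisy copies of single core variables, or noisy linear
combinations of them, mixed categorical/continuous types, and MCAR
missingness.

The dependence backbone is a Gaussian copula: core predictors are latent
standard normals with correlation matrix ``R``; a configurable fraction of
them is discretised into 2–5 quantile bins to produce categoricals.  The
outcome is Bernoulli with logit linear in the *latent* core values, and the
intercept is calibrated so the marginal prevalence hits the requested
value.  Because the generating coefficients are known, downstream stages
(replicability, effect models) can be tested for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, special
from scipy.special import roots_hermitenorm

from ._seeding import child_seed
from .cohort import Cohort, CohortValidationError, VariableMeta

__all__ = [
    "AdjunctMode",
    "CohortSpec",
    "GroundTruth",
    "calibrate_intercept",
    "simulate_cohort",
]


@dataclass
class AdjunctMode:
    """How one adjunct column relates to the core.

    kind:
        ``independent`` — iid noise, no relation to any core variable;
        ``redundant``   — noisy copy of one core variable (``source``);
        ``informative`` — noisy linear combination of core latents.
    """

    kind: Literal["independent", "redundant", "informative"]
    source: str | None = None
    weights: Sequence[float] | None = None
    noise_sd: float = 0.5
    categorical: bool = False
    n_bins: int = 3


@dataclass
class GroundTruth:
    """Generating parameters of a simulated cohort."""

    beta: np.ndarray
    intercept: float
    prevalence: float
    parameter_of_interest: str
    poi_coefficient: float


@dataclass
class CohortSpec:
    """Full recipe for one simulated cohort.

    Defaults describe a mid-sized cohort in the range the evaluated real
    datasets span: 8 core predictors (range 6–20 there), half of them
    categorical, 5% MCAR missingness, 3 quasi-identifiers, and a 30%
    outcome prevalence (the imbalance range runs from roughly balanced to
    99/1 and is freely configurable through ``outcome_prevalence``).
    """

    dataset_id: str = "sim"
    n_records: int = 20_000
    n_core_predictors: int = 8
    adjunct_pool_size: int = 8
    outcome_prevalence: float = 0.3
    beta: Sequence[float] | None = None
    latent_correlation: np.ndarray | None = None
    adjunct_modes: list[AdjunctMode] | None = None
    categorical_fraction: float = 0.5
    category_bins: Sequence[int] = (2, 3, 4, 5)
    missing_rate: float = 0.05
    qi_count: int = 3
    seed: int = 0

    def resolved_beta(self) -> np.ndarray:
        if self.beta is not None:
            b = np.asarray(self.beta, dtype=float)
            if b.shape != (self.n_core_predictors,):
                raise ValueError("beta length must equal n_core_predictors")
            return b
        # alternating, decaying effects: some strong, some weak predictors
        idx = np.arange(self.n_core_predictors)
        return np.where(idx % 2 == 0, 0.8, -0.4) / (1.0 + idx // 4)

    def resolved_R(self) -> np.ndarray:
        p = self.n_core_predictors
        if self.latent_correlation is None:
            # mild exchangeable correlation: realistically inter-related cores
            R = np.full((p, p), 0.3)
            np.fill_diagonal(R, 1.0)
            return R
        R = np.asarray(self.latent_correlation, dtype=float)
        if R.shape != (p, p):
            raise ValueError("latent_correlation must be p x p")
        if not np.allclose(R, R.T):
            raise ValueError("latent_correlation must be symmetric")
        if not np.allclose(np.diag(R), 1.0):
            raise ValueError("latent_correlation must have unit diagonal")
        ev = np.linalg.eigvalsh(R)
        if ev.min() < -1e-10:
            raise ValueError("latent_correlation must be positive semi-definite")
        return R

    def resolved_adjunct_modes(self) -> list[AdjunctMode]:
        if self.adjunct_modes is not None:
            if len(self.adjunct_modes) != self.adjunct_pool_size:
                raise ValueError("adjunct_modes length must equal adjunct_pool_size")
            return list(self.adjunct_modes)
        # default mix: half independent, quarter redundant, quarter informative
        modes: list[AdjunctMode] = []
        p = self.n_core_predictors
        for j in range(self.adjunct_pool_size):
            if j % 4 in (0, 1):
                modes.append(
                    AdjunctMode("independent", categorical=(j % 2 == 1), n_bins=3)
                )
            elif j % 4 == 2:
                modes.append(AdjunctMode("redundant", source=f"x{(j % p) + 1}", noise_sd=0.5))
            else:
                w = np.zeros(p)
                w[j % p] = 0.7
                w[(j + 1) % p] = 0.7
                modes.append(AdjunctMode("informative", weights=w, noise_sd=0.5))
        return modes


def calibrate_intercept(
    beta: Sequence[float], R: np.ndarray, prevalence: float, n_nodes: int = 201
) -> float:
    """Intercept c such that E[expit(c + beta' Z)] = prevalence, Z ~ N(0, R).

    beta' Z is univariate normal with variance s2 = beta' R beta, so the
    expectation reduces to a 1-D Gauss–Hermite quadrature; the calibration
    is a monotone scalar root-find in c.
    """
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must be in (0, 1)")
    beta = np.asarray(beta, dtype=float)
    s2 = float(beta @ np.asarray(R, dtype=float) @ beta)
    base = float(special.logit(prevalence))
    if s2 <= 0:
        return base
    s = np.sqrt(s2)
    nodes, weights = roots_hermitenorm(n_nodes)
    weights = weights / weights.sum()

    def mean_prev(c: float) -> float:
        return float(weights @ special.expit(c + s * nodes))

    lo, hi = base - 10.0 - 3 * s, base + 10.0 + 3 * s
    f_lo, f_hi = mean_prev(lo) - prevalence, mean_prev(hi) - prevalence
    if f_lo > 0 or f_hi < 0:
        raise RuntimeError("no bracketing interval for intercept calibration")
    return float(optimize.brentq(lambda c: mean_prev(c) - prevalence, lo, hi))


def _quantile_thresholds(n_bins: int) -> np.ndarray:
    """Standard-normal thresholds cutting the latent into equal-mass bins."""
    from scipy.stats import norm

    return norm.ppf(np.arange(1, n_bins) / n_bins)


def _discretize(z: np.ndarray, n_bins: int) -> np.ndarray:
    codes = np.digitize(z, _quantile_thresholds(n_bins))
    return np.array([f"c{c}" for c in codes], dtype=object)


def simulate_cohort(spec: CohortSpec) -> tuple[Cohort, GroundTruth]:
    """Simulate one cohort according to ``spec``; bit-identical per seed."""
    p = spec.n_core_predictors
    beta = spec.resolved_beta()
    R = spec.resolved_R()
    modes = spec.resolved_adjunct_modes()
    if not (0.0 <= spec.missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")

    rng = np.random.default_rng(child_seed(spec.seed, "simulate", spec.dataset_id))
    L = np.linalg.cholesky(R + 1e-12 * np.eye(p))
    Z = rng.standard_normal((spec.n_records, p)) @ L.T

    intercept = calibrate_intercept(beta, R, spec.outcome_prevalence)
    prob = special.expit(intercept + Z @ beta)
    y = rng.binomial(1, prob).astype(object)
    y = np.array([str(v) for v in y], dtype=object)

    n_cat = int(round(spec.categorical_fraction * p))
    bins_cycle = list(spec.category_bins)
    columns: dict[str, np.ndarray] = {}
    meta: list[VariableMeta] = []
    core_bins: dict[str, int] = {}
    for j in range(p):
        name = f"x{j + 1}"
        if j < n_cat:
            nb = bins_cycle[j % len(bins_cycle)]
            columns[name] = _discretize(Z[:, j], nb)
            core_bins[name] = nb
            meta.append(
                VariableMeta(name, "categorical", "core_predictor",
                             categories=[f"c{i}" for i in range(nb)])
            )
        else:
            columns[name] = Z[:, j].copy()
            meta.append(VariableMeta(name, "continuous", "core_predictor"))

    # adjuncts derived from the same latents
    core_index = {f"x{j + 1}": j for j in range(p)}
    for a, mode in enumerate(modes):
        name = f"a{a + 1}"
        noise = rng.standard_normal(spec.n_records)
        if mode.kind == "independent":
            raw = noise
        elif mode.kind == "redundant":
            if mode.source is None or mode.source not in core_index:
                raise ValueError(f"redundant adjunct {name} needs a valid source")
            raw = Z[:, core_index[mode.source]] + mode.noise_sd * noise
        elif mode.kind == "informative":
            w = np.asarray(mode.weights, dtype=float)
            if w.shape != (p,):
                raise ValueError(f"informative adjunct {name} needs a length-p weight vector")
            raw = Z @ w + mode.noise_sd * noise
        else:  # pragma: no cover - guarded by dataclass Literal
            raise ValueError(f"unknown adjunct mode {mode.kind!r}")

        if mode.kind == "redundant" and mode.source in core_bins:
            # match the source's discretisation so a noiseless copy has NMI 1
            nb = core_bins[mode.source]
            scale = np.sqrt(1.0 + mode.noise_sd**2)
            columns[name] = _discretize(raw / scale, nb)
            meta.append(
                VariableMeta(name, "categorical", "adjunct",
                             categories=[f"c{i}" for i in range(nb)])
            )
        elif mode.categorical:
            nb = mode.n_bins
            sd = float(np.std(raw)) or 1.0
            columns[name] = _discretize(raw / sd, nb)
            meta.append(
                VariableMeta(name, "categorical", "adjunct",
                             categories=[f"c{i}" for i in range(nb)])
            )
        else:
            columns[name] = raw
            meta.append(VariableMeta(name, "continuous", "adjunct"))

    columns["y"] = y
    meta.append(VariableMeta("y", "categorical", "outcome", categories=["0", "1"]))

    import pandas as pd

    df = pd.DataFrame(columns)

    # MCAR missingness on non-outcome columns
    if spec.missing_rate > 0:
        for m in meta:
            if m.role == "outcome":
                continue
            mask = rng.random(spec.n_records) < spec.missing_rate
            col = df[m.name].astype(object) if m.vtype == "categorical" else df[m.name]
            col = col.where(~mask, np.nan)
            df[m.name] = col

    # QI flags: first qi_count non-outcome variables
    flagged = 0
    for m in meta:
        if m.role == "outcome":
            continue
        if flagged < spec.qi_count:
            m.is_qi = True
            flagged += 1

    # parameter of interest: first continuous core predictor, else first core
    poi = next(
        (m.name for m in meta if m.role == "core_predictor" and m.vtype == "continuous"),
        meta[0].name,
    )
    for m in meta:
        if m.name == poi:
            m.is_parameter_of_interest = True
    poi_coef = float(beta[core_index[poi]])

    cohort = Cohort(records=df, meta=meta, dataset_id=spec.dataset_id).validate()
    truth = GroundTruth(
        beta=beta,
        intercept=float(intercept),
        prevalence=spec.outcome_prevalence,
        parameter_of_interest=poi,
        poi_coefficient=poi_coef,
    )
    return cohort, truth
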