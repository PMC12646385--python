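"""Train-on-synthetic-test-on-real (TSTR) utility.

The downstream task is binary classification on the core variables.  A
probabilistic classifier is fitted on each synthetic replicate and scored
on the real holdout; performance is AUROC averaged across the replicates
of the ensemble.  Two classifier families are provided: a gradient-boosted
machine (LightGBM, optionally tuned by 5-fold cross-validation optimised
for AUROC) and a small feed-forward network (no grid search, early
stopping against overfitting).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .cohort import Cohort
from .generators import SyntheticEnsemble

__all__ = [
    "ClassifierSpec",
    "TstrResult",
    "default_classifiers",
    "tstr_auroc",
    "trtr_auroc",
]


@dataclass
class ClassifierSpec:
    """Configuration of one TSTR classifier.

    kind: "gbm" (LightGBM) or "mlp" (scikit-learn MLP).
    tune: run a 5-fold CV grid search (gbm only) optimised for AUROC.
    grid: the CV grid (<= 24 combinations by default).
    params: fixed estimator parameters (override defaults).
    """

    kind: str = "gbm"
    tune: bool = False
    grid: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    cv_folds: int = 5

    @property
    def classifier_id(self) -> str:
        return self.kind + ("_cv" if self.tune else "")


def default_classifiers() -> list[ClassifierSpec]:
    """The two standard TSTR classifier specs: tuned GBM and fixed MLP."""
    gbm = ClassifierSpec(
        kind="gbm",
        tune=True,
        grid={
            "num_leaves": [15, 31],
            "learning_rate": [0.05, 0.1],
            "n_estimators": [100, 200],
            "min_child_samples": [10, 20],
        },
    )
    mlp = ClassifierSpec(kind="mlp", tune=False)
    return [gbm, mlp]


@dataclass
class TstrResult:
    mean_auroc: float
    per_replicate_auroc: list[float]
    classifier_id: str
    trtr_auroc: float | None = None


def _encode_tree(df: pd.DataFrame, meta, levels: dict[str, dict] | None = None):
    """Integer-code categoricals for tree models; NaN passes through."""
    out = {}
    fitted_levels = levels or {}
    for m in meta:
        col = df[m.name]
        if m.vtype == "categorical":
            if m.name not in fitted_levels:
                cats = sorted(str(v) for v in col.dropna().unique())
                fitted_levels[m.name] = {c: i for i, c in enumerate(cats)}
            lut = fitted_levels[m.name]
            out[m.name] = np.array(
                [lut.get(str(v), np.nan) if not pd.isna(v) else np.nan for v in col],
                dtype=float,
            )
        else:
            out[m.name] = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
    return pd.DataFrame(out), fitted_levels


def _encode_dense(df: pd.DataFrame, meta, stats: dict | None = None):
    """One-hot categoricals and impute for the network classifier.

    Imputation statistics are fitted on the (synthetic) training table only
    and reused for the holdout, so no holdout information leaks into
    training.
    """
    fitted = stats or {}
    blocks, names = [], []
    for m in meta:
        col = df[m.name]
        if m.vtype == "categorical":
            if m.name not in fitted:
                fitted[m.name] = {"levels": sorted(str(v) for v in col.dropna().unique())}
            for lv in fitted[m.name]["levels"]:
                blocks.append((col.astype(object).astype(str) == lv).to_numpy(dtype=float))
                names.append(f"{m.name}={lv}")
        else:
            v = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
            if m.name not in fitted:
                med = np.nanmedian(v) if not np.isnan(v).all() else 0.0
                sd = np.nanstd(v) if not np.isnan(v).all() else 1.0
                fitted[m.name] = {"median": float(med), "sd": float(sd) or 1.0}
            st = fitted[m.name]
            filled = np.where(np.isnan(v), st["median"], v)
            blocks.append((filled - st["median"]) / st["sd"])
            names.append(m.name)
            blocks.append(np.isnan(v).astype(float))
            names.append(f"{m.name}__missing")
    return np.column_stack(blocks), fitted


def _build_estimator(spec: ClassifierSpec, seed: int):
    if spec.kind == "gbm":
        from lightgbm import LGBMClassifier

        params = dict(
            n_estimators=100,
            num_leaves=31,
            learning_rate=0.1,
            min_child_samples=20,
            deterministic=True,
            force_row_wise=True,
            n_jobs=1,
            random_state=seed,
            verbose=-1,
        )
        params.update(spec.params)
        est = LGBMClassifier(**params)
        if spec.tune:
            from sklearn.model_selection import GridSearchCV

            n_combos = int(np.prod([len(v) for v in spec.grid.values()])) if spec.grid else 1
            if n_combos > 24:
                warnings.warn(f"CV grid has {n_combos} > 24 combinations", stacklevel=2)
            est = GridSearchCV(
                est, spec.grid, cv=spec.cv_folds, scoring="roc_auc", n_jobs=1, refit=True
            )
        return est
    if spec.kind == "mlp":
        from sklearn.neural_network import MLPClassifier

        params = dict(
            hidden_layer_sizes=(32, 16),
            early_stopping=True,
            validation_fraction=0.1,
            max_iter=300,
            random_state=seed,
        )
        params.update(spec.params)
        return MLPClassifier(**params)
    raise ValueError(f"unknown classifier kind {spec.kind!r}")


def _outcome_vector(cohort_df: pd.DataFrame, outcome: str, positive: str) -> np.ndarray:
    return (cohort_df[outcome].astype(object).astype(str) == positive).to_numpy(dtype=int)


def _fit_score(
    train_df: pd.DataFrame,
    holdout_df: pd.DataFrame,
    predictor_meta,
    outcome: str,
    positive: str,
    spec: ClassifierSpec,
    seed: int,
) -> float:
    y_tr = _outcome_vector(train_df, outcome, positive)
    y_ho = _outcome_vector(holdout_df, outcome, positive)
    if len(np.unique(y_ho)) < 2:
        raise ValueError("holdout outcome is single-class; AUROC undefined")
    est = _build_estimator(spec, seed)
    if spec.kind == "gbm":
        X_tr, levels = _encode_tree(train_df, predictor_meta)
        X_ho, _ = _encode_tree(holdout_df, predictor_meta, levels)
    else:
        X_tr, stats = _encode_dense(train_df, predictor_meta)
        X_ho, _ = _encode_dense(holdout_df, predictor_meta, stats)
    est.fit(X_tr, y_tr)
    scores = est.predict_proba(X_ho)[:, 1]
    return float(roc_auc_score(y_ho, scores))


def tstr_auroc(
    ensemble: SyntheticEnsemble,
    holdout: Cohort,
    classifier_spec: ClassifierSpec | None = None,
    seed: int = 0,
    with_trtr: Cohort | None = None,
) -> TstrResult:
    """TSTR AUROC of an ensemble against the real holdout, on core columns.

    A synthetic replicate whose sampled outcome collapses to one class
    cannot train a classifier; it is skipped with a warning and recorded as
    NaN in the per-replicate list.  ``with_trtr`` optionally supplies a real
    training table for a train-on-real reference AUROC.
    """
    spec = classifier_spec or ClassifierSpec(kind="gbm", tune=False)
    outcome = holdout.outcome_name
    out_meta = holdout.meta_for(outcome)
    positive = (out_meta.categories or sorted(
        holdout.records[outcome].dropna().astype(str).unique()
    ))[-1]
    predictor_meta = [m for m in holdout.meta if m.role == "core_predictor"]
    core_cols = [m.name for m in predictor_meta] + [outcome]
    ho_df = holdout.records[core_cols]

    per_rep: list[float] = []
    for i, rep in enumerate(ensemble.replicates):
        rep_df = rep.records[core_cols]
        y = _outcome_vector(rep_df, outcome, positive)
        if len(np.unique(y)) < 2:
            warnings.warn(
                f"replicate {i}: synthetic outcome single-class, recorded as missing",
                stacklevel=2,
            )
            per_rep.append(float("nan"))
            continue
        per_rep.append(
            _fit_score(rep_df, ho_df, predictor_meta, outcome, positive, spec, seed)
        )
    vals = [v for v in per_rep if not np.isnan(v)]
    mean = float(np.mean(vals)) if vals else float("nan")

    trtr = None
    if with_trtr is not None:
        trtr = _fit_score(
            with_trtr.records[core_cols], ho_df, predictor_meta, outcome, positive, spec, seed
        )
    return TstrResult(
        mean_auroc=mean,
        per_replicate_auroc=per_rep,
        classifier_id=spec.classifier_id,
        trtr_auroc=trtr,
    )


def trtr_auroc(
    train: Cohort, holdout: Cohort, classifier_spec: ClassifierSpec | None = None, seed: int = 0
) -> float:
    """Train-on-real-test-on-real reference AUROC on core columns."""
    spec = classifier_spec or ClassifierSpec(kind="gbm", tune=False)
    outcome = holdout.outcome_name
    out_meta = holdout.meta_for(outcome)
    positive = (out_meta.categories or sorted(
        holdout.records[outcome].dropna().astype(str).unique()
    ))[-1]
    predictor_meta = [m for m in holdout.meta if m.role == "core_predictor"]
    core_cols = [m.name for m in predictor_meta] + [outcome]
    return _fit_score(
        train.records[core_cols], holdout.records[core_cols],
        predictor_meta, outcome, positive, spec, seed,
    )
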