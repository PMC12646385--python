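"""End-to-end experiment orchestration.

One run config describes everything: the cohorts to simulate, how variants
are built, which generators to fit, which metrics to evaluate, and the
master seed.  ``run_experiment`` executes

    simulate -> split -> variants -> fit generator -> generate ensemble
             -> project to core -> fidelity / TSTR / replicability
             -> membership attack (both scopes) -> effect models

and returns the long-format metric table, the effect table and a run
manifest.  Any cell (dataset x variant x generator) that fails is logged
with its coordinates and the run continues; the manifest records failures
so callers can exit nonzero.

Defaults mirror the full-scale study conditions (10 000 training and
holdout records, 10 replicates, significance 0.05); desk-scale smoke runs
override sizes through the config, not through code changes.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from ._seeding import child_seed
from .cohort import (
    METRIC_TABLE_COLUMNS,
    Cohort,
    split_train_holdout,
    write_cohort,
)
from .effects import effect_table
from .fidelity import ensemble_fidelity
from .generators import generate, get_generator
from .membership import AttackConfig, vulnerability_pair
from .replicability import EstimateFailure, ensemble_replicability
from .simulate import CohortSpec, simulate_cohort
from .tstr import ClassifierSpec, tstr_auroc
from .variants import (
    DEFAULT_ENUMERATION_CAP,
    VariantSpec,
    enumerate_variants,
    project_variant,
    sample_variants,
)

__all__ = ["RunConfig", "run_experiment", "summarize_run"]

logger = logging.getLogger("sdgeval")


@dataclass
class RunConfig:
    """Declarative description of one experiment run."""

    cohorts: list[dict] = field(default_factory=list)  # CohortSpec kwargs
    generators: list[str] = field(default_factory=lambda: ["st", "independent"])
    metrics: list[str] = field(
        default_factory=lambda: ["fidelity", "tstr", "replicability", "privacy"]
    )
    n_train: int = 10_000
    n_holdout: int = 10_000
    n_replicates: int = 10
    n_synthetic_rows: int | None = None  # default: training size
    enumeration_cap: int = DEFAULT_ENUMERATION_CAP
    min_per_k: int = 5
    variant_method: str = "uniform"  # or "halton"
    fidelity_clusters: int = 20
    classifier: dict = field(default_factory=lambda: {"kind": "gbm", "tune": False})
    attack: dict = field(default_factory=dict)  # AttackConfig kwargs (minus seed)
    alpha: float = 0.05
    combine_rule: str = "partial"
    master_seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("replicate count must be >= 1")
        if not self.cohorts:
            raise ValueError("config must declare at least one cohort")
        for g in self.generators:
            get_generator(g)  # raises on unknown generator before any compute

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        return cls(**yaml.safe_load(Path(path).read_text()))


def _build_variants(cohort: Cohort, cfg: RunConfig) -> list[VariantSpec]:
    pool = cohort.adjunct_names
    core = cohort.core_predictor_names
    if len(pool) == 0:
        return [VariantSpec(cohort.dataset_id, tuple(core), ())]
    if len(pool) <= cfg.enumeration_cap:
        return enumerate_variants(core, pool, dataset_id=cohort.dataset_id,
                                  enumeration_cap=cfg.enumeration_cap)
    return sample_variants(
        core, pool, min_per_k=cfg.min_per_k,
        seed=child_seed(cfg.master_seed, "variants", cohort.dataset_id),
        method=cfg.variant_method, dataset_id=cohort.dataset_id,
    )


def run_experiment(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Execute the full experiment described by ``config``."""
    t0 = time.time()
    rows: list[dict] = []
    failures: list[dict] = []
    manifest: dict[str, Any] = {
        "master_seed": config.master_seed,
        "generators": config.generators,
        "metrics": config.metrics,
        "n_train": config.n_train,
        "n_holdout": config.n_holdout,
        "n_replicates": config.n_replicates,
        "cohorts": [],
    }
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    classifier = ClassifierSpec(**config.classifier)

    for cohort_kwargs in config.cohorts:
        spec_kwargs = dict(cohort_kwargs)
        spec_kwargs.setdefault("seed", child_seed(config.master_seed, "cohort",
                                                  spec_kwargs.get("dataset_id", "sim")))
        spec = CohortSpec(**spec_kwargs)
        cohort, truth = simulate_cohort(spec)
        did = cohort.dataset_id
        split = split_train_holdout(cohort, config.n_train, config.n_holdout,
                                    config.master_seed)
        holdout = Cohort(cohort.records.iloc[split.holdout_ids].reset_index(drop=True),
                         list(cohort.meta), did)
        variants = _build_variants(cohort, config)
        manifest["cohorts"].append(
            {"dataset_id": did, "n_records": cohort.n, "n_variants": len(variants),
             "poi": truth.parameter_of_interest}
        )
        if outdir:
            write_cohort(cohort, outdir / f"{did}.csv", outdir / f"{did}.meta.json")

        attack_cfg = AttackConfig(
            **{**config.attack, "seed": child_seed(config.master_seed, "attack", did)}
        )
        n_rows = config.n_synthetic_rows or config.n_train

        for variant in variants:
            train_variant = project_variant(
                Cohort(cohort.records.iloc[split.train_ids].reset_index(drop=True),
                       list(cohort.meta), did),
                variant,
            )
            pop_variant = project_variant(cohort, variant)
            holdout_core = holdout.project(holdout.core_names)
            for gen_name in config.generators:
                coords = {"dataset_id": did, "k_adjunct": variant.k_adjunct,
                          "adjunct_subset": list(variant.adjunct_subset),
                          "generator_id": gen_name}
                try:
                    fit_fn = get_generator(gen_name)
                    fitted = fit_fn(
                        train_variant,
                        seed=child_seed(config.master_seed, "fit", did, gen_name,
                                        variant.adjunct_subset),
                    )
                    ensemble = generate(
                        fitted, n_rows, config.n_replicates,
                        seed=child_seed(config.master_seed, "gen", did, gen_name,
                                        variant.adjunct_subset),
                        dataset_id=did,
                    )
                    core_ensemble = _project_ensemble(ensemble, holdout_core)
                    variant_id = "+".join(variant.adjunct_subset) or "core"
                    base = {"dataset_id": did, "generator_id": gen_name,
                            "k_adjunct": variant.k_adjunct,
                            "variant_id": variant_id}

                    if "fidelity" in config.metrics:
                        _, scores = ensemble_fidelity(
                            holdout_core, core_ensemble, G=config.fidelity_clusters,
                            seed=child_seed(config.master_seed, "fid", did, gen_name,
                                            variant.adjunct_subset),
                        )
                        for r, s in enumerate(scores):
                            rows.append({**base, "metric_name": "fidelity",
                                         "replicate": r, "value": s})

                    if "tstr" in config.metrics:
                        res = tstr_auroc(
                            core_ensemble, holdout_core, classifier,
                            seed=child_seed(config.master_seed, "tstr", did, gen_name,
                                            variant.adjunct_subset),
                        )
                        for r, s in enumerate(res.per_replicate_auroc):
                            rows.append({**base,
                                         "metric_name": f"tstr_{res.classifier_id}",
                                         "replicate": r, "value": s})

                    if "replicability" in config.metrics:
                        train_core = train_variant.project(
                            [c for c in train_variant.records.columns
                             if c in set(holdout.core_names)]
                        )
                        try:
                            met, _, _, _ = ensemble_replicability(
                                train_core, core_ensemble, alpha=config.alpha,
                                rule=config.combine_rule,
                            )
                            for name, val in (
                                ("decision_agreement", met.decision_agreement),
                                ("estimate_agreement", met.estimate_agreement),
                                ("standardized_difference_agreement",
                                 met.standardized_difference_agreement),
                                ("ci_overlap", met.ci_overlap),
                            ):
                                rows.append({**base, "metric_name": name,
                                             "replicate": np.nan, "value": float(val)})
                        except EstimateFailure as exc:
                            logger.warning("replicability failed for %s: %s", coords, exc)

                    if "privacy" in config.metrics:
                        vuln = vulnerability_pair(
                            pop_variant, split.train_ids, ensemble, attack_cfg,
                            core_names=holdout.core_names,
                        )
                        for name, (_, vals) in vuln.items():
                            for r, v in enumerate(vals):
                                rows.append({**base, "metric_name": name,
                                             "replicate": r, "value": v})
                except Exception as exc:  # noqa: BLE001 - keep remaining cells running
                    logger.error("cell failed %s: %s", coords, exc)
                    failures.append({**coords, "error": str(exc)})

    metric_table = pd.DataFrame(rows, columns=METRIC_TABLE_COLUMNS)
    try:
        effects = effect_table(metric_table) if len(metric_table) else pd.DataFrame()
    except Exception as exc:  # noqa: BLE001
        logger.error("effect modelling failed: %s", exc)
        effects = pd.DataFrame()
        failures.append({"stage": "effects", "error": str(exc)})

    manifest["failures"] = failures
    manifest["n_metric_rows"] = len(metric_table)
    manifest["elapsed_seconds"] = round(time.time() - t0, 3)

    if outdir:
        metric_table.to_csv(outdir / "metrics.csv", index=False)
        if len(effects):
            effects.to_csv(outdir / "effects.csv", index=False)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return metric_table, effects, manifest


def _project_ensemble(ensemble, core_cohort: Cohort):
    """Project every replicate to the core columns (strategy: synthesize the
    full variant once, evaluate the released subset)."""
    from .generators import SyntheticEnsemble

    core_cols = list(core_cohort.records.columns)
    reps = [rep.project(core_cols) for rep in ensemble.replicates]
    return SyntheticEnsemble(
        replicates=reps, generator_id=ensemble.generator_id,
        dataset_id=ensemble.dataset_id, generation_seed=ensemble.generation_seed,
    )


def summarize_run(metric_table: pd.DataFrame, metrics: list[str] | None = None) -> str:
    """Plain-text summary: per-metric means by adjunct count and generator,
    with privacy rows flagged against the 0.2 relative-F1 threshold."""
    if metric_table is None or len(metric_table) == 0:
        raise ValueError("empty metric table")
    names = metrics or sorted(metric_table["metric_name"].unique())
    missing = [m for m in names if m not in set(metric_table["metric_name"])]
    if missing:
        raise ValueError(f"metrics not present in table: {missing}")
    lines: list[str] = []
    for met in names:
        sub = metric_table[metric_table["metric_name"] == met]
        lines.append(f"== {met} ==")
        pivot = sub.groupby(["generator_id", "k_adjunct"])["value"].mean()
        for (gen, k), v in pivot.items():
            flag = ""
            if met.startswith("membership") and v >= 0.2:
                flag = "  ** above 0.2 relative-F1 threshold **"
            lines.append(f"  {gen:<12} k={k:<4d} mean={v: .4f}{flag}")
    return "\n".join(lines)
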