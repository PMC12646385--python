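"""Membership-disclosure vulnerability via a matching attack.

The adversary holds a sample of target records — a fraction p drawn from
the SDG training data (members), the rest from the remaining population —
and predicts "member" for every target that matches at least one synthetic
record on the compared variables (quasi-identifiers only, or the entire
record).  Categorical values match on equality with missing treated as a
category; continuous values match within a tolerance expressed as a
fraction of the pooled standard deviation; up to h variable mismatches are
allowed (default 0).

The attack's F1 is reported relative to the naive adversary that calls
every target a member (precision p, recall 1, F1 = 2p/(1+p)):

    relative_f1 = max(0, f1 - f1_naive)

Values below 0.2 — the conventional acceptance threshold for the relative
F1 score — are flagged as low residual risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd

from ._seeding import child_seed
from .cohort import Cohort
from .generators import SyntheticEnsemble

__all__ = [
    "AttackConfig",
    "MembershipAttackResult",
    "membership_attack",
    "vulnerability_pair",
    "ACCEPTANCE_THRESHOLD",
]

#: Literature threshold below which residual membership risk is acceptable.
ACCEPTANCE_THRESHOLD = 0.2


@dataclass
class AttackConfig:
    qi_names: list[str] = field(default_factory=list)
    attack_sample_size: int | None = None  # default min(1000, population/10)
    member_fraction: float = 0.5
    match_hamming_threshold: int = 0
    continuous_tolerance: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.member_fraction < 1.0):
            raise ValueError("member_fraction must be in (0, 1)")
        if self.match_hamming_threshold < 0:
            raise ValueError("match_hamming_threshold must be >= 0")


@dataclass
class MembershipAttackResult:
    precision: float
    recall: float
    f1: float
    f1_naive: float
    relative_f1: float
    mode: str

    @property
    def acceptable(self) -> bool:
        return self.relative_f1 < ACCEPTANCE_THRESHOLD


def _naive_f1(p: float) -> float:
    return 2.0 * p / (1.0 + p)


def _mismatch_counts(
    attack: pd.DataFrame,
    synthetic: pd.DataFrame,
    meta_by_name: dict,
    columns: list[str],
    tolerances: dict[str, float],
) -> np.ndarray:
    """Minimum per-pair mismatch count between attack and synthetic records.

    Vectorised brute force: for each attack record the mismatch count
    against every synthetic record is accumulated column-wise; the minimum
    over synthetic records is returned.
    """
    n_a, n_s = len(attack), len(synthetic)
    best = np.full(n_a, len(columns) + 1, dtype=np.int32)
    chunk = max(1, int(2_000_000 // max(n_s, 1)))
    for start in range(0, n_a, chunk):
        stop = min(start + chunk, n_a)
        total = np.zeros((stop - start, n_s), dtype=np.int16)
        for c in columns:
            m = meta_by_name[c]
            if m.vtype == "categorical":
                a = attack[c].iloc[start:stop].astype(object).where(
                    attack[c].iloc[start:stop].notna(), "__missing__"
                ).astype(str).to_numpy()
                s = synthetic[c].astype(object).where(
                    synthetic[c].notna(), "__missing__"
                ).astype(str).to_numpy()
                total += (a[:, None] != s[None, :]).astype(np.int16)
            else:
                a = pd.to_numeric(attack[c].iloc[start:stop], errors="coerce").to_numpy(float)
                s = pd.to_numeric(synthetic[c], errors="coerce").to_numpy(float)
                a_na, s_na = np.isnan(a), np.isnan(s)
                diff = np.abs(a[:, None] - s[None, :])
                ok = diff <= tolerances[c]
                # missing matches missing only
                ok = np.where(a_na[:, None] | s_na[None, :], a_na[:, None] & s_na[None, :], ok)
                total += (~ok).astype(np.int16)
        best[start:stop] = total.min(axis=1)
    return best


def _exact_match_flags(
    attack: pd.DataFrame, synthetic: pd.DataFrame, meta_by_name, columns, tolerances
) -> np.ndarray:
    """Fast path for h=0 with categorical-only columns: hashed exact keys."""
    def keys(df: pd.DataFrame) -> list[tuple]:
        parts = []
        for c in columns:
            parts.append(
                df[c].astype(object).where(df[c].notna(), "__missing__").astype(str).to_numpy()
            )
        return list(zip(*parts))

    syn_keys = set(keys(synthetic))
    return np.array([k in syn_keys for k in keys(attack)], dtype=bool)


def membership_attack(
    population: Cohort,
    train_ids: np.ndarray,
    synthetic: Cohort,
    config: AttackConfig,
    mode: str = "qi_only",
    columns: list[str] | None = None,
) -> MembershipAttackResult:
    """Run the matching attack and report precision/recall/F1/relative F1.

    ``columns`` optionally restricts the record scope (e.g. the core subset)
    before the QI/all-variables mode is applied.
    """
    if mode not in ("qi_only", "all_variables"):
        raise ValueError("mode must be 'qi_only' or 'all_variables'")
    scope = columns if columns is not None else [m.name for m in synthetic.meta]
    if mode == "qi_only":
        qis = config.qi_names or population.qi_names
        compared = [c for c in scope if c in set(qis)]
        if not compared:
            raise ValueError("no quasi-identifiers declared within the attack scope")
    else:
        compared = list(scope)

    train_ids = np.asarray(train_ids, dtype=np.int64)
    pop_n = population.n
    non_members = np.setdiff1d(np.arange(pop_n), train_ids)
    a = config.attack_sample_size or min(1000, max(pop_n // 10, 2))
    n_mem = ceil(config.member_fraction * a)
    n_non = a - n_mem
    if n_mem > train_ids.size or n_non > non_members.size:
        raise ValueError("attack sample size exceeds available records")

    rng = np.random.default_rng(child_seed(config.seed, "attack", population.dataset_id, mode))
    pick_mem = rng.choice(train_ids, size=n_mem, replace=False)
    pick_non = rng.choice(non_members, size=n_non, replace=False)
    attack_idx = np.concatenate([pick_mem, pick_non])
    truth = np.concatenate([np.ones(n_mem, dtype=bool), np.zeros(n_non, dtype=bool)])

    attack_df = population.records.iloc[attack_idx][compared].reset_index(drop=True)
    syn_df = synthetic.records[compared]

    meta_by_name = {m.name: m for m in population.meta}
    # tolerance scale: pooled sd over population and synthetic values
    tolerances = {}
    for c in compared:
        if meta_by_name[c].vtype == "continuous":
            pooled = np.concatenate(
                [
                    pd.to_numeric(population.records[c], errors="coerce").to_numpy(float),
                    pd.to_numeric(synthetic.records[c], errors="coerce").to_numpy(float),
                ]
            )
            sd = float(np.nanstd(pooled))
            tolerances[c] = config.continuous_tolerance * (sd if sd > 0 else 1.0)

    all_categorical = all(meta_by_name[c].vtype == "categorical" for c in compared)
    if config.match_hamming_threshold == 0 and all_categorical:
        predicted = _exact_match_flags(attack_df, syn_df, meta_by_name, compared, tolerances)
    else:
        best = _mismatch_counts(attack_df, syn_df, meta_by_name, compared, tolerances)
        predicted = best <= config.match_hamming_threshold

    tp = int(np.sum(predicted & truth))
    fp = int(np.sum(predicted & ~truth))
    fn = int(np.sum(~predicted & truth))
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    f1_naive = _naive_f1(config.member_fraction)
    return MembershipAttackResult(
        precision=float(precision),
        recall=float(recall),
        f1=float(f1),
        f1_naive=float(f1_naive),
        relative_f1=float(max(0.0, f1 - f1_naive)),
        mode=mode,
    )


def vulnerability_pair(
    population: Cohort,
    train_ids: np.ndarray,
    ensemble: SyntheticEnsemble,
    config: AttackConfig,
    core_names: list[str] | None = None,
) -> dict[str, tuple[float, list[float]]]:
    """Replicate-mean vulnerability for both modes and both column scopes.

    Returns ``{metric_name: (mean relative F1, per-replicate values)}`` for
    metric names ``membership_{qi,all}_{core,full}``.  The core scope uses
    the core variables (+ outcome); the full scope the entire record.
    """
    core = core_names if core_names is not None else population.core_names
    scopes = {"core": core, "full": [m.name for m in ensemble.replicates[0].meta]}
    modes = {"qi": "qi_only", "all": "all_variables"}
    out: dict[str, tuple[float, list[float]]] = {}
    for mode_key, mode in modes.items():
        for scope_key, scope_cols in scopes.items():
            vals = []
            for rep in ensemble.replicates:
                res = membership_attack(
                    population, train_ids, rep, config, mode=mode, columns=scope_cols
                )
                vals.append(res.relative_f1)
            out[f"membership_{mode_key}_{scope_key}"] = (float(np.mean(vals)), vals)
    return out
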