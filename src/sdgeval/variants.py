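"""Training-population variants: core variables plus adjunct subsets.

A *variant* is one training population: the core variable set plus one
particular subset of the adjunct pool.  When the pool is small the full
combinatorial space (all 2^m subsets, including the empty core-only subset)
is enumerated; for larger pools, subsets are sampled per adjunct count k
with a floor of 5 variants per k, exactly one variant at k = 0 (core only)
and exactly one at k = m (no variety in the combination).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from ._seeding import child_seed
from .cohort import Cohort

__all__ = [
    "VariantSpec",
    "enumerate_variants",
    "sample_variants",
    "default_per_k_target",
    "project_variant",
]

DEFAULT_ENUMERATION_CAP = 12  # enumerate up to 2^12 = 4096 subsets


@dataclass(frozen=True)
class VariantSpec:
    """One training population: a core set plus one adjunct subset."""

    dataset_id: str
    core_names: tuple[str, ...]
    adjunct_subset: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.core_names) & set(self.adjunct_subset):
            raise ValueError("adjunct subset overlaps the core set")

    @property
    def k_adjunct(self) -> int:
        return len(self.adjunct_subset)


def enumerate_variants(
    core_names: Sequence[str],
    pool: Sequence[str],
    dataset_id: str = "cohort",
    enumeration_cap: int = DEFAULT_ENUMERATION_CAP,
) -> list[VariantSpec]:
    """All 2^m adjunct subsets (core-only included), ordered by k then lexicographically."""
    pool = sorted(pool)
    m = len(pool)
    if m > enumeration_cap:
        raise ValueError(
            f"pool size {m} exceeds enumeration cap {enumeration_cap}; use sample_variants"
        )
    from itertools import combinations

    out: list[VariantSpec] = []
    for k in range(m + 1):
        for subset in combinations(pool, k):
            out.append(VariantSpec(dataset_id, tuple(core_names), subset))
    return out


def default_per_k_target(m: int, scale: float = 3.0, min_per_k: int = 5) -> Callable[[int], int]:
    """Per-k sample counts proportional to log C(m, k).

    Larger combinatorial spaces get more samples, giving a balanced
    representation of the subset space without enumerating it.
    """

    def target(k: int) -> int:
        c = math.comb(m, k)
        return max(min_per_k, int(round(scale * math.log2(c + 1))))

    return target


def _comb_unrank(rank: int, m: int, k: int) -> tuple[int, ...]:
    """rank -> the rank-th k-subset of range(m) in lexicographic order."""
    subset = []
    x = 0
    for i in range(k):
        while True:
            c = math.comb(m - x - 1, k - i - 1)
            if rank < c:
                break
            rank -= c
            x += 1
        subset.append(x)
        x += 1
    return tuple(subset)


def sample_variants(
    core_names: Sequence[str],
    pool: Sequence[str],
    per_k_target: Callable[[int], int] | None = None,
    min_per_k: int = 5,
    seed: int = 0,
    method: str = "uniform",
    dataset_id: str = "cohort",
) -> list[VariantSpec]:
    """Sample distinct adjunct subsets per adjunct count k.

    For each k in 1..m-1 the number of distinct subsets is
    ``min(max(per_k_target(k), min_per_k), C(m, k))``; exactly one variant is
    produced at k = 0 (core only) and one at k = m (the full pool).

    ``method="halton"`` replaces uniform subset ranks with a low-discrepancy
    Halton sequence over the combination ranks, for more even coverage of
    large combinatorial spaces.
    """
    pool = sorted(pool)
    m = len(pool)
    if m < 1:
        raise ValueError("pool must contain at least one adjunct variable")
    if per_k_target is None:
        per_k_target = default_per_k_target(m, min_per_k=min_per_k)

    core = tuple(core_names)
    out: list[VariantSpec] = [VariantSpec(dataset_id, core, ())]

    rng = np.random.default_rng(child_seed(seed, "variants", m))
    if method == "halton":
        from scipy.stats import qmc

        halton = qmc.Halton(d=1, scramble=True, seed=child_seed(seed, "halton", m))

    for k in range(1, m):
        space = math.comb(m, k)
        try:
            want = int(per_k_target(k))
        except Exception as exc:  # noqa: BLE001
            raise ValueError(f"per_k_target must be callable over 1..{m}") from exc
        n_k = min(max(want, min_per_k), space)
        ranks: set[int] = set()
        if method == "halton":
            while len(ranks) < n_k:
                u = halton.random(n_k - len(ranks)).ravel()
                ranks.update(int(v * space) for v in u)
        elif space <= 4 * n_k:
            ranks = set(rng.choice(space, size=n_k, replace=False).tolist())
        else:
            while len(ranks) < n_k:
                ranks.update(int(v) for v in rng.integers(0, space, size=n_k - len(ranks)))
        for r in sorted(ranks):
            idx = _comb_unrank(r, m, k)
            out.append(VariantSpec(dataset_id, core, tuple(pool[i] for i in idx)))

    out.append(VariantSpec(dataset_id, core, tuple(pool)))
    out.sort(key=lambda v: (v.k_adjunct, v.adjunct_subset))
    return out


def project_variant(cohort: Cohort, variant: VariantSpec) -> Cohort:
    """Restrict a cohort to the variant's core + adjunct columns (+ outcome)."""
    keep = set(variant.core_names) | set(variant.adjunct_subset) | {cohort.outcome_name}
    return cohort.project([c for c in cohort.records.columns if c in keep])
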