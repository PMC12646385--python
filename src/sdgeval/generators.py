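"""Tabular synthetic-data generators.

Two full generators are implemented here:

* **Sequential decision trees (ST)** — CART-style conditional synthesis:
  the first variable in the visit order is drawn from its empirical
  marginal; each later variable is modelled by a decision tree
  (classification for categoricals, regression for continuous) on the
  variables before it, and synthesis samples *donor* training values from
  the leaf a partially generated record falls into.  Donor sampling keeps
  every synthetic value in the support of the training data.

* **Bayesian network (BN)** — continuous variables are discretised into
  equal-frequency bins, the network structure is the Chow–Liu maximum
  spanning tree on pairwise mutual information rooted into a DAG, the
  conditional probability tables use add-alpha smoothing, sampling is
  ancestral, and continuous values are re-materialised by a uniform draw
  within the sampled bin's training range.

Two baselines complete the set: **independent marginals** (each column
bootstrapped independently — destroys the joint, maximally private among
data-derived samplers) and a **copy generator** (row bootstrap of the
training data — no modelling at all, the worst case for membership
disclosure; intended for test harnesses and calibration, not release).

Missing values: categoricals treat missingness as an explicit category;
each continuous column with missing training values gets a companion
binary missingness variable modelled jointly, with the value re-blanked on
synthesis, so missingness rates survive into the synthetic output.

Deep generative models (GANs, VAEs, normalizing flows, adversarial random
forests) are deliberately out of scope; third-party implementations can be
attached through :func:`register_generator` with the same fit/sample
contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import minimum_spanning_tree
from sklearn.metrics import mutual_info_score
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from ._seeding import child_seed
from .cohort import Cohort, VariableMeta

__all__ = [
    "FittedGenerator",
    "SyntheticEnsemble",
    "fit_sequential_trees",
    "fit_bayesian_network",
    "fit_independent_marginals",
    "fit_copy",
    "generate",
    "register_generator",
    "get_generator",
    "GENERATOR_REGISTRY",
]

_MISSING = "__missing__"


class FittedGenerator(Protocol):
    """Contract every generator (built-in or plugin) satisfies."""

    generator_id: str
    schema: list[VariableMeta]
    fit_seed: int

    def sample(self, n_rows: int, seed: int) -> pd.DataFrame: ...


@dataclass
class SyntheticEnsemble:
    """The replicate synthetic cohorts produced by one fitted generator."""

    replicates: list[Cohort]
    generator_id: str
    dataset_id: str
    generation_seed: int

    def __len__(self) -> int:
        return len(self.replicates)


# ---------------------------------------------------------------------------
# helpers


def _cat_levels(series: pd.Series) -> list[str]:
    levels = sorted(str(v) for v in series.dropna().unique())
    if series.isna().any():
        levels.append(_MISSING)
    return levels


def _encode_categorical(series: pd.Series, levels: list[str]) -> np.ndarray:
    """Categorical column -> integer codes with missing as its own code."""
    codes = np.empty(len(series), dtype=np.int64)
    lookup = {lv: i for i, lv in enumerate(levels)}
    vals = series.astype(object).values
    for i, v in enumerate(vals):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            codes[i] = lookup[_MISSING]
        else:
            codes[i] = lookup[str(v)]
    return codes


def _feature_matrix(
    df: pd.DataFrame, meta: dict[str, VariableMeta], columns: Sequence[str],
    levels: dict[str, list[str]], medians: dict[str, float],
) -> np.ndarray:
    """Numeric feature encoding for tree fitting/application.

    Categoricals become integer codes (missing = own code); continuous
    columns are median-imputed with a companion missing indicator.
    """
    cols: list[np.ndarray] = []
    for c in columns:
        if meta[c].vtype == "categorical":
            cols.append(_encode_categorical(df[c], levels[c]).astype(float))
        else:
            v = pd.to_numeric(df[c], errors="coerce").astype(float).values
            miss = np.isnan(v)
            filled = np.where(miss, medians[c], v)
            cols.append(filled)
            cols.append(miss.astype(float))
    return np.column_stack(cols) if cols else np.empty((len(df), 0))


# ---------------------------------------------------------------------------
# Sequential decision trees


@dataclass
class _StVariable:
    name: str
    vtype: str
    tree: object | None  # None for the first variable in the visit order
    donors: dict[int, np.ndarray] | None  # leaf id -> training target values
    marginal: np.ndarray | None  # donor pool for the first variable


@dataclass
class SequentialTreesGenerator:
    generator_id: str
    schema: list[VariableMeta]
    fit_seed: int
    visit_order: list[str]
    variables: list[_StVariable]
    levels: dict[str, list[str]]
    medians: dict[str, float]

    def sample(self, n_rows: int, seed: int) -> pd.DataFrame:
        rng = np.random.default_rng(seed)
        meta = {m.name: m for m in self.schema}
        out: dict[str, np.ndarray] = {}
        frame = pd.DataFrame(index=range(n_rows))
        for j, var in enumerate(self.variables):
            if var.tree is None:
                vals = rng.choice(var.marginal, size=n_rows, replace=True)
            else:
                X = _feature_matrix(frame, meta, self.visit_order[:j], self.levels, self.medians)
                leaves = var.tree.apply(X)
                vals = np.empty(n_rows, dtype=object)
                for leaf in np.unique(leaves):
                    idx = np.where(leaves == leaf)[0]
                    pool = var.donors[int(leaf)]
                    vals[idx] = rng.choice(pool, size=idx.size, replace=True)
            if var.vtype == "continuous":
                vals = pd.array(vals, dtype=float)
            col = pd.Series(vals, index=frame.index, dtype=object if var.vtype == "categorical" else float)
            if var.vtype == "categorical":
                col = col.where(col != _MISSING, np.nan)
            frame[var.name] = col
        # restore schema column order
        return frame[[m.name for m in self.schema]]


def fit_sequential_trees(
    train: Cohort,
    visit_order: Sequence[str] | None = None,
    tree_controls: dict | None = None,
    seed: int = 0,
) -> SequentialTreesGenerator:
    """Fit the sequential CART synthesiser.

    Default visit order is the metadata order with the outcome last; the
    default tree controls (min leaf 5, unlimited depth) are surfaced through
    ``tree_controls``.
    """
    if train.n < 1:
        raise ValueError("empty training table")
    df = train.records
    meta = {m.name: m for m in train.meta}
    if visit_order is None:
        visit_order = [m.name for m in train.meta if m.role != "outcome"] + [train.outcome_name]
    visit_order = list(visit_order)
    if sorted(visit_order) != sorted(df.columns):
        raise ValueError("visit_order must be a permutation of the cohort columns")

    controls = {"min_samples_leaf": 5, "max_depth": None}
    controls.update(tree_controls or {})

    levels = {c: _cat_levels(df[c]) for c in df.columns if meta[c].vtype == "categorical"}
    medians = {
        c: float(pd.to_numeric(df[c], errors="coerce").median())
        if pd.to_numeric(df[c], errors="coerce").notna().any()
        else 0.0
        for c in df.columns
        if meta[c].vtype == "continuous"
    }

    variables: list[_StVariable] = []
    for j, name in enumerate(visit_order):
        vtype = meta[name].vtype
        if vtype == "categorical":
            target = np.array(
                [str(v) if not _isna(v) else _MISSING for v in df[name].values], dtype=object
            )
            obs_mask = np.ones(len(df), dtype=bool)
        else:
            vals = pd.to_numeric(df[name], errors="coerce").values.astype(float)
            obs_mask = ~np.isnan(vals)
            target = vals
        if j == 0:
            pool = target if vtype == "categorical" else vals  # NaN kept for continuous
            variables.append(_StVariable(name, vtype, None, None, np.asarray(pool)))
            continue

        X = _feature_matrix(df, meta, visit_order[:j], levels, medians)
        tree_seed = child_seed(seed, "st-tree", name)
        if vtype == "categorical":
            tree = DecisionTreeClassifier(random_state=tree_seed, **controls)
            fit_X, fit_y = X, target
        else:
            tree = DecisionTreeRegressor(random_state=tree_seed, **controls)
            if not obs_mask.any():
                # fully missing continuous column: treat as constant-missing
                variables.append(
                    _StVariable(name, vtype, None, None, np.array([np.nan]))
                )
                continue
            fit_X, fit_y = X[obs_mask], target[obs_mask]
        tree.fit(fit_X, fit_y)
        # donor pools: training values reaching each leaf.  For continuous
        # columns with missing values, rows where the value is missing keep a
        # NaN donor so the missingness rate is reproduced conditionally.
        leaves_all = tree.apply(X)
        donors: dict[int, np.ndarray] = {}
        donor_vals = target if vtype == "categorical" else vals
        for leaf in np.unique(leaves_all):
            donors[int(leaf)] = donor_vals[leaves_all == leaf]
        variables.append(_StVariable(name, vtype, tree, donors, None))

    return SequentialTreesGenerator(
        generator_id="st",
        schema=list(train.meta),
        fit_seed=seed,
        visit_order=visit_order,
        variables=variables,
        levels=levels,
        medians=medians,
    )


def _isna(v: object) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v))


# ---------------------------------------------------------------------------
# Chow-Liu Bayesian network


@dataclass
class _BnNode:
    name: str
    vtype: str
    parent: str | None
    levels: list[str] | None  # categorical levels (incl. missing)
    bin_edges: np.ndarray | None  # continuous bin edges
    bin_ranges: list[tuple[float, float]] | None  # per-bin (lo, hi) in training
    has_missing_bin: bool
    cpt: np.ndarray  # root: (n_codes,), child: (n_parent_codes, n_codes)


@dataclass
class BayesianNetworkGenerator:
    generator_id: str
    schema: list[VariableMeta]
    fit_seed: int
    order: list[str]  # ancestral order
    nodes: dict[str, _BnNode]
    edges: list[tuple[str, str]]  # (parent, child)

    def sample(self, n_rows: int, seed: int) -> pd.DataFrame:
        rng = np.random.default_rng(seed)
        codes: dict[str, np.ndarray] = {}
        for name in self.order:
            node = self.nodes[name]
            k = node.cpt.shape[-1]
            if node.parent is None:
                codes[name] = rng.choice(k, size=n_rows, p=node.cpt)
            else:
                parent_codes = codes[node.parent]
                out = np.empty(n_rows, dtype=np.int64)
                for pc in np.unique(parent_codes):
                    idx = np.where(parent_codes == pc)[0]
                    out[idx] = rng.choice(k, size=idx.size, p=node.cpt[pc])
                codes[name] = out
        frame = pd.DataFrame(index=range(n_rows))
        for m in self.schema:
            node = self.nodes[m.name]
            c = codes[m.name]
            if node.vtype == "categorical":
                vals = np.array(
                    [node.levels[i] for i in c], dtype=object
                )
                col = pd.Series(vals, dtype=object)
                col = col.where(col != _MISSING, np.nan)
            else:
                n_bins = len(node.bin_ranges)
                vals = np.full(n_rows, np.nan)
                for b in range(n_bins):
                    idx = np.where(c == b)[0]
                    if idx.size:
                        lo, hi = node.bin_ranges[b]
                        vals[idx] = rng.uniform(lo, hi, size=idx.size) if hi > lo else lo
                # codes beyond n_bins are the missing bin -> stay NaN
                col = pd.Series(vals, dtype=float)
            frame[m.name] = col
        return frame[[m.name for m in self.schema]]


def fit_bayesian_network(
    train: Cohort, seed: int = 0, max_bins: int = 8, alpha: float = 0.5
) -> BayesianNetworkGenerator:
    """Fit the Chow-Liu tree Bayesian network synthesiser."""
    if train.n < 1:
        raise ValueError("empty training table")
    df = train.records
    meta = {m.name: m for m in train.meta}
    names = list(df.columns)

    codes: dict[str, np.ndarray] = {}
    node_proto: dict[str, dict] = {}
    for c in names:
        if meta[c].vtype == "categorical":
            levels = _cat_levels(df[c])
            codes[c] = _encode_categorical(df[c], levels)
            node_proto[c] = dict(
                vtype="categorical", levels=levels, bin_edges=None,
                bin_ranges=None, has_missing_bin=_MISSING in levels,
                n_codes=len(levels),
            )
        else:
            vals = pd.to_numeric(df[c], errors="coerce").values.astype(float)
            obs = vals[~np.isnan(vals)]
            if obs.size == 0:
                obs = np.array([0.0])
            qs = np.linspace(0, 1, max_bins + 1)
            edges = np.unique(np.quantile(obs, qs))
            n_bins = max(len(edges) - 1, 1)
            binned = np.clip(np.searchsorted(edges, obs, side="right") - 1, 0, n_bins - 1)
            code = np.full(len(vals), n_bins, dtype=np.int64)  # missing bin
            code[~np.isnan(vals)] = binned
            has_missing = bool(np.isnan(vals).any())
            ranges = []
            for b in range(n_bins):
                in_bin = obs[binned == b]
                if in_bin.size:
                    ranges.append((float(in_bin.min()), float(in_bin.max())))
                else:
                    ranges.append((float(edges[b]), float(edges[min(b + 1, len(edges) - 1)])))
            codes[c] = code
            node_proto[c] = dict(
                vtype="continuous", levels=None, bin_edges=edges,
                bin_ranges=ranges, has_missing_bin=has_missing,
                n_codes=n_bins + (1 if has_missing else 0),
            )
            if not has_missing:
                codes[c] = np.clip(code, 0, n_bins - 1)

    # Chow-Liu: maximum spanning tree on pairwise MI
    p = len(names)
    mi = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            mi[i, j] = mutual_info_score(codes[names[i]], codes[names[j]])
    parent: dict[str, str | None] = {names[0]: None}
    edges_out: list[tuple[str, str]] = []
    if p > 1:
        # minimum spanning tree of -MI == maximum spanning tree of MI; offset
        # keeps weights strictly negative so zero-MI edges are not dropped.
        w = -(mi + 1e-9)
        mst = minimum_spanning_tree(csr_matrix(np.triu(w, 1))).toarray()
        adj: dict[int, list[int]] = {i: [] for i in range(p)}
        for i in range(p):
            for j in range(p):
                if mst[i, j] != 0:
                    adj[i].append(j)
                    adj[j].append(i)
        # BFS from node 0 to orient the tree into a DAG
        seen = {0}
        queue = [0]
        while queue:
            u = queue.pop(0)
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    parent[names[v]] = names[u]
                    edges_out.append((names[u], names[v]))
                    queue.append(v)
        for i in range(p):  # disconnected pieces become roots
            parent.setdefault(names[i], None)

    # ancestral order: parents before children
    order: list[str] = []
    remaining = set(names)
    while remaining:
        for c in names:
            if c in remaining and (parent.get(c) is None or parent[c] in order):
                order.append(c)
                remaining.discard(c)

    nodes: dict[str, _BnNode] = {}
    for c in names:
        proto = node_proto[c]
        k = proto["n_codes"]
        par = parent.get(c)
        if par is None:
            counts = np.bincount(codes[c], minlength=k).astype(float) + alpha
            cpt = counts / counts.sum()
        else:
            kp = node_proto[par]["n_codes"]
            counts = np.full((kp, k), alpha, dtype=float)
            np.add.at(counts, (codes[par], codes[c]), 1.0)
            cpt = counts / counts.sum(axis=1, keepdims=True)
        nodes[c] = _BnNode(
            name=c, vtype=proto["vtype"], parent=par, levels=proto["levels"],
            bin_edges=proto["bin_edges"], bin_ranges=proto["bin_ranges"],
            has_missing_bin=proto["has_missing_bin"], cpt=cpt,
        )

    return BayesianNetworkGenerator(
        generator_id="bn",
        schema=list(train.meta),
        fit_seed=seed,
        order=order,
        nodes=nodes,
        edges=edges_out,
    )


# ---------------------------------------------------------------------------
# baselines


@dataclass
class IndependentMarginalsGenerator:
    generator_id: str
    schema: list[VariableMeta]
    fit_seed: int
    columns: dict[str, np.ndarray]  # training values per column, NaN included

    def sample(self, n_rows: int, seed: int) -> pd.DataFrame:
        rng = np.random.default_rng(seed)
        frame = pd.DataFrame(index=range(n_rows))
        for m in self.schema:
            pool = self.columns[m.name]
            vals = rng.choice(pool, size=n_rows, replace=True)
            if m.vtype == "categorical":
                frame[m.name] = pd.Series(vals, dtype=object)
            else:
                frame[m.name] = pd.Series(vals.astype(float), dtype=float)
        return frame


def fit_independent_marginals(train: Cohort, seed: int = 0) -> IndependentMarginalsGenerator:
    """Bootstrap each column independently; the joint structure is destroyed.

    Missing cells stay in the per-column donor pools, so the synthetic
    missingness rate matches training in expectation.
    """
    if train.n < 1:
        raise ValueError("empty training table")
    cols = {}
    for m in train.meta:
        if m.vtype == "categorical":
            cols[m.name] = np.array(
                [np.nan if _isna(v) else str(v) for v in train.records[m.name].values],
                dtype=object,
            )
        else:
            cols[m.name] = pd.to_numeric(train.records[m.name], errors="coerce").values.astype(float)
    return IndependentMarginalsGenerator(
        generator_id="independent", schema=list(train.meta), fit_seed=seed, columns=cols
    )


@dataclass
class CopyGenerator:
    """Row bootstrap of the training table — a privacy worst case.

    Intended for test harnesses and calibration of the membership attack;
    it deliberately performs no modelling.
    """

    generator_id: str
    schema: list[VariableMeta]
    fit_seed: int
    table: pd.DataFrame

    def sample(self, n_rows: int, seed: int) -> pd.DataFrame:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(self.table), size=n_rows)
        return self.table.iloc[idx].reset_index(drop=True)


def fit_copy(train: Cohort, seed: int = 0) -> CopyGenerator:
    if train.n < 1:
        raise ValueError("empty training table")
    return CopyGenerator(
        generator_id="copy", schema=list(train.meta), fit_seed=seed,
        table=train.records.copy(),
    )


# ---------------------------------------------------------------------------
# registry + ensemble generation

GENERATOR_REGISTRY: dict[str, Callable[..., FittedGenerator]] = {
    "st": fit_sequential_trees,
    "bn": fit_bayesian_network,
    "independent": fit_independent_marginals,
    "copy": fit_copy,
}


def register_generator(name: str, fit_fn: Callable[..., FittedGenerator]) -> None:
    """Register a plugin generator: ``fit_fn(train, seed=...) -> fitted``.

    The fitted object must expose ``generator_id``, ``schema`` and
    ``sample(n_rows, seed) -> DataFrame`` with the training schema.
    """
    GENERATOR_REGISTRY[name] = fit_fn


def get_generator(name: str) -> Callable[..., FittedGenerator]:
    try:
        return GENERATOR_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown generator {name!r}; registered: {sorted(GENERATOR_REGISTRY)}"
        ) from None


def generate(
    fitted: FittedGenerator,
    n_rows: int,
    n_replicates: int = 10,
    seed: int = 0,
    dataset_id: str | None = None,
) -> SyntheticEnsemble:
    """Draw ``n_replicates`` independent synthetic cohorts of ``n_rows`` each.

    Each replicate uses its own child seed derived from ``seed``, so the
    ensemble is reproducible as a whole while replicates differ.
    """
    if n_rows <= 0:
        raise ValueError("n_rows must be positive")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    dataset_id = dataset_id or "synthetic"
    replicates = []
    for r in range(n_replicates):
        rep_seed = child_seed(seed, "generate", fitted.generator_id, r)
        df = fitted.sample(n_rows, rep_seed)
        replicates.append(
            Cohort(records=df, meta=list(fitted.schema), dataset_id=f"{dataset_id}/rep{r}")
        )
    return SyntheticEnsemble(
        replicates=replicates,
        generator_id=fitted.generator_id,
        dataset_id=dataset_id,
        generation_seed=seed,
    )
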