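"""Pairwise normalized mutual information between cohort variables.

A dataset diagnostic: how much of a core variable's information is carried
by other variables, grouped into core-to-core and core-to-adjunct pairs.
Continuous variables are discretised into equal-frequency bins (default
10); NMI(X, Y) = I(X; Y) / sqrt(H(X) H(Y)) from the empirical joint over
pairwise-complete observations, so values lie in [0, 1] with 1 for a
deterministic bijection and 0 for independence (asymptotically).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import entropy
from sklearn.metrics import mutual_info_score

from .cohort import Cohort

__all__ = ["NmiReport", "pairwise_nmi", "nmi_pair"]


@dataclass
class NmiReport:
    """Long-format pairwise NMI table with a core/adjunct group label."""

    table: pd.DataFrame  # columns: var_i, var_j, group, nmi

    def value(self, a: str, b: str) -> float:
        t = self.table
        row = t[((t.var_i == a) & (t.var_j == b)) | ((t.var_i == b) & (t.var_j == a))]
        if row.empty:
            raise KeyError((a, b))
        return float(row.nmi.iloc[0])


def _discretize_column(col: pd.Series, vtype: str, n_bins: int) -> pd.Series:
    if vtype == "categorical":
        return col.astype(object).astype(str).where(col.notna(), np.nan)
    v = pd.to_numeric(col, errors="coerce")
    if v.dropna().nunique() <= 1:
        return pd.Series(np.where(v.notna(), "b0", np.nan), index=col.index, dtype=object)
    binned = pd.qcut(v, q=n_bins, duplicates="drop", labels=False)
    return binned.astype(object).where(binned.notna(), np.nan)


def nmi_pair(x: pd.Series, y: pd.Series) -> float:
    """NMI of two discrete series over pairwise-complete observations."""
    keep = x.notna() & y.notna()
    if keep.sum() == 0:
        return 0.0
    xv = x[keep].astype(str)
    yv = y[keep].astype(str)
    hx = entropy(xv.value_counts(normalize=True).to_numpy())
    hy = entropy(yv.value_counts(normalize=True).to_numpy())
    if hx <= 0 or hy <= 0:
        warnings.warn("constant variable in NMI pair; NMI defined as 0", stacklevel=2)
        return 0.0
    mi = mutual_info_score(xv, yv)
    return float(np.clip(mi / np.sqrt(hx * hy), 0.0, 1.0))


def pairwise_nmi(cohort: Cohort, n_bins: int = 10) -> NmiReport:
    """All core-to-core and core-to-adjunct NMI pairs of a cohort."""
    if len(cohort.meta) < 2:
        raise ValueError("need at least two variables")
    disc = {
        m.name: _discretize_column(cohort.records[m.name], m.vtype, n_bins)
        for m in cohort.meta
    }
    core = cohort.core_predictor_names
    adjunct = cohort.adjunct_names
    rows = []
    for i, a in enumerate(core):
        for b in core[i + 1 :]:
            rows.append((a, b, "core_core", nmi_pair(disc[a], disc[b])))
        for b in adjunct:
            rows.append((a, b, "core_adjunct", nmi_pair(disc[a], disc[b])))
    return NmiReport(table=pd.DataFrame(rows, columns=["var_i", "var_j", "group", "nmi"]))
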