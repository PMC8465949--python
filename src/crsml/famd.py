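"""Factor analysis of mixed data (FAMD): joint projection of continuous and
categorical variables.

Continuous (interval and ordinal) columns are centered and scaled to unit
variance, exactly as in a standardized PCA. Each categorical level's 0/1
indicator column is divided by the square root of the level proportion and
centered, which reproduces multiple correspondence analysis for an
all-categorical table. The combined matrix is decomposed by SVD; the
eigenvalue of dimension k is the squared singular value divided by the row
count, so the classical Kaiser rule (retain eigenvalues > 1, i.e.
dimensions explaining more than one variable's worth of variance) is well
defined. Total inertia equals (number of continuous columns) + (total
category levels - number of categorical variables).

Patient-occasion scores on the retained dimensions feed the occasion-
separation tests, and per-variable contribution percentages (summing to 100
within each dimension, indicator columns aggregated to their parent
variable) identify the projection-relevant variables against the uniform-
contribution threshold 100/d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import Schema

__all__ = ["FamdModel", "famd_fit", "dimension_separation", "top_contributors"]


@dataclass
class FamdModel:
    eigenvalues: np.ndarray            # all dimensions, descending
    explained_variance_pct: np.ndarray
    scores: pd.DataFrame               # rows x retained dims ("dim1", ...)
    contributions: pd.DataFrame        # variables x retained dims, percent
    n_retained: int
    n_variables: int                   # original variables entering the fit
    dropped: tuple = ()


def _design_blocks(table: pd.DataFrame, schema: Schema):
    """Split a complete table into standardized continuous and weighted
    indicator blocks; returns (matrix, column variable names, dropped)."""
    cols = []
    names = []
    dropped = []
    n = len(table)
    variables = [v for v in schema if v.name in table.columns]
    for var in variables:
        if table[var.name].isna().any():
            raise ValueError(f"missing values in {var.name}; impute first")
        if var.is_numeric:
            raw = table[var.name].to_numpy(float)
            sd = raw.std()  # population scaling keeps inertia = column count
            if sd == 0:
                dropped.append(var.name)
                continue
            cols.append((raw - raw.mean()) / sd)
            names.append(var.name)
        else:
            raw = table[var.name].to_numpy()
            levels = np.unique(raw)
            if levels.size < 2:
                dropped.append(var.name)
                continue
            for lv in levels:
                ind = (raw == lv).astype(float)
                prop = ind.mean()
                z = ind / np.sqrt(prop)
                cols.append(z - z.mean())
                names.append(var.name)
    if dropped:
        warnings.warn(f"dropped constant variables: {dropped}", stacklevel=3)
    if not cols:
        raise ValueError("no usable variables")
    return np.column_stack(cols), names, tuple(dropped)


def famd_fit(table: pd.DataFrame, schema: Schema) -> FamdModel:
    """Fit the mixed-data projection on a complete cohort/design table.

    ``table`` may carry ``patient_id``/``occasion`` columns; only schema
    variables enter the decomposition. Ordinal variables are treated as
    continuous. Constant columns are dropped with a warning; an empty
    table is an error.
    """
    if len(table) == 0:
        raise ValueError("empty table")
    mat, col_vars, dropped = _design_blocks(table, schema)
    n = mat.shape[0]

    u, s, vt = np.linalg.svd(mat, full_matrices=False)
    # Deterministic sign: first nonzero loading of each dimension positive.
    for k in range(s.size):
        row = vt[k]
        nz = np.flatnonzero(np.abs(row) > 1e-12)
        if nz.size and row[nz[0]] < 0:
            vt[k] = -row
            u[:, k] = -u[:, k]

    eig = s**2 / n
    keep = eig > 1.0
    n_ret = max(int(keep.sum()), 1)  # always expose at least one dimension
    total_inertia = eig.sum()
    explained = eig / total_inertia * 100.0

    scores = pd.DataFrame(
        u[:, :n_ret] * s[:n_ret],
        index=table.index,
        columns=[f"dim{k + 1}" for k in range(n_ret)],
    )
    contrib_cols = vt[:n_ret] ** 2 * 100.0  # per column, sums to 100 per dim
    var_names = sorted(set(col_vars), key=col_vars.index)
    contrib = pd.DataFrame(0.0, index=var_names,
                           columns=[f"dim{k + 1}" for k in range(n_ret)])
    for j, vname in enumerate(col_vars):
        contrib.loc[vname] += contrib_cols[:, j]

    n_vars = len(var_names)
    return FamdModel(eigenvalues=eig, explained_variance_pct=explained,
                     scores=scores, contributions=contrib,
                     n_retained=n_ret, n_variables=n_vars, dropped=dropped)


def dimension_separation(model: FamdModel, labels, alpha: float = 0.05
                         ) -> pd.DataFrame:
    """Mann-Whitney U test of group separation per retained dimension.

    ``labels`` is a two-group vector aligned with the score rows (e.g. the
    occasion). Returns a frame with U statistic, p-value and a significance
    flag at ``alpha``.
    """
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if groups.size != 2:
        raise ValueError(f"need exactly two groups, got {groups.size}")
    m0 = labels == groups[0]
    m1 = labels == groups[1]
    if not m0.any() or not m1.any():
        raise ValueError("one group is empty")
    rows = []
    for col in model.scores.columns:
        a = model.scores.loc[m0, col].to_numpy()
        b = model.scores.loc[m1, col].to_numpy()
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"dimension": col, "u_statistic": float(res.statistic),
                     "p_value": float(res.pvalue),
                     "significant": bool(res.pvalue < alpha)})
    return pd.DataFrame(rows).set_index("dimension")


def top_contributors(model: FamdModel, dim: int) -> list[str]:
    """Variables whose contribution to dimension ``dim`` (1-based) exceeds
    the uniform expectation 100/d."""
    col = f"dim{dim}"
    if col not in model.contributions.columns:
        raise ValueError(f"dimension {dim} not retained")
    threshold = 100.0 / model.n_variables
    series = model.contributions[col]
    return list(series.index[series > threshold])
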