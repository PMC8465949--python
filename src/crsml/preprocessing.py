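"""Data preprocessing: distribution transforms, outlier removal, imputation
and one-hot recoding.

The pipeline mirrors standard clinical-tabular practice: (i) each interval
variable is screened for a variance-stabilizing transform along Tukey's
ladder of powers, chosen by Kolmogorov-Smirnov distance to normality;
(ii) gross outliers are removed per variable by iterated two-sided Grubbs
tests and set missing; (iii) missing values are imputed separately within
each of the four variable-category blocks, by per-column medians or by an
iterated random-forest scheme; (iv) binary and nominal variables are
one-hot recoded with missing values assigned to the zero condition, after
which the table is complete.

Ordinal variables (bounded instrument scores) are exempt from
transformation and Grubbs masking: their supports are bounded by design and
extreme grades are genuine findings, not measurement errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import OCCASIONS, Schema, default_schema

__all__ = [
    "TransformChoice",
    "tukey_select",
    "ladder_transform",
    "grubbs_iterative",
    "grubbs_critical_value",
    "impute_block",
    "encode_onehot",
    "preprocess_cohort",
    "PreprocessReport",
    "TUKEY_LADDER",
]

# Candidate exponents of the power ladder; 0 denotes the logarithm.
TUKEY_LADDER = (1.0, -1.0, -0.5, 0.0, 0.5, 2.0)


@dataclass(frozen=True)
class TransformChoice:
    """Selected ladder transform for one variable.

    ``lam`` is the ladder exponent (0 = log); ``shift`` is the additive
    offset applied before log / negative powers to ensure positivity;
    ``constant`` flags degenerate (zero-variance) input, for which the
    identity is returned.
    """

    lam: float
    shift: float = 0.0
    constant: bool = False


def ladder_transform(values, lam: float, shift: float = 0.0) -> np.ndarray:
    """Apply one rung of the power ladder, order-preserving.

    Positive powers are sign-preserving, sign(x)|x|**lam; lam = 0 maps to
    log(x + shift); negative powers map to -(x + shift)**lam so that the
    transform remains monotone increasing (these two require the shifted
    values to be strictly positive).
    """
    x = np.asarray(values, float) + shift
    if lam == 0.0:
        return np.log(x)
    if lam < 0:
        return -np.power(x, lam)
    return np.sign(x) * np.power(np.abs(x), lam)


def _ks_to_normal(z: np.ndarray) -> float:
    mu, sd = z.mean(), z.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return np.inf
    return stats.kstest(z, "norm", args=(mu, sd)).statistic


def tukey_select(values, candidates=TUKEY_LADDER) -> TransformChoice:
    """Choose the ladder exponent whose transform looks most normal.

    Candidates are compared by the Kolmogorov-Smirnov statistic against a
    normal with the transformed sample's own mean/SD; the identity wins
    ties. Log and negative powers require strictly positive input, so a
    shift of 1 - min(x) is applied when min(x) <= 0. Requires at least 8
    observed values; constant input returns the identity with a flag.
    """
    x = np.asarray(values, float)
    x = x[~np.isnan(x)]
    if x.size < 8:
        raise ValueError(f"need >= 8 non-missing values, got {x.size}")
    if np.ptp(x) == 0:
        return TransformChoice(lam=1.0, constant=True)
    shift = 1.0 - x.min() if x.min() <= 0 else 0.0

    best_lam, best_ks, best_shift = 1.0, _ks_to_normal(x), 0.0
    for lam in candidates:
        if lam == 1.0:
            continue
        s = shift if lam <= 0 else 0.0  # log / negative powers need positivity
        z = ladder_transform(x, lam, s)
        if not np.all(np.isfinite(z)):
            continue
        ks = _ks_to_normal(z)
        if ks < best_ks - 1e-12:
            best_lam, best_ks, best_shift = lam, ks, s
    return TransformChoice(lam=best_lam, shift=best_shift)


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value for a sample of size n."""
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_iterative(values, alpha: float = 0.05) -> np.ndarray:
    """Boolean mask of outliers found by iterated two-sided Grubbs tests.

    Each iteration compares G = max|x_i - mean| / sd against the critical
    value; the most extreme point is masked and the test repeats on the
    remainder until non-significant. Zero-variance input yields an empty
    mask. Positions of missing input values are never flagged.
    """
    x = np.asarray(values, float)
    mask = np.zeros(x.size, dtype=bool)
    active = ~np.isnan(x)
    if active.sum() < 3:
        raise ValueError("need >= 3 non-missing values")
    while active.sum() >= 3:
        sub = x[active]
        mean, sd = sub.mean(), sub.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(sub - mean)
        g = dev.max() / sd
        if g <= grubbs_critical_value(active.sum(), alpha):
            break
        idx_active = np.flatnonzero(active)
        worst = idx_active[np.argmax(dev)]
        mask[worst] = True
        active[worst] = False
    return mask


def _forest_impute_block(block: pd.DataFrame, numeric: list[str],
                         seed: int, n_trees: int, max_sweeps: int,
                         tol: float) -> pd.DataFrame:
    """Iterated random-forest imputation within one variable block."""
    from sklearn.ensemble import RandomForestRegressor

    out = block.copy()
    miss = {c: out[c].isna().to_numpy() for c in numeric if out[c].isna().any()}
    # Initialize with per-column medians, then refine column by column.
    for c in miss:
        out[c] = out[c].fillna(out[c].median())
    feature_cols = [c for c in block.columns if c in numeric or c == "_occ"]
    prev = {c: out.loc[miss[c], c].to_numpy(copy=True) for c in miss}
    for sweep in range(max_sweeps):
        max_change = 0.0
        for k, c in enumerate(miss):
            others = [f for f in feature_cols if f != c]
            model = RandomForestRegressor(n_estimators=n_trees,
                                          random_state=seed + 31 * k)
            obs = ~miss[c]
            model.fit(out.loc[obs, others], out.loc[obs, c])
            pred = model.predict(out.loc[miss[c], others])
            scale = max(float(out[c].std(ddof=0)), 1e-9)
            max_change = max(max_change,
                             float(np.max(np.abs(pred - prev[c]))) / scale)
            out.loc[miss[c], c] = pred
            prev[c] = pred
        if max_change < tol:
            break
    return out


def impute_block(table: pd.DataFrame, schema: Schema, category: str,
                 method: str = "forest", seed: int = 0, n_trees: int = 100,
                 max_sweeps: int = 10, tol: float = 1e-3) -> pd.DataFrame:
    """Fill missing cells of one variable-category block.

    ``method="median"`` uses the per-variable, per-occasion median (binary
    and nominal variables get the per-occasion mode). ``method="forest"``
    predicts each missing numeric cell from the other variables of the same
    block with an ensemble-of-trees regressor, iterated to convergence.
    A variable that is entirely missing is an error.
    """
    if category not in {v.category for v in schema}:
        raise ValueError(f"unknown category {category!r}")
    if method not in ("median", "forest"):
        raise ValueError(f"unknown imputation method {method!r}")
    block_vars = [v for v in schema.by_category(category) if v.name in table.columns]
    out = table.copy()
    for v in block_vars:
        if out[v.name].isna().all():
            raise ValueError(f"variable {v.name!r} is entirely missing")

    numeric = [v.name for v in block_vars if v.is_numeric]
    categorical = [v.name for v in block_vars if not v.is_numeric]

    # Categorical cells always take the per-occasion mode; numeric cells
    # take the median or the forest prediction.
    for occ in OCCASIONS:
        rows = out["occasion"] == occ
        if not rows.any():
            continue
        for c in categorical:
            col = out.loc[rows, c]
            if col.isna().any():
                mode = col.mode(dropna=True)
                fill = mode.iloc[0] if not mode.empty else 0
                out.loc[rows & out[c].isna(), c] = fill

    if method == "median":
        for occ in OCCASIONS:
            rows = out["occasion"] == occ
            for c in numeric:
                med = out.loc[rows, c].median()
                out.loc[rows & out[c].isna(), c] = med
    else:
        sub = out[numeric].copy()
        sub["_occ"] = (out["occasion"] == "post").astype(float)
        sub = _forest_impute_block(sub, numeric, seed, n_trees, max_sweeps, tol)
        for v in block_vars:
            if v.name in numeric:
                vals = sub[v.name]
                if v.scale == "ordinal":
                    lo, hi = v.support
                    vals = np.clip(np.rint(vals), lo, hi)
                out[v.name] = np.asarray(vals, float)
    return out


def encode_onehot(table: pd.DataFrame, schema: Schema) -> pd.DataFrame:
    """Numeric design table: one-hot recode binary/nominal variables.

    Binary variables become a single 0/1 column; each nominal level becomes
    its own 0/1 column named ``var=level``; missing binary/nominal values
    are assigned to the zero condition in all derived columns.
    Interval/ordinal columns pass through unchanged. A nominal value not
    listed in the schema support is an error.
    """
    cols: dict[str, np.ndarray] = {}
    for key in ("patient_id", "occasion"):
        if key in table.columns:
            cols[key] = table[key].to_numpy()
    for var in schema:
        if var.name not in table.columns:
            continue
        col = table[var.name]
        if var.is_numeric:
            cols[var.name] = col.to_numpy(float)
        elif var.scale == "binary":
            vals = col.to_numpy(object)
            out = np.zeros(len(col))
            for i, x in enumerate(vals):
                if pd.isna(x):
                    continue
                if x not in var.support and float(x) not in var.support:
                    raise ValueError(f"unseen level {x!r} in binary {var.name}")
                out[i] = float(x) == float(max(var.support))
            cols[var.name] = out
        else:  # nominal
            observed = set(col.dropna().unique())
            unseen = observed - set(var.support)
            if unseen:
                raise ValueError(f"unseen levels {sorted(unseen)} in nominal {var.name}")
            for level in var.support:
                cols[f"{var.name}={level}"] = (col == level).astype(float).to_numpy()
    return pd.DataFrame(cols, index=table.index)


@dataclass
class PreprocessReport:
    """What the preprocessing pipeline did, per variable."""

    transforms: dict = field(default_factory=dict)       # name -> TransformChoice
    outliers: list = field(default_factory=list)         # (patient, occ, name, value)
    imputation_method: dict = field(default_factory=dict)  # category -> method
    missing_before: dict = field(default_factory=dict)
    missing_after: dict = field(default_factory=dict)


def preprocess_cohort(table: pd.DataFrame, schema: Schema | None = None,
                      impute: str = "forest", alpha: float = 0.05,
                      transform: bool = True, seed: int = 0,
                      ) -> tuple[pd.DataFrame, PreprocessReport]:
    """Run the full pipeline: transform selection, iterated Grubbs outlier
    masking, per-block imputation, one-hot recoding.

    Returns the complete numeric design table (no missing cells) and a
    report of every decision taken. Outlier screening pools both occasions
    per variable; ordinal variables are exempt from transformation and
    outlier masking.
    """
    schema = schema or default_schema()
    report = PreprocessReport()
    out = table.copy()
    report.missing_before = {v.name: int(out[v.name].isna().sum()) for v in schema}

    interval = [v for v in schema if v.scale == "interval"]
    for v in interval:
        x = out[v.name].to_numpy(float)
        if np.isnan(x).all() or (~np.isnan(x)).sum() < 8:
            continue
        choice = tukey_select(x)
        report.transforms[v.name] = choice
        if transform and not choice.constant and choice.lam != 1.0:
            obs = ~np.isnan(x)
            x[obs] = ladder_transform(x[obs], choice.lam, choice.shift)
            out[v.name] = x

    for v in interval:
        x = out[v.name].to_numpy(float)
        if (~np.isnan(x)).sum() < 3:
            continue
        mask = grubbs_iterative(x, alpha=alpha)
        for i in np.flatnonzero(mask):
            report.outliers.append((out["patient_id"].iloc[i],
                                    out["occasion"].iloc[i], v.name, float(x[i])))
            x[i] = np.nan
        out[v.name] = x

    for category in sorted({v.category for v in schema}):
        out = impute_block(out, schema, category, method=impute, seed=seed)
        report.imputation_method[category] = impute

    report.missing_after = {v.name: int(out[v.name].isna().sum()) for v in schema}
    design = encode_onehot(out, schema)
    return design, report
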