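"""Post-selection clinical interpretation of surgery-associated changes.

Once the informative variables are selected, each patient's pre-to-post
change per variable is coded as +1 (improved), 0 (unchanged) or -1
(worsened), after standardizing the sign of improvement across variables
(e.g. a falling polyp score and a rising olfactory self-rating both code
+1). Row sums of this sign matrix classify patients into overall improved,
no consistent effect, or predominantly worsened; column-pair chi-squared
tests quantify the agreement of change directions between variables;
instrument cutoffs count symptom-free patients per occasion; and Spearman
correlations of the per-patient deltas (and of the raw post-surgery
values) check that the selected variables are not redundant.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import (
    LUND_KENNEDY_NO_FINDINGS_CUTOFF,
    SNOT_GENERAL_CUTOFF,
    SNOT_PRIMARY_CUTOFF,
    SNOT_SECONDARY_CUTOFF,
    SNOT_TOTAL_CUTOFF,
    Schema,
    olfactory_diagnosis,
    perceptible_improvement,
)

__all__ = [
    "sign_matrix",
    "agreement_chi2",
    "patient_outcomes",
    "symptom_free_counts",
    "delta_correlations",
]


def _paired_wide(table: pd.DataFrame, variables) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(baseline, post) frames indexed by patient, completers only."""
    base = table[table["occasion"] == "baseline"].set_index("patient_id")
    post = table[table["occasion"] == "post"].set_index("patient_id")
    common = base.index.intersection(post.index)
    return base.loc[common, list(variables)], post.loc[common, list(variables)]


def sign_matrix(table: pd.DataFrame, selected, schema: Schema) -> pd.DataFrame:
    """Patients x selected-variables change codes in {-1, 0, +1}.

    +1 means the change went in the variable's direction of improvement,
    -1 the opposite, 0 an exact tie. Variables whose schema direction is
    "none" carry no outcome meaning and are excluded with a warning.
    """
    usable, skipped = [], []
    for name in selected:
        if schema[name].improves_when == "none":
            skipped.append(name)
        else:
            usable.append(name)
    if skipped:
        warnings.warn(f"excluded direction-free variables: {skipped}", stacklevel=2)
    if not usable:
        raise ValueError("no variables with a defined improvement direction")
    base, post = _paired_wide(table, usable)
    out = {}
    for name in usable:
        raw = np.sign(post[name].to_numpy(float) - base[name].to_numpy(float))
        if schema[name].improves_when == "decreases":
            raw = -raw
        out[name] = raw.astype(int)
    return pd.DataFrame(out, index=base.index)


def agreement_chi2(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise chi-squared tests of change-direction agreement.

    For every variable pair the cross-table of sign codes is tested
    (Pearson chi-squared, unadjusted p-values). Pairs where either column
    shows a single sign are flagged untestable, as are tables that
    degenerate below 2 x 2 — with only two patients no association test
    has any degrees of freedom to work with.
    """
    cols = list(matrix.columns)
    if len(cols) < 2:
        raise ValueError("need at least two columns")
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            ct = pd.crosstab(matrix[a], matrix[b])
            if ct.shape[0] < 2 or ct.shape[1] < 2 or len(matrix) < 3:
                rows.append({"var_a": a, "var_b": b, "chi2": np.nan,
                             "p_value": np.nan, "untestable": True})
                continue
            chi2, p, _, _ = stats.chi2_contingency(ct.to_numpy(), correction=False)
            rows.append({"var_a": a, "var_b": b, "chi2": float(chi2),
                         "p_value": float(p), "untestable": False})
    return pd.DataFrame(rows)


def patient_outcomes(matrix: pd.DataFrame) -> dict:
    """Patient-level overall outcome from the sign-matrix row sums.

    Positive row sum: improvement predominates; zero: the changes balance
    or nothing changed (no consistent effect); negative: worsening
    predominates.
    """
    row_sums = matrix.sum(axis=1)
    return {
        "improved": int((row_sums > 0).sum()),
        "no_consistent_effect": int((row_sums == 0).sum()),
        "worsened": int((row_sums < 0).sum()),
        "row_sums": row_sums,
    }


def _chi2_counts(pre_counts, post_counts) -> tuple[float, float]:
    tab = np.array([pre_counts, post_counts], float)
    tab = tab[:, tab.sum(axis=0) > 0]
    if tab.shape[1] < 2:
        return np.nan, np.nan
    chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
    return float(chi2), float(p)


def symptom_free_counts(table: pd.DataFrame, schema: Schema) -> dict:
    """Occasion-wise symptom-freedom tallies at the instrument cutoffs.

    Counts per occasion: normal polyp score (Lildholdt = 0), no relevant
    endoscopic findings (Lund-Kennedy < 2), SNOT-20 total < 12, primary
    nasal symptoms < 12, secondary nasal symptoms < 10.5, general quality
    of life < 14; the olfactory diagnosis tallies (anosmia / hyposmia /
    normosmia) and the count of perceptible TDI improvements (>= 5.5).
    Each criterion's pre/post counts are compared by Pearson chi-squared
    on the occasion x category table.
    """
    names = ["lildholdt", "lund_kennedy", "snot20_sum", "primary_nasal_symptoms",
             "secondary_nasal_symptoms", "general_life_quality", "tdi"]
    base, post = _paired_wide(table, [n for n in names if n in table.columns])
    n = len(base)
    out: dict = {"n_paired": n}

    criteria = {
        "lildholdt_normal": lambda f: f["lildholdt"] == 0,
        "lund_kennedy_no_findings":
            lambda f: f["lund_kennedy"] < LUND_KENNEDY_NO_FINDINGS_CUTOFF,
        "snot_total_free": lambda f: f["snot20_sum"] < SNOT_TOTAL_CUTOFF,
        "primary_nasal_free":
            lambda f: f["primary_nasal_symptoms"] < SNOT_PRIMARY_CUTOFF,
        "secondary_nasal_free":
            lambda f: f["secondary_nasal_symptoms"] < SNOT_SECONDARY_CUTOFF,
        "general_qol_free":
            lambda f: f["general_life_quality"] < SNOT_GENERAL_CUTOFF,
    }
    for key, crit in criteria.items():
        try:
            pre_k = int(crit(base).sum())
            post_k = int(crit(post).sum())
        except KeyError:
            continue
        chi2, p = _chi2_counts([pre_k, n - pre_k], [post_k, n - post_k])
        out[key] = {"baseline": pre_k, "post": post_k, "chi2": chi2, "p_value": p}

    if "tdi" in base.columns:
        cats = ("anosmia", "hyposmia", "normosmia")
        pre_diag = base["tdi"].map(olfactory_diagnosis)
        post_diag = post["tdi"].map(olfactory_diagnosis)
        pre_counts = [int((pre_diag == c).sum()) for c in cats]
        post_counts = [int((post_diag == c).sum()) for c in cats]
        chi2, p = _chi2_counts(pre_counts, post_counts)
        out["tdi_diagnosis"] = {
            "baseline": dict(zip(cats, pre_counts)),
            "post": dict(zip(cats, post_counts)),
            "chi2": chi2, "p_value": p,
        }
        perceptible = [perceptible_improvement(a, b)
                       for a, b in zip(base["tdi"], post["tdi"])]
        out["tdi_perceptible_improvement"] = int(np.sum(perceptible))
        out["tdi_improved"] = int((post["tdi"] > base["tdi"]).sum())
        out["tdi_worsened"] = int((post["tdi"] < base["tdi"]).sum())
    return out


def delta_correlations(table: pd.DataFrame, selected) -> dict:
    """Spearman correlations of changes and of raw post-surgery values.

    Returns matrices ``rho`` and ``p`` in which the lower triangle holds
    the correlations of per-patient deltas (post - baseline) and the upper
    triangle the correlations of raw post-surgery values; the diagonal is
    1. Variables with constant deltas are flagged and their entries left
    as NaN.
    """
    base, post = _paired_wide(table, selected)
    deltas = post - base
    k = len(selected)
    rho = pd.DataFrame(np.eye(k), index=selected, columns=selected)
    pval = pd.DataFrame(np.zeros((k, k)), index=selected, columns=selected)
    flagged = []
    for name in selected:
        if np.ptp(deltas[name].to_numpy(float)) == 0:
            flagged.append(name)
    for i, a in enumerate(selected):
        for j, b in enumerate(selected):
            if i == j:
                continue
            if i > j:  # lower triangle: deltas
                xa, xb = deltas[a], deltas[b]
                degenerate = a in flagged or b in flagged
            else:      # upper triangle: raw post values
                xa, xb = post[a], post[b]
                degenerate = (np.ptp(xa.to_numpy(float)) == 0
                              or np.ptp(xb.to_numpy(float)) == 0)
            if degenerate:
                rho.iloc[i, j] = np.nan
                pval.iloc[i, j] = np.nan
                continue
            res = stats.spearmanr(xa, xb)
            rho.iloc[i, j] = float(res.statistic)
            pval.iloc[i, j] = float(res.pvalue)
    return {"rho": rho, "p": pval, "constant_delta": flagged}
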