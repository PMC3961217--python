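"""qPCR relative quantification (2^-ddCt) and a simple gene-level
differential-expression stage.

The ddCt estimator assumes amplification efficiency exactly 2: with a
target and a reference gene measured in treated and control samples,

    dCt_cond  = Ct_target,cond - Ct_reference,cond
    ddCt      = dCt_treated - dCt_control
    expr      = 2 ** (-ddCt)

Technical replicates are averaged on the Ct scale before the deltas.

The DE stage is a deliberately simple gene-level Welch test with
Benjamini-Hochberg adjustment, operating on expression tables rather
than reads; it stands in for a full isoform-level RNA-seq model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["delta_delta_ct", "bh_qvalues", "call_de", "split_de"]


def bh_qvalues(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (step-up, across all tests)."""
    p = np.asarray(p_values, dtype=float)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q

_CELLS = [
    ("treated", "target"),
    ("treated", "reference"),
    ("control", "target"),
    ("control", "reference"),
]


def delta_delta_ct(measurements: pd.DataFrame) -> float:
    """Relative expression 2^-ddCt from a Ct table.

    ``measurements`` needs columns (condition, role, ct) with condition
    in {treated, control} and role in {target, reference}; technical
    replicates are averaged per cell of the 2x2 design. A missing cell is
    an error naming the cell.
    """
    df = measurements.copy()
    means = df.groupby(["condition", "role"], observed=True)["ct"].mean()
    for cell in _CELLS:
        if cell not in means.index:
            raise ValueError(f"missing Ct measurements for (condition={cell[0]}, role={cell[1]})")
    dct_treated = means[("treated", "target")] - means[("treated", "reference")]
    dct_control = means[("control", "target")] - means[("control", "reference")]
    ddct = dct_treated - dct_control
    return float(2.0 ** (-ddct))


def call_de(
    expr: pd.DataFrame,
    groups: pd.Series,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Two-group differential expression on a genes x samples matrix.

    Per gene: log2 fold change of treated vs control group means (on the
    log2 scale), a Welch two-sample t-test on log2 values, and BH
    adjustment across all tested genes. A gene is significant iff its
    q-value is strictly below ``q_threshold``. Genes with zero variance
    in both groups get p = 1 when the group means are equal and the
    smallest positive p otherwise.
    """
    groups = groups.reindex(expr.columns)
    if groups.isna().any():
        raise ValueError("every expression column needs a group label")
    levels = set(groups)
    if levels != {"treated", "control"}:
        raise ValueError(f"groups must be exactly {{treated, control}}, got {sorted(levels)}")
    t_cols = groups[groups == "treated"].index
    c_cols = groups[groups == "control"].index
    if len(t_cols) < 2 or len(c_cols) < 2:
        raise ValueError("need >= 2 replicates per group")
    if (expr.to_numpy() <= 0).any():
        raise ValueError("expression values must be positive (linear scale)")

    log2e = np.log2(expr.to_numpy(dtype=float))
    ti = [expr.columns.get_loc(c) for c in t_cols]
    ci = [expr.columns.get_loc(c) for c in c_cols]
    xt, xc = log2e[:, ti], log2e[:, ci]
    l2fc = xt.mean(axis=1) - xc.mean(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(xt, xc, axis=1, equal_var=False)
    # zero variance in both groups: the t statistic is undefined, so apply
    # the documented rule instead of whatever scipy emitted
    degenerate = (xt.var(axis=1) == 0) & (xc.var(axis=1) == 0)
    degenerate |= ~np.isfinite(p)
    if degenerate.any():
        equal_means = np.isclose(l2fc, 0.0)
        p = np.where(degenerate & equal_means, 1.0, p)
        p = np.where(degenerate & ~equal_means, np.finfo(float).tiny, p)

    q = bh_qvalues(p)
    return pd.DataFrame(
        {
            "gene": expr.index,
            "log2_fold_change": l2fc,
            "p_value": p,
            "q_value": q,
            "significant": q < q_threshold,
        }
    ).reset_index(drop=True)


def split_de(de: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition the significant genes by fold-change sign.

    Returns (up, down). Significant genes with a log2 fold change of
    exactly zero cannot occur (equal means are never significant), so the
    two lists partition the significant set.
    """
    sig = de.loc[de["significant"].astype(bool)]
    up = sig[sig["log2_fold_change"] > 0].reset_index(drop=True)
    down = sig[sig["log2_fold_change"] < 0].reset_index(drop=True)
    return up, down
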