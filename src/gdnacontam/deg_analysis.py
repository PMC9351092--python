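"""DEG detection and gDNA-correlation screening.

Filtering and testing follow the fixed recipe: add 0.01 to every FPKM, drop
genes below 0.02 (pre-offset) in at least 30% of a method's libraries, call a
gene differentially expressed by a two-sided pooled-variance Student t test on
log2 values (unadjusted p < 0.05) together with |log2 fold-change| > 1, then
partition DEGs by whether the gene's expression is Pearson-correlated with the
nominal spiked gDNA fraction (two-sided, Bonferroni-adjusted p < 0.05 over all
filtered genes).  "Correlated" DEGs are read as gDNA-driven false discoveries;
"Not Correlated" ones as noise-driven (or mixed).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix, MatrixStateError

CORRELATED = "Correlated"
NOT_CORRELATED = "NotCorrelated"

DEFAULT_OFFSET = 0.01
DEFAULT_MIN_FPKM = 0.02
DEFAULT_LOW_FRACTION = 0.30


def add_offset_and_filter(
    matrix: ExpressionMatrix,
    offset: float = DEFAULT_OFFSET,
    min_fpkm: float = DEFAULT_MIN_FPKM,
    max_low_fraction: float = DEFAULT_LOW_FRACTION,
) -> tuple[ExpressionMatrix, list[str]]:
    """Apply the pseudocount and drop weakly expressed genes.

    A gene is removed when its pre-offset FPKM is below *min_fpkm* in at least
    *max_low_fraction* of the matrix's libraries ("at least" is the inclusive
    reading of the 30% rule; callers filter each library-prep method's matrix
    separately).  Returns the offset matrix and the removed gene ids.
    """
    if matrix.offset_applied:
        raise MatrixStateError("offset already applied")
    low = (matrix.values < min_fpkm).mean(axis=1)
    removed = list(matrix.values.index[low >= max_low_fraction])
    kept = matrix.values.drop(index=removed) + offset
    return (
        ExpressionMatrix(
            values=kept,
            offset_applied=True,
            offset=offset,
            adjusted=matrix.adjusted,
            n_clipped=matrix.n_clipped,
        ),
        removed,
    )


def detect_degs(
    matrix: ExpressionMatrix,
    treatment: Sequence[str],
    control: Sequence[str],
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    log_scale: bool = True,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-gene Student t test plus fold-change call.

    The t test runs on log2 FPKM by default (``log_scale=False`` for linear);
    the fold change is log2(mean_treatment / mean_control) on the linear,
    offset-included values.  Both thresholds are strict inequalities.  Genes
    with zero variance in both groups get p = 1 when the group means are equal
    and p = 0 otherwise.
    """
    if not matrix.offset_applied:
        raise MatrixStateError("apply the offset/filter step before DEG testing")
    if len(treatment) < 2 or len(control) < 2:
        raise ValueError("need >= 2 libraries per group")
    treat = matrix.values[list(treatment)].to_numpy()
    ctrl = matrix.values[list(control)].to_numpy()
    t_in, c_in = (np.log2(treat), np.log2(ctrl)) if log_scale else (treat, ctrl)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant genes trigger scipy's precision-loss warning; their
        # p-values are patched below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(t_in, c_in, axis=1, equal_var=equal_var)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        equal_means = np.isclose(t_in.mean(axis=1), c_in.mean(axis=1))
        p[degenerate & equal_means] = 1.0
        p[degenerate & ~equal_means] = 0.0
    log2_fc = np.log2(treat.mean(axis=1) / ctrl.mean(axis=1))
    is_deg = (p < alpha) & (np.abs(log2_fc) > lfc_threshold)
    return pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "p_value": p,
            "log2_fold_change": log2_fc,
            "is_deg": is_deg,
        }
    ).set_index("gene_id", drop=False)


def correlate_with_gdna(
    matrix: ExpressionMatrix,
    dna_a: Mapping[str, float] | pd.Series,
    alpha: float = 0.05,
    log_scale: bool = True,
) -> pd.DataFrame:
    """Pearson correlation of each gene's expression with the spiked fraction.

    All replicate libraries with known DNA_a enter as separate points on the
    linear concentration scale; libraries with unknown DNA_a (NaN) are
    excluded.  Two-sided p-values come from the t transform of r and are
    Bonferroni-corrected over all genes of the (filtered) matrix.  Genes with
    constant expression have undefined r and are flagged, never correlated.
    """
    if not matrix.offset_applied:
        raise MatrixStateError("apply the offset/filter step before correlation")
    dna_a = pd.Series(dict(dna_a) if not isinstance(dna_a, pd.Series) else dna_a)
    dna_a = dna_a.reindex(matrix.library_ids).dropna()
    if len(dna_a) < 3:
        raise ValueError("need >= 3 libraries with known dna_a")
    x = dna_a.to_numpy(dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("dna_a is constant across libraries")
    values = matrix.values[list(dna_a.index)].to_numpy()
    y = np.log2(values) if log_scale else values
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean(axis=1, keepdims=True)
    sy = np.sqrt((yc**2).sum(axis=1))
    constant = sy == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (yc @ xc) / (np.sqrt((xc**2).sum()) * sy)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p_raw = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p_raw[np.isnan(t)] = np.nan  # constant genes
    p_raw[np.isinf(t)] = 0.0  # |r| = 1 exactly
    n_tested = len(matrix.gene_ids)
    p_bonf = np.minimum(1.0, p_raw * n_tested)
    correlated = p_bonf < alpha
    correlated[constant] = False
    return pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "pearson_r": np.where(constant, np.nan, r),
            "p_raw": p_raw,
            "p_bonferroni": p_bonf,
            "correlated": correlated,
            "constant_expression": constant,
        }
    ).set_index("gene_id", drop=False)


def classify_degs(
    degs: pd.DataFrame, correlations: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Label each DEG Correlated/NotCorrelated by the correlation screen.

    Returns the DEG table with a ``deg_class`` column ("NA" for non-DEGs) and
    summary counts.  A DEG absent from the correlation results is a
    consistency error.
    """
    missing = set(degs.loc[degs["is_deg"], "gene_id"]) - set(correlations["gene_id"])
    if missing:
        raise KeyError(
            f"DEGs missing from correlation results: {sorted(missing)[:5]}"
        )
    corr = correlations["correlated"].reindex(degs["gene_id"]).fillna(False)
    out = degs.copy()
    out["deg_class"] = np.where(
        out["is_deg"], np.where(corr.to_numpy(), CORRELATED, NOT_CORRELATED), "NA"
    )
    n_deg = int(out["is_deg"].sum())
    n_corr = int((out["deg_class"] == CORRELATED).sum())
    summary = {
        "n_deg": n_deg,
        "n_correlated": n_corr,
        "n_not_correlated": n_deg - n_corr,
        "fraction_correlated": (n_corr / n_deg) if n_deg else 0.0,
    }
    return out, summary
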