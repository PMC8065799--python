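"""TPM quantification, two-group differential expression, volcano
classification, Benjamini–Hochberg FDR and per-gene Z-score matrices.

Differential expression runs on log2(TPM + pseudocount) values with a Welch
two-sample t-test by default; a Wilcoxon rank-sum and a paired t-test are
available. Fold changes are always ratios of linear-scale group means with
the same pseudocount.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ExpressionMatrix, Scale

logger = logging.getLogger(__name__)

__all__ = [
    "compute_tpm",
    "differential_expression",
    "volcano_classify",
    "bh_fdr",
    "compute_zscores",
    "ZScoreMatrix",
]

DEG_COLUMNS = ("mean_a", "mean_b", "log2fc", "p_value", "q_value", "class")


def compute_tpm(counts: pd.DataFrame, gene_lengths: pd.Series) -> ExpressionMatrix:
    """Convert a gene x sample count matrix to TPM.

    ``TPM_gs = (counts_gs / length_g) / sum_g'(counts_g's / length_g') * 1e6``
    so each sample column sums to 1e6. Lengths are in bases.
    """
    missing = [g for g in counts.index if g not in gene_lengths.index]
    if missing:
        raise ValueError(f"genes without a length: {missing[:5]}")
    lengths = gene_lengths.reindex(counts.index).astype(float)
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][:5].tolist()
        raise ValueError(f"non-positive gene lengths: {bad}")
    arr = counts.to_numpy(float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    rate = arr / lengths.to_numpy()[:, None]
    colsum = rate.sum(axis=0)
    zero = np.flatnonzero(colsum == 0)
    if zero.size:
        raise ValueError(f"sample {counts.columns[zero[0]]!r} has zero total counts")
    tpm = rate / colsum * 1e6
    return ExpressionMatrix(pd.DataFrame(tpm, index=counts.index,
                                         columns=counts.columns), Scale.LINEAR_TPM)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} p_(j) * m / j`` over p sorted ascending, capped at
    1, returned in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def volcano_classify(
    deg: pd.DataFrame,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    inclusive: bool = True,
) -> pd.DataFrame:
    """Assign each gene a volcano class: ``up``, ``down`` or ``ns``.

    With ``inclusive`` (default) a gene is up when log2fc >= fc_threshold and
    p <= p_threshold; with ``inclusive=False`` the comparisons are strict.
    Down is symmetric with ``-fc_threshold``. Returns a copy with the
    ``class`` column replaced.
    """
    if fc_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be positive")
    lfc = deg["log2fc"].to_numpy(float)
    p = deg["p_value"].to_numpy(float)
    if inclusive:
        up = (lfc >= fc_threshold) & (p <= p_threshold)
        down = (lfc <= -fc_threshold) & (p <= p_threshold)
    else:
        up = (lfc > fc_threshold) & (p < p_threshold)
        down = (lfc < -fc_threshold) & (p < p_threshold)
    out = deg.copy()
    out["class"] = np.select([up, down], ["up", "down"], default="ns")
    return out


def differential_expression(
    mat_a: ExpressionMatrix,
    mat_b: ExpressionMatrix,
    pseudocount: float = 1.0,
    test: str = "welch",
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    inclusive: bool = True,
) -> pd.DataFrame:
    """Per-gene two-group differential expression of A over B.

    Returns a DataFrame indexed by gene with columns ``mean_a``, ``mean_b``
    (linear-scale group means), ``log2fc`` =
    log2((mean_a + pseudocount)/(mean_b + pseudocount)), ``p_value`` from the
    configured test on log2(x + pseudocount) values, ``q_value`` (BH over all
    genes) and the volcano ``class``.

    ``test`` is one of ``welch`` (default), ``wilcoxon`` or ``paired-t``
    (pairs taken by column order; requires equal group sizes).
    """
    if set(mat_a.gene_ids) != set(mat_b.gene_ids):
        raise ValueError("gene spaces of the two matrices differ")
    if test not in ("welch", "wilcoxon", "paired-t"):
        raise ValueError(f"unknown test {test!r}")
    a = mat_a.to_linear().values
    b = mat_b.to_linear().values.reindex(a.index)
    if test in ("welch", "paired-t") and (a.shape[1] < 2 or b.shape[1] < 2):
        raise ValueError("t-tests require at least 2 samples per group")
    if test == "paired-t" and a.shape[1] != b.shape[1]:
        raise ValueError("paired-t requires equal group sizes")

    av = a.to_numpy(float)
    bv = b.to_numpy(float)
    mean_a = av.mean(axis=1)
    mean_b = bv.mean(axis=1)
    log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))

    la = np.log2(av + pseudocount)
    lb = np.log2(bv + pseudocount)
    with np.errstate(all="ignore"):
        if test == "welch":
            res = stats.ttest_ind(la, lb, axis=1, equal_var=False)
            p = np.asarray(res.pvalue, float)
        elif test == "paired-t":
            res = stats.ttest_rel(la, lb, axis=1)
            p = np.asarray(res.pvalue, float)
        else:
            res = stats.mannwhitneyu(la, lb, axis=1, alternative="two-sided")
            p = np.asarray(res.pvalue, float)

    # degenerate rows: zero variance in both groups
    flat = (la.std(axis=1) == 0) & (lb.std(axis=1) == 0)
    same = np.isclose(la.mean(axis=1), lb.mean(axis=1))
    p = np.where(flat & same, 1.0, p)
    p = np.where(flat & ~same, 0.0, p)
    p = np.where(np.isnan(p), 1.0, p)

    deg = pd.DataFrame(
        {"mean_a": mean_a, "mean_b": mean_b, "log2fc": log2fc,
         "p_value": p, "q_value": bh_fdr(p)},
        index=a.index,
    )
    return volcano_classify(deg, fc_threshold, p_threshold, inclusive)


@dataclass
class ZScoreMatrix:
    """Per-gene standardized matrix: row mean 0, sample SD (ddof=1) 1.

    Constant rows cannot be standardized and are mapped to all-zero; their
    gene ids are recorded in ``constant_genes``.
    """

    values: pd.DataFrame
    constant_genes: list[str]


def compute_zscores(mat: ExpressionMatrix | pd.DataFrame) -> ZScoreMatrix:
    """Row-standardize a gene x sample matrix ((x - mean) / sample SD)."""
    df = mat.values if isinstance(mat, ExpressionMatrix) else mat
    if df.shape[1] < 2:
        raise ValueError("Z-scores require at least 2 samples")
    arr = df.to_numpy(float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (arr - mean) / sd
    z[constant, :] = 0.0
    const_genes = df.index[constant].tolist()
    if const_genes:
        logger.info("compute_zscores: %d constant rows set to zero", len(const_genes))
    return ZScoreMatrix(pd.DataFrame(z, index=df.index, columns=df.columns),
                        const_genes)
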