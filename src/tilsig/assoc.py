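"""Post-signature association analyses.

* per-gene correlation of expression with deconvolution-estimated CD4/CD8
  immune fractions (simple least-squares regression; the reported R is the
  signed Pearson coefficient and p the two-sided slope test),
* hypergeometric over-representation analysis (ORA) of a gene list against
  GMT gene sets,
* Z-score matrices restricted to curated T-cell subset panels (immune
  checkpoints, Treg/Th1/Th2/Th17 markers).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .data_io import ExpressionMatrix, GeneSetCollection, Scale
from .diffexpr import bh_fdr, compute_zscores

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationMatrix",
    "PanelMatrix",
    "correlate_genes_with_fractions",
    "summarize_significant_fraction",
    "hypergeometric_enrichment_p",
    "ora_enrichment",
    "panel_zscore_matrix",
    "load_default_panels",
]

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class CorrelationMatrix:
    """Gene x subset Pearson correlations with two-sided p-values.

    ``undefined`` flags gene/subset pairs where either vector was constant
    (R and p are NaN there and the pair is excluded from significance
    tallies).
    """

    r: pd.DataFrame
    p: pd.DataFrame
    undefined: pd.DataFrame
    n_patients: int

    @property
    def significant(self) -> pd.DataFrame:
        return (self.p < SIGNIFICANCE_LEVEL) & ~self.undefined


def correlate_genes_with_fractions(
    expr: ExpressionMatrix,
    fractions: pd.DataFrame,
    method: str = "pearson",
) -> CorrelationMatrix:
    """Correlate each gene's expression with each immune-fraction column.

    Expression is used on the log2(x+1) scale (converted if needed); the
    patients are the intersection of expression samples and fraction rows
    (>= 3 required). ``method`` is ``pearson`` (simple linear regression;
    default) or ``spearman``.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    shared = [p for p in expr.sample_ids if p in set(fractions.index)]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared patients, got {len(shared)}")
    X = expr.to_log2p1().values[shared].to_numpy(float)      # genes x n
    F = fractions.loc[shared].to_numpy(float)                # n x subsets
    n = len(shared)
    if method == "spearman":
        X = stats.rankdata(X, axis=1)
        F = stats.rankdata(F, axis=0)
    xc = X - X.mean(axis=1, keepdims=True)
    fc = F - F.mean(axis=0, keepdims=True)
    xs = np.sqrt((xc ** 2).sum(axis=1))
    fs = np.sqrt((fc ** 2).sum(axis=0))
    undef = (xs[:, None] == 0) | (fs[None, :] == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ fc) / (xs[:, None] * fs[None, :])
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r ** 2, 0.0, None))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isinf(t), 0.0, p)
    r[undef] = np.nan
    p[undef] = np.nan
    idx, cols = expr.values.index, fractions.columns
    return CorrelationMatrix(
        pd.DataFrame(r, index=idx, columns=cols),
        pd.DataFrame(p, index=idx, columns=cols),
        pd.DataFrame(undef, index=idx, columns=cols),
        n_patients=n,
    )


def summarize_significant_fraction(
    corr: CorrelationMatrix,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Percentage of evaluable genes significantly correlated, per subset.

    ``genes`` restricts the tally to one signature arm. Undefined pairs are
    excluded from the denominator; the bookkeeping columns satisfy
    significant + non-significant + undefined = total.
    """
    p = corr.p if genes is None else corr.p.loc[[g for g in genes if g in corr.p.index]]
    undef = corr.undefined.loc[p.index]
    sig = (p < SIGNIFICANCE_LEVEL) & ~undef
    total = len(p)
    n_undef = undef.sum(axis=0)
    evaluable = total - n_undef
    n_sig = sig.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * n_sig / evaluable.replace(0, np.nan)
    return pd.DataFrame({
        "percent_significant": pct,
        "significant": n_sig,
        "non_significant": evaluable - n_sig,
        "undefined": n_undef,
        "total": total,
    })


def hypergeometric_enrichment_p(k: int, K: int, q: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k) for an overlap of ``k``
    between a query of size ``q`` and a term of size ``K`` in a universe of
    size ``N``."""
    if not (0 <= k <= min(q, K) and K <= N and q <= N):
        raise ValueError("inconsistent hypergeometric arguments")
    return float(stats.hypergeom.sf(k - 1, N, K, q))


def ora_enrichment(
    query_genes: list[str],
    sets: GeneSetCollection,
    universe: list[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query_genes`` in each set.

    Query genes outside the universe are logged and dropped; term sizes are
    taken after intersection with the universe (terms with no universe gene
    are skipped). Returns a DataFrame sorted by p then fold enrichment, with
    BH q-values across terms.
    """
    uni = set(universe)
    N = len(uni)
    query = [g for g in dict.fromkeys(query_genes) if g in uni]
    dropped = len(set(query_genes)) - len(query)
    if dropped:
        logger.warning("ora_enrichment: %d query genes outside universe dropped",
                       dropped)
    if not query:
        raise ValueError("empty query after intersection with universe")
    q = len(query)
    qset = set(query)
    rows = []
    for name, genes in sets.sets.items():
        term = set(genes) & uni
        K = len(term)
        if K == 0:
            logger.info("ora_enrichment: term %s has no universe genes, skipped", name)
            continue
        k = len(term & qset)
        fold = (k / q) / (K / N)
        rows.append((name, k, q, K, N, fold,
                     hypergeometric_enrichment_p(k, K, q, N)))
    out = pd.DataFrame(rows, columns=["term", "overlap", "query_size",
                                      "term_size", "universe_size",
                                      "fold_enrichment", "p_value"])
    out["q_value"] = bh_fdr(out["p_value"].to_numpy()) if len(out) else []
    out = out.sort_values(["p_value", "fold_enrichment"],
                          ascending=[True, False], kind="stable")
    return out.set_index("term")


@dataclass
class PanelMatrix:
    """Z-score matrix restricted to a curated marker-gene panel."""

    panel_name: str
    genes: list[str]
    values: pd.DataFrame
    missing_genes: list[str] = field(default_factory=list)


def panel_zscore_matrix(
    expr: ExpressionMatrix | pd.DataFrame,
    panel_genes: list[str],
    panel_name: str,
) -> PanelMatrix:
    """Row Z-scores of the expression matrix restricted to ``panel_genes``.

    Panel genes absent from the matrix are reported, not silently dropped;
    at least one must be present.
    """
    df = expr.values if isinstance(expr, ExpressionMatrix) else expr
    present = [g for g in panel_genes if g in df.index]
    missing = [g for g in panel_genes if g not in df.index]
    if not present:
        raise ValueError(f"no {panel_name!r} panel genes present in expression")
    if missing:
        logger.info("panel %s: %d genes missing from expression: %s",
                    panel_name, len(missing), missing[:5])
    z = compute_zscores(df.loc[present])
    return PanelMatrix(panel_name, present, z.values, missing)


def load_default_panels() -> dict[str, list[str]]:
    """Curated immune-checkpoint and Treg/Th1/Th2/Th17 marker panels."""
    text = resources.files("tilsig").joinpath("panels.yaml").read_text()
    return yaml.safe_load(text)
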