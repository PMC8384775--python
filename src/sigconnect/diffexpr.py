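"""Differential expression stand-in, BH adjustment and DEG overlap statistics.

The DEG caller fits, per gene, an ordinary least-squares model on
log2(count / size_factor + 0.5) with a treatment indicator and (optionally)
an additive batch covariate, then applies Benjamini-Hochberg across genes.
It is a documented stand-in for a negative-binomial Wald test: the interface
also accepts externally computed tables with the same schema.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix
from .qc import size_factors

logger = logging.getLogger(__name__)

DEG_COLUMNS = ["gene", "l2fc", "stat", "p", "adj_p", "is_deg"]


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-D array")
    if not np.isfinite(p).all() or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must be finite and within [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adjusted, 0.0, 1.0)
    return out


def call_degs(
    mat: ExpressionMatrix,
    treatment_samples: list[str],
    control_samples: list[str],
    alpha: float = 0.05,
    batch_mode: str = "separate",
    size_factors_override: pd.Series | None = None,
) -> pd.DataFrame:
    """Call DEGs for treatment vs control samples.

    Returns a frame indexed like ``mat.counts`` with columns ``gene, l2fc,
    stat, p, adj_p, is_deg``. ``batch_mode='corrected'`` adds an additive
    batch term to the design; ``'separate'`` fits treatment only (the caller
    is expected to pass samples from a single batch).
    """
    if batch_mode not in ("separate", "corrected"):
        raise ValueError(f"unknown batch_mode {batch_mode!r}")
    treatment_samples, control_samples = list(treatment_samples), list(control_samples)
    if len(treatment_samples) < 2 or len(control_samples) < 2:
        raise ValueError("need at least two replicates per group")
    samples = treatment_samples + control_samples
    counts = mat.counts[samples]
    if size_factors_override is not None:
        factors = size_factors_override.loc[samples]
    else:
        factors = size_factors(counts)
    y = np.log2(counts.to_numpy(dtype=float) / factors.to_numpy() + 0.5)

    is_treated = np.array([s in set(treatment_samples) for s in samples], dtype=float)
    design = [np.ones(len(samples)), is_treated]
    if batch_mode == "corrected":
        batches = mat.meta.loc[samples, "batch"].to_numpy()
        levels = np.unique(batches)
        for level in levels[1:]:
            design.append((batches == level).astype(float))
    X = np.column_stack(design)
    n, p_params = X.shape
    if n <= p_params:
        raise ValueError("not enough samples for the design")

    # vectorized per-gene OLS; treatment coefficient is column 1
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = y @ X @ xtx_inv  # genes x params
    resid = y - beta @ X.T
    dof = n - p_params
    sigma2 = (resid**2).sum(axis=1) / dof
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 1e-300))
    tstat = beta[:, 1] / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)
    adj = benjamini_hochberg(pvals)

    out = pd.DataFrame(
        {
            "gene": mat.annotation["gene_symbol"].to_numpy(),
            "l2fc": beta[:, 1],
            "stat": tstat,
            "p": pvals,
            "adj_p": adj,
            "is_deg": adj < alpha,
        },
        index=mat.counts.index,
    )
    logger.info("called %d DEGs of %d genes (alpha=%g)", int(out.is_deg.sum()), len(out), alpha)
    return out


def load_deg_table(path) -> pd.DataFrame:
    """Read an externally produced DEG table (same TSV schema)."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in DEG_COLUMNS if c not in table.columns and c != "stat"]
    if missing:
        raise ValueError(f"DEG table missing columns {missing}")
    return table.set_index(table.columns[0]) if table.columns[0] != "gene" else table


def deg_overlap(a: pd.DataFrame, b: pd.DataFrame) -> dict:
    """Overlap statistics between two DEG tables on the same gene universe.

    Returns counts of shared / exclusive DEGs, their fractions of the union,
    and the Pearson r of l2fc over the shared DEGs (None when fewer than 2).
    """
    genes_a = set(a.loc[a["is_deg"], "gene"])
    genes_b = set(b.loc[b["is_deg"], "gene"])
    shared = genes_a & genes_b
    union = genes_a | genes_b
    n_union = len(union)
    report = {
        "n_overlap": len(shared),
        "n_only_a": len(genes_a - genes_b),
        "n_only_b": len(genes_b - genes_a),
        "frac_overlap": len(shared) / n_union if n_union else 0.0,
        "frac_only_a": len(genes_a - genes_b) / n_union if n_union else 0.0,
        "frac_only_b": len(genes_b - genes_a) / n_union if n_union else 0.0,
        "pearson_r_overlap": None,
    }
    if len(shared) >= 2:
        la = a.set_index("gene").loc[sorted(shared), "l2fc"].to_numpy()
        lb = b.set_index("gene").loc[sorted(shared), "l2fc"].to_numpy()
        if np.std(la) > 0 and np.std(lb) > 0:
            report["pearson_r_overlap"] = float(stats.pearsonr(la, lb).statistic)
    return report


def union_deg_matrix(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Genes x treatments L2FC matrix over the union of DEGs of all tables.

    Rows are all genes flagged DEG in at least one treatment; values are each
    treatment's l2fc for those genes whether significant there or not.
    """
    union: set[str] = set()
    for table in tables.values():
        union |= set(table.loc[table["is_deg"], "gene"])
    if not union:
        logger.warning("union of DEGs is empty")
        return pd.DataFrame(columns=list(tables))
    genes = sorted(union)
    data = {}
    for name, table in tables.items():
        indexed = table.set_index("gene")["l2fc"]
        data[name] = indexed.reindex(genes)
    return pd.DataFrame(data, index=genes)


def venn_counts(union_a, union_b) -> tuple[int, int, int]:
    """(only_a, shared, only_b) partition sizes of two gene sets."""
    a, b = set(union_a), set(union_b)
    return len(a - b), len(a & b), len(b - a)
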