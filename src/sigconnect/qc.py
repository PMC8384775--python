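"""Replicate-level QC: read depth, zero fractions, replicate correlations,
variance stabilization and PCA.

All correlation and depth statistics operate on raw counts over all probes;
no normalization or pre-filtering is applied before them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

REPLICATE_PAIRS = ((1, 2), (1, 3), (2, 3))


@dataclass
class QCSummary:
    per_sample: pd.DataFrame  # columns: total_reads, zero_fraction
    technical_r: pd.DataFrame | None = None  # one row per (treatment, batch, pair)
    biological_r: pd.DataFrame | None = None  # one row per (treatment, replicate)


def read_depth_summary(mat: ExpressionMatrix) -> QCSummary:
    """Per-sample total reads and fraction of probes with zero count."""
    counts = mat.counts
    per_sample = pd.DataFrame(
        {
            "total_reads": counts.sum(axis=0).astype(np.int64),
            "zero_fraction": (counts == 0).sum(axis=0) / counts.shape[0],
        }
    )
    per_sample.index.name = "sample_id"
    return QCSummary(per_sample=per_sample)


def consistent_zero_fraction(mat: ExpressionMatrix) -> float:
    """Fraction of probes with zero count in every sample."""
    if mat.n_samples < 2:
        raise ValueError("need at least two samples")
    return float((mat.counts == 0).all(axis=1).mean())


def _replicate_column(mat: ExpressionMatrix, chemical, concentration, batch, replicate):
    mask = (
        (mat.meta["chemical"] == chemical)
        & (mat.meta["concentration_uM"] == concentration)
        & (mat.meta["batch"] == batch)
        & (mat.meta["replicate"] == replicate)
    )
    ids = mat.meta.index[mask]
    if len(ids) != 1:
        raise ValueError(
            f"expected exactly one sample for (chemical={chemical!r}, "
            f"concentration={concentration}, batch={batch}, replicate={replicate}); "
            f"found {len(ids)}"
        )
    return mat.counts[ids[0]].to_numpy(dtype=float)


def technical_replicate_correlations(
    mat: ExpressionMatrix, chemical: str, concentration: float, batch: int
) -> dict[tuple[int, int], float]:
    """Pearson r of raw counts for replicate pairs (1,2), (1,3), (2,3) within a batch."""
    cols = {
        r: _replicate_column(mat, chemical, concentration, batch, r) for r in (1, 2, 3)
    }
    return {
        (a, b): float(stats.pearsonr(cols[a], cols[b]).statistic)
        for a, b in REPLICATE_PAIRS
    }


def biological_replicate_correlations(
    mat: ExpressionMatrix, chemical: str, concentration: float
) -> dict[int, float]:
    """Pearson r between replicate-index-matched samples of batches 1 and 2."""
    out = {}
    for r in (1, 2, 3):
        x = _replicate_column(mat, chemical, concentration, 1, r)
        y = _replicate_column(mat, chemical, concentration, 2, r)
        out[r] = float(stats.pearsonr(x, y).statistic)
    return out


def qc_summary(mat: ExpressionMatrix) -> QCSummary:
    """Full QC sweep: depth + zero fractions + all replicate correlations."""
    base = read_depth_summary(mat)
    tech_rows, bio_rows = [], []
    treatments = mat.meta[~mat.meta["is_vehicle"].astype(bool)][
        ["chemical", "concentration_uM"]
    ].drop_duplicates()
    batches = sorted(mat.meta["batch"].unique())
    for chemical, conc in treatments.itertuples(index=False):
        for batch in batches:
            try:
                rs = technical_replicate_correlations(mat, chemical, conc, batch)
            except ValueError:
                continue
            for (a, b), r in rs.items():
                tech_rows.append(
                    {"chemical": chemical, "concentration_uM": conc, "batch": batch,
                     "pair": f"{a}-{b}", "pearson_r": r}
                )
        if {1, 2} <= set(batches):
            try:
                rs = biological_replicate_correlations(mat, chemical, conc)
            except ValueError:
                continue
            for rep, r in rs.items():
                bio_rows.append(
                    {"chemical": chemical, "concentration_uM": conc,
                     "replicate": rep, "pearson_r": r}
                )
    return QCSummary(
        per_sample=base.per_sample,
        technical_r=pd.DataFrame(tech_rows) if tech_rows else None,
        biological_r=pd.DataFrame(bio_rows) if bio_rows else None,
    )


# ---------------------------------------------------------------------------
# variance stabilization (median-of-ratios stand-in) and PCA
# ---------------------------------------------------------------------------


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Reference = per-probe geometric mean over samples, computed on probes with
    strictly positive counts everywhere; size factor = median of
    count/reference over those probes.
    """
    values = counts.to_numpy(dtype=float)
    if (values.sum(axis=0) == 0).any():
        bad = counts.columns[values.sum(axis=0) == 0][0]
        raise ValueError(f"sample {bad!r} has all-zero counts")
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no probe has positive counts in every sample")
    log_values = np.log(values[positive])
    log_ref = log_values.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_values - log_ref, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def variance_stabilize(mat: ExpressionMatrix) -> pd.DataFrame:
    """log2(count / size_factor + 1), a documented stand-in for DESeq2's vst.

    Assumes the low-count filter has already been applied. Preserves the
    rank/variance behaviour needed for PCA visualization; not numerically
    equivalent to varianceStabilizingTransformation.
    """
    factors = size_factors(mat.counts)
    return np.log2(mat.counts / factors + 1.0)


def pca_scores(transformed: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """Centered PCA scores of samples (columns) on the transformed matrix.

    Returns a samples x components frame with attrs['explained_variance'].
    """
    n_samples = transformed.shape[1]
    if n_samples < 2:
        raise ValueError("need at least two samples")
    if n_components > n_samples:
        raise ValueError(f"n_components={n_components} exceeds sample count {n_samples}")
    X = transformed.to_numpy(dtype=float).T  # samples x probes
    X = X - X.mean(axis=0, keepdims=True)
    # SVD rather than sklearn: keeps sign convention pinned for determinism
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # fix signs: largest-magnitude loading positive
    signs = np.sign(Vt[np.arange(Vt.shape[0]), np.abs(Vt).argmax(axis=1)])
    signs[signs == 0] = 1.0
    scores = (U * S)[:, :n_components] * signs[:n_components]
    out = pd.DataFrame(
        scores,
        index=transformed.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    out.attrs["explained_variance"] = (S**2 / max(X.shape[0] - 1, 1))[:n_components]
    out.attrs["total_variance"] = float((S**2).sum() / max(X.shape[0] - 1, 1))
    return out
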