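"""The five connectivity-scoring algorithms and ranked retrieval.

Scores
------
sji   signed Jaccard index of up/down set overlaps, bounded in [-1, 1]
gtes  gene set total enrichment score: bidirectional sum of weighted-KS
      enrichment scores (query tails in the reference ranking plus reference
      tails in the query ranking), bounded in [-4, 4]
xc    extreme cosine: cosine of query L2FC vs the reference profile masked to
      its nr most extreme genes per tail
xcp   extreme Pearson on the same masked vectors
xcs   extreme Spearman on the same masked vectors

Undefined scores (insufficient gene overlap, zero variance) are returned as
NaN and always sort after all defined scores.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .expression import L2FCProfile, ProfileDatabase
from .signatures import QuerySignature, RestrictedProfile, _ranked_genes, restrict_reference

logger = logging.getLogger(__name__)

ALGORITHMS = ("sji", "gtes", "xc", "xcp", "xcs")

SCORE_BOUNDS = {
    "sji": (-1.0, 1.0),
    "gtes": (-4.0, 4.0),
    "xc": (-1.0, 1.0),
    "xcp": (-1.0, 1.0),
    "xcs": (-1.0, 1.0),
}


# ---------------------------------------------------------------------------
# weighted Kolmogorov-Smirnov enrichment score
# ---------------------------------------------------------------------------


def weighted_ks_es(gene_set, ranking: pd.Series, weight_p: float = 1.0) -> float:
    """Weighted-KS enrichment score of ``gene_set`` in a ranked gene list.

    ``ranking`` maps gene -> statistic, ordered by descending statistic. The
    running sum increments at set members by |statistic|^p (normalized over
    members) and decrements at non-members by 1/(N - N_hit); the ES is the
    signed extremum (maximum deviation from zero).
    """
    genes = ranking.index
    n = len(genes)
    hit_mask = genes.isin(set(gene_set))
    positions = np.flatnonzero(hit_mask)
    n_hit = positions.size
    if n_hit == 0:
        raise ValueError("gene set does not intersect the ranking")
    if n_hit == n:
        raise ValueError("gene set covers the entire ranking")

    weights = np.abs(ranking.to_numpy(dtype=float)[positions]) ** weight_p
    total = weights.sum()
    if total == 0:  # all member statistics are zero: fall back to equal weights
        weights = np.ones(n_hit)
        total = float(n_hit)
    cum_hits = np.cumsum(weights) / total
    miss_step = 1.0 / (n - n_hit)
    misses_before = positions - np.arange(n_hit)
    peaks = cum_hits - misses_before * miss_step  # value just after each hit
    valleys = peaks - weights / total  # value just before each hit
    max_dev, min_dev = peaks.max(), min(valleys.min(), 0.0)
    # an exactly balanced deviation (|max| == |min|, which has positive
    # probability via the rational miss steps) scores 0: this keeps the ES
    # antisymmetric under ranking reversal
    if abs(max_dev + min_dev) <= 1e-12:
        return 0.0 if max_dev > 0 else float(max_dev)
    return float(max_dev) if max_dev > -min_dev else float(min_dev)


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------


def _cached_gene_set(obj, attr: str, series: pd.Series) -> set:
    cached = getattr(obj, attr, None)
    if cached is None:
        cached = set(series.index)
        object.__setattr__(obj, attr, cached)
    return cached


def _jaccard(a: set, b: set) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def score_sji(q: QuerySignature, r: RestrictedProfile) -> float:
    """Signed Jaccard: concordant overlaps minus discordant, halved to [-1, 1]."""
    up_q, dn_q = set(q.up), set(q.down)
    return 0.5 * (
        _jaccard(up_q, r.up)
        + _jaccard(dn_q, r.down)
        - _jaccard(up_q, r.down)
        - _jaccard(dn_q, r.up)
    )


def score_gtes(
    q: QuerySignature, q_full_ranking: pd.Series, r: RestrictedProfile,
    weight_p: float = 1.0,
) -> float:
    """Bidirectional total enrichment score in [-4, 4].

    Sum of (ES of query-up minus query-down tails in the reference ranking)
    and (ES of reference-up minus reference-down tails in the query ranking).
    """
    ref_genes = _cached_gene_set(r, "_universe", r.full_ranking)
    query_genes = set(q_full_ranking.index)
    es_q_up = weighted_ks_es(set(q.up) & ref_genes, r.full_ranking, weight_p)
    es_q_dn = weighted_ks_es(set(q.down) & ref_genes, r.full_ranking, weight_p)
    es_r_up = weighted_ks_es(r.up & query_genes, q_full_ranking, weight_p)
    es_r_dn = weighted_ks_es(r.down & query_genes, q_full_ranking, weight_p)
    return (es_q_up - es_q_dn) + (es_r_up - es_r_dn)


def score_extreme(
    q: QuerySignature, r: RestrictedProfile, flavor: str, min_overlap: int = 3,
    drop_masked: bool = False,
) -> float:
    """Extreme cosine / Pearson / Spearman over the signature gene vector.

    The reference vector keeps its L2FC only for genes inside its nr most
    extreme tails; other genes (including genes absent from the reference
    universe) contribute 0 (set ``drop_masked=True`` to exclude them
    instead). Returns NaN when fewer than ``min_overlap`` signature genes
    fall inside the reference extremes, or on zero variance/norm.
    """
    if flavor not in ("xc", "xcp", "xcs"):
        raise ValueError(f"unknown extreme flavor {flavor!r}")
    sig_genes = q.genes
    x = q.values.loc[sig_genes].to_numpy(dtype=float)
    lookup = getattr(r, "_extreme_values", None)
    if lookup is None:  # r.values covers exactly the up/down extremes
        lookup = r.values.to_dict()
        object.__setattr__(r, "_extreme_values", lookup)
    y = np.array([lookup.get(g, 0.0) for g in sig_genes])
    inside = np.array([g in lookup for g in sig_genes])
    if inside.sum() < min_overlap:
        return float("nan")
    if drop_masked:
        x, y = x[inside], y[inside]
    if flavor == "xc":
        nx, ny = np.linalg.norm(x), np.linalg.norm(y)
        if nx == 0 or ny == 0:
            return float("nan")
        return float(np.dot(x, y) / (nx * ny))
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    if flavor == "xcp":
        return float(stats.pearsonr(x, y).statistic)
    return float(stats.spearmanr(x, y).statistic)


def score_pair(
    q: QuerySignature,
    q_full_ranking: pd.Series,
    r: RestrictedProfile,
    algorithms=ALGORITHMS,
) -> dict[str, float]:
    """All requested scores for one (query, reference) pair; NaN on failure."""
    out: dict[str, float] = {}
    for algorithm in algorithms:
        try:
            if algorithm == "sji":
                out[algorithm] = score_sji(q, r)
            elif algorithm == "gtes":
                out[algorithm] = score_gtes(q, q_full_ranking, r)
            else:
                out[algorithm] = score_extreme(q, r, algorithm)
        except ValueError as exc:
            logger.debug("score %s undefined for %s vs %s: %s",
                         algorithm, q.query_id, r.reference_id, exc)
            out[algorithm] = float("nan")
    return out


# ---------------------------------------------------------------------------
# ranked retrieval
# ---------------------------------------------------------------------------


def prepare_references(db: ProfileDatabase, nr: int) -> list[RestrictedProfile]:
    """Restrict every database profile once for reuse across queries."""
    return [restrict_reference(profile, nr) for profile in db]


def score_table(
    q: QuerySignature,
    q_full_ranking: pd.Series,
    references: list[RestrictedProfile],
    algorithms=ALGORITHMS,
) -> pd.DataFrame:
    """One row per reference, one column per algorithm (unordered)."""
    rows = []
    for restricted in references:
        scores = score_pair(q, q_full_ranking, restricted, algorithms)
        rows.append({"reference_id": restricted.reference_id, **scores})
    return pd.DataFrame(rows)


def rank_table(scores: pd.DataFrame, algorithm: str) -> pd.DataFrame:
    """Order a score table descending by ``algorithm``.

    NaN scores sort last; ties break by ascending reference_id; a ``rank``
    column (1-based) is inserted.
    """
    table = scores.copy()
    table["_defined"] = ~table[algorithm].isna()
    table = table.sort_values(
        ["_defined", algorithm, "reference_id"],
        ascending=[False, False, True],
        kind="stable",
    ).drop(columns="_defined")
    if "rank" in table.columns:
        table = table.drop(columns="rank")
    table.insert(1, "rank", np.arange(1, len(table) + 1))
    return table.reset_index(drop=True)


def rank_references(
    q: QuerySignature,
    q_full_ranking: pd.Series,
    db: ProfileDatabase | list[RestrictedProfile],
    nr: int,
    algorithm: str = "sji",
    extra_algorithms=(),
) -> pd.DataFrame:
    """Score every database profile and rank descending by ``algorithm``.

    ``db`` may be a ProfileDatabase (restricted on the fly at ``nr``) or a
    pre-restricted list from :func:`prepare_references`.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if len(db) == 0:
        raise ValueError("empty profile database")
    references = db if isinstance(db, list) else prepare_references(db, nr)
    wanted = [algorithm] + [a for a in extra_algorithms if a != algorithm]
    return rank_table(score_table(q, q_full_ranking, references, wanted), algorithm)


def connect(
    query_profile: L2FCProfile,
    db: ProfileDatabase,
    nq: int,
    nr: int,
    sort_by: str = "sji",
    top: int | None = None,
) -> pd.DataFrame:
    """Convenience wrapper: build the signature and rank with all five scores."""
    from .signatures import make_query_signature

    q = make_query_signature(query_profile, nq)
    q_full = _ranked_genes(query_profile)
    table = rank_references(q, q_full, db, nr, algorithm=sort_by,
                            extra_algorithms=ALGORITHMS)
    return table.head(top) if top else table
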