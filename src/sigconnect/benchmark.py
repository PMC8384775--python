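"""Rank-of-correct-hit retrieval benchmarking: Fr1/Fr5/Fr10 metrics,
the (algorithm, nq, nr) evaluation grid and best-rank summary tables."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .connectivity import ALGORITHMS, prepare_references, rank_table, score_table
from .expression import L2FCProfile, ProfileDatabase, normalize_chemical
from .signatures import _ranked_genes, make_query_signature

logger = logging.getLogger(__name__)

FR_KS = (1, 5, 10)


def correct_hit_rank(
    hits: pd.DataFrame, query_chemical: str, chemical_of: dict[str, str],
    score_column: str | None = None,
) -> int | None:
    """Rank of the best-ranked reference whose chemical matches the query's.

    Chemical matching is case- and punctuation-insensitive. Returns None when
    the chemical is absent from the database or every matching reference's
    score is undefined.
    """
    target = normalize_chemical(query_chemical)
    lookup = {tid: normalize_chemical(chem) for tid, chem in chemical_of.items()}
    matching = hits["reference_id"].map(lookup) == target
    if not matching.any():
        if target not in set(lookup.values()):
            logger.info("chemical %r absent from database", query_chemical)
        return None
    score_column = score_column or [
        c for c in hits.columns if c not in ("reference_id", "rank")
    ][0]
    defined = matching & ~hits[score_column].isna()
    if not defined.any():
        logger.info("chemical %r present but all matching scores undefined", query_chemical)
        return None
    return int(hits.loc[defined, "rank"].min())


def fraction_metrics(ranks) -> tuple[float, float, float]:
    """(Fr1, Fr5, Fr10): fraction of chemicals with rank <= k.

    ``None`` entries count in the denominator but never the numerator.
    """
    ranks = list(ranks)
    if not ranks:
        raise ValueError("no ranks supplied")
    n = len(ranks)
    return tuple(
        sum(1 for r in ranks if r is not None and r <= k) / n for k in FR_KS
    )


def grid_evaluate(
    queries: dict[str, L2FCProfile],
    db: ProfileDatabase,
    nq_grid,
    nr_grid,
    algorithms=ALGORITHMS,
    chemical_of_query=None,
    assay: str = "",
) -> pd.DataFrame:
    """Exhaustive (algorithm, nq, nr) retrieval benchmark.

    ``queries`` maps treatment id -> query profile; a chemical queried at
    several concentrations is aggregated by its best (minimum) rank. Returns
    a long-format frame with one row per (assay, algorithm, nq, nr, chemical)
    plus the cell-level Fr1/Fr5/Fr10.
    """
    nq_grid, nr_grid = list(nq_grid), list(nr_grid)
    if not nq_grid or not nr_grid:
        raise ValueError("empty grid")
    if chemical_of_query is None:
        from .expression import parse_treatment_id

        chemical_of_query = {
            tid: parse_treatment_id(tid)["chemical"] for tid in queries
        }

    rankings = {tid: _ranked_genes(profile) for tid, profile in queries.items()}
    signatures: dict[tuple[str, int], object] = {}
    for tid, profile in queries.items():
        for nq in nq_grid:
            if 2 * nq > len(profile.values):
                logger.info("query %s lacks 2*nq=%d genes; cell skipped", tid, 2 * nq)
                continue
            signatures[(tid, nq)] = make_query_signature(profile, nq, query_id=tid)

    # score each (query, nq, nr) once for all algorithms, then rank per algorithm
    ranks_by_cell: dict[tuple[str, int, int], dict[str, int | None]] = {
        (algorithm, nq, nr): {}
        for algorithm in algorithms for nq in nq_grid for nr in nr_grid
    }
    for nr in nr_grid:
        references = prepare_references(db, nr)
        for nq in nq_grid:
            for tid in queries:
                sig = signatures.get((tid, nq))
                if sig is None:
                    continue
                scores = score_table(sig, rankings[tid], references, algorithms)
                chem = normalize_chemical(chemical_of_query[tid])
                for algorithm in algorithms:
                    hits = rank_table(scores, algorithm)
                    rank = correct_hit_rank(hits, chemical_of_query[tid],
                                            db.chemical_of, score_column=algorithm)
                    cell = ranks_by_cell[(algorithm, nq, nr)]
                    candidates = [r for r in (cell.get(chem), rank) if r is not None]
                    cell[chem] = min(candidates) if candidates else None

    rows = []
    for algorithm in algorithms:
        for nq in nq_grid:
            for nr in nr_grid:
                chem_ranks = ranks_by_cell[(algorithm, nq, nr)]
                if not chem_ranks:
                    continue
                fr1, fr5, fr10 = fraction_metrics(list(chem_ranks.values()))
                for chem, rank in sorted(chem_ranks.items()):
                    rows.append(
                        {"assay": assay, "algorithm": algorithm, "nq": nq, "nr": nr,
                         "chemical": chem, "rank": rank,
                         "Fr1": fr1, "Fr5": fr5, "Fr10": fr10}
                    )
    return pd.DataFrame(rows)


def grid_summary(grid: pd.DataFrame) -> pd.DataFrame:
    """Per-algorithm mean/SD of the Fr metrics across grid cells."""
    cells = grid.drop_duplicates(["assay", "algorithm", "nq", "nr"])
    return (
        cells.groupby(["assay", "algorithm"])[["Fr1", "Fr5", "Fr10"]]
        .agg(["mean", "std"])
        .reset_index()
    )


def best_rank_table(grid: pd.DataFrame, selection_metric: str = "Fr1") -> pd.DataFrame:
    """Per algorithm, pick the (nq, nr) cell maximizing the selection metric
    (ties -> smallest nq, then smallest nr) and report per-chemical best
    ranks plus median/mean rank rows.

    None ranks are excluded from the median/mean but retained as NaN cells.
    """
    if selection_metric not in ("Fr1", "Fr5", "Fr10"):
        raise ValueError(f"selection_metric must be one of Fr1/Fr5/Fr10")
    out_cols = {}
    meta_rows = {}
    for (assay, algorithm), sub in grid.groupby(["assay", "algorithm"]):
        cells = sub.drop_duplicates(["nq", "nr"]).sort_values(
            [selection_metric, "nq", "nr"], ascending=[False, True, True],
            kind="stable",
        )
        nq, nr = int(cells.iloc[0]["nq"]), int(cells.iloc[0]["nr"])
        chosen = sub[(sub["nq"] == nq) & (sub["nr"] == nr)].set_index("chemical")
        ranks = chosen["rank"]
        key = (assay, algorithm)
        out_cols[key] = ranks
        defined = ranks.dropna()
        meta_rows[key] = {
            "nq": nq, "nr": nr,
            "median_rank": float(defined.median()) if len(defined) else np.nan,
            "mean_rank": float(defined.mean()) if len(defined) else np.nan,
        }
    table = pd.DataFrame(out_cols)
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["assay", "algorithm"])
    meta = pd.DataFrame(meta_rows)
    meta.columns = table.columns
    return pd.concat([meta, table])
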