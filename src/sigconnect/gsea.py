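"""Weighted-KS gene set enrichment with gene-label permutation NES/FDR.

The enrichment statistic is shared with the connectivity module
(:func:`sigconnect.connectivity.weighted_ks_es`). The permutation null draws
size-matched random gene sets from the ranking universe; NES normalizes the
observed ES by the mean |null ES| of matching sign, and the permutation
p-value uses the same-sign null tail with a +1 floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import weighted_ks_es
from .diffexpr import benjamini_hochberg

logger = logging.getLogger(__name__)

MIN_RECOMMENDED_SIZE = 15
MAX_RECOMMENDED_SIZE = 500


@dataclass
class GeneSetCollection:
    sets: dict[str, set[str]]
    source: str = ""
    flags: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def load_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (set name, description, tab-separated gene symbols)."""
    sets: dict[str, set[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line {lineno}: expected >= 3 fields")
            name, genes = fields[0], [g for g in fields[2:] if g]
            if name in sets:
                raise ValueError(f"duplicate gene set name {name!r} at line {lineno}")
            unique = set(genes)
            if len(unique) < len(genes):
                logger.info("gene set %s: %d duplicate genes dropped",
                            name, len(genes) - len(unique))
            sets[name] = unique
    return GeneSetCollection(sets=sets, source=str(path))


def write_gmt(col: GeneSetCollection, path) -> None:
    with open(path, "w") as handle:
        for name, genes in col.sets.items():
            handle.write("\t".join([name, col.source or "na"] + sorted(genes)) + "\n")


def restrict_collection(
    col: GeneSetCollection,
    universe,
    min_size: int = MIN_RECOMMENDED_SIZE,
    max_size: int = MAX_RECOMMENDED_SIZE,
) -> GeneSetCollection:
    """Intersect every set with the measured gene universe.

    Sets falling below ``min_size`` or above ``max_size`` after restriction
    are kept but flagged (size caveats are reported, not enforced); empty
    sets are flagged ``empty`` and skipped at scoring time.
    """
    universe = set(universe)
    restricted: dict[str, set[str]] = {}
    flags: dict[str, list[str]] = {}
    for name, genes in col.sets.items():
        inside = genes & universe
        restricted[name] = inside
        tags = []
        if len(inside) == 0:
            tags.append("empty")
        elif len(inside) < min_size:
            tags.append("small")
        elif len(inside) > max_size:
            tags.append("large")
        if tags:
            flags[name] = tags
    return GeneSetCollection(sets=restricted, source=col.source, flags=flags)


def _null_es_pool(
    universe: pd.Series, size: int, n_perm: int, weight_p: float, rng: np.random.Generator
) -> np.ndarray:
    genes = universe.index.to_numpy()
    out = np.empty(n_perm)
    for i in range(n_perm):
        draw = rng.choice(genes, size=size, replace=False)
        out[i] = weighted_ks_es(draw, universe, weight_p)
    return out


def run_gsea(
    ranking: pd.Series,
    col: GeneSetCollection,
    n_perm: int = 1000,
    weight_p: float = 1.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Permutation GSEA over a collection.

    ``ranking`` maps gene -> statistic (any order; sorted internally by
    descending statistic with a lexicographic tiebreak). Null ES pools are
    drawn once per distinct effective set size and shared across sets of that
    size. Results carry ES, NES, pval, fdr, set size and size flags.
    """
    if ranking.index.has_duplicates:
        raise ValueError("ranking contains duplicate genes")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    frame = ranking.rename("stat").rename_axis("gene").reset_index()
    frame = frame.sort_values(["stat", "gene"], ascending=[False, True], kind="stable")
    ordered = pd.Series(frame["stat"].to_numpy(), index=frame["gene"].to_numpy())

    restricted = restrict_collection(col, set(ordered.index))
    rng = np.random.default_rng(seed)
    pools: dict[int, np.ndarray] = {}
    rows = []
    for name, genes in restricted.sets.items():
        tags = restricted.flags.get(name, [])
        if not genes or len(genes) == len(ordered):
            logger.info("gene set %s skipped (unusable size %d)", name, len(genes))
            continue
        es = weighted_ks_es(genes, ordered, weight_p)
        size = len(genes)
        if size not in pools:
            pools[size] = _null_es_pool(ordered, size, n_perm, weight_p, rng)
        null = pools[size]
        same_sign = null >= 0 if es >= 0 else null < 0
        n_same = int(same_sign.sum())
        if n_same:
            mean_abs = np.abs(null[same_sign]).mean()
            nes = es / mean_abs if mean_abs > 0 else np.nan
            pval = (1 + int((np.abs(null[same_sign]) >= abs(es)).sum())) / (1 + n_same)
        else:
            nes, pval = np.nan, 1.0 / (1 + n_perm)
        rows.append(
            {"set": name, "ES": es, "NES": nes, "pval": pval,
             "size": size, "flags": ";".join(tags)}
        )
    result = pd.DataFrame(rows)
    if len(result):
        result["fdr"] = benjamini_hochberg(result["pval"].to_numpy())
    else:
        result["fdr"] = pd.Series(dtype=float)
    return result.set_index("set")


def nes_concordance(a: pd.DataFrame, b: pd.DataFrame, top_k: int = 5) -> dict:
    """Pearson r of NES over shared sets plus top-k set overlap by NES."""
    shared = a.index.intersection(b.index)
    out = {"pearson_r": None, "top5_overlap": None, "n_shared": len(shared)}
    if len(shared) >= 2:
        x = a.loc[shared, "NES"].to_numpy(dtype=float)
        y = b.loc[shared, "NES"].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() >= 2 and np.std(x[ok]) > 0 and np.std(y[ok]) > 0:
            out["pearson_r"] = float(np.corrcoef(x[ok], y[ok])[0, 1])
    top_a = set(a["NES"].sort_values(ascending=False).head(top_k).index)
    top_b = set(b["NES"].sort_values(ascending=False).head(top_k).index)
    out["top5_overlap"] = len(top_a & top_b)
    return out


def significant_sets(results: pd.DataFrame, fdr_alpha: float = 0.05) -> pd.Series:
    """Classify each set as 'up', 'down' or 'ns' at the FDR threshold."""
    labels = pd.Series("ns", index=results.index, name="direction")
    significant = results["fdr"] < fdr_alpha
    labels[significant & (results["NES"] > 0)] = "up"
    labels[significant & (results["NES"] < 0)] = "down"
    return labels
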