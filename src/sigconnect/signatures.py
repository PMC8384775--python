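"""Query signatures (top-nq up/down genes) and restricted reference profiles.

Ranking is by L2FC magnitude-with-sign: "up" genes are the nq largest values,
"down" genes the nq smallest, regardless of sign. Ties at rank boundaries are
broken by ascending lexicographic gene symbol so results are deterministic
across platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import L2FCProfile

logger = logging.getLogger(__name__)

NQ_GRID_DEFAULT = tuple(range(100, 1001, 100))
NR_GRID_DEFAULT = tuple(range(1000, 6001, 1000))


def _ranked_genes(profile: L2FCProfile) -> pd.Series:
    """Profile values sorted by descending L2FC, ties by ascending gene symbol."""
    frame = profile.values.rename("l2fc").rename_axis("gene").reset_index()
    frame = frame.sort_values(["l2fc", "gene"], ascending=[False, True], kind="stable")
    return pd.Series(frame["l2fc"].to_numpy(), index=frame["gene"].to_numpy())


@dataclass
class QuerySignature:
    """Top-nq most up- and nq most down-regulated genes of a query profile."""

    up: list[str]
    down: list[str]
    values: pd.Series  # signature genes only
    nq: int
    query_id: str = ""

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise ValueError("up and down gene lists overlap")
        if len(self.up) != self.nq or len(self.down) != self.nq:
            raise ValueError("signature lists do not match nq")

    @property
    def genes(self) -> list[str]:
        return self.up + self.down


@dataclass
class RestrictedProfile:
    """A reference profile restricted to its nr most extreme genes per tail.

    ``full_ranking`` keeps every gene ordered by descending L2FC (needed for
    enrichment-based scoring); ``values`` covers up+down genes only.
    """

    up: set[str]
    down: set[str]
    values: pd.Series
    full_ranking: pd.Series  # all genes, descending L2FC
    nr: int
    reference_id: str = ""


def make_query_signature(profile: L2FCProfile, nq: int, query_id: str = "") -> QuerySignature:
    if nq < 1:
        raise ValueError("nq must be positive")
    if 2 * nq > len(profile.values):
        raise ValueError(
            f"profile has {len(profile.values)} genes; cannot take 2*nq={2 * nq}"
        )
    ranked = _ranked_genes(profile)
    up = list(ranked.index[:nq])
    down = list(ranked.index[-nq:][::-1])  # ascending L2FC
    sign_flip = sum(ranked[up] < 0) + sum(ranked[down] > 0)
    if sign_flip:
        logger.info("signature %s: %d sign-inconsistent tail genes", query_id, sign_flip)
    values = ranked[up + down]
    return QuerySignature(
        up=up, down=down, values=values, nq=nq,
        query_id=query_id or profile.treatment_id,
    )


def restrict_reference(profile: L2FCProfile, nr: int) -> RestrictedProfile:
    """Restrict to nr genes per tail, clamping when the universe is small."""
    ranked = _ranked_genes(profile)
    n = len(ranked)
    effective = min(nr, n // 2)
    if effective < nr:
        logger.info(
            "restrict_reference %s: nr clamped %d -> %d (universe %d)",
            profile.treatment_id, nr, effective, n,
        )
    up = set(ranked.index[:effective])
    down = set(ranked.index[-effective:])
    values = ranked[ranked.index.isin(up | down)]
    return RestrictedProfile(
        up=up, down=down, values=values, full_ranking=ranked, nr=nr,
        reference_id=profile.treatment_id,
    )


def default_grids() -> tuple[list[int], list[int]]:
    """The (nq, nr) evaluation grids: 100..1000 by 100 and 1000..6000 by 1000."""
    return list(NQ_GRID_DEFAULT), list(NR_GRID_DEFAULT)


def signature_to_frame(sig: QuerySignature) -> pd.DataFrame:
    """Two-column serialization: gene, direction, l2fc."""
    rows = [{"gene": g, "direction": "up", "l2fc": sig.values[g]} for g in sig.up]
    rows += [{"gene": g, "direction": "down", "l2fc": sig.values[g]} for g in sig.down]
    return pd.DataFrame(rows)


def signature_to_gmt(sig: QuerySignature, name: str | None = None) -> str:
    """GMT export: one line per direction."""
    name = name or sig.query_id or "signature"
    lines = [
        "\t".join([f"{name}_UP", "up-regulated"] + sig.up),
        "\t".join([f"{name}_DN", "down-regulated"] + sig.down),
    ]
    return "\n".join(lines) + "\n"
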