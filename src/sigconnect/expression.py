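"""Count-matrix data model, I/O, filtering, isoform aggregation and L2FC profiles.

The central objects are :class:`ExpressionMatrix` (probes x samples raw
counts with probe annotation and sample metadata), :class:`L2FCProfile`
(per-treatment gene -> average log2 fold-change) and
:class:`ProfileDatabase` (a collection of reference L2FC profiles keyed by
treatment identifier).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PANELS = ("ST", "WT")

ANNOTATION_COLUMNS = ["probe_id", "gene_symbol", "panel"]
META_COLUMNS = [
    "sample_id",
    "chemical",
    "concentration_uM",
    "batch",
    "replicate",
    "panel",
    "is_vehicle",
]


class SchemaError(ValueError):
    """Raised when an input table violates the declared schema."""


@dataclass
class ExpressionMatrix:
    """Raw integer counts (probes x samples) with annotation and metadata.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer counts; index = probe ids, columns = sample ids.
    annotation : pandas.DataFrame
        One row per probe: ``probe_id``, ``gene_symbol``, ``panel``; indexed
        by ``probe_id`` and aligned with ``counts.index``.
    meta : pandas.DataFrame
        One row per sample (see :data:`META_COLUMNS`), indexed by
        ``sample_id`` and aligned with ``counts.columns``.
    """

    counts: pd.DataFrame
    annotation: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if not self.counts.index.equals(self.annotation.index):
            raise SchemaError("counts rows and annotation rows are not aligned")
        if not self.counts.columns.equals(self.meta.index):
            raise SchemaError("counts columns and metadata rows are not aligned")
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise SchemaError(f"duplicate probe_id {dup!r}")
        values = self.counts.to_numpy()
        if values.size and values.min() < 0:
            raise SchemaError("negative count encountered")
        if (self.annotation["gene_symbol"].astype(str).str.len() == 0).any():
            raise SchemaError("empty gene_symbol in annotation")
        bad_panel = set(self.meta["panel"]) - set(PANELS)
        if bad_panel:
            raise SchemaError(f"unknown panel value(s): {sorted(bad_panel)}")
        key = self.meta[["chemical", "concentration_uM", "batch", "replicate", "panel"]]
        if key.duplicated().any():
            raise SchemaError("duplicate (chemical, concentration, batch, replicate, panel)")
        vehicle = self.meta["is_vehicle"].astype(bool)
        if (self.meta.loc[vehicle, "concentration_uM"] != 0).any():
            raise SchemaError("vehicle sample with non-zero concentration")

    # -- convenience ------------------------------------------------------
    @property
    def n_probes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            counts=self.counts[sample_ids],
            annotation=self.annotation,
            meta=self.meta.loc[sample_ids],
        )

    def samples_for(
        self,
        chemical: str | None = None,
        concentration: float | None = None,
        batch: int | None = None,
        vehicle: bool | None = None,
    ) -> list[str]:
        """Sample ids matching the given metadata filters (None = wildcard)."""
        mask = pd.Series(True, index=self.meta.index)
        if chemical is not None:
            mask &= self.meta["chemical"] == chemical
        if concentration is not None:
            mask &= self.meta["concentration_uM"] == concentration
        if batch is not None:
            mask &= self.meta["batch"] == batch
        if vehicle is not None:
            mask &= self.meta["is_vehicle"].astype(bool) == vehicle
        return list(self.meta.index[mask])


@dataclass
class L2FCProfile:
    """Per-treatment gene -> average log2 fold-change vector."""

    treatment_id: str
    values: pd.Series  # index gene_symbol, float l2fc
    platform: str = ""

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise SchemaError(f"duplicate gene {dup!r} in profile {self.treatment_id}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise SchemaError(f"non-finite L2FC in profile {self.treatment_id}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index


@dataclass
class ProfileDatabase:
    """Reference L2FC profiles indexed by treatment id, with chemical lookup."""

    profiles: list[L2FCProfile]
    chemical_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.treatment_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            raise SchemaError("duplicate treatment_ids in database")
        for tid in ids:
            if tid not in self.chemical_of:
                self.chemical_of[tid] = parse_treatment_id(tid)["chemical"]

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self):
        return iter(self.profiles)

    def treatment_ids(self) -> list[str]:
        return [p.treatment_id for p in self.profiles]

    def to_frame(self) -> pd.DataFrame:
        """Genes x treatments matrix (union of genes; missing -> NaN)."""
        return pd.DataFrame({p.treatment_id: p.values for p in self.profiles})

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, chemical_of: dict[str, str] | None = None
    ) -> "ProfileDatabase":
        profiles = [
            L2FCProfile(treatment_id=col, values=frame[col].dropna())
            for col in frame.columns
        ]
        return cls(profiles=profiles, chemical_of=dict(chemical_of or {}))


# ---------------------------------------------------------------------------
# treatment id convention: chemical-<conc>uM-<duration>-<species>-<cell>-<study>
# e.g. valproic-acid-400.00uM-24h-rn-hep-e-mtab-797
# ---------------------------------------------------------------------------

_CONC_TOKEN = re.compile(r"^(\d+(?:\.\d+)?)uM$")


def make_treatment_id(
    chemical: str,
    concentration_uM: float,
    duration: str = "24h",
    species: str = "rn",
    cell: str = "hep",
    study: str = "e-mtab-797",
) -> str:
    chem = chemical.strip().lower().replace(" ", "-")
    return f"{chem}-{concentration_uM:.2f}uM-{duration}-{species}-{cell}-{study}"


def parse_treatment_id(treatment_id: str) -> dict:
    """Parse a hyphen-joined treatment id, splitting from the right.

    Chemical names may themselves contain hyphens, so the chemical is
    everything left of the concentration token.
    """
    tokens = treatment_id.split("-")
    conc_idx = None
    for i in range(len(tokens) - 1, -1, -1):
        if _CONC_TOKEN.match(tokens[i]):
            conc_idx = i
            break
    if conc_idx is None or conc_idx == 0:
        raise ValueError(f"cannot parse treatment id {treatment_id!r}: no concentration token")
    return {
        "chemical": "-".join(tokens[:conc_idx]),
        "concentration_uM": float(_CONC_TOKEN.match(tokens[conc_idx]).group(1)),
        "suffix": "-".join(tokens[conc_idx + 1 :]),
    }


def normalize_chemical(name: str) -> str:
    """Lowercase, punctuation-insensitive chemical key ('WY-14643' == 'wy14643')."""
    return re.sub(r"[^a-z0-9]", "", name.lower())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def load_counts(counts_path, annotation_path, meta_path) -> ExpressionMatrix:
    """Load a counts TSV + probe annotation TSV + sample metadata TSV.

    The counts file has ``probe_id`` as its first column and one column per
    sample. Every probe must be present in the annotation; counts must be
    integral.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    annotation = pd.read_csv(annotation_path, sep="\t")
    meta = pd.read_csv(meta_path, sep="\t")

    missing = [c for c in ANNOTATION_COLUMNS if c not in annotation.columns]
    if missing:
        raise SchemaError(f"annotation missing columns {missing}")
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise SchemaError(f"metadata missing columns {missing}")

    annotation = annotation.set_index("probe_id")
    unknown = counts.index.difference(annotation.index)
    if len(unknown):
        raise SchemaError(f"probe {unknown[0]!r} has no annotation entry")
    annotation = annotation.loc[counts.index]

    meta = meta.set_index("sample_id")
    unknown = counts.columns.difference(meta.index)
    if len(unknown):
        raise SchemaError(f"sample {unknown[0]!r} has no metadata entry")
    meta = meta.loc[counts.columns]
    meta["is_vehicle"] = meta["is_vehicle"].astype(bool)

    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if not np.allclose(values, np.round(values)):
            bad = counts.index[np.where(~np.isclose(values, np.round(values)))[0][0]]
            raise SchemaError(f"non-integer count at probe {bad!r}")
        counts = counts.round().astype(np.int64)
    mat = ExpressionMatrix(counts=counts, annotation=annotation, meta=meta)
    logger.info("loaded %d probes x %d samples", mat.n_probes, mat.n_samples)
    return mat


def write_counts(mat: ExpressionMatrix, counts_path, annotation_path, meta_path) -> None:
    mat.counts.to_csv(counts_path, sep="\t", index_label="probe_id")
    mat.annotation.to_csv(annotation_path, sep="\t", index_label="probe_id")
    mat.meta.to_csv(meta_path, sep="\t", index_label="sample_id")


def load_profile_database(path, chemical_of: dict[str, str] | None = None) -> ProfileDatabase:
    """Load a gene x treatment L2FC TSV as a ProfileDatabase."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return ProfileDatabase.from_frame(frame, chemical_of=chemical_of)


def write_profile_database(db: ProfileDatabase, path) -> None:
    db.to_frame().to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def filter_low_counts(mat: ExpressionMatrix, min_mean: float = 10) -> ExpressionMatrix:
    """Drop probes whose mean count across *all* samples is strictly below
    ``min_mean``. Idempotent; keeps the sample set unchanged."""
    if mat.n_probes == 0:
        raise ValueError("empty matrix")
    keep = mat.counts.mean(axis=1) >= min_mean
    if not keep.any():
        logger.warning("filter_low_counts removed every probe (min_mean=%g)", min_mean)
    return ExpressionMatrix(
        counts=mat.counts.loc[keep],
        annotation=mat.annotation.loc[keep],
        meta=mat.meta,
    )


def aggregate_isoforms(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Sum probe counts per gene_symbol, producing one row per gene.

    Per-sample totals are conserved exactly. The aggregated matrix uses the
    gene symbol as the probe id; the panel of the first contributing probe is
    retained.
    """
    genes = mat.annotation["gene_symbol"]
    summed = mat.counts.groupby(genes.to_numpy()).sum()
    summed.index.name = "probe_id"
    first_panel = mat.annotation.groupby(genes.to_numpy())["panel"].first()
    annotation = pd.DataFrame(
        {"gene_symbol": summed.index, "panel": first_panel.loc[summed.index]},
        index=summed.index,
    )
    return ExpressionMatrix(counts=summed, annotation=annotation, meta=mat.meta)


def compute_l2fc_profile(
    mat: ExpressionMatrix,
    treatment_samples: list[str],
    control_samples: list[str],
    pseudocount: float = 0.5,
    treatment_id: str = "",
    intensity_mode: bool = False,
) -> L2FCProfile:
    """Average log2 fold-change of treatment over control.

    In counts mode ``value(g) = log2((mean_t + pc) / (mean_c + pc))``.  With
    ``intensity_mode=True`` the input is assumed to already be on the log2
    scale and the profile is a plain difference of means (reference-database
    construction from normalized array intensities).
    """
    if not treatment_samples or not control_samples:
        raise ValueError("treatment and control sample lists must be non-empty")
    if set(treatment_samples) & set(control_samples):
        raise ValueError("treatment and control samples overlap")
    panels = set(mat.meta.loc[list(treatment_samples) + list(control_samples), "panel"])
    if len(panels) > 1:
        raise ValueError(f"samples span multiple panels: {sorted(panels)}")

    mean_t = mat.counts[list(treatment_samples)].mean(axis=1)
    mean_c = mat.counts[list(control_samples)].mean(axis=1)
    if intensity_mode:
        values = mean_t - mean_c
    else:
        if pseudocount == 0 and (mean_c == 0).any():
            raise ValueError(
                "control mean of zero with pseudocount=0; use a positive pseudocount"
            )
        values = np.log2(mean_t + pseudocount) - np.log2(mean_c + pseudocount)
    values.index = mat.annotation["gene_symbol"].to_numpy()
    if values.index.has_duplicates:
        raise ValueError(
            "profile indexed by non-unique gene symbols; aggregate isoforms or "
            "collapse probes first"
        )
    return L2FCProfile(
        treatment_id=treatment_id or "-".join(treatment_samples),
        values=values.astype(float),
        platform=panels.pop(),
    )


def collapse_probes_to_genes(
    probe_values: pd.Series, annotation: pd.DataFrame, rule: str = "mean"
) -> pd.Series:
    """Collapse a probe-indexed L2FC vector to one value per gene.

    ``rule='mean'`` averages probe values; ``rule='max_abs'`` keeps the value
    of largest magnitude (sign preserved).
    """
    if rule not in ("mean", "max_abs"):
        raise ValueError(f"unknown collapse rule {rule!r}")
    genes = annotation.loc[probe_values.index, "gene_symbol"]
    grouped = probe_values.groupby(genes.to_numpy())
    if rule == "mean":
        out = grouped.mean()
    else:
        out = grouped.apply(lambda s: s.iloc[int(np.argmax(np.abs(s.to_numpy())))])
    out.index.name = "gene_symbol"
    return out


def relative_viability(lum_treatment, lum_vehicle) -> float:
    """Mean treatment luminescence as a percentage of mean vehicle luminescence."""
    t = np.asarray(lum_treatment, dtype=float)
    v = np.asarray(lum_vehicle, dtype=float)
    if t.size == 0 or v.size == 0:
        raise ValueError("empty luminescence input")
    if v.mean() <= 0:
        raise ValueError("vehicle mean must be positive")
    return 100.0 * t.mean() / v.mean()
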