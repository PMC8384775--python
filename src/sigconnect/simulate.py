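"""Synthetic data generator emulating the study design the pipeline expects.

Structure produced:

* a WT-like gene universe partitioned into mechanism *programs* plus
  background, with hallmark-style gene sets aligned to the programs;
* negative-binomial counts for 14 chemicals x 2 concentrations + vehicle,
  in triplicate wells across 2 batches, with per-gene batch effects,
  lognormal library sizes and extra dropout tuned so per-sample zero
  fractions land in a 15-40% band;
* a surrogate (ST-like) panel stratified over programs and nested in the
  whole (WT-like) panel;
* a reference L2FC database containing the same chemicals at three
  concentrations plus decoy chemicals, with configurable noise, a slightly
  reduced gene universe, and a ground-truth answer key.

Every generator is deterministic under its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, L2FCProfile, ProfileDatabase, make_treatment_id
from .gsea import GeneSetCollection

logger = logging.getLogger(__name__)

QUERY_CONC_UM = (10.0, 50.0)  # low:high = 1:5
REF_CONC_UM = (10.0, 50.0, 250.0)  # 1:5:25


@dataclass
class GeneratorConfig:
    n_genes_wt: int = 20000
    surrogate_fraction: float = 0.12
    n_programs: int = 8
    program_size: int = 100
    n_chemicals: int = 14
    n_concentrations: int = 2
    effect_ratio: float = 5.0
    n_decoy_chemicals: int = 20
    replicates: int = 3
    batches: int = 2
    programs_per_chemical: int = 3
    loading_scale: float = 2.0
    loading_sd: float = 0.4
    dense_effect_sd: float = 0.3  # chemical-specific dense fingerprint (log2)
    baseline_log_mean: float = 1.0  # natural-log scale of lognormal baseline means
    baseline_log_sd: float = 1.8
    program_baseline_boost: float = 3.0  # program genes are well-expressed (log-scale)
    nb_dispersion: float = 0.08
    batch_sd: float = 0.25  # log2 multiplicative per (gene, batch)
    libsize_sd: float = 0.2
    st_depth_boost: float = 1.2  # per-probe depth gain of the surrogate assay
    zero_fraction_band: tuple = (0.15, 0.40)  # calibration target per sample
    dropout: float = 0.06
    program_core_fraction: float = 0.5  # of each program carried into the panel
    set_jitter: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_programs * self.program_size > self.n_genes_wt:
            raise ValueError("programs do not fit in the gene universe")
        for name in ("n_genes_wt", "n_programs", "program_size", "n_chemicals",
                     "replicates", "batches"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def concentration_scale(self, conc_uM: float) -> float:
        """Effect multiplier: 1.0 at the high query concentration, scaling
        linearly with concentration (the 1:5 design)."""
        return conc_uM / QUERY_CONC_UM[-1]


@dataclass
class GroundTruth:
    genes: pd.Index
    program_of: pd.Series  # gene -> program index, -1 for background
    loadings: pd.DataFrame  # chemicals x programs, signed effects
    dense: pd.DataFrame  # genes x chemicals, small dense chemical fingerprints
    baseline: pd.Series  # gene -> baseline mean count
    chemicals: list[str] = field(default_factory=list)

    def l2fc(self, chemical: str, conc_scale: float) -> pd.Series:
        """True L2FC vector for a chemical at a concentration scale."""
        effect = self.dense[chemical].copy()
        for program, loading in self.loadings.loc[chemical].items():
            effect[self.program_of == program] += loading
        return conc_scale * effect


def _gene_names(n: int) -> pd.Index:
    return pd.Index([f"G{i:05d}" for i in range(1, n + 1)], name="gene")


def make_universe(
    cfg: GeneratorConfig, seed: int | None = None
) -> tuple[pd.DataFrame, GroundTruth, GeneSetCollection]:
    """Gene universe with program structure, chemical loadings and gene sets."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    genes = _gene_names(cfg.n_genes_wt)

    program_of = pd.Series(-1, index=genes, name="program")
    shuffled = rng.permutation(cfg.n_genes_wt)
    for p in range(cfg.n_programs):
        members = shuffled[p * cfg.program_size : (p + 1) * cfg.program_size]
        program_of.iloc[members] = p

    chemicals = [f"cmpd-{i:02d}" for i in range(1, cfg.n_chemicals + 1)]
    loadings = pd.DataFrame(0.0, index=chemicals, columns=range(cfg.n_programs))
    seen: set[tuple] = set()
    for chem in chemicals:
        # rejection-sample a distinct signed program combination per chemical
        while True:
            chosen = tuple(sorted(rng.choice(cfg.n_programs,
                                             size=cfg.programs_per_chemical,
                                             replace=False)))
            signs = tuple(rng.choice([-1.0, 1.0], size=cfg.programs_per_chemical))
            if (chosen, signs) not in seen:
                seen.add((chosen, signs))
                break
        magnitudes = cfg.loading_scale + cfg.loading_sd * rng.standard_normal(len(chosen))
        for program, sign, magnitude in zip(chosen, signs, magnitudes):
            loadings.loc[chem, program] = sign * abs(magnitude)

    dense = pd.DataFrame(
        cfg.dense_effect_sd * rng.standard_normal((cfg.n_genes_wt, cfg.n_chemicals)),
        index=genes, columns=chemicals,
    )
    log_baseline = cfg.baseline_log_mean + cfg.baseline_log_sd * rng.standard_normal(
        cfg.n_genes_wt
    )
    log_baseline[(program_of >= 0).to_numpy()] += cfg.program_baseline_boost
    baseline = pd.Series(np.exp(log_baseline), index=genes, name="baseline")
    truth = GroundTruth(
        genes=genes, program_of=program_of, loadings=loadings,
        dense=dense, baseline=baseline, chemicals=chemicals,
    )

    sets: dict[str, set[str]] = {}
    background = genes[program_of == -1]
    for p in range(cfg.n_programs):
        core = list(genes[program_of == p])
        n_swap = int(round(cfg.set_jitter * len(core)))
        members = set(core)
        if n_swap:
            out = rng.choice(len(core), size=n_swap, replace=False)
            dropped = {core[i] for i in out}
            added = rng.choice(background, size=n_swap, replace=False)
            members = (members - dropped) | set(added)
        sets[f"PROGRAM_{p}"] = members
    for i in range(3):  # deliberately tiny sets to exercise size flags
        sets[f"TINY_{i}"] = set(rng.choice(background, size=8, replace=False))
    for i in range(4):  # off-program decoy sets
        sets[f"DECOY_SET_{i}"] = set(rng.choice(background, size=60, replace=False))

    annotation = pd.DataFrame(
        {"gene_symbol": genes, "panel": "WT", "program": program_of.to_numpy()},
        index=genes.rename("probe_id"),
    )
    collection = GeneSetCollection(sets=sets, source="synthetic-programs")
    return annotation, truth, collection


def make_surrogate_panel(truth: GroundTruth, cfg: GeneratorConfig,
                         seed: int | None = None) -> pd.Index:
    """Stratified surrogate panel: a fixed share of every program core plus
    well-expressed background fill, nested in the WT universe."""
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 104729)
    chosen: list[str] = []
    for p in range(cfg.n_programs):
        core = list(truth.genes[truth.program_of == p])
        n_keep = max(min(15, len(core)), int(round(cfg.program_core_fraction * len(core))))
        keep = rng.choice(core, size=min(n_keep, len(core)), replace=False)
        chosen.extend(keep)
    target = int(round(cfg.surrogate_fraction * len(truth.genes)))
    remaining = truth.genes[~truth.genes.isin(set(chosen))]
    n_fill = max(0, target - len(chosen))
    if n_fill:
        fill = rng.choice(remaining, size=min(n_fill, len(remaining)), replace=False)
        chosen.extend(fill)
    panel = truth.genes[truth.genes.isin(set(chosen))]
    logger.info("surrogate panel: %d of %d genes", len(panel), len(truth.genes))
    return panel


def _sample_frame(cfg: GeneratorConfig, truth: GroundTruth, panel_name: str) -> pd.DataFrame:
    rows = []
    for batch in range(1, cfg.batches + 1):
        for rep in range(1, cfg.replicates + 1):
            rows.append({"sample_id": f"vehicle_b{batch}_r{rep}_{panel_name}",
                         "chemical": "vehicle", "concentration_uM": 0.0,
                         "batch": batch, "replicate": rep, "panel": panel_name,
                         "is_vehicle": True})
            for chem in truth.chemicals:
                for conc in QUERY_CONC_UM[: cfg.n_concentrations]:
                    rows.append({
                        "sample_id": f"{chem}_{conc:g}uM_b{batch}_r{rep}_{panel_name}",
                        "chemical": chem, "concentration_uM": conc,
                        "batch": batch, "replicate": rep, "panel": panel_name,
                        "is_vehicle": False,
                    })
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_counts(
    cfg: GeneratorConfig,
    truth: GroundTruth,
    panel: pd.Index | None = None,
    panel_name: str = "WT",
    seed: int | None = None,
) -> ExpressionMatrix:
    """Negative-binomial counts for one assay panel.

    ``mean = baseline * 2^L2FC(treatment) * 2^batch_effect * library_size``;
    counts are gamma-Poisson draws followed by Bernoulli dropout. The ST-like
    assay is produced by passing the surrogate panel, which re-draws counts
    with its own (boosted per-probe) library sizes.
    """
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 7919)
    genes = truth.genes if panel is None else panel
    baseline = truth.baseline[genes].to_numpy()
    meta = _sample_frame(cfg, truth, panel_name)

    batch_fx = {
        b: np.zeros(len(genes)) if b == 1
        else cfg.batch_sd * rng.standard_normal(len(genes))
        for b in range(1, cfg.batches + 1)
    }
    depth = cfg.st_depth_boost if panel is not None else 1.0
    l2fc_cache: dict[tuple[str, float], np.ndarray] = {}
    columns = {}
    for sample_id, row in meta.iterrows():
        if row["is_vehicle"]:
            fold = np.ones(len(genes))
        else:
            key = (row["chemical"], row["concentration_uM"])
            if key not in l2fc_cache:
                scale = cfg.concentration_scale(row["concentration_uM"])
                l2fc_cache[key] = truth.l2fc(row["chemical"], scale)[genes].to_numpy()
            fold = 2.0 ** l2fc_cache[key]
        lib = depth * np.exp(cfg.libsize_sd * rng.standard_normal())
        mean = baseline * fold * 2.0 ** batch_fx[row["batch"]] * lib
        r = 1.0 / cfg.nb_dispersion
        lam = rng.gamma(shape=r, scale=mean / r)
        counts = rng.poisson(lam)
        if cfg.dropout > 0:
            counts = counts * (rng.random(len(genes)) >= cfg.dropout)
        columns[sample_id] = counts
    counts = pd.DataFrame(columns, index=genes).astype(np.int64)
    counts.index.name = "probe_id"
    annotation = pd.DataFrame(
        {"gene_symbol": genes, "panel": panel_name}, index=genes.rename("probe_id")
    )
    meta = meta.copy()
    meta["panel"] = panel_name
    return ExpressionMatrix(counts=counts, annotation=annotation, meta=meta)


def build_reference_db(
    cfg: GeneratorConfig,
    truth: GroundTruth,
    noise_sd: float = 0.1,
    seed: int | None = None,
    gene_dropout: float = 0.05,
    conc_uM=REF_CONC_UM,
    study: str = "ref-db",
) -> tuple[ProfileDatabase, dict[str, str]]:
    """Reference L2FC database: real chemicals at three concentrations plus
    decoys, on a slightly reduced gene universe, with additive noise
    emulating an independent platform. Returns (database, answer key)."""
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 15485863)
    n_keep = int(round((1.0 - gene_dropout) * len(truth.genes)))
    kept = truth.genes[np.sort(rng.choice(len(truth.genes), size=n_keep, replace=False))]

    decoys = [f"decoy-{i:02d}" for i in range(1, cfg.n_decoy_chemicals + 1)]
    decoy_truth: dict[str, pd.Series] = {}
    for decoy in decoys:
        effect = pd.Series(
            cfg.dense_effect_sd * rng.standard_normal(len(truth.genes)),
            index=truth.genes,
        )
        programs = rng.choice(cfg.n_programs, size=cfg.programs_per_chemical, replace=False)
        for program in programs:
            loading = rng.choice([-1.0, 1.0]) * (
                cfg.loading_scale + cfg.loading_sd * rng.standard_normal()
            )
            effect[truth.program_of == program] += loading
        decoy_truth[decoy] = effect

    profiles: list[L2FCProfile] = []
    answer_key: dict[str, str] = {}
    for chem in truth.chemicals + decoys:
        for conc in conc_uM:
            scale = cfg.concentration_scale(conc)
            if chem in decoy_truth:
                values = scale * decoy_truth[chem][kept]
            else:
                values = truth.l2fc(chem, scale)[kept]
            if noise_sd > 0:
                values = values + noise_sd * rng.standard_normal(len(kept))
            tid = make_treatment_id(chem, conc, study=study)
            profiles.append(L2FCProfile(treatment_id=tid, values=values.astype(float),
                                        platform="reference"))
            answer_key[tid] = chem
    db = ProfileDatabase(profiles=profiles, chemical_of=dict(answer_key))
    return db, answer_key


# ---------------------------------------------------------------------------
# direct NES-matrix simulation (for clustering-level tests)
# ---------------------------------------------------------------------------


def simulate_nes_matrix(
    n_sets: int = 50,
    per_cluster: tuple[int, int, int] = (10, 10, 8),
    delta: float = 3.0,
    n_discriminating: int = 5,
    n_markers_c: int = 5,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """NES matrix with three planted treatment archetypes.

    Archetypes A and B differ by ``delta`` mean NES on ``n_discriminating``
    sets (A positive, B negative); archetype C carries its own marker block
    and sits at zero on the discriminating sets. Returns (matrix, archetype
    labels, names of the planted discriminating sets).
    """
    if n_discriminating + n_markers_c > n_sets:
        raise ValueError("planted blocks exceed n_sets")
    rng = np.random.default_rng(seed)
    set_names = [f"SET_{i:02d}" for i in range(n_sets)]
    columns, labels = [], []
    for archetype, count in zip("ABC", per_cluster):
        for j in range(count):
            columns.append(f"{archetype}{j + 1}")
            labels.append(archetype)
    means = pd.DataFrame(0.0, index=set_names, columns=columns)
    discriminating = set_names[:n_discriminating]
    markers_c = set_names[n_discriminating : n_discriminating + n_markers_c]
    for col, archetype in zip(columns, labels):
        if archetype == "A":
            means.loc[discriminating, col] = delta / 2.0
        elif archetype == "B":
            means.loc[discriminating, col] = -delta / 2.0
        else:
            means.loc[markers_c, col] = delta
    nes = means + noise_sd * rng.standard_normal(means.shape)
    return nes, pd.Series(labels, index=columns, name="archetype"), discriminating
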