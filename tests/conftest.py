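import numpy as np
import pandas as pd
import pytest

from sigconnect.expression import ExpressionMatrix


def build_matrix(counts, probe_ids=None, gene_symbols=None, meta=None, panel="WT"):
    """Assemble a valid ExpressionMatrix from a plain array for tests."""
    counts = np.asarray(counts)
    n_probes, n_samples = counts.shape
    probe_ids = probe_ids or [f"p{i}" for i in range(1, n_probes + 1)]
    gene_symbols = gene_symbols or [f"g{i}" for i in range(1, n_probes + 1)]
    frame = pd.DataFrame(
        counts.astype(np.int64),
        index=pd.Index(probe_ids, name="probe_id"),
        columns=[f"s{i}" for i in range(1, n_samples + 1)] if meta is None else meta["sample_id"],
    )
    annotation = pd.DataFrame(
        {"gene_symbol": gene_symbols, "panel": panel},
        index=frame.index,
    )
    if meta is None:
        rows = []
        for i in range(n_samples):
            rows.append(
                {"sample_id": f"s{i + 1}", "chemical": "chem",
                 "concentration_uM": 1.0, "batch": i // 3 + 1,
                 "replicate": i % 3 + 1, "panel": panel, "is_vehicle": False}
            )
        meta = pd.DataFrame(rows)
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    return ExpressionMatrix(counts=frame, annotation=annotation, meta=meta.loc[frame.columns])


def replicate_meta(chemicals, batches=(1, 2), replicates=(1, 2, 3), panel="WT",
                   concentration=1.0):
    """Metadata grid of treatment triplicates (plus vehicle when listed)."""
    rows = []
    for chem in chemicals:
        vehicle = chem == "vehicle"
        for batch in batches:
            for rep in replicates:
                rows.append(
                    {"sample_id": f"{chem}_b{batch}_r{rep}",
                     "chemical": chem,
                     "concentration_uM": 0.0 if vehicle else concentration,
                     "batch": batch, "replicate": rep, "panel": panel,
                     "is_vehicle": vehicle}
                )
    return pd.DataFrame(rows)


@pytest.fixture
def toy_matrix():
    return build_matrix([[3, 4], [1, 0], [5, 5]])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
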