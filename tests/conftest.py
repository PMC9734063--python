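import numpy as np
import pandas as pd
import pytest

from regionomics import simdata
from regionomics.containers import CountMatrix


@pytest.fixture(scope="session")
def small_bulk():
    """Two-region bulk dataset with one 20-gene module planted in R01."""
    module = simdata.PlantedModule(
        "m1", tuple(f"g{i + 1:05d}" for i in range(20)), {"R01": 1.0}
    )
    cfg = simdata.BulkSimConfig(
        n_regions=2, n_genes=300, n_replicates=4, modules=(module,), seed=11
    )
    return simdata.simulate_bulk(cfg), module


@pytest.fixture(scope="session")
def planted_sc():
    """Single-cell sim with one planted effect of every kind (6 types)."""
    module_genes = tuple(f"g{i + 1:05d}" for i in range(200, 230))
    cfg = simdata.ScSimConfig(
        n_genes=800,
        n_types=6,
        n_replicates=5,
        cells_per_replicate=120,
        proportion_shift={"type03": 2.0},
        module_shift=simdata.ModuleShift(module_genes, "type01", 1.0),
        regulon_shift=simdata.RegulonShift(
            "g00231", tuple(f"g{i + 1:05d}" for i in range(231, 261)), "type01", 1.0
        ),
        lr_shift=simdata.LREdgeShift("g00011", "g00031", "type01", "type02", 1.0),
        seed=9,
    )
    return simdata.simulate_scrna(cfg), cfg


@pytest.fixture(scope="session")
def normalized_sc(planted_sc):
    """QC'd, normalized AnnData of the planted sim (both conditions)."""
    import anndata as ad

    from regionomics import scpipe

    sim, cfg = planted_sc
    adata = ad.concat([sim.sham, sim.treated], join="outer", merge="same")
    adata = scpipe.qc_and_normalize(adata, min_genes=200, max_mito=0.2)
    return adata


def make_count_matrix(counts: np.ndarray, n_sham: int, n_treated: int, region="R01"):
    """Wrap a raw array as a CountMatrix with sham columns first."""
    n = n_sham + n_treated
    cols = [f"s{i + 1}" for i in range(n)]
    conditions = ["sham"] * n_sham + ["treated"] * n_treated
    meta = pd.DataFrame(
        {
            "region": region,
            "condition": conditions,
            "replicate": [f"r{i + 1}" for i in range(n)],
        },
        index=pd.Index(cols, name="sample_id"),
    )
    df = pd.DataFrame(
        counts, index=[f"g{i + 1}" for i in range(counts.shape[0])], columns=cols
    )
    return CountMatrix(df, meta)
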