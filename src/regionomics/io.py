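"""Readers and writers for the plain-text formats the pipeline exchanges.

Counts travel as TSV (features x samples) next to a sample-metadata TSV;
single-cell counts as MatrixMarket triplets with barcode/feature sidecars;
intervals as 4-column BED (0-based half-open); gene sets as GMT.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from regionomics.containers import CountMatrix

FLOAT_FMT = "%.6g"


def write_counts_tsv(cm: CountMatrix, counts_path: str, meta_path: str) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="feature_id")
    cm.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")


def read_counts_tsv(counts_path: str, meta_path: str) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="feature_id")
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
    meta["replicate"] = meta["replicate"].astype(str)
    return CountMatrix(counts, meta)


def write_table(df: pd.DataFrame, path: str, index_label: str | None = None) -> None:
    """Write an analysis table with stable column order and 6-sig-digit floats."""
    df.to_csv(
        path,
        sep="\t",
        index=index_label is not None,
        index_label=index_label,
        float_format=FLOAT_FMT,
    )


def read_table(path: str, index_col: str | None = None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_bed(intervals: pd.DataFrame, path: str) -> None:
    """4-column BED: chrom, start, end, name; 0-based half-open."""
    intervals[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path: str) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "name"]
    )
    if (df["end"] <= df["start"]).any():
        raise ValueError("malformed BED interval: end <= start")
    return df


def write_tss(tss: pd.DataFrame, path: str) -> None:
    """BED-like TSS table: chrom, pos, strand, gene_id."""
    tss[["chrom", "pos", "strand", "gene_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_tss(path: str) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "pos", "strand", "gene_id"]
    )


def write_gmt(sets: Mapping[str, list], path: str, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sets:
            members = "\t".join(str(m) for m in sets[name])
            fh.write(f"{name}\t{description}\t{members}\n")


def read_gmt(path: str) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [p for p in parts[2:] if p]
    return sets


def write_lr_catalogue(pairs: pd.DataFrame, path: str) -> None:
    pairs[["ligand", "receptor"]].to_csv(path, sep="\t", index=False)


def read_lr_catalogue(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"ligand", "receptor"} <= set(df.columns):
        raise ValueError("ligand-receptor catalogue needs ligand/receptor columns")
    return df


def write_mtx_dir(adata, outdir: str) -> None:
    """10x-style triplet directory: matrix.mtx (genes x cells), features/barcodes."""
    os.makedirs(outdir, exist_ok=True)
    x = adata.X
    if not sp.issparse(x):
        x = sp.csr_matrix(x)
    scipy.io.mmwrite(os.path.join(outdir, "matrix.mtx"), x.T.astype(np.int64))
    pd.Series(adata.var_names).to_csv(
        os.path.join(outdir, "features.tsv"), sep="\t", header=False, index=False
    )
    pd.Series(adata.obs_names).to_csv(
        os.path.join(outdir, "barcodes.tsv"), sep="\t", header=False, index=False
    )
    adata.obs.to_csv(os.path.join(outdir, "cell_meta.tsv"), sep="\t", index_label="cell_id")


def read_mtx_dir(indir: str):
    import anndata as ad

    x = scipy.io.mmread(os.path.join(indir, "matrix.mtx")).tocsr().T.tocsr()
    var = pd.read_csv(
        os.path.join(indir, "features.tsv"), sep="\t", header=None
    )[0].astype(str)
    obs_names = pd.read_csv(
        os.path.join(indir, "barcodes.tsv"), sep="\t", header=None
    )[0].astype(str)
    obs = pd.read_csv(os.path.join(indir, "cell_meta.tsv"), sep="\t", index_col="cell_id")
    obs.index = obs.index.astype(str)
    obs = obs.loc[obs_names]
    obs["replicate"] = obs["replicate"].astype(str)
    adata = ad.AnnData(X=x.astype(np.float64), obs=obs)
    adata.var_names = list(var)
    return adata
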