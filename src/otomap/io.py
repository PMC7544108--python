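"""Readers and writers for the pipeline's plain-text formats.

Summary statistics, gene models, loops and dosage tables are TSV;
peak sets are BED3 (+ name); chain maps use the UCSC chain format
(see :mod:`otomap.chromatin`); UMI counts are MatrixMarket triplets with
genes/barcodes sidecar TSVs. Generated files carry ``# key=value`` header
comments recording the seed and stage.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .chromatin import BED_COLUMNS, PeakSet


def _write_tsv(df: pd.DataFrame, path, header_meta: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in (header_meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_sumstats(df: pd.DataFrame, path, seed: int | None = None, stage: str = "sumstats"):
    meta = {} if seed is None else {"seed": seed, "stage": stage}
    _write_tsv(df, path, meta)


def read_sumstats(path) -> pd.DataFrame:
    df = _read_tsv(path)
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_bed(peaks: PeakSet, path) -> None:
    cols = BED_COLUMNS + (["name"] if "name" in peaks.df.columns else [])
    peaks.df[cols].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path) -> PeakSet:
    df = pd.read_csv(path, sep="\t", header=None)
    df.columns = (BED_COLUMNS + ["name"] + [f"extra{i}" for i in range(len(df.columns))])[
        : len(df.columns)
    ]
    return PeakSet(df)


def write_genes(genes: pd.DataFrame, path) -> None:
    _write_tsv(genes, path)


def read_genes(path) -> pd.DataFrame:
    df = _read_tsv(path)
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_loops(loops: pd.DataFrame, path) -> None:
    _write_tsv(loops, path)


def read_loops(path) -> pd.DataFrame:
    df = _read_tsv(path)
    for c in ("chromA", "chromB"):
        df[c] = df[c].astype(str)
    return df


def write_dosages(dosages: pd.DataFrame, path) -> None:
    """Transposed dosage TSV: rows = SNPs, columns = individuals."""
    dosages.T.to_csv(path, sep="\t", index_label="id")


def read_dosages(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="id").T
    df.columns.name = None
    return df


def write_counts_mtx(adata, prefix) -> None:
    """MTX + genes/barcodes TSV triplet (genes x cells orientation)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    X = sparse.csr_matrix(np.asarray(adata.X).T)  # genes x cells
    spio.mmwrite(str(prefix) + ".mtx", X, field="integer")
    genes = pd.DataFrame({"gene": adata.var_names, "mito": adata.var["mito"].astype(int)})
    genes.to_csv(str(prefix) + ".genes.tsv", sep="\t", index=False)
    pd.DataFrame({"barcode": adata.obs_names}).to_csv(
        str(prefix) + ".barcodes.tsv", sep="\t", index=False
    )


def read_counts_mtx(prefix):
    import anndata as ad

    X = spio.mmread(str(Path(prefix)) + ".mtx").toarray().T  # cells x genes
    genes = pd.read_csv(str(prefix) + ".genes.tsv", sep="\t")
    barcodes = pd.read_csv(str(prefix) + ".barcodes.tsv", sep="\t")
    return ad.AnnData(
        X=X.astype(float),
        obs=pd.DataFrame(index=barcodes["barcode"].astype(str)),
        var=pd.DataFrame(
            {"mito": genes["mito"].astype(bool).to_numpy()}, index=genes["gene"].astype(str)
        ),
    )
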