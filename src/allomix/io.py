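"""Reading and writing the pipeline's on-disk formats.

Count matrices travel as 10x-style Matrix Market triples
(``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``); tag counts,
whitelists, annotations, classification calls and ground truth as plain
CSV/TSV.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "write_10x",
    "read_10x",
    "write_tag_counts",
    "read_tag_counts",
    "write_whitelist",
    "read_whitelist",
    "read_calls",
]


def write_10x(adata: ad.AnnData, outdir: str | Path) -> Path:
    """Write genes x cells MTX with feature/barcode TSVs (uncompressed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    spio.mmwrite(str(outdir / "matrix.mtx"), X.T.tocoo())
    pd.DataFrame(
        {"gene_id": adata.var_names, "gene_name": adata.var_names}
    ).to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )
    if len(adata.obs.columns):
        adata.obs.to_csv(outdir / "ground_truth.csv")
    return outdir


def read_10x(indir: str | Path) -> ad.AnnData:
    """Read a 10x-style MTX directory into cells x genes AnnData."""
    indir = Path(indir)
    mtx = indir / "matrix.mtx"
    if not mtx.exists():
        raise FileNotFoundError(f"{mtx} not found")
    try:
        X = spio.mmread(str(mtx)).tocsr().T.tocsr()
    except Exception as exc:  # pragma: no cover - malformed input path
        raise ValueError(f"malformed matrix file {mtx}: {exc}") from exc
    features = pd.read_csv(indir / "features.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)
    adata = ad.AnnData(X=X.astype(np.int32))
    adata.var_names = features[0].astype(str).tolist()
    adata.obs_names = barcodes[0].astype(str).tolist()
    truth = indir / "ground_truth.csv"
    if truth.exists():
        obs = pd.read_csv(truth, index_col=0)
        adata.obs = obs.loc[adata.obs_names]
    return adata


def write_tag_counts(tags: pd.DataFrame, path: str | Path) -> None:
    tags.to_csv(path)


def read_tag_counts(path: str | Path) -> pd.DataFrame:
    tags = pd.read_csv(path, index_col=0)
    tags.index.name = "tag"
    return tags


def write_whitelist(entries: list[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(entries, columns=["donor", "sequence"]).to_csv(path, index=False)


def read_whitelist(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path)
    if not {"donor", "sequence"} <= set(df.columns):
        raise ValueError(f"whitelist {path} needs 'donor' and 'sequence' columns")
    return list(df[["donor", "sequence"]].itertuples(index=False, name=None))


def read_calls(path: str | Path) -> pd.Series:
    """External per-cell donor calls: CSV with columns cell, donor."""
    df = pd.read_csv(path)
    if not {"cell", "donor"} <= set(df.columns):
        raise ValueError(f"calls file {path} needs 'cell' and 'donor' columns")
    return pd.Series(df["donor"].to_numpy(), index=df["cell"], name="call")
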