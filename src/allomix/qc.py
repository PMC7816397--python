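"""Quality control, normalization, embedding and marker-based annotation.

The QC contract is deliberately simple: discard cells with fewer than 250
transcript UMIs, then genes with fewer than 3 UMIs across the retained
cells.  Counts are depth-scaled to the median cell total and
log2(x+1)-transformed; per-gene centering/scaling is applied only as
input to dimensionality reduction.  Cell types are assigned per cluster
by the marker gene with the highest cluster-mean z-score; CD4 T cells
are sub-labelled into naive / memory / activated states from the
SELL / S100A4 / GPR183 high-low patterns, with "high" meaning above the
gene's median across CD4 cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
from sklearn.cluster import KMeans

__all__ = [
    "QCParams",
    "MarkerRuleSet",
    "filter_counts",
    "normalize_log",
    "embed2d",
    "annotate",
]


@dataclass(frozen=True)
class QCParams:
    min_cell_umis: int = 250
    min_gene_umis: int = 3

    def __post_init__(self) -> None:
        if self.min_cell_umis <= 0 or self.min_gene_umis <= 0:
            raise ValueError("QC thresholds must be positive")


@dataclass(frozen=True)
class MarkerRuleSet:
    """Marker genes per cell type plus CD4-subtype high/low triples."""

    celltype: dict[str, list[str]] = field(
        default_factory=lambda: {
            "B": ["MS4A1"],
            "CD14 Monocyte": ["CD14"],
            "CD16 Monocyte": ["FCGR3A"],
            "CD4 T": ["IL7R"],
            "CD8 T": ["CD8A"],
            "NK": ["SPON2"],
        }
    )
    cd4_subtype: dict[str, dict[str, str]] = field(
        default_factory=lambda: {
            "activated": {"SELL": "high", "S100A4": "low", "GPR183": "high"},
            "memory": {"SELL": "low", "S100A4": "high", "GPR183": "high"},
            "naive": {"SELL": "high", "S100A4": "low", "GPR183": "low"},
        }
    )
    cd4_label: str = "CD4 T"

    def bind(self, genes: pd.Index) -> None:
        """Validate that every referenced gene exists in the matrix."""
        wanted = {g for gs in self.celltype.values() for g in gs}
        wanted |= {g for rule in self.cd4_subtype.values() for g in rule}
        missing = sorted(wanted - set(genes))
        if missing:
            raise KeyError(f"marker genes absent from matrix: {missing}")


def filter_counts(adata: ad.AnnData, params: QCParams = QCParams()) -> ad.AnnData:
    """Remove low-depth cells, then low-count genes.

    Cells with total UMIs below ``min_cell_umis`` go first; genes whose
    total over the *retained* cells falls below ``min_gene_umis`` go
    second.  The number removed at each step is recorded in
    ``uns['qc_report']``.  Applying the filter twice removes nothing
    further (gene removal cannot push a surviving cell below a total it
    already met — totals are computed once per step — so the operation is
    idempotent on its own output only in terms of dimensions; a repeat
    run re-checks both axes).
    """
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("empty matrix")
    out = adata.copy()
    n_cells0, n_genes0 = out.shape
    cell_totals = np.asarray(out.X.sum(axis=1)).ravel()
    out = out[cell_totals >= params.min_cell_umis].copy()
    gene_totals = np.asarray(out.X.sum(axis=0)).ravel()
    out = out[:, gene_totals >= params.min_gene_umis].copy()
    if out.n_obs == 0 or out.n_vars == 0:
        raise ValueError("QC filtering removed all cells or genes")
    out.uns["qc_report"] = {
        "cells_removed": int(n_cells0 - out.n_obs),
        "genes_removed": int(n_genes0 - out.n_vars),
        "min_cell_umis": params.min_cell_umis,
        "min_gene_umis": params.min_gene_umis,
    }
    return out


def normalize_log(adata: ad.AnnData) -> ad.AnnData:
    """Depth-scale each cell to the median total, then log2(x+1).

    Raw counts are preserved in ``layers['counts']``.
    """
    out = adata.copy()
    out.layers["counts"] = out.X.copy()
    sc.pp.normalize_total(out, target_sum=None)
    sc.pp.log1p(out, base=2)
    return out


def embed2d(
    adata: ad.AnnData,
    seed: int = 0,
    backend: str = "pca",
    n_comps: int = 30,
) -> np.ndarray:
    """Two-dimensional embedding of normalized expression.

    Genes are centered and scaled, principal components computed, and
    either the first two PCs returned directly (``backend='pca'``, fully
    deterministic) or passed through UMAP (``backend='umap'``).  Stored
    in ``obsm['X_embed2d']``.
    """
    if adata.n_obs < 20:
        raise ValueError("need at least 20 cells to embed")
    n_comps = min(n_comps, adata.n_obs - 1, adata.n_vars - 1)
    if n_comps < 2:
        raise ValueError("matrix too small for a 2-D embedding")
    work = adata.copy()
    sc.pp.scale(work, max_value=10)
    sc.tl.pca(work, n_comps=n_comps, svd_solver="arpack", random_state=seed)
    if backend == "pca":
        coords = np.asarray(work.obsm["X_pca"][:, :2], dtype=float)
    elif backend == "umap":
        sc.pp.neighbors(work, use_rep="X_pca", random_state=seed)
        sc.tl.umap(work, random_state=seed)
        coords = np.asarray(work.obsm["X_umap"], dtype=float)
    else:
        raise ValueError(f"unknown embedding backend {backend!r}")
    adata.obsm["X_embed2d"] = coords
    adata.obsm["X_pca"] = work.obsm["X_pca"]
    return coords


def _dense(adata: ad.AnnData) -> np.ndarray:
    X = adata.X
    return np.asarray(X.todense()) if not isinstance(X, np.ndarray) else X


def annotate(
    adata: ad.AnnData,
    rules: MarkerRuleSet = MarkerRuleSet(),
    clusters: pd.Series | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Cluster cells and assign cell types (and CD4 subtypes) by markers.

    When no cluster labels are supplied, cells are clustered by k-means
    on the principal components, with k equal to the number of cell-type
    rules.  Each cluster receives the cell type whose marker gene has the
    highest cluster-mean z-score; clusters in which every marker is
    entirely unexpressed are labelled ``unassigned``.  Ties break
    alphabetically with a warning.

    Cells typed as CD4 T are sub-clustered on the z-scored subtype genes
    and each sub-cluster mapped to the subtype rule it matches best
    (fewest high/low mismatches; "high" = above the per-gene median over
    CD4 cells).

    Returns a DataFrame (cell, cluster, cell_type, cd4_subtype) and
    stores the columns in ``adata.obs`` with a ``pred_`` prefix.
    """
    rules.bind(adata.var_names)
    X = _dense(adata)
    genes = pd.Index(adata.var_names)

    if clusters is None:
        if "X_pca" not in adata.obsm:
            embed2d(adata, seed=seed)
        k = len(rules.celltype)
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        clusters = pd.Series(
            km.fit_predict(adata.obsm["X_pca"]), index=adata.obs_names,
            name="cluster",
        )
    else:
        clusters = clusters.reindex(adata.obs_names)
        if clusters.isna().any():
            raise ValueError("cluster labels missing for some cells")

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    cluster_type: dict[object, str] = {}
    for cl in pd.unique(clusters):
        rows = (clusters == cl).to_numpy()
        scores: dict[str, float] = {}
        raw_max: dict[str, float] = {}
        for ct, markers in rules.celltype.items():
            cols = genes.get_indexer(markers)
            scores[ct] = float(Z[np.ix_(rows, cols)].mean())
            raw_max[ct] = float(X[np.ix_(rows, cols)].max())
        if max(raw_max.values()) == 0.0:
            cluster_type[cl] = "unassigned"
            continue
        best = max(scores.values())
        winners = sorted(ct for ct, s in scores.items() if s == best)
        if len(winners) > 1:
            warnings.warn(
                f"cluster {cl}: marker-score tie between {winners}; "
                "taking alphabetical first", stacklevel=2,
            )
        cluster_type[cl] = winners[0]

    cell_type = clusters.map(cluster_type)
    cd4_subtype = pd.Series("", index=adata.obs_names, name="cd4_subtype")
    cd4_mask = (cell_type == rules.cd4_label).to_numpy()
    if rules.cd4_subtype and cd4_mask.sum() >= len(rules.cd4_subtype) * 2:
        sub_genes = sorted({g for r in rules.cd4_subtype.values() for g in r})
        cols = genes.get_indexer(sub_genes)
        sub_X = X[np.ix_(cd4_mask, cols)]
        med = np.median(sub_X, axis=0)
        s_mu, s_sd = sub_X.mean(axis=0), sub_X.std(axis=0)
        s_sd[s_sd == 0] = 1.0
        km = KMeans(n_clusters=len(rules.cd4_subtype), n_init=10,
                    random_state=seed)
        sub_cl = km.fit_predict((sub_X - s_mu) / s_sd)
        labels = np.empty(len(sub_X), dtype=object)
        for cl in np.unique(sub_cl):
            rows = sub_cl == cl
            high = sub_X[rows].mean(axis=0) > med
            mismatches = {}
            for sub, rule in rules.cd4_subtype.items():
                want = np.array([rule[g] == "high" for g in sub_genes])
                mismatches[sub] = int((want != high).sum())
            best = min(mismatches.values())
            winners = sorted(s for s, m in mismatches.items() if m == best)
            labels[rows] = winners[0]
        cd4_subtype.iloc[np.flatnonzero(cd4_mask)] = labels

    result = pd.DataFrame(
        {
            "cluster": clusters.astype(str),
            "cell_type": cell_type,
            "cd4_subtype": cd4_subtype,
        },
        index=adata.obs_names,
    )
    adata.obs["pred_cluster"] = result["cluster"]
    adata.obs["pred_cell_type"] = result["cell_type"]
    adata.obs["pred_cd4_subtype"] = result["cd4_subtype"]
    return result
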