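"""Synthetic multi-donor PBMC scRNA-seq generator with sample-tag counts.

Emulates a donor-multiplexing experiment in which PBMCs from one reference
donor (donor A) are profiled alone and after pooling with PBMCs from
unrelated donors across four microfluidic lanes:

* lane 1 — donor A alone (unmixed),
* lane 2 — donors A-D pooled (mixed),
* lane 3 — donors A-H pooled (mixed),
* lane 4 — donor A alone again (technical replicate of lane 1).

Counts follow a Gamma-Poisson (negative binomial) law with a per-cell
log-normal size factor, cell-type marker structure, multiplicative
per-donor expression offsets, and an optional injected "alloreactivity"
signature restricted to mixed-lane cells of a target cell type.  Sample
tags are simulated per cell with cell-type-dependent capture efficiency so
that antibody-tag classification bias can be reproduced on demand.

Ground truth (donor, lane, mixing status, cell type, CD4 subtype,
effect flag) travels in ``AnnData.obs``; generative gene metadata in
``AnnData.var`` / ``uns`` so that counts for individual genes can be
re-drawn exactly (used by :func:`inject_allo_effect`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "AlloEffectSpec",
    "TagParams",
    "GeneratorConfig",
    "SyntheticData",
    "default_tag_whitelist",
    "generate_counts",
    "inject_allo_effect",
    "emit_tag_reads",
]

# Cell types simulated by default, with the canonical marker gene used by
# the annotation rules downstream.
CANONICAL_MARKERS = {
    "B": "MS4A1",
    "CD14 Monocyte": "CD14",
    "CD16 Monocyte": "FCGR3A",
    "CD4 T": "IL7R",
    "CD8 T": "CD8A",
    "NK": "SPON2",
}

DEFAULT_CELLTYPE_PROPORTIONS = {
    "CD4 T": 0.30,
    "CD8 T": 0.18,
    "CD14 Monocyte": 0.20,
    "CD16 Monocyte": 0.06,
    "NK": 0.13,
    "B": 0.13,
}

# CD4 subtype definitions: (SELL, S100A4, GPR183) high/low pattern.
CD4_SUBTYPE_PATTERNS = {
    "activated": {"SELL": "high", "S100A4": "low", "GPR183": "high"},
    "memory": {"SELL": "low", "S100A4": "high", "GPR183": "high"},
    "naive": {"SELL": "high", "S100A4": "low", "GPR183": "low"},
}
CD4_SUBTYPE_GENES = ("SELL", "S100A4", "GPR183")
DEFAULT_CD4_SUBTYPE_PROPORTIONS = {"naive": 0.45, "memory": 0.35, "activated": 0.20}

# Alloreactivity gene pool reserved in every simulated gene universe; the
# first entries are the literature markers of T-cell allo-activation.
ALLO_UP_POOL = ["IFNG", "CD40LG"] + [f"ALLOUP{i:02d}" for i in range(3, 26)]
ALLO_DOWN_POOL = ["DUSP1", "FOS"] + [f"ALLODN{i:02d}" for i in range(3, 26)]

DEFAULT_LANE_DESIGN = {
    1: frozenset("A"),
    2: frozenset("ABCD"),
    3: frozenset("ABCDEFGH"),
    4: frozenset("A"),
}


def default_tag_whitelist(donors: list[str], length: int = 8) -> list[tuple[str, str]]:
    """Barcode per donor built from homopolymer half-blocks.

    Two barcodes differ in at least one half-block, giving a minimum
    pairwise Hamming distance of ``length // 2`` — comfortably above the
    ``2 * radius`` bound required for unambiguous single-substitution
    correction at the default radius of 1.
    """
    if len(donors) > 16:
        raise ValueError("default whitelist supports at most 16 donors")
    if length % 2:
        raise ValueError("barcode length must be even")
    half = length // 2
    blocks = ["A" * half, "C" * half, "G" * half, "T" * half]
    entries = []
    for i, donor in enumerate(donors):
        entries.append((donor, blocks[i // 4] + blocks[i % 4]))
    return entries


@dataclass(frozen=True)
class AlloEffectSpec:
    """Injected alloreactivity signature for mixed-lane cells.

    Expected counts of ``up_genes`` are multiplied by ``fold_change_up``
    and those of ``down_genes`` divided by ``fold_change_down`` in a
    random ``affected_fraction`` of target cells.
    """

    up_genes: tuple[str, ...] = ("IFNG", "CD40LG")
    down_genes: tuple[str, ...] = ("DUSP1", "FOS")
    fold_change_up: float = 4.0
    fold_change_down: float = 4.0
    affected_fraction: float = 0.5
    target_celltype: str = "CD4 T"
    target_condition: str = "mixed-lanes-only"

    def __post_init__(self) -> None:
        if set(self.up_genes) & set(self.down_genes):
            raise ValueError("up_genes and down_genes must be disjoint")
        if not 0.0 <= self.affected_fraction <= 1.0:
            raise ValueError("affected_fraction must lie in [0, 1]")
        if self.fold_change_up <= 0 or self.fold_change_down <= 0:
            raise ValueError("fold changes must be positive")
        if self.target_condition != "mixed-lanes-only":
            raise ValueError("only 'mixed-lanes-only' targeting is supported")


@dataclass(frozen=True)
class TagParams:
    """Sample-tag read simulation parameters.

    ``capture_efficiency_by_celltype`` scales the read mass landing on a
    cell's own donor tag; depressing it for T/NK cells reproduces the
    classification bias seen with antibody-based tagging kits.
    ``sequencing_error_rate`` is a per-base substitution probability; at
    the count-matrix level an errored read is dropped, while
    :func:`emit_tag_reads` emits literal sequences with the substitutions
    applied.
    """

    tag_whitelist: tuple[tuple[str, str], ...] | None = None
    reads_per_cell_mean: float = 200.0
    background_fraction: float = 0.05
    capture_efficiency_by_celltype: dict[str, float] = field(default_factory=dict)
    sequencing_error_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_fraction < 1.0:
            raise ValueError("background_fraction must lie in [0, 1)")
        if self.reads_per_cell_mean <= 0:
            raise ValueError("reads_per_cell_mean must be positive")
        for ct, eff in self.capture_efficiency_by_celltype.items():
            if not 0.0 < eff <= 1.0:
                raise ValueError(f"capture efficiency for {ct!r} must be in (0, 1]")
        if not 0.0 <= self.sequencing_error_rate < 1.0:
            raise ValueError("sequencing_error_rate must lie in [0, 1)")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of one simulated multiplexing experiment."""

    n_genes: int = 400
    donors: tuple[str, ...] = tuple("ABCDEFGH")
    lane_design: dict[int, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_LANE_DESIGN)
    )
    cells_per_donor_per_lane: int = 1000
    celltype_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CELLTYPE_PROPORTIONS)
    )
    cd4_subtype_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CD4_SUBTYPE_PROPORTIONS)
    )
    n_marker_genes_per_type: int = 5
    marker_fold_change: float = 4.0
    donor_effect_sd: float = 0.25
    donor_effect_gene_fraction: float = 0.30
    dispersion: float = 10.0
    library_size_log_mean: float = float(np.log(2500.0))
    library_size_log_sd: float = 0.35
    allo_effect: AlloEffectSpec | None = None
    tag_params: TagParams = field(default_factory=TagParams)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.celltype_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"celltype_proportions must sum to 1 (got {total})")
        if abs(sum(self.cd4_subtype_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("cd4_subtype_proportions must sum to 1")
        if self.n_genes <= 0 or self.cells_per_donor_per_lane <= 0:
            raise ValueError("n_genes and cells_per_donor_per_lane must be positive")
        if self.n_marker_genes_per_type <= 0:
            raise ValueError("n_marker_genes_per_type must be positive")
        if self.marker_fold_change <= 0 or self.dispersion <= 0:
            raise ValueError("marker_fold_change and dispersion must be positive")
        if self.donor_effect_sd < 0:
            raise ValueError("donor_effect_sd must be nonnegative")
        if not 0.0 <= self.donor_effect_gene_fraction <= 1.0:
            raise ValueError("donor_effect_gene_fraction must lie in [0, 1]")
        for lane, members in self.lane_design.items():
            if not members:
                raise ValueError(f"lane {lane} has no donors")
            unknown = set(members) - set(self.donors)
            if unknown:
                raise ValueError(f"lane {lane} references unknown donors {unknown}")
        n_special = (
            len(self.celltype_proportions) * self.n_marker_genes_per_type
            + len(CD4_SUBTYPE_GENES)
            + len(ALLO_UP_POOL)
            + len(ALLO_DOWN_POOL)
        )
        if self.n_genes < n_special + 10:
            raise ValueError(
                f"n_genes={self.n_genes} too small; need at least {n_special + 10}"
            )
        if np.exp(self.library_size_log_mean + 5 * self.library_size_log_sd) > 1e8:
            raise ValueError("library size parameters imply overflow-scale counts")

    def whitelist_entries(self) -> list[tuple[str, str]]:
        if self.tag_params.tag_whitelist is not None:
            return list(self.tag_params.tag_whitelist)
        return default_tag_whitelist(list(self.donors))


@dataclass
class SyntheticData:
    """Simulated experiment: counts + ground truth + sample-tag counts.

    ``adata`` is cells x genes with raw counts in ``X``; ground truth in
    ``obs`` (donor, lane, group, mixing_status, cell_type, cd4_subtype,
    allo_affected) and generative metadata in ``var`` / ``uns``.
    ``tag_counts`` is a tags x cells DataFrame indexed by donor label.
    """

    adata: ad.AnnData
    tag_counts: pd.DataFrame
    whitelist: list[tuple[str, str]]
    config: GeneratorConfig


def _gene_universe(config: GeneratorConfig, rng: np.random.Generator):
    """Gene names, base weights and per-celltype multipliers."""
    celltypes = sorted(config.celltype_proportions)
    names: list[str] = []
    marker_of: list[str] = []
    for ct in celltypes:
        canonical = CANONICAL_MARKERS.get(ct)
        abbr = ct.replace(" ", "").upper()
        for j in range(config.n_marker_genes_per_type):
            if j == 0 and canonical is not None:
                names.append(canonical)
            else:
                names.append(f"{abbr}.MK{j + 1}")
            marker_of.append(ct)
    names.extend(CD4_SUBTYPE_GENES)
    marker_of.extend(["" for _ in CD4_SUBTYPE_GENES])
    names.extend(ALLO_UP_POOL)
    names.extend(ALLO_DOWN_POOL)
    marker_of.extend(["" for _ in ALLO_UP_POOL + ALLO_DOWN_POOL])
    n_bg = config.n_genes - len(names)
    names.extend(f"G{i:04d}" for i in range(1, n_bg + 1))
    marker_of.extend(["" for _ in range(n_bg)])

    n_structured = (
        len(celltypes) * config.n_marker_genes_per_type + len(CD4_SUBTYPE_GENES)
    )
    # Background / allo-pool genes span a wide log-normal expression range;
    # marker and subtype genes are kept at moderate-to-high baseline so the
    # fold change is observable at realistic depth.
    log_w = rng.normal(0.0, 1.0, size=config.n_genes)
    log_w[:n_structured] = rng.normal(0.5, 0.5, size=n_structured)
    weights = np.exp(log_w)
    weights /= weights.sum()

    marker_mult = pd.DataFrame(1.0, index=names, columns=celltypes)
    for g, ct in zip(names, marker_of):
        if ct:
            marker_mult.loc[g, ct] = config.marker_fold_change
    # Subtype genes are low outside CD4 T and per-subtype inside it.
    cd4_mult = pd.DataFrame(1.0, index=list(CD4_SUBTYPE_GENES),
                            columns=sorted(config.cd4_subtype_proportions))
    for sub, pattern in CD4_SUBTYPE_PATTERNS.items():
        if sub not in cd4_mult.columns:
            continue
        for gene, level in pattern.items():
            cd4_mult.loc[gene, sub] = (
                config.marker_fold_change if level == "high" else 1.0
            )
    var = pd.DataFrame({"marker_of": marker_of, "base_weight": weights}, index=names)
    var.index.name = "gene"
    return var, marker_mult, cd4_mult


def _assign_cells(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    celltypes = sorted(config.celltype_proportions)
    probs = np.array([config.celltype_proportions[ct] for ct in celltypes])
    subtypes = sorted(config.cd4_subtype_proportions)
    sub_probs = np.array([config.cd4_subtype_proportions[s] for s in subtypes])

    frames = []
    ct_arr = np.array(celltypes)
    sub_arr = np.array(subtypes)
    for lane in sorted(config.lane_design):
        members = sorted(config.lane_design[lane])
        mixed = "mixed" if len(members) > 1 else "unmixed"
        for donor in members:
            n = config.cells_per_donor_per_lane
            ct = ct_arr[rng.choice(len(celltypes), size=n, p=probs)]
            sub = sub_arr[rng.choice(len(subtypes), size=n, p=sub_probs)]
            frames.append(
                pd.DataFrame(
                    {
                        "donor": donor,
                        "lane": lane,
                        "group": f"{donor}{lane}",
                        "mixing_status": mixed,
                        "cell_type": ct,
                        "cd4_subtype": np.where(ct == "CD4 T", sub, ""),
                    }
                )
            )
    obs = pd.concat(frames, ignore_index=True)
    obs.index = pd.Index([f"C{i:06d}" for i in range(len(obs))], name="cell")
    return obs


def _expected_means(
    obs: pd.DataFrame,
    var: pd.DataFrame,
    marker_mult: pd.DataFrame,
    cd4_mult: pd.DataFrame,
    donor_loading: pd.DataFrame,
    config: GeneratorConfig,
) -> np.ndarray:
    """Per-cell x per-gene expected counts (dense, cells x genes)."""
    genes = var.index
    base = var["base_weight"].to_numpy()
    lib = obs["library_size"].to_numpy()
    mu = np.empty((len(obs), len(genes)))
    key = obs[["donor", "cell_type", "cd4_subtype", "allo_affected"]]
    for (donor, ct, sub, allo), idx in key.groupby(
        ["donor", "cell_type", "cd4_subtype", "allo_affected"], sort=False,
        observed=True,
    ).groups.items():
        prof = base * marker_mult[ct].to_numpy() * donor_loading[donor].to_numpy()
        if ct == "CD4 T" and sub:
            prof = prof.copy()
            pos = genes.get_indexer(cd4_mult.index)
            prof[pos] *= cd4_mult[sub].to_numpy()
        if allo and config.allo_effect is not None:
            spec = config.allo_effect
            prof = prof.copy()
            prof[genes.get_indexer(list(spec.up_genes))] *= spec.fold_change_up
            prof[genes.get_indexer(list(spec.down_genes))] /= spec.fold_change_down
        rows = obs.index.get_indexer(idx)
        mu[rows] = lib[rows, None] * prof[None, :]
    if mu.max() > 1e7:
        raise ValueError("expected counts overflow plausible scRNA-seq scale")
    return mu


def _sample_nb(mu: np.ndarray, theta: float, rng: np.random.Generator) -> np.ndarray:
    """Negative binomial with inverse-dispersion theta (var = mu + mu^2/theta)."""
    return rng.negative_binomial(theta, theta / (theta + mu))


def _sample_tags(
    obs: pd.DataFrame,
    whitelist: list[tuple[str, str]],
    params: TagParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    donors = [d for d, _ in whitelist]
    seq_len = len(whitelist[0][1])
    k = len(donors)
    cap = np.array(
        [params.capture_efficiency_by_celltype.get(ct, 1.0)
         for ct in obs["cell_type"]]
    )
    own_mean = params.reads_per_cell_mean * (1.0 - params.background_fraction) * cap
    bg_mean = params.reads_per_cell_mean * params.background_fraction / max(k - 1, 1)
    counts = rng.poisson(bg_mean, size=(k, len(obs)))
    donor_row = pd.Index(donors).get_indexer(obs["donor"])
    own = rng.poisson(own_mean)
    counts[donor_row, np.arange(len(obs))] = own
    if params.sequencing_error_rate > 0:
        # an errored read fails exact attribution at the counter: thin by
        # the probability of an error-free read
        keep = (1.0 - params.sequencing_error_rate) ** seq_len
        counts = rng.binomial(counts, keep)
    return pd.DataFrame(counts, index=pd.Index(donors, name="tag"),
                        columns=obs.index)


def generate_counts(config: GeneratorConfig) -> SyntheticData:
    """Simulate one multiplexing experiment.

    Returns counts, tag counts and ground truth; bit-reproducible for a
    given config (including seed).
    """
    ss = np.random.SeedSequence(config.seed)
    rng_cells, rng_genes, rng_counts, rng_tags, rng_allo = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    obs = _assign_cells(config, rng_cells)
    var, marker_mult, cd4_mult = _gene_universe(config, rng_genes)

    donor_loading = pd.DataFrame(1.0, index=var.index, columns=list(config.donors))
    for donor in config.donors:
        mask = rng_genes.random(config.n_genes) < config.donor_effect_gene_fraction
        offsets = np.exp(rng_genes.normal(0.0, config.donor_effect_sd,
                                          size=config.n_genes))
        donor_loading[donor] = np.where(mask, offsets, 1.0)

    obs["library_size"] = rng_cells.lognormal(
        config.library_size_log_mean, config.library_size_log_sd, size=len(obs)
    )
    obs["allo_affected"] = False
    if config.allo_effect is not None:
        spec = config.allo_effect
        missing = (set(spec.up_genes) | set(spec.down_genes)) - set(var.index)
        if missing:
            raise KeyError(f"allo-effect genes not in gene universe: {sorted(missing)}")
        target = (
            (obs["cell_type"] == spec.target_celltype)
            & (obs["mixing_status"] == "mixed")
        )
        hit = rng_allo.random(len(obs)) < spec.affected_fraction
        obs["allo_affected"] = (target & hit).to_numpy()

    mu = _expected_means(obs, var, marker_mult, cd4_mult, donor_loading, config)
    counts = _sample_nb(mu, config.dispersion, rng_counts).astype(np.int32)

    adata = ad.AnnData(
        X=sparse.csr_matrix(counts),
        obs=obs,
        var=var,
    )
    adata.varm["donor_loading"] = donor_loading.to_numpy()
    adata.uns["donor_loading_columns"] = list(donor_loading.columns)
    adata.uns["celltype_multiplier"] = marker_mult
    adata.uns["cd4_multiplier"] = cd4_mult
    adata.uns["dispersion"] = config.dispersion

    whitelist = config.whitelist_entries()
    tags = _sample_tags(obs, whitelist, config.tag_params, rng_tags)
    return SyntheticData(adata=adata, tag_counts=tags, whitelist=whitelist,
                         config=config)


def inject_allo_effect(
    data: SyntheticData, spec: AlloEffectSpec, seed: int | None = None
) -> SyntheticData:
    """Re-draw the signature genes with the allo effect applied post hoc.

    Affected cells are selected among the target population of mixed-lane
    cells; their counts for ``spec.up_genes`` / ``spec.down_genes`` are
    re-sampled from the stored generative model with scaled means.  All
    other cells and genes are untouched.
    """
    adata = data.adata
    genes = adata.var.index
    all_genes = list(spec.up_genes) + list(spec.down_genes)
    missing = [g for g in all_genes if g not in genes]
    if missing:
        raise KeyError(f"unknown gene id(s): {missing}")

    new = data.adata.copy()
    obs = new.obs
    if seed is None:
        seed = data.config.seed + 1_000_003
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    target = (
        (obs["cell_type"] == spec.target_celltype)
        & (obs["mixing_status"] == "mixed")
    )
    affected = (rng.random(len(obs)) < spec.affected_fraction) & target
    obs["allo_affected"] = affected.to_numpy()
    if spec.affected_fraction == 0 or not affected.any():
        return SyntheticData(new, data.tag_counts.copy(), list(data.whitelist),
                             replace(data.config, allo_effect=spec))

    donor_loading = pd.DataFrame(
        new.varm["donor_loading"], index=genes,
        columns=new.uns["donor_loading_columns"],
    )
    marker_mult = new.uns["celltype_multiplier"]
    cd4_mult = new.uns["cd4_multiplier"]
    cols = genes.get_indexer(all_genes)
    fold = np.array(
        [spec.fold_change_up] * len(spec.up_genes)
        + [1.0 / spec.fold_change_down] * len(spec.down_genes)
    )
    base = adata.var["base_weight"].to_numpy()[cols]
    X = np.asarray(new.X.todense())
    rows = np.flatnonzero(affected.to_numpy())
    sub = obs.iloc[rows]
    for (donor, sub_label), idx in sub.groupby(
        ["donor", "cd4_subtype"], sort=False, observed=True
    ).groups.items():
        prof = base * marker_mult.loc[all_genes, spec.target_celltype].to_numpy()
        prof = prof * donor_loading.loc[all_genes, donor].to_numpy()
        if spec.target_celltype == "CD4 T" and sub_label:
            in_cd4 = np.array([g in cd4_mult.index for g in all_genes])
            extra = np.ones(len(all_genes))
            extra[in_cd4] = cd4_mult.loc[
                [g for g, m in zip(all_genes, in_cd4) if m], sub_label
            ].to_numpy()
            prof = prof * extra
        r = obs.index.get_indexer(idx)
        mu = obs["library_size"].to_numpy()[r][:, None] * (prof * fold)[None, :]
        draws = _sample_nb(mu, float(new.uns["dispersion"]), rng)
        X[np.ix_(r, cols)] = draws
    new.X = sparse.csr_matrix(X.astype(np.int32))
    return SyntheticData(new, data.tag_counts.copy(), list(data.whitelist),
                         replace(data.config, allo_effect=spec))


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def emit_tag_reads(
    data: SyntheticData, seed: int, error_rate: float | None = None,
    max_cells: int | None = None,
) -> pd.DataFrame:
    """Expand tag counts into literal read sequences with per-base errors.

    Returns a DataFrame with columns ``cell`` and ``read`` suitable for
    read-level counting against the whitelist.  Intended for exercising
    the Hamming-correcting counter on realistic input; ``max_cells``
    bounds the output size.
    """
    if error_rate is None:
        error_rate = data.config.tag_params.sequencing_error_rate
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    seqs = {donor: seq for donor, seq in data.whitelist}
    tag_counts = data.tag_counts
    cells = list(tag_counts.columns[:max_cells]) if max_cells else list(
        tag_counts.columns)
    cell_col: list[str] = []
    read_arrays: list[np.ndarray] = []
    length = len(next(iter(seqs.values())))
    for tag in tag_counts.index:
        template = np.frombuffer(seqs[tag].encode(), dtype=np.uint8)
        counts = tag_counts.loc[tag, cells]
        total = int(counts.sum())
        if total == 0:
            continue
        reads = np.tile(template, (total, 1))
        if error_rate > 0:
            err = rng.random(reads.shape) < error_rate
            # substitute with a uniformly random different base
            shift = rng.integers(1, 4, size=reads.shape)
            idx_in = np.searchsorted(_BASES, reads)
            reads = np.where(err, _BASES[(idx_in + shift) % 4], reads)
        read_arrays.append(reads)
        cell_col.extend(np.repeat(cells, counts.to_numpy()))
    if not read_arrays:
        return pd.DataFrame({"cell": [], "read": []})
    allreads = np.vstack(read_arrays)
    decoded = [row.tobytes().decode() for row in allreads]
    out = pd.DataFrame({"cell": cell_col, "read": decoded})
    assert all(len(r) == length for r in out["read"].head(10))
    return out
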