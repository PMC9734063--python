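"""Synthetic multi-region multi-omics datasets with planted ground truth.

Three generators emulate the structure of a multi-region treatment study:

``simulate_bulk``
    Bulk RNA counts for ``n_regions`` regions x 2 conditions x
    ``n_replicates`` replicates. Counts are negative binomial with
    per-gene lognormal baseline means, per-gene Gamma-distributed
    dispersion (variance = mu + alpha * mu**2) and lognormal per-sample
    size factors. Treatment effects are planted as co-regulated modules:
    sets of genes that share a per-region log2 fold-change.

``simulate_chip``
    A consensus peak set on a synthetic genome: one promoter peak per
    gene (centre within +/-1 kb of the TSS) plus distal decoy peaks at
    least 10 kb from any TSS. Promoter-peak treatment effects are drawn
    with a chosen correlation ``rho`` to the cognate gene's expression
    effect; counts follow the same NB machinery with 2 replicates per
    condition, mirroring typical ChIP-seq designs.

``simulate_scrna``
    Droplet-style single-cell counts: cell types defined by disjoint
    marker blocks, per-cell depth ~ Poisson-lognormal (around 2,000
    counts), cells multinomial over type-specific expression profiles
    with replicate-level Dirichlet proportion noise and lognormal
    replicate expression noise. Optional planted perturbations: a
    cell-type proportion shift, a gene-module expression shift, a
    regulon (TF target set) activation and a ligand-receptor edge shift.

All randomness flows from one ``numpy.random.Generator`` seeded per
call; a fixed seed reproduces byte-identical outputs. Every planted
effect is recorded in a :class:`~regionomics.containers.TruthTable`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from regionomics.containers import CONDITIONS, CountMatrix, TruthTable


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


# ---------------------------------------------------------------------------
# bulk RNA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedModule:
    """A co-regulated gene module with per-region log2 effects."""

    label: str
    gene_ids: tuple[str, ...]
    region_effects: Mapping[str, float]

    def validate(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise SimConfigError(f"module {self.label!r}: duplicate gene ids")
        for region, eff in self.region_effects.items():
            if not math.isfinite(eff):
                raise SimConfigError(
                    f"module {self.label!r}: non-finite effect in {region!r}"
                )


@dataclass
class BulkSimConfig:
    n_regions: int = 27
    n_genes: int = 2000
    n_replicates: int = 4
    baseline_mean_log: tuple[float, float] = (4.0, 1.5)
    dispersion_shape: float = 2.0
    dispersion_mean: float = 0.1
    size_factor_sigma: float = 0.2
    modules: tuple[PlantedModule, ...] = ()
    seed: int = 0

    @property
    def regions(self) -> list[str]:
        return [f"R{i + 1:02d}" for i in range(self.n_regions)]

    @property
    def gene_ids(self) -> list[str]:
        return [f"g{i + 1:05d}" for i in range(self.n_genes)]

    def validate(self) -> None:
        if self.n_regions < 1 or self.n_genes < 1:
            raise SimConfigError("non-positive dimensions")
        if self.n_replicates < 2:
            raise SimConfigError("need at least 2 replicates per condition")
        if self.dispersion_mean <= 0 or self.dispersion_shape <= 0:
            raise SimConfigError("dispersion parameters must be positive")
        universe = set(self.gene_ids)
        regions = set(self.regions)
        seen: set[str] = set()
        for mod in self.modules:
            mod.validate()
            ids = set(mod.gene_ids)
            if ids & seen:
                raise SimConfigError(
                    f"module {mod.label!r} shares genes with another module"
                )
            if not ids <= universe:
                raise SimConfigError(f"module {mod.label!r}: gene ids outside universe")
            if not set(mod.region_effects) <= regions:
                raise SimConfigError(f"module {mod.label!r}: unknown regions")
            seen |= ids


@dataclass
class BulkSimResult:
    sham: CountMatrix
    treated: CountMatrix
    truth: TruthTable
    base_mean: pd.Series = field(default_factory=pd.Series)
    dispersion: pd.Series = field(default_factory=pd.Series)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mean=mu, var=mu + alpha mu^2) via (n, p) parameterisation."""
    n = 1.0 / alpha
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def effect_matrix(config: BulkSimConfig) -> pd.DataFrame:
    """Genes x regions matrix of planted log2 fold-changes (0 = null)."""
    eff = pd.DataFrame(
        0.0, index=pd.Index(config.gene_ids, name="feature_id"), columns=config.regions
    )
    for mod in config.modules:
        for region, value in mod.region_effects.items():
            eff.loc[list(mod.gene_ids), region] = value
    return eff


def simulate_bulk(config: BulkSimConfig) -> BulkSimResult:
    """Simulate a two-condition multi-region bulk count dataset.

    Returns the sham and treated :class:`CountMatrix` (columns ordered
    region-major, replicate-minor) and the planted truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = config.gene_ids
    regions = config.regions

    loc, scale = config.baseline_mean_log
    base = np.exp(rng.normal(loc, scale, size=config.n_genes))
    alpha = rng.gamma(
        config.dispersion_shape,
        config.dispersion_mean / config.dispersion_shape,
        size=config.n_genes,
    )
    alpha = np.maximum(alpha, 1e-8)
    effects = effect_matrix(config)

    matrices: dict[str, CountMatrix] = {}
    for condition in CONDITIONS:
        cols, meta_rows = [], []
        blocks = []
        for region in regions:
            mu_region = base * np.exp2(
                effects[region].to_numpy() if condition == "treated" else 0.0
            )
            sf = np.exp(rng.normal(0.0, config.size_factor_sigma, config.n_replicates))
            mu = mu_region[:, None] * sf[None, :]
            blocks.append(_nb_draw(rng, mu, alpha[:, None]))
            for rep in range(config.n_replicates):
                cols.append(f"{region}_{condition}_r{rep + 1}")
                meta_rows.append((region, condition, f"r{rep + 1}"))
        counts = pd.DataFrame(
            np.concatenate(blocks, axis=1),
            index=pd.Index(genes, name="feature_id"),
            columns=cols,
        )
        meta = pd.DataFrame(
            meta_rows,
            index=pd.Index(cols, name="sample_id"),
            columns=["region", "condition", "replicate"],
        )
        matrices[condition] = CountMatrix(counts, meta)

    truth = TruthTable(effects=effects)
    return BulkSimResult(
        sham=matrices["sham"],
        treated=matrices["treated"],
        truth=truth,
        base_mean=pd.Series(base, index=genes, name="base_mean"),
        dispersion=pd.Series(alpha, index=genes, name="dispersion"),
    )


# ---------------------------------------------------------------------------
# ChIP peaks
# ---------------------------------------------------------------------------


@dataclass
class PeakGeometry:
    peak_width: int = 500
    gene_spacing: int = 50_000
    promoter_jitter: int = 750
    decoy_min_tss_gap: int = 10_000
    n_decoys: int | None = None  # default: one decoy in every other inter-gene gap

    def validate(self) -> None:
        if self.peak_width < 2 or self.gene_spacing <= 0:
            raise SimConfigError("invalid peak geometry")
        if self.promoter_jitter + self.peak_width // 2 > 1000:
            raise SimConfigError("promoter peaks must stay within +/-1 kb of the TSS")


@dataclass
class ChipSimResult:
    sham: CountMatrix
    treated: CountMatrix
    peaks: pd.DataFrame  # chrom, start, end, name
    tss: pd.DataFrame  # chrom, pos, strand, gene_id
    truth: TruthTable
    promoter_map: pd.Series = field(default_factory=pd.Series)  # peak id -> gene id


def simulate_chip(
    bulk_truth: TruthTable,
    rho: float,
    geometry: PeakGeometry | None = None,
    genome_size: int | None = None,
    n_replicates: int = 2,
    seed: int = 0,
    baseline_mean_log: tuple[float, float] = (6.5, 1.0),
    dispersion_shape: float = 2.0,
    dispersion_mean: float = 0.01,
    size_factor_sigma: float = 0.2,
) -> ChipSimResult:
    """Simulate a consensus peak set whose promoter peaks track the genes.

    Promoter-peak log2 effects for planted genes are ``rho * e + sqrt(1 -
    rho^2) * sigma_r * z`` where ``e`` is the gene's expression effect and
    ``sigma_r`` the spread of planted effects in that region, so the
    planted peak-vs-gene effect correlation equals ``rho``. Null genes and
    decoy peaks carry no effect.
    """
    if not -1.0 <= rho <= 1.0:
        raise SimConfigError("rho must lie in [-1, 1]")
    geometry = geometry or PeakGeometry()
    geometry.validate()
    if n_replicates < 2:
        raise SimConfigError("need at least 2 replicates per condition")

    effects = bulk_truth.effects
    genes = list(effects.index)
    regions = list(effects.columns)
    n_genes = len(genes)
    spacing = geometry.gene_spacing
    min_size = spacing * (n_genes + 1)
    if genome_size is None:
        genome_size = min_size
    if genome_size < min_size:
        raise SimConfigError("genome too small for the requested gene spacing")

    rng = np.random.default_rng(seed)

    tss_pos = spacing * (np.arange(n_genes) + 1)
    tss = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": tss_pos,
            "strand": np.where(np.arange(n_genes) % 2 == 0, "+", "-"),
            "gene_id": genes,
        }
    )

    half = geometry.peak_width // 2
    centres = tss_pos + rng.integers(
        -geometry.promoter_jitter, geometry.promoter_jitter + 1, size=n_genes
    )
    promoter = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": centres - half,
            "end": centres - half + geometry.peak_width,
            "name": [f"pk_prom_{g}" for g in genes],
        }
    )

    n_decoys = geometry.n_decoys if geometry.n_decoys is not None else n_genes // 2
    decoy_rows = []
    gap_lo = geometry.decoy_min_tss_gap + half + 1
    usable = spacing - 2 * gap_lo
    if n_decoys > 0 and usable <= 0:
        raise SimConfigError("gene spacing too tight to place decoy peaks")
    gap_idx = 0
    while len(decoy_rows) < n_decoys:
        if gap_idx >= n_genes - 1:
            raise SimConfigError("not enough inter-gene gaps for decoy peaks")
        left_tss = tss_pos[gap_idx]
        centre = left_tss + gap_lo + int(rng.integers(0, usable))
        decoy_rows.append(
            ("chr1", centre - half, centre - half + geometry.peak_width,
             f"pk_decoy_{len(decoy_rows) + 1:05d}")
        )
        gap_idx += 2  # every other gap keeps decoys pairwise far apart
    decoys = pd.DataFrame(decoy_rows, columns=["chrom", "start", "end", "name"])
    peaks = pd.concat([promoter, decoys], ignore_index=True)
    if (peaks["start"] < 0).any() or (peaks["end"] > genome_size).any():
        raise SimConfigError("peaks exceed genome bounds")

    peak_ids = list(peaks["name"])
    promoter_map = pd.Series(genes, index=promoter["name"].to_numpy(), name="gene_id")

    # planted peak effects, correlated with the gene's expression effect
    peak_eff = pd.DataFrame(
        0.0, index=pd.Index(peak_ids, name="feature_id"), columns=regions
    )
    gene_eff = effects.to_numpy()
    noise = rng.normal(size=gene_eff.shape)
    for j, region in enumerate(regions):
        planted = gene_eff[:, j] != 0
        if planted.sum() == 0:
            continue
        sigma = float(gene_eff[planted, j].std())
        vals = rho * gene_eff[planted, j]
        if abs(rho) < 1.0:
            vals = vals + math.sqrt(1.0 - rho * rho) * sigma * noise[planted, j]
        col = np.zeros(len(peak_ids))
        col[: n_genes][planted] = vals
        peak_eff[region] = col

    n_peaks = len(peak_ids)
    base = np.exp(rng.normal(*baseline_mean_log, size=n_peaks))
    alpha = np.maximum(
        rng.gamma(dispersion_shape, dispersion_mean / dispersion_shape, size=n_peaks),
        1e-8,
    )

    matrices: dict[str, CountMatrix] = {}
    for condition in CONDITIONS:
        cols, meta_rows, blocks = [], [], []
        for region in regions:
            mu_region = base * np.exp2(
                peak_eff[region].to_numpy() if condition == "treated" else 0.0
            )
            sf = np.exp(rng.normal(0.0, size_factor_sigma, n_replicates))
            mu = mu_region[:, None] * sf[None, :]
            blocks.append(_nb_draw(rng, mu, alpha[:, None]))
            for rep in range(n_replicates):
                cols.append(f"{region}_{condition}_chip_r{rep + 1}")
                meta_rows.append((region, condition, f"r{rep + 1}"))
        counts = pd.DataFrame(
            np.concatenate(blocks, axis=1),
            index=pd.Index(peak_ids, name="feature_id"),
            columns=cols,
        )
        meta = pd.DataFrame(
            meta_rows,
            index=pd.Index(cols, name="sample_id"),
            columns=["region", "condition", "replicate"],
        )
        matrices[condition] = CountMatrix(counts, meta)

    return ChipSimResult(
        sham=matrices["sham"],
        treated=matrices["treated"],
        peaks=peaks,
        tss=tss,
        truth=TruthTable(effects=peak_eff),
        promoter_map=promoter_map,
    )


# ---------------------------------------------------------------------------
# scRNA-seq
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModuleShift:
    gene_ids: tuple[str, ...]
    cell_type: str
    log2fc: float
    label: str = "module_shift"


@dataclass(frozen=True)
class RegulonShift:
    tf: str
    targets: tuple[str, ...]
    cell_type: str
    log2fc: float


@dataclass(frozen=True)
class LREdgeShift:
    ligand: str
    receptor: str
    sender: str
    receiver: str
    log2fc: float


@dataclass
class ScSimConfig:
    n_genes: int = 2000
    n_types: int = 12
    n_replicates: int = 5
    cells_per_replicate: int = 180
    markers_per_type: int = 20
    marker_fold: float = 8.0
    n_mito: int = 10
    mito_weight: float = 6.0  # relative weight of each mito gene (~3% of counts)
    depth_log_mean: float = math.log(2000.0)
    depth_log_sd: float = 0.3
    replicate_sigma: float = 0.15
    dirichlet_concentration: float = 200.0
    region: str = "dorDG"
    base_proportions: tuple[float, ...] | None = None
    proportion_shift: Mapping[str, float] = field(default_factory=dict)
    module_shift: ModuleShift | None = None
    regulon_shift: RegulonShift | None = None
    lr_shift: LREdgeShift | None = None
    seed: int = 0

    @property
    def gene_ids(self) -> list[str]:
        ids = [f"mt-g{i + 1:05d}" for i in range(self.n_mito)]
        ids += [f"g{i + 1:05d}" for i in range(self.n_mito, self.n_genes)]
        return ids

    @property
    def cell_types(self) -> list[str]:
        return [f"type{i + 1:02d}" for i in range(self.n_types)]

    def markers(self) -> dict[str, list[str]]:
        """Disjoint marker blocks, laid out after the mitochondrial genes."""
        ids = self.gene_ids
        out = {}
        for t in range(self.n_types):
            lo = self.n_mito + t * self.markers_per_type
            out[self.cell_types[t]] = ids[lo : lo + self.markers_per_type]
        return out

    def proportions(self) -> np.ndarray:
        if self.base_proportions is not None:
            p = np.asarray(self.base_proportions, dtype=float)
            if len(p) != self.n_types:
                raise SimConfigError("base_proportions length != n_types")
        else:
            p = 1.0 / (np.arange(self.n_types) + 2.0)
        if (p <= 0).any():
            raise SimConfigError("proportions must be positive")
        return p / p.sum()

    def validate(self) -> None:
        if self.n_replicates < 2:
            raise SimConfigError("need at least 2 replicates per condition")
        if self.n_types < 2 or self.cells_per_replicate < 1:
            raise SimConfigError("non-positive dimensions")
        if self.n_mito + self.n_types * self.markers_per_type > self.n_genes:
            raise SimConfigError("marker blocks exceed gene universe")
        types = set(self.cell_types)
        for t in self.proportion_shift:
            if t not in types:
                raise SimConfigError(f"proportion shift on unknown type {t!r}")
        for shift in (self.module_shift, self.regulon_shift):
            if shift is not None and shift.cell_type not in types:
                raise SimConfigError("planted shift on unknown cell type")
        self.proportions()


@dataclass
class ScSimResult:
    sham: "object"  # AnnData
    treated: "object"  # AnnData
    truth: TruthTable
    markers: dict[str, list[str]] = field(default_factory=dict)


def _type_profiles(config: ScSimConfig) -> pd.DataFrame:
    """Deterministic genes x types relative-expression weights."""
    rng = np.random.default_rng(config.seed + 1_000_003)
    ids = config.gene_ids
    base = np.exp(rng.normal(0.0, 1.0, size=config.n_genes))
    base[: config.n_mito] = config.mito_weight
    profiles = np.tile(base[:, None], (1, config.n_types))
    markers = config.markers()
    index = pd.Index(ids)
    for t, ctype in enumerate(config.cell_types):
        rows = index.get_indexer(markers[ctype])
        profiles[rows, t] *= config.marker_fold
    return pd.DataFrame(profiles, index=index, columns=config.cell_types)


def simulate_scrna(config: ScSimConfig) -> ScSimResult:
    """Simulate paired sham/treated single-cell datasets for one region."""
    import anndata as ad
    import scipy.sparse as sp

    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = config.gene_ids
    gene_index = pd.Index(genes)
    types = config.cell_types
    profiles = _type_profiles(config)

    # proportion shifts are planted on the proportion scale: the shifted
    # type's expected share becomes fold * base share and only the other
    # types are renormalized, so the realized ratio matches the planted fold
    base_props = config.proportions()
    props_by_cond = {"sham": base_props}
    treated_props = base_props.copy()
    shifted_idx = [types.index(t) for t in config.proportion_shift]
    for ctype, fold in config.proportion_shift.items():
        treated_props[types.index(ctype)] = base_props[types.index(ctype)] * fold
    shifted_mass = treated_props[shifted_idx].sum() if shifted_idx else 0.0
    if shifted_mass >= 1.0:
        raise SimConfigError("proportion shift pushes total share to >= 1")
    if shifted_idx:
        others = np.setdiff1d(np.arange(config.n_types), shifted_idx)
        treated_props[others] *= (1.0 - shifted_mass) / treated_props[others].sum()
    props_by_cond["treated"] = treated_props

    # treated-only expression perturbations per (type, gene)
    perturb = np.ones((config.n_genes, config.n_types))
    sc_rows = []
    for ctype, fold in config.proportion_shift.items():
        sc_rows.append(("proportion", ctype, ctype, fold))
    if config.module_shift is not None:
        ms = config.module_shift
        rows = gene_index.get_indexer(list(ms.gene_ids))
        if (rows < 0).any():
            raise SimConfigError("module shift genes outside universe")
        perturb[rows, types.index(ms.cell_type)] *= 2.0 ** ms.log2fc
        sc_rows.append(("expression", ms.cell_type, ms.label, ms.log2fc))
    if config.regulon_shift is not None:
        rs = config.regulon_shift
        rows = gene_index.get_indexer(list(rs.targets))
        if (rows < 0).any():
            raise SimConfigError("regulon targets outside universe")
        perturb[rows, types.index(rs.cell_type)] *= 2.0 ** rs.log2fc
        sc_rows.append(("regulon", rs.cell_type, rs.tf, rs.log2fc))
    if config.lr_shift is not None:
        ls = config.lr_shift
        row = gene_index.get_indexer([ls.ligand])
        if (row < 0).any():
            raise SimConfigError("ligand outside universe")
        perturb[row, types.index(ls.sender)] *= 2.0 ** ls.log2fc
        sc_rows.append(
            ("lr-edge", ls.sender, f"{ls.ligand}:{ls.receptor}:{ls.sender}:{ls.receiver}",
             ls.log2fc)
        )

    results = {}
    for condition in CONDITIONS:
        mats, obs_rows = [], []
        for rep in range(config.n_replicates):
            rep_id = f"r{rep + 1}"
            rep_noise = np.exp(rng.normal(0.0, config.replicate_sigma, config.n_genes))
            props = rng.dirichlet(config.dirichlet_concentration * props_by_cond[condition])
            type_counts = rng.multinomial(config.cells_per_replicate, props)
            for t, ctype in enumerate(types):
                n_cells = int(type_counts[t])
                if n_cells == 0:
                    continue
                weights = profiles[ctype].to_numpy() * rep_noise
                if condition == "treated":
                    weights = weights * perturb[:, t]
                p = weights / weights.sum()
                depths = rng.poisson(
                    np.exp(rng.normal(config.depth_log_mean, config.depth_log_sd, n_cells))
                )
                depths = np.maximum(depths, 1)
                mats.append(rng.multinomial(depths, p))
                for _ in range(n_cells):
                    obs_rows.append((rep_id, condition, config.region, ctype))
        x = np.concatenate(mats, axis=0) if mats else np.zeros((0, config.n_genes))
        obs = pd.DataFrame(
            obs_rows, columns=["replicate", "condition", "region", "true_type"]
        )
        obs.index = pd.Index(
            [f"{config.region}_{condition}_c{i + 1:05d}" for i in range(len(obs))],
            name="cell_id",
        )
        adata = ad.AnnData(X=sp.csr_matrix(x.astype(np.float64)), obs=obs)
        adata.var_names = genes
        results[condition] = adata

    truth = TruthTable(
        sc_effects=pd.DataFrame(
            sc_rows, columns=["kind", "cell_type", "target", "magnitude"]
        )
    )
    return ScSimResult(
        sham=results["sham"],
        treated=results["treated"],
        truth=truth,
        markers=config.markers(),
    )


# ---------------------------------------------------------------------------
# canned plantings used by the demo pipeline and power studies
# ---------------------------------------------------------------------------


def default_bulk_modules(
    n_regions: int,
    n_genes: int,
    genes_per_module: int = 50,
    effect: float = 1.0,
) -> tuple[PlantedModule, ...]:
    """Eight stereotyped modules with region 1 carrying the largest budget.

    Two global modules (up/down everywhere), two hemi-brain modules, and
    four modules private to the first few regions, so that region ``R01``
    accumulates the most planted effects in both modalities - a stand-in
    for the strongest-responding region of a real study.
    """
    if n_regions < 4:
        raise SimConfigError("default plantings need at least 4 regions")
    regions = [f"R{i + 1:02d}" for i in range(n_regions)]
    gene_ids = [f"g{i + 1:05d}" for i in range(n_genes)]
    need = 8 * genes_per_module
    if need > n_genes:
        raise SimConfigError("gene universe too small for default modules")
    blocks = [
        tuple(gene_ids[i * genes_per_module : (i + 1) * genes_per_module])
        for i in range(8)
    ]
    half = n_regions // 2
    layouts: list[Mapping[str, float]] = [
        {r: effect for r in regions},                       # global up
        {r: -effect for r in regions},                      # global down
        {r: effect for r in regions[:half]},                # rostral up
        {r: -effect for r in regions[half:]},               # caudal down
        {regions[0]: 1.5 * effect},                         # region-1 private
        {regions[0]: -1.5 * effect},                        # region-1 private
        {regions[0]: effect, regions[1]: effect},           # region 1+2
        {regions[2]: effect, regions[3]: -effect},          # regions 3/4
    ]
    return tuple(
        PlantedModule(label=f"module{i + 1}", gene_ids=blocks[i], region_effects=layout)
        for i, layout in enumerate(layouts)
    )
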