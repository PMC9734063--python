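"""Single-cell analysis stage.

Operates on an :class:`anndata.AnnData` of cells x genes raw counts with
``obs`` columns ``replicate``, ``condition`` (sham/treated) and
``region``. The stage covers, in order: QC filtering and depth
normalization, two-step cell typing (marker-correlation assignment
refined by unsupervised clustering), replicate-level cell-type
proportion tests, pseudo-bulk differential expression, expression-bin
matched module scores, rank-based regulon activity (AUCell-style area
under the recovery curve), and ligand-receptor edge specificity.

Rank-sum tests use the exact conditional distribution whenever the two
groups together hold at most 12 observations (replicate-level tests) and
the tie-corrected normal approximation otherwise (cell-level tests).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from regionomics.diffcount import bh_adjust
from regionomics.containers import STATUS_DOWN, STATUS_NS, STATUS_UP

MITO_PREFIXES = ("mt-", "Mt-", "MT-")
EXACT_RANKSUM_MAX_N = 12
AMBIGUOUS = "ambiguous"


def _dense(x) -> np.ndarray:
    return x.toarray() if sp.issparse(x) else np.asarray(x)


# ---------------------------------------------------------------------------
# rank-sum machinery
# ---------------------------------------------------------------------------


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided rank-sum p-value.

    Exact conditional distribution (enumeration of group assignments on
    the observed, possibly tied, ranks) when ``len(x)+len(y) <= 12``;
    tie-corrected normal approximation with continuity correction above.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    n = len(x) + len(y)
    if n <= EXACT_RANKSUM_MAX_N:
        ranks = stats.rankdata(np.concatenate([x, y]))
        w_obs = ranks[: len(x)].sum()
        mu = len(x) * (n + 1) / 2.0
        dev_obs = abs(w_obs - mu)
        count = 0
        total = 0
        for combo in itertools.combinations(range(n), len(x)):
            w = ranks[list(combo)].sum()
            total += 1
            if abs(w - mu) >= dev_obs - 1e-9:
                count += 1
        return count / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------


def qc_and_normalize(
    adata,
    min_genes: int = 500,
    max_mito: float = 0.20,
    min_cells_per_gene: int = 3,
    mito_prefixes: Sequence[str] = MITO_PREFIXES,
):
    """Filter low-quality cells/genes and add a log-normalized layer.

    Cells need >= ``min_genes`` detected genes and a mitochondrial count
    fraction <= ``max_mito``; genes must be detected in >=
    ``min_cells_per_gene`` surviving cells. The normalized value is
    ``log(1 + 1e4 * count / total_counts)``. QC metrics are computed once
    from the raw library and stored in ``obs`` (``total_counts``,
    ``n_genes_detected``, ``mito_fraction``); re-running on the output
    reuses them, which makes the operation idempotent.
    """
    adata = adata.copy()
    x = adata.X
    if not sp.issparse(x):
        x = sp.csr_matrix(x)
        adata.X = x
    if "total_counts" not in adata.obs:
        adata.obs["total_counts"] = np.asarray(x.sum(axis=1)).ravel()
        adata.obs["n_genes_detected"] = np.asarray((x > 0).sum(axis=1)).ravel()
        is_mito = np.array(
            [any(g.startswith(p) for p in mito_prefixes) for g in adata.var_names]
        )
        mito_counts = np.asarray(x[:, is_mito].sum(axis=1)).ravel() if is_mito.any() else 0.0
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(
                adata.obs["total_counts"] > 0,
                mito_counts / np.maximum(adata.obs["total_counts"], 1),
                0.0,
            )
        adata.obs["mito_fraction"] = frac
    keep_cells = (adata.obs["n_genes_detected"] >= min_genes) & (
        adata.obs["mito_fraction"] <= max_mito
    )
    if keep_cells.sum() == 0:
        raise ValueError("all cells removed by QC")
    adata = adata[keep_cells.to_numpy()].copy()
    detected_in = np.asarray((adata.X > 0).sum(axis=0)).ravel()
    adata = adata[:, detected_in >= min_cells_per_gene].copy()
    totals = adata.obs["total_counts"].to_numpy()
    norm = adata.X.multiply(1e4 / totals[:, None]).tocsr()
    norm.data = np.log1p(norm.data)
    adata.layers["lognorm"] = norm
    return adata


# ---------------------------------------------------------------------------
# cell typing
# ---------------------------------------------------------------------------


@dataclass
class ReferenceCentroids:
    """Per-type mean log-normalized profile over the union of marker genes."""

    profiles: pd.DataFrame  # marker genes x cell types
    markers: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError("marker lists must be non-empty")
        for t, ms in self.markers.items():
            if not ms:
                raise ValueError(f"cell type {t!r} has an empty marker list")
        if self.profiles.columns.duplicated().any():
            raise ValueError("cell types must be uniquely named")

    @classmethod
    def from_marker_lists(cls, markers: Mapping[str, Iterable[str]]) -> "ReferenceCentroids":
        """Binary on/off centroids over the union of all marker genes."""
        markers = {t: list(ms) for t, ms in markers.items()}
        union: list[str] = []
        seen: set[str] = set()
        for ms in markers.values():
            for g in ms:
                if g not in seen:
                    seen.add(g)
                    union.append(g)
        prof = pd.DataFrame(0.0, index=pd.Index(union, name="gene_id"), columns=list(markers))
        for t, ms in markers.items():
            prof.loc[ms, t] = 1.0
        return cls(profiles=prof, markers=markers)

    @classmethod
    def from_labelled(cls, adata, labels: pd.Series, markers: Mapping[str, Iterable[str]]):
        """Mean log-normalized marker profiles of a labelled reference."""
        markers = {t: list(ms) for t, ms in markers.items()}
        union = sorted({g for ms in markers.values() for g in ms})
        shared = [g for g in union if g in set(adata.var_names)]
        cols = adata.var_names.get_indexer(shared)
        x = _dense(adata.layers["lognorm"][:, cols])
        prof = {}
        for t in markers:
            mask = (labels == t).to_numpy()
            if mask.sum() == 0:
                raise ValueError(f"no reference cells labelled {t!r}")
            prof[t] = x[mask].mean(axis=0)
        return cls(
            profiles=pd.DataFrame(prof, index=pd.Index(shared, name="gene_id")),
            markers=markers,
        )


def assign_cell_types(
    adata,
    ref: ReferenceCentroids,
    min_corr: float = 0.2,
    n_pcs: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-step cell typing: marker correlation, then cluster consensus.

    Step 1 computes the Spearman correlation of each cell's marker-gene
    profile to every reference centroid and assigns the argmax when it
    reaches ``min_corr`` (else ``ambiguous``). Step 2 clusters the cells
    (k-means on the top principal components, k = number of reference
    types) and flags as ``low_confidence`` the cells whose supervised
    label disagrees with the majority label of their cluster.
    """
    shared = [g for g in ref.profiles.index if g in set(adata.var_names)]
    if not shared:
        raise ValueError("no marker genes shared with the matrix")
    cols = adata.var_names.get_indexer(shared)
    x = _dense(adata.layers["lognorm"][:, cols])
    centroids = ref.profiles.loc[shared]

    # Spearman = Pearson on ranks; rank per cell across marker genes
    def _rank_rows(a: np.ndarray) -> np.ndarray:
        return np.apply_along_axis(stats.rankdata, 1, a)

    rx = _rank_rows(x)
    rc = _rank_rows(centroids.to_numpy().T)
    rx = rx - rx.mean(axis=1, keepdims=True)
    rc = rc - rc.mean(axis=1, keepdims=True)
    num = rx @ rc.T
    denom = np.sqrt(
        (rx**2).sum(axis=1, keepdims=True) * (rc**2).sum(axis=1)[None, :]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, num / denom, 0.0)
    best = corr.argmax(axis=1)
    best_corr = corr[np.arange(corr.shape[0]), best]
    types = list(centroids.columns)
    labels = np.where(
        best_corr >= min_corr, np.array(types, dtype=object)[best], AMBIGUOUS
    )

    full = _dense(adata.layers["lognorm"])
    n_comp = min(n_pcs, full.shape[0] - 1, full.shape[1] - 1)
    pcs = PCA(n_components=n_comp, random_state=int(seed) % (2**32)).fit_transform(full)
    km = KMeans(
        n_clusters=len(types), n_init=10, random_state=int(seed) % (2**32)
    ).fit(pcs)
    clusters = km.labels_

    majority = {}
    for c in np.unique(clusters):
        members = labels[clusters == c]
        members = members[members != AMBIGUOUS]
        if len(members):
            vals, counts = np.unique(members, return_counts=True)
            majority[c] = vals[counts.argmax()]
        else:
            majority[c] = AMBIGUOUS
    low_conf = np.array(
        [
            lab != AMBIGUOUS and majority[c] != AMBIGUOUS and lab != majority[c]
            for lab, c in zip(labels, clusters)
        ]
    )
    return pd.DataFrame(
        {
            "label": labels,
            "correlation": best_corr,
            "cluster": clusters,
            "low_confidence": low_conf,
        },
        index=adata.obs_names.rename("cell_id"),
    )


# ---------------------------------------------------------------------------
# proportions
# ---------------------------------------------------------------------------


def test_proportions(labels: pd.Series, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-type replicate-level proportion shifts, exact rank-sum tested.

    ``meta`` must carry ``replicate`` and ``condition`` per cell. Types
    absent from a replicate enter as proportion 0; types with zero cells
    everywhere are skipped (listed in the result with NaN p).
    """
    df = pd.DataFrame(
        {
            "label": labels,
            "replicate": meta["replicate"].astype(str),
            "condition": meta["condition"],
        }
    )
    for cond in ("sham", "treated"):
        if df.loc[df["condition"] == cond, "replicate"].nunique() < 2:
            raise ValueError(f"need >= 2 replicates in condition {cond!r}")
    counts = (
        df.groupby(["condition", "replicate", "label"], observed=False)
        .size()
        .unstack(fill_value=0)
    )
    props = counts.div(counts.sum(axis=1), axis=0)
    rows = []
    for ctype in props.columns:
        sham = props.loc["sham"][ctype].to_numpy()
        trt = props.loc["treated"][ctype].to_numpy()
        if sham.sum() == 0 and trt.sum() == 0:
            rows.append((ctype, np.nan, np.nan, "none", np.nan))
            continue
        p = rank_sum_test(trt, sham)
        delta = trt.mean() - sham.mean()
        direction = "up" if delta > 0 else ("down" if delta < 0 else "none")
        rows.append((ctype, sham.mean(), trt.mean(), direction, p))
    return pd.DataFrame(
        rows,
        columns=["cell_type", "mean_prop_sham", "mean_prop_treated", "direction", "p_value"],
    ).set_index("cell_type")


# ---------------------------------------------------------------------------
# pseudo-bulk DE
# ---------------------------------------------------------------------------


def pseudobulk_units(adata, labels: pd.Series, cell_type: str, min_cells: int = 10):
    """Mean log-normalized profile per (condition, replicate) for one type."""
    mask = (labels == cell_type).to_numpy()
    sub = adata[mask]
    units = {}
    for (cond, rep), idx in sub.obs.groupby(
        ["condition", "replicate"], observed=False
    ).indices.items():
        if len(idx) < min_cells:
            continue
        units[(cond, str(rep))] = np.asarray(
            sub.layers["lognorm"][idx].mean(axis=0)
        ).ravel()
    return units


def pseudobulk_de(
    adata,
    labels: pd.Series,
    min_cells_per_unit: int = 10,
    fc_threshold: float = math.log2(1.25),
    q_threshold: float = 0.2,
) -> dict[str, pd.DataFrame]:
    """Per-type Welch t-test on replicate pseudo-bulk profiles.

    Each qualifying (condition, replicate) pair contributes one unit: the
    mean normalized expression over that replicate's cells of the type.
    Types without >= 2 units per condition are excluded. log2FC comes
    from unit means with a pseudocount of 0.1; BH is applied per type.
    """
    out: dict[str, pd.DataFrame] = {}
    for ctype in pd.unique(labels):
        if ctype == AMBIGUOUS:
            continue
        units = pseudobulk_units(adata, labels, ctype, min_cells_per_unit)
        sham = np.array([v for (c, _), v in units.items() if c == "sham"])
        trt = np.array([v for (c, _), v in units.items() if c == "treated"])
        if len(sham) < 2 or len(trt) < 2:
            continue
        mean_sham = sham.mean(axis=0)
        mean_trt = trt.mean(axis=0)
        log2fc = np.log2((mean_trt + 0.1) / (mean_sham + 0.1))
        import warnings

        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            # near-constant genes trip scipy's catastrophic-cancellation
            # warning; their NaN p-values are resolved explicitly below
            warnings.simplefilter("ignore", RuntimeWarning)
            t_res = stats.ttest_ind(trt, sham, axis=0, equal_var=False)
        p = np.asarray(t_res.pvalue)
        zero_spread = np.isnan(p)
        p = np.where(zero_spread & (mean_trt == mean_sham), 1.0, p)
        p = np.where(np.isnan(p), 0.0, p)  # zero variance, different means
        q = bh_adjust(p)
        status = np.full(len(p), STATUS_NS, dtype=object)
        sig = q <= q_threshold
        status[sig & (log2fc >= fc_threshold)] = STATUS_UP
        status[sig & (log2fc <= -fc_threshold)] = STATUS_DOWN
        out[ctype] = pd.DataFrame(
            {
                "base_mean": (mean_sham + mean_trt) / 2.0,
                "log2fc": log2fc,
                "p_value": p,
                "q_value": q,
                "status": status,
                "n_units_sham": len(sham),
                "n_units_treated": len(trt),
            },
            index=adata.var_names.rename("feature_id"),
        )
    return out


# ---------------------------------------------------------------------------
# module scores
# ---------------------------------------------------------------------------


def score_gene_module(
    adata,
    gene_set: Iterable[str],
    labels: pd.Series,
    n_bins: int = 25,
    n_control_per_gene: int = 100,
    seed: int = 0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Expression-bin matched module score per cell, rank-sum per type.

    Score(cell) = mean normalized expression over the set minus the mean
    over control genes drawn (seeded) from the same average-expression
    bins as the set genes. Bins are equal-width intervals of the average
    log-normalized expression and each set gene's controls are drawn with
    a generator seeded from (seed, gene id), so scores are reproducible
    and unaffected by genes that enter neither the set nor a set gene's
    bin. Returns the per-cell scores and a per-type table with condition
    means, delta, rank-sum p and BH q.
    """
    import zlib

    genes = pd.Index(adata.var_names)
    members = [g for g in dict.fromkeys(gene_set) if g in set(genes)]
    if len(members) < 5:
        raise ValueError("gene set shares fewer than 5 genes with the matrix")
    x = adata.layers["lognorm"]
    avg = np.asarray(x.mean(axis=0)).ravel()
    hi = float(avg.max())  # bins anchored at 0 (log-normalized values are >= 0)
    width = hi / n_bins if hi > 0 else 1.0
    bin_of = np.clip((avg / width).astype(int), 0, n_bins - 1)
    member_idx = genes.get_indexer(members)
    control_idx: list[np.ndarray] = []
    for g, gi in zip(members, member_idx):
        pool = np.flatnonzero(bin_of == bin_of[gi])
        take = min(n_control_per_gene, len(pool))
        rng = np.random.default_rng([seed, zlib.crc32(g.encode())])
        chosen = rng.choice(len(pool), size=take, replace=False)
        control_idx.append(pool[np.sort(chosen)])
    controls = np.concatenate(control_idx)

    set_mean = np.asarray(x[:, member_idx].mean(axis=1)).ravel()
    ctrl_mean = np.asarray(x[:, controls].mean(axis=1)).ravel()
    scores = pd.Series(set_mean - ctrl_mean, index=adata.obs_names, name="module_score")

    cond = adata.obs["condition"]
    rows = []
    for ctype in pd.unique(labels):
        if ctype == AMBIGUOUS:
            continue
        mask = (labels == ctype).to_numpy()
        s_sham = scores[mask & (cond == "sham").to_numpy()]
        s_trt = scores[mask & (cond == "treated").to_numpy()]
        if len(s_sham) == 0 or len(s_trt) == 0:
            continue
        p = rank_sum_test(s_trt, s_sham)
        rows.append(
            (ctype, s_sham.mean(), s_trt.mean(), s_trt.mean() - s_sham.mean(), p)
        )
    table = pd.DataFrame(
        rows, columns=["cell_type", "mean_sham", "mean_treated", "delta", "p_value"]
    ).set_index("cell_type")
    table["q_value"] = bh_adjust(table["p_value"].to_numpy()) if len(table) else []
    return scores, table


# ---------------------------------------------------------------------------
# regulon activity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Regulon:
    tf: str
    targets: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError(f"regulon {self.tf!r} has no targets")
        if self.tf in self.targets:
            raise ValueError(f"regulon {self.tf!r} contains its own TF as target")

    @property
    def genes(self) -> tuple[str, ...]:
        return (self.tf, *self.targets)


def regulon_activity(adata, regulons: Sequence[Regulon], top_fraction: float = 0.05) -> pd.DataFrame:
    """AUCell-style per-cell activity: area under the recovery curve.

    Genes are ranked per cell by normalized expression (ties broken by
    gene order, deterministic); activity is the area under the curve of
    recovered regulon genes within the top ``ceil(top_fraction * G)``
    ranks, normalized to [0, 1] by the maximal achievable area.
    """
    genes = pd.Index(adata.var_names)
    g = len(genes)
    x_top = max(1, math.ceil(top_fraction * g))
    x = _dense(adata.layers["lognorm"])
    # stable argsort on -expr => position of each gene in the ranking
    order = np.argsort(-x, axis=1, kind="stable")
    pos = np.empty_like(order)
    rows = np.arange(x.shape[0])[:, None]
    pos[rows, order] = np.arange(g)[None, :]

    out = {}
    for reg in regulons:
        idx = genes.get_indexer([gg for gg in reg.genes if gg in set(genes)])
        idx = idx[idx >= 0]
        if len(idx) < 5:
            raise ValueError(f"regulon {reg.tf!r} shares fewer than 5 genes with the matrix")
        contrib = np.clip(x_top - pos[:, idx], 0, x_top).sum(axis=1)
        k = min(len(idx), x_top)
        max_area = (x_top * k) - (k * (k - 1)) // 2
        out[reg.tf] = contrib / max_area
    return pd.DataFrame(out, index=adata.obs_names.rename("cell_id"))


def differential_regulons(
    adata,
    regulons: Sequence[Regulon],
    labels: pd.Series,
    top_fraction: float = 0.05,
    q_threshold: float = 0.1,
) -> dict[str, pd.DataFrame]:
    """Per-type rank-sum comparison of regulon activity, BH across regulons."""
    activity = regulon_activity(adata, regulons, top_fraction)
    cond = adata.obs["condition"]
    out: dict[str, pd.DataFrame] = {}
    for ctype in pd.unique(labels):
        if ctype == AMBIGUOUS:
            continue
        mask = (labels == ctype).to_numpy()
        sham_mask = mask & (cond == "sham").to_numpy()
        trt_mask = mask & (cond == "treated").to_numpy()
        if sham_mask.sum() == 0 or trt_mask.sum() == 0:
            continue
        rows = []
        for tf in activity.columns:
            a_sham = activity.loc[sham_mask, tf].to_numpy()
            a_trt = activity.loc[trt_mask, tf].to_numpy()
            p = rank_sum_test(a_trt, a_sham)
            fold = (a_trt.mean() + 1e-9) / (a_sham.mean() + 1e-9)
            rows.append((tf, a_sham.mean(), a_trt.mean(), fold, p))
        table = pd.DataFrame(
            rows,
            columns=["tf", "mean_activity_sham", "mean_activity_treated", "fold_change", "p_value"],
        ).set_index("tf")
        table["q_value"] = bh_adjust(table["p_value"].to_numpy())
        table["significant"] = table["q_value"] < q_threshold
        out[ctype] = table
    return out


# ---------------------------------------------------------------------------
# ligand-receptor edges
# ---------------------------------------------------------------------------


def lr_edges_and_diff(
    adata,
    labels: pd.Series,
    catalogue: pd.DataFrame,
    min_detect_fraction: float = 0.10,
) -> pd.DataFrame:
    """Differential ligand-receptor edge specificity between conditions.

    Per condition, the ligand specificity of a sender type is its mean
    expression share across types (mean expr / sum over types, 0/0 -> 0);
    receptor specificity is analogous for the receiver. An edge's weight
    is the product, and ``delta`` is treated minus sham. Edges are kept
    only when ligand and receptor are detected in >= ``min_detect_fraction``
    of the sender / receiver cells in at least one condition. Catalogue
    pairs whose genes are absent from the matrix are skipped and counted
    in the ``n_skipped`` attribute of the result.
    """
    genes = set(adata.var_names)
    pairs = [
        (lg, rc)
        for lg, rc in catalogue[["ligand", "receptor"]].itertuples(index=False)
        if lg in genes and rc in genes
    ]
    n_skipped = len(catalogue) - len(pairs)
    if not pairs:
        raise ValueError("no catalogue pair is present in the matrix")
    needed = sorted({g for pair in pairs for g in pair})
    col_idx = adata.var_names.get_indexer(needed)
    # linear-scale normalized expression: log compression would shrink true
    # fold-changes in the specificity numerator
    x = np.expm1(_dense(adata.layers["lognorm"][:, col_idx]))
    raw = _dense(adata.X[:, col_idx])
    gene_pos = {g: i for i, g in enumerate(needed)}

    cond = adata.obs["condition"].to_numpy()
    types = [t for t in pd.unique(labels) if t != AMBIGUOUS]
    mean_expr: dict[str, pd.DataFrame] = {}
    detect: dict[str, pd.DataFrame] = {}
    for c in ("sham", "treated"):
        rows_mean, rows_det = [], []
        for t in types:
            mask = (labels == t).to_numpy() & (cond == c)
            if mask.sum() == 0:
                rows_mean.append(np.zeros(len(needed)))
                rows_det.append(np.zeros(len(needed)))
            else:
                rows_mean.append(x[mask].mean(axis=0))
                rows_det.append((raw[mask] > 0).mean(axis=0))
        mean_expr[c] = pd.DataFrame(rows_mean, index=types, columns=needed)
        detect[c] = pd.DataFrame(rows_det, index=types, columns=needed)

    def specificity(c: str, gene: str) -> pd.Series:
        col = mean_expr[c][gene]
        total = col.sum()
        if total <= 0:
            return col * 0.0
        return col / total

    rows = []
    for lg, rc in dict.fromkeys(pairs):
        spec_l = {c: specificity(c, lg) for c in ("sham", "treated")}
        spec_r = {c: specificity(c, rc) for c in ("sham", "treated")}
        for sender in types:
            for receiver in types:
                detected = any(
                    detect[c].loc[sender, lg] >= min_detect_fraction
                    and detect[c].loc[receiver, rc] >= min_detect_fraction
                    for c in ("sham", "treated")
                )
                if not detected:
                    continue
                w_sham = float(spec_l["sham"][sender] * spec_r["sham"][receiver])
                w_trt = float(spec_l["treated"][sender] * spec_r["treated"][receiver])
                rows.append(
                    (lg, rc, sender, receiver, w_sham, w_trt, w_trt - w_sham)
                )
    out = pd.DataFrame(
        rows,
        columns=[
            "ligand", "receptor", "sender", "receiver",
            "weight_sham", "weight_treated", "delta",
        ],
    )
    out = out.reindex(out["delta"].abs().sort_values(ascending=False, kind="stable").index)
    out = out.reset_index(drop=True)
    out.attrs["n_skipped"] = n_skipped
    return out
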