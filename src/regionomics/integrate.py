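"""Cross-modality and cross-comparison integration.

Ties the bulk RNA and peak modalities together: peaks are assigned to
promoters by a symmetric TSS window, differential genes are correlated
with their promoter peak fold-changes (Spearman), regions are ranked by
the sum of natural-log ranks of their DEG and DA-peak counts (smaller =
stronger multimodal response), and pairs of signed differential rankings
are compared threshold-free with rank-rank hypergeometric overlap maps.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from regionomics.containers import STATUS_DOWN, STATUS_UP

DEFAULT_PROMOTER_WINDOW = 2_000


def assign_peaks_to_promoters(
    peaks: pd.DataFrame,
    tss: pd.DataFrame,
    window: int = DEFAULT_PROMOTER_WINDOW,
) -> pd.Series:
    """Map each peak to the gene with the nearest TSS within ``window`` bp.

    Distances are measured from the peak midpoint; ties break toward the
    lexicographically smaller gene id; peaks with no TSS in range are
    omitted from the returned Series.
    """
    if (peaks["end"] <= peaks["start"]).any():
        raise ValueError("malformed intervals: end <= start")
    if tss["gene_id"].duplicated().any():
        raise ValueError("TSS table must be unique per gene")
    assignments: dict[str, str] = {}
    for chrom, peak_group in peaks.groupby("chrom"):
        t = tss[tss["chrom"] == chrom].sort_values(["pos", "gene_id"])
        if t.empty:
            continue
        pos = t["pos"].to_numpy()
        gene_ids = t["gene_id"].to_numpy()
        mids = ((peak_group["start"] + peak_group["end"]) // 2).to_numpy()
        for mid, name in zip(mids, peak_group["name"]):
            dist = np.abs(pos - mid)
            best = dist.min() if len(dist) else None
            if best is None or best > window:
                continue
            candidates = gene_ids[dist == best]
            assignments[name] = min(candidates)
    return pd.Series(assignments, name="gene_id", dtype=object)


@dataclass
class ConcordanceResult:
    region: str
    n_pairs: int
    spearman_rho: float
    p_value: float


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho (small n only).

    The rank variances are permutation-invariant, so rho is monotone in
    the dot product of the rank vectors; permutations are enumerated in
    vectorised chunks.
    """
    rx = stats.rankdata(x) - (len(x) + 1) / 2
    ry = stats.rankdata(y) - (len(y) + 1) / 2
    n = len(rx)
    scale = math.sqrt((rx**2).sum() * (ry**2).sum())
    if scale == 0:
        return 1.0
    count = 0
    total = 0
    chunk: list[tuple[int, ...]] = []
    threshold = abs(rho_obs) * scale - 1e-9
    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        if len(chunk) == 100_000:
            dots = ry[np.asarray(chunk)] @ rx
            count += int((np.abs(dots) >= threshold).sum())
            total += len(chunk)
            chunk = []
    if chunk:
        dots = ry[np.asarray(chunk)] @ rx
        count += int((np.abs(dots) >= threshold).sum())
        total += len(chunk)
    return count / total


def promoter_concordance(
    deg: pd.DataFrame,
    da: pd.DataFrame,
    assignment: pd.Series,
    region: str = "",
) -> ConcordanceResult:
    """Spearman correlation of DEG log2FC vs their promoter DA-peak log2FC.

    Pairs are genes with differential status that have an assigned,
    differential promoter peak. Average ranks; the p-value uses the
    t-approximation, switching to exact permutation for <= 10 pairs.
    """
    deg_hits = deg[deg["status"].isin([STATUS_UP, STATUS_DOWN])]
    da_hits = da[da["status"].isin([STATUS_UP, STATUS_DOWN])]
    peak_gene = assignment[assignment.index.isin(da_hits.index)]
    gene_to_peak = {g: p for p, g in peak_gene.items()}
    pairs = [(g, gene_to_peak[g]) for g in deg_hits.index if g in gene_to_peak]
    n_pairs = len(pairs)
    if n_pairs < 3:
        raise ValueError("fewer than 3 DEG/promoter-peak pairs")
    x = deg_hits.loc[[g for g, _ in pairs], "log2fc"].to_numpy()
    y = da_hits.loc[[p for _, p in pairs], "log2fc"].to_numpy()
    rho, p_t = stats.spearmanr(x, y)
    rho = float(rho)
    p = _spearman_exact_p(x, y, rho) if n_pairs <= 10 else float(p_t)
    return ConcordanceResult(region=region, n_pairs=n_pairs, spearman_rho=rho, p_value=p)


def composite_region_ranking(
    n_deg: dict[str, int] | pd.Series, n_da: dict[str, int] | pd.Series
) -> pd.DataFrame:
    """Rank regions by sum of natural-log ranks of DEG and DA-peak counts.

    Counts are ranked descending with average ties; the composite score
    ``ln(rank_rna) + ln(rank_chip)`` is sorted ascending so the strongest
    multimodal responder comes first.
    """
    n_deg = pd.Series(n_deg, dtype=float)
    n_da = pd.Series(n_da, dtype=float)
    if set(n_deg.index) != set(n_da.index):
        raise ValueError("region keys differ between modalities")
    n_da = n_da.reindex(n_deg.index)
    rank_rna = pd.Series(stats.rankdata(-n_deg.to_numpy(), method="average"), index=n_deg.index)
    rank_chip = pd.Series(stats.rankdata(-n_da.to_numpy(), method="average"), index=n_deg.index)
    score = np.log(rank_rna) + np.log(rank_chip)
    out = pd.DataFrame(
        {
            "n_deg": n_deg.astype(int),
            "n_da": n_da.astype(int),
            "rank_rna": rank_rna,
            "rank_chip": rank_chip,
            "composite_score": score,
        }
    )
    out.index.name = "region"
    return out.sort_values(["composite_score", "region"], kind="stable")


@dataclass
class RRHOMap:
    """Signed rank-rank hypergeometric overlap grid.

    ``neglog10`` holds -log10 of the hypergeometric upper-tail overlap
    p-value at each rank-threshold pair; ``sign`` is +1 where the overlap
    exceeds its expectation and -1 where it falls short (depletion).
    """

    neglog10: pd.DataFrame
    sign: pd.DataFrame
    overlap: pd.DataFrame
    step: int
    n_features: int

    def signed(self) -> pd.DataFrame:
        return self.neglog10 * self.sign


def default_rrho_step(n_features: int) -> int:
    """Step keeping the map at most 100 x 100 cells."""
    return max(1, n_features // 100)


def rrho_map(list1: pd.Series, list2: pd.Series, step: int | None = None) -> RRHOMap:
    """Rank-rank hypergeometric overlap of two signed ranking score lists.

    Both Series map the same feature universe to a signed ranking score
    (by convention -log10(p) * sign(log2FC)); features are sorted most
    upregulated first. Cell (i, j) compares the top ``i*step`` of list 1
    with the top ``j*step`` of list 2.
    """
    if set(list1.index) != set(list2.index):
        raise ValueError("feature universes differ")
    n = len(list1)
    if step is None:
        step = default_rrho_step(n)
    if step < 1:
        raise ValueError("step must be >= 1")
    order1 = list1.sort_values(ascending=False, kind="stable").index
    order2 = list2.sort_values(ascending=False, kind="stable").index
    rank2 = pd.Series(np.arange(1, n + 1), index=order2)
    rank2_in_1 = rank2.reindex(order1).to_numpy()

    n_cells = math.ceil(n / step)
    thresholds = np.minimum(np.arange(1, n_cells + 1) * step, n)
    # cumulative 2D histogram of (rank1, rank2) pairs over the grid
    cell1 = np.minimum((np.arange(1, n + 1) - 1) // step, n_cells - 1)
    cell2 = np.minimum((rank2_in_1 - 1) // step, n_cells - 1)
    hist = np.zeros((n_cells, n_cells))
    np.add.at(hist, (cell1, cell2), 1.0)
    overlap = hist.cumsum(axis=0).cumsum(axis=1)
    # ragged last cell: thresholds clipped to n
    a = thresholds[:, None].astype(float)
    b = thresholds[None, :].astype(float)
    expected = a * b / n
    p = stats.hypergeom.sf(overlap - 1, n, a, b)
    with np.errstate(divide="ignore"):
        neglog = -np.log10(np.maximum(p, np.finfo(float).tiny))
    sign = np.where(overlap >= expected, 1.0, -1.0)
    idx = pd.Index(thresholds, name="top_list1")
    cols = pd.Index(thresholds, name="top_list2")
    return RRHOMap(
        neglog10=pd.DataFrame(neglog, index=idx, columns=cols),
        sign=pd.DataFrame(sign, index=idx, columns=cols),
        overlap=pd.DataFrame(overlap.astype(int), index=idx, columns=cols),
        step=step,
        n_features=n,
    )


def signed_ranking_score(table: pd.DataFrame) -> pd.Series:
    """Default RRHO score: -log10(p) signed by log2FC, log2FC fallback.

    Untested features (NaN p) fall back to signed log2FC, i.e. 0 change.
    """
    p = table["p_value"].to_numpy(dtype=float)
    lfc = table["log2fc"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        mag = -np.log10(np.maximum(p, np.finfo(float).tiny))
    score = np.where(np.isnan(p), lfc, mag * np.sign(lfc))
    return pd.Series(score, index=table.index, name="score")
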