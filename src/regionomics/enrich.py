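"""Set-enrichment statistics: overlap ORA, GSEA running sum, genomic binomial.

Three related statistics cover the enrichment questions of the pipeline:

* :func:`ora` - hypergeometric over-representation of a query gene list
  in named gene sets, with fold-enrichment ``(k/n)/(K/N)`` and BH
  correction across the collection. The universe is the set of features
  actually tested for differential status, guarding against detection
  bias.
* :func:`gsea` - the weighted Kolmogorov-Smirnov running-sum enrichment
  score over a ranked list, with a gene-permutation null for the
  normalized enrichment score (NES) and one-sided permutation p-value.
  Gene permutation (rather than phenotype permutation) is used because
  the bulk designs here have too few replicates to permute labels.
* :func:`region_enrichment_binomial` - a regulatory-domain binomial test
  for peak sets: each gene owns a basal domain (TSS +/- 5 kb) extended up
  to 100 kb or the nearest neighbouring basal domain, and a peak counts
  as a hit when its midpoint falls in the union of the set's domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from regionomics.diffcount import bh_adjust

BASAL_HALF_WIDTH = 5_000
MAX_EXTENSION = 100_000


# ---------------------------------------------------------------------------
# overlap ORA
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene sets intersected with a testable universe.

    Set members outside the universe are dropped at construction; sets
    left empty are removed. ``n_dropped`` counts the discarded ids.
    """

    sets: dict[str, frozenset]
    universe: frozenset
    n_dropped: int = 0

    @classmethod
    def from_dict(
        cls, raw: Mapping[str, Iterable[str]], universe: Iterable[str]
    ) -> "GeneSetCollection":
        uni = frozenset(universe)
        if not uni:
            raise ValueError("empty universe")
        filtered: dict[str, frozenset] = {}
        dropped = 0
        for name, members in raw.items():
            members = frozenset(members)
            kept = members & uni
            dropped += len(members) - len(kept)
            if kept:
                filtered[name] = kept
        return cls(sets=filtered, universe=uni, n_dropped=dropped)


def ora(query: Iterable[str], collection: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric upper-tail over-representation of ``query`` per set."""
    query_set = frozenset(query) & collection.universe
    if not query_set:
        raise ValueError("query empty after intersection with the universe")
    n = len(query_set)
    N = len(collection.universe)
    rows = []
    for name, members in collection.sets.items():
        K = len(members)
        k = len(query_set & members)
        fold = (k / n) / (K / N)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append((name, k, n, K, N, fold, min(p, 1.0)))
    out = pd.DataFrame(
        rows, columns=["set_name", "k", "n", "K", "N", "fold_enrichment", "p_value"]
    )
    out["q_value"] = bh_adjust(out["p_value"].to_numpy()) if len(out) else []
    return out


# ---------------------------------------------------------------------------
# GSEA
# ---------------------------------------------------------------------------


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p_value: float
    leading_edge: list[str] = field(default_factory=list)
    n_perm: int = 0


def _running_es(hit_mask: np.ndarray, weights: np.ndarray) -> tuple[float, int]:
    """ES and its position for one hit configuration.

    ``weights`` are |score|^w; hit increments are normalized to sum 1
    over the set, miss decrements are 1/(N-K). Ties in |deviation| break
    toward the positive deviation.
    """
    n = hit_mask.size
    k = int(hit_mask.sum())
    hit_w = weights * hit_mask
    total = hit_w.sum()
    if total <= 0:  # all hit scores zero: fall back to equal increments
        hit_w = hit_mask.astype(float)
        total = float(k)
    steps = hit_w / total
    if k < n:
        steps = steps - (~hit_mask).astype(float) / (n - k)
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    hi, lo = running[i_max], running[i_min]
    if hi >= -lo:
        return float(hi), i_max
    return float(lo), i_min


def gsea(
    scores: pd.Series,
    gene_set: Iterable[str],
    set_name: str = "set",
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> GseaResult:
    """Weighted KS enrichment of ``gene_set`` in a score-ranked gene list.

    ``scores`` maps feature id to a real ranking score; the list is
    sorted descending internally (stable in input order for ties). NES is
    ES divided by the mean |ES| of same-sign gene-permutation nulls, and
    the p-value is the one-sided permutation tail on that sign.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be at least 10")
    if scores.index.duplicated().any():
        raise ValueError("duplicate feature ids in the ranked list")
    order = np.argsort(-scores.to_numpy(), kind="stable")
    ranked = scores.iloc[order]
    members = frozenset(gene_set)
    hit_mask = ranked.index.isin(members)
    k = int(hit_mask.sum())
    n = hit_mask.size
    if k == 0:
        raise ValueError("gene set does not intersect the ranked list")
    weights = np.abs(ranked.to_numpy()) ** weight

    es, i_es = _running_es(hit_mask, weights)
    if es >= 0:
        leading = list(ranked.index[: i_es + 1][hit_mask[: i_es + 1]])
    else:
        leading = list(ranked.index[i_es:][hit_mask[i_es:]])

    if k == n:  # degenerate: every gene is a hit; null is the observed value
        return GseaResult(set_name, es, 1.0, 1.0, leading, 0)

    rng = np.random.default_rng(seed)
    null_es = np.empty(n_perm)
    positions = np.arange(n)
    for b in range(n_perm):
        perm_hits = np.zeros(n, dtype=bool)
        perm_hits[rng.choice(positions, size=k, replace=False)] = True
        null_es[b], _ = _running_es(perm_hits, weights)

    same_sign = null_es >= 0 if es >= 0 else null_es < 0
    denom_pool = np.abs(null_es[same_sign])
    if denom_pool.size == 0:
        denom_pool = np.abs(null_es)
    mean_abs = float(denom_pool.mean()) if denom_pool.size else abs(es)
    nes = es / mean_abs if mean_abs > 0 else 0.0
    n_same = int(same_sign.sum())
    n_extreme = int((np.abs(null_es[same_sign]) >= abs(es) - 1e-12).sum())
    p = (1 + n_extreme) / (1 + n_same) if n_same else 1.0
    return GseaResult(set_name, es, float(nes), float(min(p, 1.0)), leading, n_perm)


# ---------------------------------------------------------------------------
# regulatory-domain binomial
# ---------------------------------------------------------------------------


@dataclass
class RegulatoryDomains:
    """Per-gene regulatory intervals on a known-size genome."""

    domains: pd.DataFrame  # gene_id, chrom, start, end
    genome_size: int

    def coverage_fraction(self, gene_set: Iterable[str]) -> float:
        members = set(gene_set)
        sub = self.domains[self.domains["gene_id"].isin(members)]
        if sub.empty:
            return 0.0
        covered = 0
        for _, group in sub.groupby("chrom"):
            ivals = group[["start", "end"]].sort_values("start").to_numpy()
            cur_s, cur_e = ivals[0]
            for s, e in ivals[1:]:
                if s > cur_e:
                    covered += cur_e - cur_s
                    cur_s, cur_e = s, e
                else:
                    cur_e = max(cur_e, e)
            covered += cur_e - cur_s
        return min(covered / self.genome_size, 1.0)

    def midpoint_hits(self, peaks: pd.DataFrame, gene_set: Iterable[str]) -> int:
        members = set(gene_set)
        sub = self.domains[self.domains["gene_id"].isin(members)]
        mid = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
        chroms = peaks["chrom"].to_numpy()
        hits = np.zeros(len(peaks), dtype=bool)
        for chrom, group in sub.groupby("chrom"):
            on_chrom = chroms == chrom
            if not on_chrom.any():
                continue
            for _, row in group.iterrows():
                hits |= on_chrom & (mid >= row["start"]) & (mid < row["end"])
        return int(hits.sum())


def build_regulatory_domains(
    tss: pd.DataFrame,
    genome_size: int,
    basal: int = BASAL_HALF_WIDTH,
    extension: int = MAX_EXTENSION,
) -> RegulatoryDomains:
    """Basal-plus-extension regulatory domains from a TSS table.

    Each gene owns TSS +/- ``basal``; the domain then extends outward up
    to ``extension`` bp or to the nearest neighbouring basal domain,
    whichever is closer, and is clipped to the genome.
    """
    rows = []
    for chrom, group in tss.groupby("chrom"):
        group = group.sort_values("pos").reset_index(drop=True)
        pos = group["pos"].to_numpy()
        basal_start = pos - basal
        basal_end = pos + basal
        for i in range(len(group)):
            prev_end = basal_end[i - 1] if i > 0 else 0
            next_start = basal_start[i + 1] if i + 1 < len(group) else genome_size
            start = min(basal_start[i], max(pos[i] - extension, prev_end))
            end = max(basal_end[i], min(pos[i] + extension, next_start))
            rows.append(
                (group["gene_id"].iloc[i], chrom, max(int(start), 0),
                 min(int(end), genome_size))
            )
    return RegulatoryDomains(
        domains=pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"]),
        genome_size=int(genome_size),
    )


def region_enrichment_binomial(
    peaks: pd.DataFrame,
    domains: RegulatoryDomains,
    gene_set: Iterable[str],
    set_name: str = "set",
) -> pd.Series:
    """Binomial upper-tail enrichment of peak midpoints in a set's domains."""
    gene_set = list(gene_set)
    n = len(peaks)
    if n == 0:
        raise ValueError("empty peak set")
    p0 = domains.coverage_fraction(gene_set)
    k = domains.midpoint_hits(peaks, gene_set)
    if p0 == 0.0 and k > 0:
        raise ValueError("inconsistent inputs: hits found with zero coverage")
    if k == 0:
        p = 1.0
    else:
        p = float(stats.binom.sf(k - 1, n, p0))
    expected = n * p0
    fold = (k / expected) if expected > 0 else 0.0
    return pd.Series(
        {
            "set_name": set_name,
            "k": k,
            "n": n,
            "coverage": p0,
            "fold_enrichment": fold,
            "p_value": min(p, 1.0),
        }
    )
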