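"""Cross-region sharing summaries and k-means fold-change modules.

Differential features (genes or peaks) from all regions are assembled
into a fold-change profile matrix (rows = features differential in at
least one region, columns = regions) and partitioned by k-means into
co-regulated modules. Profiles are clustered on raw log2FC - the sign
and magnitude pattern across regions is the biology of interest - with
an optional z-scoring switch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from regionomics.containers import STATUS_DOWN, STATUS_UP


@dataclass
class FoldChangeMatrix:
    """Fold-change profiles with a tested/untested companion mask.

    Untested entries (feature absent or untestable in a region) are 0 in
    ``values`` and False in ``tested``: "no evidence of change".
    """

    values: pd.DataFrame
    tested: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.shape == self.tested.shape:
            raise ValueError("mask shape must match value shape")


@dataclass
class ModulePartition:
    assignments: pd.Series  # feature id -> module id in 1..k
    centroids: pd.DataFrame  # module x region
    k: int
    seed: int
    inertia: float
    masked_per_module: pd.Series | None = None


@dataclass
class SharingSummary:
    per_feature: pd.DataFrame  # columns n_up, n_down
    histogram: pd.DataFrame  # sharing degree x direction counts
    fraction_specific: float  # union DEGs differential in exactly 1 region
    fraction_three_plus: float  # union DEGs differential in >= 3 regions


def build_foldchange_matrix(
    per_region: Mapping[str, pd.DataFrame]
) -> FoldChangeMatrix:
    """Assemble log2FC profiles of features differential in >= 1 region."""
    if not per_region:
        raise ValueError("need at least one region")
    regions = list(per_region)
    union: list[str] = []
    seen: set[str] = set()
    for region in regions:
        table = per_region[region]
        hits = table.index[table["status"].isin([STATUS_UP, STATUS_DOWN])]
        for f in hits:
            if f not in seen:
                seen.add(f)
                union.append(f)
    if not union:
        raise ValueError("no differential features in any region")
    values = pd.DataFrame(0.0, index=pd.Index(union, name="feature_id"), columns=regions)
    tested = pd.DataFrame(False, index=values.index, columns=regions)
    for region in regions:
        table = per_region[region].reindex(union)
        ok = table["p_value"].notna()
        values.loc[ok, region] = table.loc[ok, "log2fc"]
        tested[region] = ok.to_numpy()
    return FoldChangeMatrix(values=values, tested=tested)


def cluster_modules(
    fcm: FoldChangeMatrix,
    k: int = 8,
    n_restarts: int = 25,
    seed: int = 0,
    scale_rows: bool = False,
) -> ModulePartition:
    """Partition fold-change profiles into k modules (k-means++, best of restarts)."""
    n_rows = fcm.values.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_rows:
        raise ValueError(f"k={k} exceeds number of rows ({n_rows})")
    x = fcm.values.to_numpy(dtype=float)
    if scale_rows:
        sd = x.std(axis=1, keepdims=True)
        x = (x - x.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_restarts,
        random_state=int(seed) % (2**32),
    ).fit(x)
    labels = km.labels_ + 1
    assignments = pd.Series(labels, index=fcm.values.index, name="module")
    centroids = pd.DataFrame(
        km.cluster_centers_,
        index=pd.Index(np.arange(1, k + 1), name="module"),
        columns=fcm.values.columns,
    )
    masked = (~fcm.tested).sum(axis=1).groupby(assignments).sum()
    masked = masked.reindex(centroids.index, fill_value=0)
    return ModulePartition(
        assignments=assignments,
        centroids=centroids,
        k=k,
        seed=seed,
        inertia=float(km.inertia_),
        masked_per_module=masked,
    )


def sharing_summary(per_region: Mapping[str, pd.DataFrame]) -> SharingSummary:
    """Count, per feature, the regions where it is up and where it is down."""
    if not per_region:
        raise ValueError("need at least one region")
    regions = list(per_region)
    features: pd.Index | None = None
    n_up = None
    n_down = None
    for region in regions:
        table = per_region[region]
        if features is None:
            features = table.index
            n_up = pd.Series(0, index=features, dtype=int)
            n_down = pd.Series(0, index=features, dtype=int)
        status = table["status"].reindex(features)
        n_up += (status == STATUS_UP).astype(int)
        n_down += (status == STATUS_DOWN).astype(int)
    per_feature = pd.DataFrame({"n_up": n_up, "n_down": n_down})
    per_feature.index.name = "feature_id"
    degree = per_feature["n_up"] + per_feature["n_down"]
    union = per_feature[degree > 0]
    union_degree = degree[degree > 0]

    rows = []
    for d in range(1, len(regions) + 1):
        rows.append(
            {
                "degree": d,
                "n_features": int((union_degree == d).sum()),
                "n_up_dominant": int(
                    ((union_degree == d) & (union["n_up"] >= union["n_down"])).sum()
                ),
                "n_down_dominant": int(
                    ((union_degree == d) & (union["n_down"] > union["n_up"])).sum()
                ),
            }
        )
    histogram = pd.DataFrame(rows).set_index("degree")
    n_union = len(union)
    return SharingSummary(
        per_feature=per_feature,
        histogram=histogram,
        fraction_specific=float((union_degree == 1).sum() / n_union) if n_union else 0.0,
        fraction_three_plus=float((union_degree >= 3).sum() / n_union) if n_union else 0.0,
    )
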