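"""Core in-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("sham", "treated")

#: status labels used by every differential table in the package
STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_NS = "ns"


@dataclass
class CountMatrix:
    """Features x samples integer counts with per-sample design metadata.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, index = feature ids,
        columns = sample ids.
    sample_meta
        DataFrame indexed by sample id with columns ``region``,
        ``condition`` (``sham``/``treated``) and ``replicate``.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate feature ids in count matrix")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids in count matrix")
        if not self.counts.columns.equals(self.sample_meta.index):
            raise ValueError("sample_meta index must match count columns")
        vals = self.counts.to_numpy()
        if vals.size and (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if vals.size and not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integral")
        missing = {"region", "condition", "replicate"} - set(self.sample_meta.columns)
        if missing:
            raise ValueError(f"sample_meta missing columns: {sorted(missing)}")
        bad = set(self.sample_meta["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def regions(self) -> list[str]:
        return list(pd.unique(self.sample_meta["region"]))

    def subset_region(self, region: str) -> "CountMatrix":
        keep = self.sample_meta.index[self.sample_meta["region"] == region]
        if len(keep) == 0:
            raise KeyError(f"no samples for region {region!r}")
        return CountMatrix(self.counts[keep], self.sample_meta.loc[keep])

    def condition_columns(self, condition: str) -> pd.Index:
        return self.sample_meta.index[self.sample_meta["condition"] == condition]

    @staticmethod
    def concat(first: "CountMatrix", second: "CountMatrix") -> "CountMatrix":
        """Column-wise concatenation of two matrices over one feature universe."""
        if not first.counts.index.equals(second.counts.index):
            raise ValueError("feature universes differ")
        counts = pd.concat([first.counts, second.counts], axis=1)
        meta = pd.concat([first.sample_meta, second.sample_meta], axis=0)
        return CountMatrix(counts, meta)


@dataclass
class TruthTable:
    """Planted ground truth of a synthetic dataset.

    ``effects`` holds the true per-feature, per-region log2 fold-change
    (0 for null features); ``sc_effects`` records planted single-cell
    perturbations, one row each, with columns ``kind``
    (``proportion``/``expression``/``regulon``/``lr-edge``),
    ``cell_type``, ``target`` and ``magnitude``.
    """

    effects: pd.DataFrame = field(default_factory=pd.DataFrame)
    sc_effects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["kind", "cell_type", "target", "magnitude"]
        )
    )

    def status(self) -> pd.DataFrame:
        """Per feature x region true status (up/down/null)."""
        out = pd.DataFrame(
            np.where(
                self.effects.to_numpy() > 0,
                "up",
                np.where(self.effects.to_numpy() < 0, "down", "null"),
            ),
            index=self.effects.index,
            columns=self.effects.columns,
        )
        return out

    @property
    def n_nonnull(self) -> int:
        return int((self.effects.to_numpy() != 0).sum())
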