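"""Guide-count matrix with sample metadata and per-sample read accounting.

The accounting identity ``mapped + filtered_low_quality + unmatched ==
total_reads`` holds for every sample, and each count column sums to that
sample's mapped reads.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = ("condition", "replicate", "timepoint")
STAT_COLUMNS = ("total_reads", "mapped_reads", "filtered_low_quality", "unmatched")


class CountTable:
    """Guides x samples non-negative integer counts plus sample metadata.

    Parameters
    ----------
    counts : DataFrame indexed by guide_id, one integer column per sample.
    samples : DataFrame indexed by sample name with columns
        ``condition, replicate, timepoint``.
    stats : optional per-sample read accounting; if omitted every read is
        taken as mapped (``total = mapped = column sum``).
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        samples: pd.DataFrame,
        stats: pd.DataFrame | None = None,
    ):
        counts = counts.astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
        if missing:
            raise ValueError(f"sample sheet is missing columns: {missing}")
        if list(samples.index) != list(counts.columns):
            samples = samples.loc[list(counts.columns)]
        colsum = counts.sum(axis=0)
        if stats is None:
            stats = pd.DataFrame(
                {
                    "total_reads": colsum,
                    "mapped_reads": colsum,
                    "filtered_low_quality": 0,
                    "unmatched": 0,
                }
            )
        stats = stats.loc[list(counts.columns), list(STAT_COLUMNS)].astype(np.int64)
        bad = stats["total_reads"] != (
            stats["mapped_reads"] + stats["filtered_low_quality"] + stats["unmatched"]
        )
        if bad.any():
            raise ValueError(
                f"read accounting identity violated for sample {bad.idxmax()!r}"
            )
        off = colsum != stats["mapped_reads"]
        if off.any():
            raise ValueError(
                f"count column sum != mapped_reads for sample {off.idxmax()!r}"
            )
        self.counts = counts
        self.samples = samples
        self.stats = stats

    # -- accessors -------------------------------------------------------
    @property
    def guide_ids(self) -> np.ndarray:
        return self.counts.index.to_numpy()

    @property
    def n_guides(self) -> int:
        return len(self.counts)

    @property
    def sample_names(self) -> list[str]:
        return list(self.counts.columns)

    def samples_where(self, **criteria) -> list[str]:
        """Sample names whose metadata match all given column=value pairs."""
        mask = pd.Series(True, index=self.samples.index)
        for key, value in criteria.items():
            mask &= self.samples[key] == value
        return list(self.samples.index[mask])

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, counts_path, samples_path, stats_path=None) -> None:
        out = self.counts.copy()
        out.insert(0, "guide_id", out.index)
        out.to_csv(counts_path, sep="\t", index=False)
        self.samples.rename_axis("sample").reset_index().to_csv(
            samples_path, sep="\t", index=False
        )
        if stats_path is not None:
            self.stats.rename_axis("sample").reset_index().to_csv(
                stats_path, sep="\t", index=False
            )

    @classmethod
    def from_tsv(cls, counts_path, samples_path, stats_path=None) -> "CountTable":
        counts = pd.read_csv(counts_path, sep="\t").set_index("guide_id")
        samples = pd.read_csv(samples_path, sep="\t").set_index("sample")
        stats = None
        if stats_path is not None and Path(stats_path).exists():
            stats = pd.read_csv(stats_path, sep="\t").set_index("sample")
        return cls(counts, samples, stats)
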