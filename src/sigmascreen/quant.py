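"""Read quantification: FASTQ -> guide-count matrix.

Pipeline per read: mean-Phred quality filter (> 20, strict), anchor-based
protospacer extraction (leftmost exact anchor match, next 20 bases), then
exact hash lookup against the library (optionally with a unique 1-mismatch
rescue).  Per-sample accounting satisfies
``mapped + filtered_low_quality + unmatched == total_reads``.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .counts import CountTable
from .library import PROTOSPACER_LEN, GuideLibrary

DEFAULT_MIN_MEAN_PHRED = 20.0


def _open_text(source) -> IO[str]:
    if hasattr(source, "read"):
        return source
    path = Path(source)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq(source) -> Iterator[tuple[str, str, str]]:
    """Yield (title, sequence, quality), raising with the record index on
    malformed input."""
    handle = _open_text(source)
    it = FastqGeneralIterator(handle)
    i = 0
    while True:
        try:
            rec = next(it)
        except StopIteration:
            return
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record at index {i}: {exc}") from exc
        i += 1
        yield rec


def mean_phred(quality: str) -> float:
    if not quality:
        raise ValueError("empty quality string")
    return float(np.frombuffer(quality.encode("ascii"), dtype=np.uint8).mean() - 33.0)


def filter_quality(
    sequence: str, quality: str, min_mean_phred: float = DEFAULT_MIN_MEAN_PHRED
) -> bool:
    """Keep a read iff its mean base Phred strictly exceeds the threshold."""
    if len(sequence) != len(quality):
        raise ValueError("sequence and quality strings differ in length")
    return mean_phred(quality) > min_mean_phred


def extract_protospacer(
    sequence: str, anchor: str, length: int = PROTOSPACER_LEN
) -> str | None:
    """Return the ``length`` bases following the leftmost exact anchor match,
    or None if the anchor is absent or too close to the read end."""
    if not anchor:
        raise ValueError("anchor must be a non-empty string")
    pos = sequence.find(anchor)
    if pos < 0:
        return None
    start = pos + len(anchor)
    if start + length > len(sequence):
        return None
    return sequence[start : start + length]


def _mismatch_neighbors(kmer: str) -> Iterator[str]:
    for i, base in enumerate(kmer):
        for alt in "ACGT":
            if alt != base:
                yield kmer[:i] + alt + kmer[i + 1 :]


class GuideMatcher:
    """Exact (default) or unique-best 1-mismatch protospacer lookup."""

    def __init__(self, library: GuideLibrary, max_mismatches: int = 0):
        if max_mismatches not in (0, 1):
            raise ValueError("max_mismatches must be 0 or 1")
        self.library = library
        self.max_mismatches = max_mismatches
        self._lookup = dict(
            zip(library.frame["protospacer"], library.frame["guide_id"])
        )
        if len(self._lookup) != library.n_guides:
            raise ValueError("duplicate protospacers in library")

    def match(self, protospacer: str) -> str | None:
        hit = self._lookup.get(protospacer)
        if hit is not None or self.max_mismatches == 0:
            return hit
        hits = {
            self._lookup[n]
            for n in _mismatch_neighbors(protospacer)
            if n in self._lookup
        }
        if len(hits) == 1:
            return hits.pop()
        return None  # ambiguous or no neighbor -> unmatched


def match_guides(
    protospacers: Iterable[str],
    library: GuideLibrary,
    max_mismatches: int = 0,
) -> tuple[pd.Series, int]:
    """Count a stream of extracted protospacers against the library.

    Returns (counts indexed by guide_id in library order, n_unmatched).
    """
    matcher = GuideMatcher(library, max_mismatches)
    counts: dict[str, int] = {}
    unmatched = 0
    for p in protospacers:
        gid = matcher.match(p)
        if gid is None:
            unmatched += 1
        else:
            counts[gid] = counts.get(gid, 0) + 1
    series = pd.Series(counts, dtype=np.int64).reindex(
        library.guide_ids, fill_value=0
    )
    return series, unmatched


def quantify_fastq(
    source,
    library: GuideLibrary,
    anchor: str,
    max_mismatches: int = 0,
    min_mean_phred: float = DEFAULT_MIN_MEAN_PHRED,
) -> tuple[pd.Series, dict[str, int]]:
    """Quantify one sample's FASTQ into guide counts plus read accounting."""
    matcher = GuideMatcher(library, max_mismatches)
    counts: dict[str, int] = {}
    total = filtered = unmatched = mapped = 0
    for _title, seq, qual in iter_fastq(source):
        total += 1
        if not filter_quality(seq, qual, min_mean_phred):
            filtered += 1
            continue
        proto = extract_protospacer(seq, anchor)
        gid = matcher.match(proto) if proto is not None else None
        if gid is None:
            unmatched += 1
        else:
            mapped += 1
            counts[gid] = counts.get(gid, 0) + 1
    series = pd.Series(counts, dtype=np.int64).reindex(
        library.guide_ids, fill_value=0
    )
    stats = {
        "total_reads": total,
        "mapped_reads": mapped,
        "filtered_low_quality": filtered,
        "unmatched": unmatched,
    }
    return series, stats


def quantify_samples(
    fastq_by_sample: Mapping[str, object],
    sample_sheet: pd.DataFrame,
    library: GuideLibrary,
    anchor: str,
    max_mismatches: int = 0,
    min_mean_phred: float = DEFAULT_MIN_MEAN_PHRED,
) -> CountTable:
    """Quantify one FASTQ per sample (demultiplexed upstream) into a
    CountTable with the sample sheet's metadata."""
    counts = {}
    stats = {}
    for sample in sample_sheet.index:
        src = fastq_by_sample[sample]
        counts[sample], stats[sample] = quantify_fastq(
            src, library, anchor, max_mismatches, min_mean_phred
        )
    frame = pd.DataFrame(counts, index=library.guide_ids)
    stat_frame = pd.DataFrame(stats).T
    return CountTable(frame, sample_sheet, stat_frame)


def gini(values: np.ndarray) -> float:
    """Gini coefficient of non-negative counts (0 = perfectly uniform)."""
    x = np.sort(np.asarray(values, dtype=float))
    if x.size == 0:
        raise ValueError("empty input")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total == 0:
        return 0.0
    n = x.size
    ranks = np.arange(1, n + 1)
    return float((2.0 * (ranks * x).sum()) / (n * total) - (n + 1.0) / n)


def coverage_stats(table: CountTable) -> dict:
    """Library-coverage statistics per sample and pooled.

    ``mean_reads_per_guide`` is mapped reads / n_guides; ``fraction_zero``
    the share of guide cells with zero counts; ``gini`` the inequality of
    the pooled per-guide totals.
    """
    if table.counts.shape[1] == 0 or table.n_guides == 0:
        raise ValueError("empty count table")
    per_sample = pd.DataFrame(
        {
            "mean_reads_per_guide": table.stats["mapped_reads"] / table.n_guides,
            "fraction_zero_guides": (table.counts == 0).mean(axis=0),
            "gini": [gini(table.counts[s].to_numpy()) for s in table.counts.columns],
        }
    )
    pooled_counts = table.counts.sum(axis=1).to_numpy()
    pooled = {
        "mean_reads_per_guide": float(per_sample["mean_reads_per_guide"].mean()),
        "fraction_zero_guides": float((table.counts.to_numpy() == 0).mean()),
        "gini": gini(pooled_counts),
    }
    return {"per_sample": per_sample, "pooled": pooled}
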