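"""Guide library container and synthetic library construction.

A pooled knockout library is a table of sgRNAs: each guide carries a unique
identifier, the gene symbol it targets (or ``CONTROL`` for non-targeting
guides), and a unique 20-nt protospacer.  The genome-wide design emulated by
:func:`build_library` is ~19,000 genes x 4 guides plus 1,000 control guides,
the scale of the Brunello library.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd

PROTOSPACER_LEN = 20
CONTROL_GENE = "CONTROL"
_BASES = np.array(list("ACGT"))

_REQUIRED_COLUMNS = ("guide_id", "gene", "protospacer", "is_control")


class GuideLibrary:
    """Immutable-ish guide universe backed by a pandas DataFrame.

    Invariants enforced at construction: unique guide ids, unique
    protospacers, 20-mer protospacers over ACGT, and consistency between the
    control flag and the ``CONTROL`` gene symbol.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"guide library is missing columns: {missing}")
        frame = frame.loc[:, list(_REQUIRED_COLUMNS)].reset_index(drop=True)
        frame["is_control"] = frame["is_control"].astype(bool)
        if frame["guide_id"].duplicated().any():
            dup = frame.loc[frame["guide_id"].duplicated(), "guide_id"].iloc[0]
            raise ValueError(f"duplicate guide_id in library: {dup!r}")
        if frame["protospacer"].duplicated().any():
            dup = frame.loc[frame["protospacer"].duplicated(), "protospacer"].iloc[0]
            raise ValueError(f"duplicate protospacer in library: {dup!r}")
        bad = ~frame["protospacer"].str.fullmatch(f"[ACGT]{{{PROTOSPACER_LEN}}}")
        if bad.any():
            raise ValueError(
                f"protospacers must be {PROTOSPACER_LEN}-mers over ACGT; "
                f"offending guide: {frame.loc[bad, 'guide_id'].iloc[0]!r}"
            )
        ctrl_gene = frame["gene"] == CONTROL_GENE
        if not (ctrl_gene == frame["is_control"]).all():
            raise ValueError(
                f"control guides must (and only they may) carry gene == {CONTROL_GENE!r}"
            )
        self.frame = frame

    # -- basic accessors -------------------------------------------------
    @property
    def n_guides(self) -> int:
        return len(self.frame)

    @property
    def guide_ids(self) -> np.ndarray:
        return self.frame["guide_id"].to_numpy()

    @property
    def targeting(self) -> np.ndarray:
        """Boolean mask over guides, True for gene-targeting guides."""
        return ~self.frame["is_control"].to_numpy()

    @property
    def genes(self) -> list[str]:
        """Targeting gene symbols in order of first appearance."""
        g = self.frame.loc[~self.frame["is_control"], "gene"]
        return list(dict.fromkeys(g))

    @property
    def n_controls(self) -> int:
        return int(self.frame["is_control"].sum())

    def gene_of_guide(self) -> pd.Series:
        """guide_id -> gene symbol (``CONTROL`` for control guides)."""
        return pd.Series(
            self.frame["gene"].to_numpy(), index=self.frame["guide_id"].to_numpy()
        )

    def mean_guides_per_gene(self) -> float:
        return (self.n_guides - self.n_controls) / len(self.genes)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.n_guides

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path) -> None:
        out = self.frame.copy()
        out["is_control"] = out["is_control"].astype(int)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GuideLibrary":
        frame = pd.read_csv(path, sep="\t", dtype={"guide_id": str, "gene": str})
        frame["is_control"] = frame["is_control"].astype(int).astype(bool)
        return cls(frame)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for rec in self.frame.itertuples(index=False):
                fh.write(f">{rec.guide_id}\n{rec.protospacer}\n")


def _random_kmers(rng: np.random.Generator, n: int, seen: set[str]) -> list[str]:
    out: list[str] = []
    while len(out) < n:
        batch = _BASES[rng.integers(0, 4, size=(n - len(out), PROTOSPACER_LEN))]
        for row in batch:
            s = "".join(row)
            if s not in seen:
                seen.add(s)
                out.append(s)
    return out


def build_library(
    n_genes: int, guides_per_gene: int, n_controls: int, seed: int
) -> GuideLibrary:
    """Construct a synthetic guide library with distinct random protospacers.

    Gene symbols are ``GENE00001`` ...; guide ids ``GENE00001_g1`` ...; control
    guides are ``CTRL0001`` ... with gene ``CONTROL``.  Deterministic for a
    fixed seed.
    """
    if n_genes < 1 or guides_per_gene < 1 or n_controls < 0:
        raise ValueError("need n_genes >= 1, guides_per_gene >= 1, n_controls >= 0")
    total = n_genes * guides_per_gene + n_controls
    if total > 4**PROTOSPACER_LEN // 4:
        raise ValueError(
            f"cannot draw {total} distinct {PROTOSPACER_LEN}-mers collision-free"
        )
    rng = np.random.default_rng(seed)
    seqs = _random_kmers(rng, total, set())

    width = max(5, len(str(n_genes)))
    cwidth = max(4, len(str(max(n_controls, 1))))
    guide_ids, gene_col, is_ctrl = [], [], []
    for i in range(n_genes):
        gene = f"GENE{i + 1:0{width}d}"
        for j in range(guides_per_gene):
            guide_ids.append(f"{gene}_g{j + 1}")
            gene_col.append(gene)
            is_ctrl.append(False)
    for i in range(n_controls):
        guide_ids.append(f"CTRL{i + 1:0{cwidth}d}")
        gene_col.append(CONTROL_GENE)
        is_ctrl.append(True)

    frame = pd.DataFrame(
        {
            "guide_id": guide_ids,
            "gene": gene_col,
            "protospacer": seqs,
            "is_control": is_ctrl,
        }
    )
    return GuideLibrary(frame)


def screen_design_stats(
    n_guides_total: int,
    n_control_guides: int,
    n_genes: int,
    bottleneck_cells: float,
    mapped_reads_per_sample: float,
) -> dict[str, float]:
    """Design arithmetic of a pooled screen.

    Returns cells-per-guide representation at the passaging bottleneck, mean
    mappable reads per guide, and mean targeting guides per gene -- the three
    coverage figures a screen design is judged by.
    """
    if n_guides_total <= 0 or n_genes <= 0:
        raise ValueError("guide and gene totals must be positive")
    if not 0 <= n_control_guides <= n_guides_total:
        raise ValueError("control guide count out of range")
    return {
        "cells_per_guide": bottleneck_cells / n_guides_total,
        "mean_reads_per_guide": mapped_reads_per_sample / n_guides_total,
        "mean_guides_per_gene": (n_guides_total - n_control_guides) / n_genes,
    }
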