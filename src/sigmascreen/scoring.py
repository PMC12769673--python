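"""Sigma (Z) scoring: guide log2 fold-changes, gene scores, Z differences.

The screen statistic is built in four steps: (1) counts are converted to
relative abundances with a pseudocount; (2) each treated sample's guide
abundances are compared to the shared T0 baseline of its replicate as a
log2 fold-change; (3) guide LFCs are averaged over a gene's guides and the
condition's replicates; (4) gene scores are Z-transformed within each
condition over gene-targeting genes (population SD, controls excluded).
The sigma-plot quantity is the per-gene Z difference between two
conditions, and hits are called at |dZ| >= 3 (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts import CountTable
from .library import GuideLibrary


# ---------------------------------------------------------------------------
# Normalization and fold-changes
# ---------------------------------------------------------------------------
def normalize_counts(
    table: CountTable | pd.DataFrame,
    pseudocount: float = 0.5,
    method: str = "total",
) -> pd.DataFrame:
    """Per-sample normalized guide abundances.

    ``total`` (default): (count + pseudocount) / column total, so columns
    sum to 1.  ``median-ratio``: DESeq-style size factors (median ratio to
    the per-guide geometric mean across samples) applied to
    (count + pseudocount); columns then share a common scale but do not sum
    to 1.
    """
    counts = table.counts if isinstance(table, CountTable) else table
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    depth = counts.sum(axis=0)
    if (depth == 0).any():
        raise ValueError(f"zero-depth sample: {depth.idxmin()!r}")
    shifted = counts.astype(float) + pseudocount
    if method == "total":
        return shifted / shifted.sum(axis=0)
    if method == "median-ratio":
        log_geo = np.log(shifted).mean(axis=1)
        size = np.exp(np.log(shifted).sub(log_geo, axis=0).median(axis=0))
        return shifted / size
    raise ValueError(f"unknown normalization method {method!r}")


def guide_lfc(
    abundances: pd.DataFrame,
    samples: pd.DataFrame,
    baseline_timepoint: str = "T0",
) -> pd.DataFrame:
    """log2 fold-change of each treated sample versus its replicate's T0.

    Returns a guides x (condition, replicate) MultiIndex frame.  Every
    treated sample must have exactly one baseline sample sharing its
    replicate at ``baseline_timepoint``.
    """
    is_base = samples["timepoint"] == baseline_timepoint
    baselines = samples[is_base]
    treated = samples[~is_base]
    if treated.empty:
        raise ValueError("no treated samples in sample sheet")
    base_by_rep = {}
    for name, row in baselines.iterrows():
        rep = row["replicate"]
        if rep in base_by_rep:
            raise ValueError(f"multiple {baseline_timepoint} samples for replicate {rep}")
        base_by_rep[rep] = name

    cols = {}
    for name, row in treated.iterrows():
        rep = row["replicate"]
        if rep not in base_by_rep:
            raise ValueError(
                f"missing {baseline_timepoint} baseline for replicate {rep} "
                f"(sample {name!r})"
            )
        cols[(row["condition"], rep)] = np.log2(
            abundances[name] / abundances[base_by_rep[rep]]
        )
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["condition", "replicate"])
    return out.sort_index(axis=1)


# ---------------------------------------------------------------------------
# Gene aggregation and Z transform
# ---------------------------------------------------------------------------
def gene_score(lfc: pd.DataFrame, library: GuideLibrary) -> pd.DataFrame:
    """Per-gene per-condition mean LFC (controls excluded).

    Unweighted nested mean: replicates are averaged within each guide, then
    guides within each gene.  Every gene must have at least one guide.
    """
    gene_map = library.gene_of_guide()
    targeting = library.frame.loc[~library.frame["is_control"], "guide_id"]
    missing = [g for g in targeting if g not in lfc.index]
    if missing:
        raise ValueError(f"guides without LFC data: {missing[:5]}")
    sub = lfc.loc[targeting]
    per_guide = sub.T.groupby(level="condition").mean().T  # mean over replicates
    genes = gene_map.loc[targeting].to_numpy()
    return per_guide.groupby(genes).mean()


def control_guide_lfc(lfc: pd.DataFrame, library: GuideLibrary) -> pd.DataFrame:
    """Control-guide LFCs (replicate-averaged) as an empirical-null
    diagnostic; not part of gene scoring."""
    ctrl = library.frame.loc[library.frame["is_control"], "guide_id"]
    return lfc.loc[lfc.index.intersection(ctrl)].T.groupby(level="condition").mean().T


def zscore(gene_scores: pd.DataFrame) -> pd.DataFrame:
    """Z-transform gene scores within each condition (population SD).

    The mean and SD are taken over gene-targeting genes only; a zero SD is a
    degenerate screen and raises.
    """
    if len(gene_scores) < 2:
        raise ValueError("need at least two genes to Z-transform")
    mu = gene_scores.mean(axis=0)
    sd = gene_scores.std(axis=0, ddof=0)
    if (sd == 0).any():
        raise ValueError(f"zero SD in condition {sd.idxmin()!r}: degenerate screen")
    return (gene_scores - mu) / sd


def gene_score_z_first(lfc: pd.DataFrame, library: GuideLibrary) -> pd.DataFrame:
    """Alternative aggregation order: Z-score guide LFCs within each
    condition (pooled over guides and replicates), then average per gene."""
    targeting = library.frame.loc[~library.frame["is_control"], "guide_id"]
    sub = lfc.loc[targeting]
    gene_map = library.gene_of_guide()
    out = {}
    for cond in sub.columns.get_level_values("condition").unique():
        block = sub[cond]
        vals = block.to_numpy()
        mu, sd = vals.mean(), vals.std(ddof=0)
        if sd == 0:
            raise ValueError(f"zero SD in condition {cond!r}")
        z = (block - mu) / sd
        out[cond] = z.mean(axis=1).groupby(gene_map.loc[targeting].to_numpy()).mean()
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Sigma differences and hit calling
# ---------------------------------------------------------------------------
def sigma_diff(z: pd.DataFrame, condition_a: str, condition_b: str) -> pd.Series:
    """Per-gene Z difference z_a - z_b (the sigma-plot quantity).

    For suppressor contrasts, ``condition_a`` is the drug arm so that
    enriched (suppressor) genes have positive values.
    """
    for cond in (condition_a, condition_b):
        if cond not in z.columns:
            raise ValueError(f"unknown condition {cond!r}")
    delta = z[condition_a] - z[condition_b]
    delta.name = f"{condition_a}-{condition_b}"
    return delta


def call_hits(
    delta_z: pd.Series, threshold: float = 3.0, direction: str = "both"
) -> pd.DataFrame:
    """Call suppressors (dZ >= threshold) and/or synthetic-sick genes
    (dZ <= -threshold); sorted by |dZ| descending, ties by gene symbol."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if direction not in ("both", "suppressor", "synthetic_sick"):
        raise ValueError(f"unknown direction {direction!r}")
    rows = []
    for gene, value in delta_z.items():
        if value >= threshold and direction in ("both", "suppressor"):
            rows.append((gene, "suppressor", float(value)))
        elif value <= -threshold and direction in ("both", "synthetic_sick"):
            rows.append((gene, "synthetic_sick", float(value)))
    rows.sort(key=lambda r: (-abs(r[2]), r[0]))
    out = pd.DataFrame(rows, columns=["gene", "direction", "delta_z"])
    out["threshold"] = threshold
    return out


# ---------------------------------------------------------------------------
# End-to-end scoring and export
# ---------------------------------------------------------------------------
@dataclass
class ScreenScores:
    """Gene-level result bundle for a scored screen."""

    mean_lfc: pd.DataFrame  # genes x conditions
    z: pd.DataFrame  # genes x conditions
    delta_z: dict[tuple[str, str], pd.Series] = field(default_factory=dict)
    hits: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)


def score_screen(
    table: CountTable,
    library: GuideLibrary,
    contrasts: list[tuple[str, str]] | None = None,
    pseudocount: float = 0.5,
    normalization: str = "total",
    z_before_average: bool = False,
    threshold: float = 3.0,
    hit_direction: str = "both",
    baseline_timepoint: str = "T0",
) -> ScreenScores:
    """Counts -> abundances -> LFC -> gene scores -> Z -> dZ -> hits."""
    abund = normalize_counts(table, pseudocount=pseudocount, method=normalization)
    lfc = guide_lfc(abund, table.samples, baseline_timepoint=baseline_timepoint)
    if z_before_average:
        mean_lfc = gene_score(lfc, library)
        z = gene_score_z_first(lfc, library)
    else:
        mean_lfc = gene_score(lfc, library)
        z = zscore(mean_lfc)
    scores = ScreenScores(mean_lfc=mean_lfc, z=z)
    for a, b in contrasts or []:
        delta = sigma_diff(z, a, b)
        scores.delta_z[(a, b)] = delta
        scores.hits[(a, b)] = call_hits(delta, threshold=threshold, direction=hit_direction)
    return scores


def export_sigma_table(
    z: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    path,
    threshold: float = 3.0,
) -> pd.DataFrame:
    """Write the ranked sigma table for a contrast (rank 1 = largest dZ).

    Deterministic ordering: delta_z descending, ties by gene symbol.
    """
    delta = sigma_diff(z, condition_a, condition_b)
    frame = pd.DataFrame(
        {
            "gene": delta.index,
            "z_a": z.loc[delta.index, condition_a].to_numpy(),
            "z_b": z.loc[delta.index, condition_b].to_numpy(),
            "delta_z": delta.to_numpy(),
        }
    )
    frame = frame.sort_values(
        ["delta_z", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    frame["hit"] = (frame["delta_z"].abs() >= threshold).astype(int)
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return frame


def read_sigma_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def plot_sigma(z: pd.DataFrame, condition_a: str, condition_b: str, path) -> None:
    """Minimal ranked sigma-plot figure (diagnostic convenience)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    delta = sigma_diff(z, condition_a, condition_b).sort_values(ascending=False)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(np.arange(1, len(delta) + 1), delta.to_numpy(), s=4, alpha=0.6)
    ax.axhline(3, color="grey", lw=0.5)
    ax.axhline(-3, color="grey", lw=0.5)
    ax.set_xlabel("gene rank")
    ax.set_ylabel(f"dZ ({condition_a} - {condition_b})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
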