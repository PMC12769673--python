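"""Gene-set enrichment of hit lists by right-tailed Fisher's exact test.

For each gene set the 2x2 table (hits-in-set, hits-out, nonhits-in,
nonhits-out) over the screen universe is tested with a right-tailed
Fisher's exact test (hypergeometric upper tail, summed in log space via
log-gamma to stay stable at genome scale), followed by Benjamini-Hochberg
adjustment across the retained sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")


def read_gmt(path) -> list[GeneSet]:
    """Read a GMT file (name, description, members per tab-separated line)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets.append(GeneSet(fields[0], frozenset(g for g in fields[2:] if g)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, description, *sorted(s.members)]) + "\n")


def _log_hypergeom_pmf(k: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    # P(X = k) for k successes in n draws from N with K successes total
    return (
        gammaln(K + 1) - gammaln(k + 1) - gammaln(K - k + 1)
        + gammaln(N - K + 1) - gammaln(n - k + 1) - gammaln(N - K - n + k + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def fisher_right(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Right-tailed Fisher's exact test of the 2x2 table [[a, b], [c, d]].

    Returns (p, odds_ratio) with p = P(X >= a) for the hypergeometric with
    the table's margins.  The odds ratio is (a*d)/(b*c); when b*c == 0 the
    Haldane-Anscombe continuity correction (+0.5 to every cell) is applied.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("table counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    N = a + b + c + d
    K = a + c  # column-1 margin (e.g. set size)
    n = a + b  # row-1 margin (e.g. number of hits)
    if a == 0:
        p = 1.0
    else:
        kmax = min(n, K)
        ks = np.arange(a, kmax + 1)
        if ks.size == 0:
            p = 0.0
        else:
            logpmf = _log_hypergeom_pmf(ks, N, K, n)
            m = logpmf.max()
            p = float(np.exp(m) * np.exp(logpmf - m).sum())
            p = min(p, 1.0)
    if b * c == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return p, float(odds)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_sets(
    hits: Iterable[str],
    universe: Iterable[str],
    sets: Iterable[GeneSet],
    min_set_size: int = 3,
) -> pd.DataFrame:
    """Test each gene set for over-representation among the hits.

    Sets are intersected with the universe first and dropped below
    ``min_set_size``; BH adjustment runs across the retained sets; results
    are sorted by (p, name).
    """
    universe_set = set(universe)
    hit_set = set(hits)
    offenders = sorted(hit_set - universe_set)
    if offenders:
        raise ValueError(f"hits not in universe: {offenders[:10]}")
    n_universe = len(universe_set)
    n_hits = len(hit_set)
    rows = []
    for s in sets:
        members = s.members & universe_set
        if len(members) < min_set_size:
            continue
        a = len(hit_set & members)
        b = n_hits - a
        c = len(members) - a
        d = n_universe - n_hits - c
        p, odds = fisher_right(a, b, c, d)
        rows.append(
            {
                "set": s.name,
                "set_size": len(members),
                "hits_in_set": a,
                "hits_not_in_set": b,
                "nonhits_in_set": c,
                "nonhits_not_in_set": d,
                "odds_ratio": odds,
                "p": p,
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "set", "set_size", "hits_in_set", "hits_not_in_set",
            "nonhits_in_set", "nonhits_not_in_set", "odds_ratio", "p",
        ],
    )
    if len(result):
        result["q"] = bh_adjust(result["p"].to_numpy())
        result = result.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
    else:
        result["q"] = []
    return result
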