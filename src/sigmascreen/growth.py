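"""Growth bookkeeping: population doublings, cumulative curves, MOI.

Population doubling over an interval is ``(log(N_end) - log(N_start)) /
log(2)`` -- the log-base cancels, natural log is used internally.  The
infection-efficiency to MOI conversion assumes single-hit Poisson
infection, ``infected fraction = 1 - exp(-MOI)``.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd


def population_doubling(n_start: float, n_end: float) -> float:
    """Doublings from a starting to an ending cell count (may be negative)."""
    if n_start <= 0 or n_end <= 0:
        raise ValueError("cell counts must be positive")
    return (math.log(n_end) - math.log(n_start)) / math.log(2.0)


def cumulative_doublings(records: pd.DataFrame) -> pd.DataFrame:
    """Per-interval and cumulative doublings from seeded/harvested counts.

    ``records`` needs columns ``time_days, seeded, harvested`` and may carry
    ``condition`` and ``replicate`` (each (condition, replicate) series is
    accumulated separately).  Timepoints must be strictly increasing within
    each series.
    """
    for col in ("time_days", "seeded", "harvested"):
        if col not in records.columns:
            raise ValueError(f"missing column {col!r}")
    frame = records.copy()
    group_cols = [c for c in ("condition", "replicate") if c in frame.columns]
    groups = frame.groupby(group_cols, sort=False) if group_cols else [((), frame)]
    out = []
    for _key, sub in groups:
        t = sub["time_days"].to_numpy()
        if (np.diff(t) <= 0).any():
            raise ValueError("timepoints must be strictly increasing")
        sub = sub.copy()
        sub["doublings"] = [
            population_doubling(s, h)
            for s, h in zip(sub["seeded"], sub["harvested"])
        ]
        sub["cumulative_doublings"] = sub["doublings"].cumsum()
        out.append(sub)
    return pd.concat(out).sort_index()


def infection_efficiency(
    survivors_with_puromycin: float, survivors_without: float
) -> float:
    """Fraction of infected cells from paired selected/unselected counts."""
    if survivors_without <= 0:
        raise ValueError("unselected survivor count must be positive")
    if survivors_with_puromycin < 0:
        raise ValueError("selected survivor count must be non-negative")
    eff = survivors_with_puromycin / survivors_without
    if eff > 1.0:
        warnings.warn(
            "more survivors with selection than without; clipping efficiency to 1",
            stacklevel=2,
        )
        eff = 1.0
    return eff


def moi_from_efficiency(eff: float) -> float:
    """Poisson-inverted multiplicity of infection: MOI = -ln(1 - eff)."""
    if not 0.0 <= eff < 1.0:
        raise ValueError("efficiency must be in [0, 1)")
    return -math.log1p(-eff)


def efficiency_from_moi(moi: float) -> float:
    if moi < 0:
        raise ValueError("MOI must be non-negative")
    return 1.0 - math.exp(-moi)


def moi_window(eff_low: float = 0.30, eff_high: float = 0.50) -> tuple[float, float]:
    """Poisson-implied MOI interval for a target infection-efficiency window
    (the 30-50% efficiency target maps to roughly [0.357, 0.693])."""
    return moi_from_efficiency(eff_low), moi_from_efficiency(eff_high)
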