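"""[1,2-13C2]-glucose isotope-tracing arithmetic.

Measured mass-isotopomer distributions (MIDs) are corrected for natural 13C
abundance (~1.07%) and tracer impurity by inverting a binomial convolution
matrix with non-negative least squares, normalized to total metabolite
intensity, and summarized as ratios: the lactate m+1/m+2 ratio separates
oxidative pentose-phosphate-pathway flux (C1 lost as CO2 -> m+1 lactate)
from intact glycolysis (m+2 lactate), and the G6P/glucose total-pool ratio
indexes glucose uptake.

A two-pathway forward simulator generates 3-carbon MIDs under the classic
single-pass mixing model so the whole chain is testable: a glycolytic
glucose yields one m+2 and one m+0 lactate, an oxPPP glucose one m+1 and
one m+0, hence labeled-lactate fractions satisfy m1/(m1+m2) = f_ppp.
Non-oxidative PPP recycling and exchange fluxes are deliberately excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from scipy.stats import binom

logger = logging.getLogger(__name__)

NATURAL_13C_ABUNDANCE = 0.0107


@dataclass
class MIDVector:
    """Isotopologue vector m+0 .. m+n for one metabolite with n carbons."""

    metabolite: str
    n_carbons: int
    intensities: np.ndarray

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.n_carbons < 1:
            raise ValueError("metabolite must have at least one carbon")
        if self.intensities.shape != (self.n_carbons + 1,):
            raise ValueError(
                f"{self.metabolite}: expected {self.n_carbons + 1} isotopologue "
                f"entries, got {self.intensities.shape}"
            )
        if (self.intensities < 0).any():
            raise ValueError(f"{self.metabolite}: negative intensities")

    @property
    def total(self) -> float:
        return float(self.intensities.sum())

    def fractions(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError(f"{self.metabolite}: all-zero MID")
        return self.intensities / self.total


@dataclass(frozen=True)
class TracerSpec:
    """[1,2-13C2]glucose tracer: two labeled positions, isotopic purity, and
    the natural 13C abundance used for background correction."""

    labeled_positions: tuple[str, str] = ("C1", "C2")
    purity: float = 1.0
    p13: float = NATURAL_13C_ABUNDANCE

    def __post_init__(self):
        if not 0.0 < self.purity <= 1.0:
            raise ValueError("purity must be in (0, 1]")
        if not 0.0 <= self.p13 < 0.5:
            raise ValueError("natural abundance must be in [0, 0.5)")


@dataclass(frozen=True)
class FluxScenario:
    """Two-pathway glucose fate: fraction f_ppp through oxidative PPP, the
    remainder via glycolysis; pool sizes in arbitrary intensity units."""

    f_ppp: float
    glucose_pool: float = 1.0
    uptake_ratio: float = 0.5  # G6P total / glucose total
    lactate_pool: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.f_ppp <= 1.0:
            raise ValueError("f_ppp must be in [0, 1]")


# ---------------------------------------------------------------------------
# Correction matrix and inversion
# ---------------------------------------------------------------------------
def correction_matrix(
    n_carbons: int, p13: float = NATURAL_13C_ABUNDANCE, purity: float = 1.0
) -> np.ndarray:
    """(n+1) x (n+1) matrix M with M[i, j] = P(observed mass m+i | j
    tracer-derived labels).

    Column j is the convolution of Binomial(j, purity) retention over the
    labeled carbons with Binomial(n - j, p13) natural enrichment over the
    unlabeled carbons.  Only carbon isotopes are modeled, so each column
    sums to 1.
    """
    if n_carbons < 1:
        raise ValueError("n_carbons must be >= 1")
    if not 0.0 <= p13 < 0.5:
        raise ValueError("natural abundance must be in [0, 0.5)")
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must be in (0, 1]")
    n = n_carbons
    M = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        labeled = binom.pmf(np.arange(j + 1), j, purity)
        natural = binom.pmf(np.arange(n - j + 1), n - j, p13)
        M[:, j] = np.convolve(labeled, natural)
    return M


def correct_mid(raw: MIDVector | np.ndarray, M: np.ndarray) -> tuple[MIDVector, float]:
    """Invert the convolution by non-negative least squares.

    Returns the corrected fraction-mode MID (sums to 1) and the NNLS
    residual norm relative to the total raw intensity.  NNLS rather than a
    plain solve forbids negative corrected fractions on noisy input.
    """
    if isinstance(raw, MIDVector):
        name, n_carbons, y = raw.metabolite, raw.n_carbons, raw.intensities
    else:
        y = np.asarray(raw, dtype=float)
        name, n_carbons = "metabolite", len(y) - 1
    if M.shape != (len(y), len(y)):
        raise ValueError("correction matrix and MID dimensions disagree")
    total = y.sum()
    if total == 0:
        raise ValueError(f"{name}: cannot correct an all-zero MID")
    t, residual = nnls(M, y / total)
    if t.sum() == 0:
        raise ValueError(f"{name}: correction produced an all-zero vector")
    corrected = MIDVector(name, n_carbons, t / t.sum())
    return corrected, float(residual)


def normalize_total(
    mids: list[MIDVector] | dict[str, MIDVector],
) -> tuple[list[MIDVector], dict[str, float]]:
    """Convert MIDs to fraction mode; retain totals as pool-size statistics
    ("total sum of all masses").  Idempotent on fraction-mode input."""
    items = list(mids.values()) if isinstance(mids, dict) else list(mids)
    fractions = []
    totals: dict[str, float] = {}
    for mid in items:
        if mid.total <= 0:
            raise ValueError(f"{mid.metabolite}: zero total intensity")
        totals[mid.metabolite] = mid.total
        fractions.append(MIDVector(mid.metabolite, mid.n_carbons, mid.fractions()))
    return fractions, totals


# ---------------------------------------------------------------------------
# Ratios
# ---------------------------------------------------------------------------
def ppp_index(lactate: MIDVector) -> float:
    """Lactate m+1 / m+2 fraction ratio; rises with oxidative PPP flux."""
    if lactate.n_carbons != 3:
        raise ValueError("lactate has 3 carbons")
    f = lactate.fractions()
    if f[2] == 0:
        raise ValueError("lactate m+2 is zero: uninformative labeling")
    return float(f[1] / f[2])


def ppp_fraction(lactate: MIDVector) -> float:
    """m1 / (m1 + m2): equals f_ppp under the single-pass mixing model."""
    f = lactate.fractions()
    if f[1] + f[2] == 0:
        raise ValueError("no labeled lactate: uninformative")
    return float(f[1] / (f[1] + f[2]))


def uptake_index(g6p_total: float, glucose_total: float) -> float:
    """G6P / glucose total-pool ratio (glucose-uptake index)."""
    if glucose_total <= 0:
        raise ValueError("glucose total must be positive")
    if g6p_total < 0:
        raise ValueError("G6P total must be non-negative")
    return g6p_total / glucose_total


# ---------------------------------------------------------------------------
# Forward simulator
# ---------------------------------------------------------------------------
def simulate_labeling(
    scenario: FluxScenario,
    tracer: TracerSpec = TracerSpec(),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> dict[str, MIDVector]:
    """Forward-simulate observed MIDs for lactate, G6P and glucose.

    True tracer-label distributions: lactate (m0, m1, m2, m3) =
    (1/2, f/2, (1-f)/2, 0); medium glucose and G6P carry two tracer labels.
    Observed intensities are the natural-abundance/purity convolution of the
    true vectors (correction_matrix forward mode), optionally with
    proportional Gaussian noise truncated at zero.
    """
    f = scenario.f_ppp
    rng = np.random.default_rng(seed)

    lactate_true = np.array([0.5, f / 2.0, (1.0 - f) / 2.0, 0.0])
    m3 = correction_matrix(3, tracer.p13, tracer.purity)
    m6 = correction_matrix(6, tracer.p13, tracer.purity)
    glucose_true = np.zeros(7)
    glucose_true[2] = 1.0  # medium glucose is the 1,2-13C2 tracer

    out = {
        "lactate": scenario.lactate_pool * (m3 @ lactate_true),
        "g6p": scenario.uptake_ratio * scenario.glucose_pool * (m6 @ glucose_true),
        "glucose": scenario.glucose_pool * (m6 @ glucose_true),
    }
    mids = {}
    for name, intens in out.items():
        if noise_sd > 0:
            intens = np.clip(
                intens * (1.0 + rng.normal(0.0, noise_sd, size=intens.size)), 0.0, None
            )
        mids[name] = MIDVector(name, len(intens) - 1, intens)
    return mids


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------
def write_mid_csv(mids: dict[str, dict[str, MIDVector]], path) -> None:
    """Write per-sample MIDs: columns sample, metabolite, m0..mN (unused
    isotopologue columns empty)."""
    import pandas as pd

    max_n = max(m.n_carbons for sample in mids.values() for m in sample.values())
    rows = []
    for sample in sorted(mids):
        for name in sorted(mids[sample]):
            mid = mids[sample][name]
            row = {"sample": sample, "metabolite": name}
            for i in range(max_n + 1):
                row[f"m{i}"] = (
                    mid.intensities[i] if i <= mid.n_carbons else np.nan
                )
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def read_mid_csv(path) -> dict[str, dict[str, MIDVector]]:
    """Read per-sample MIDs written by :func:`write_mid_csv`; the carbon
    count of each metabolite is inferred from its populated columns."""
    import pandas as pd

    frame = pd.read_csv(path)
    if frame.empty:
        raise ValueError(f"empty MID table: {path}")
    mcols = [c for c in frame.columns if c.startswith("m") and c[1:].isdigit()]
    mcols.sort(key=lambda c: int(c[1:]))
    out: dict[str, dict[str, MIDVector]] = {}
    for row in frame.itertuples(index=False):
        vals = [getattr(row, c) for c in mcols]
        while vals and np.isnan(vals[-1]):
            vals.pop()
        out.setdefault(row.sample, {})[row.metabolite] = MIDVector(
            row.metabolite, len(vals) - 1, np.asarray(vals)
        )
    return out


# ---------------------------------------------------------------------------
# Replicate QC
# ---------------------------------------------------------------------------
def flag_low_yield(
    totals: dict[str, float], min_fraction_of_median: float = 0.2
) -> tuple[list[str], list[str]]:
    """Split samples into (kept, excluded) by total intensity relative to
    the batch median; exclusions are logged, never silent."""
    if not totals:
        raise ValueError("no samples to QC")
    median = float(np.median(list(totals.values())))
    kept, excluded = [], []
    for sample, total in totals.items():
        if median > 0 and total < min_fraction_of_median * median:
            excluded.append(sample)
            logger.warning(
                "excluding sample %r: total intensity %.3g < %.0f%% of batch median %.3g",
                sample, total, 100 * min_fraction_of_median, median,
            )
        else:
            kept.append(sample)
    return kept, excluded
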