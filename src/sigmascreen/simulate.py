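"""Generative model of the pooled knockout fitness screen.

The simulator reproduces the screen design end to end: a clonally expanded
pool is split at T0 into drug conditions (solvent reference, mistranslation
inducer, translation inhibitor, and their combination), each in three
replicates, passaged every 72 h at a fixed 4e7-cell bottleneck for 15 days,
and sequenced at ~150x guide coverage.

Growth between passages is deterministic exponential competition: guide *g*
in condition *c* multiplies by ``2 ** (D_c * (1 + s_eff(g, c)))`` per
passage, where ``D_c = passage_interval_h / untreated_doubling_time_h *
(1 - growth_inhibition(c))`` is the condition's population doublings per
passage and ``s_eff = guide_efficacy * s(gene, c)`` is the efficacy-weighted
selection coefficient.  The bottleneck renormalizes relative abundances
(optionally with multinomial sampling at the bottleneck cell number), and
sequencing draws multinomial counts from the final abundance vector.
Everything is deterministic for a fixed master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import IO, Mapping

import numpy as np
import pandas as pd

from .counts import CountTable
from .library import CONTROL_GENE, GuideLibrary, build_library

GENE_CLASSES = ("neutral", "suppressor", "synthetic_sick")


# ---------------------------------------------------------------------------
# Screen design
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class ScreenDesign:
    """Screen layout and growth parameters.

    Defaults mirror the genome-wide screen: four conditions with an ethanol
    solvent reference, three replicates, 15 days of 72 h passages at a 4e7
    cell bottleneck, a 24 h untreated doubling time, ~40% growth inhibition
    in every drug arm, and sequencing at 150x guide coverage.
    """

    conditions: tuple[str, ...] = ("ETOH", "ACT", "CAP", "ACTCAP")
    reference_condition: str = "ETOH"
    n_replicates: int = 3
    duration_days: float = 15.0
    passage_interval_h: float = 72.0
    bottleneck_cells: int = 40_000_000
    untreated_doubling_time_h: float = 24.0
    growth_inhibition: Mapping[str, float] = field(
        default_factory=lambda: {"ACT": 0.40, "CAP": 0.40, "ACTCAP": 0.40}
    )
    baseline_timepoint: str = "T0"
    treated_timepoint: str = "D15"
    coverage: float = 150.0
    reads_per_sample: int | None = None

    def __post_init__(self):
        if self.reference_condition not in self.conditions:
            raise ValueError(
                f"reference condition {self.reference_condition!r} not declared"
            )
        n_pass = self.duration_days * 24.0 / self.passage_interval_h
        if abs(n_pass - round(n_pass)) > 1e-9 or n_pass < 1:
            raise ValueError("duration must divide into whole passages")
        for cond, frac in self.growth_inhibition.items():
            if not 0.0 <= frac < 1.0:
                raise ValueError(f"growth inhibition for {cond!r} must be in [0, 1)")
            if cond not in self.conditions:
                raise ValueError(f"growth inhibition given for unknown condition {cond!r}")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")

    @property
    def n_passages(self) -> int:
        return int(round(self.duration_days * 24.0 / self.passage_interval_h))

    def doublings_per_passage(self, condition: str) -> float:
        if condition not in self.conditions:
            raise ValueError(f"unknown condition {condition!r}")
        inhibition = self.growth_inhibition.get(condition, 0.0)
        return (
            self.passage_interval_h / self.untreated_doubling_time_h
            * (1.0 - inhibition)
        )

    def n_reads(self, n_guides: int) -> int:
        if self.reads_per_sample is not None:
            return int(self.reads_per_sample)
        return int(round(self.coverage * n_guides))


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------
@dataclass
class FitnessTruth:
    """Simulator ground truth: per-gene per-condition selection, guide efficacy.

    ``selection`` holds the dimensionless per-doubling growth-rate offset *s*
    (relative growth rate = 1 + s); ``classes`` its categorical label.
    """

    classes: pd.DataFrame  # genes x conditions, values in GENE_CLASSES
    selection: pd.DataFrame  # genes x conditions, float
    guide_efficacy: pd.Series  # guide_id -> [0, 1]
    seed: int | None = None

    def __post_init__(self):
        if list(self.classes.index) != list(self.selection.index) or list(
            self.classes.columns
        ) != list(self.selection.columns):
            raise ValueError("classes and selection must share genes and conditions")
        sel = self.selection.to_numpy()
        cls = self.classes.to_numpy()
        if ((sel > 0) != (cls == "suppressor")).any() or (
            (sel < 0) != (cls == "synthetic_sick")
        ).any():
            raise ValueError("sign of s inconsistent with gene class")
        eff = self.guide_efficacy.to_numpy()
        if ((eff < 0) | (eff > 1)).any():
            raise ValueError("guide efficacies must be in [0, 1]")

    def s_eff(self, library: GuideLibrary) -> pd.DataFrame:
        """Efficacy-weighted selection per guide: s_eff = efficacy * s(gene)."""
        genes = library.frame["gene"]
        conditions = list(self.selection.columns)
        out = np.zeros((library.n_guides, len(conditions)))
        targeting = ~library.frame["is_control"].to_numpy()
        sel = self.selection.reindex(genes[targeting]).to_numpy()
        eff = self.guide_efficacy.reindex(library.guide_ids).to_numpy()
        out[targeting] = sel * eff[targeting, None]
        return pd.DataFrame(out, index=library.guide_ids, columns=conditions)

    def to_json(self, path) -> None:
        payload = {
            "conditions": list(self.selection.columns),
            "genes": list(self.selection.index),
            "classes": {c: list(self.classes[c]) for c in self.classes.columns},
            "selection": {c: list(map(float, self.selection[c])) for c in self.selection},
            "guide_ids": list(self.guide_efficacy.index),
            "guide_efficacy": [float(v) for v in self.guide_efficacy],
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "FitnessTruth":
        with open(path) as fh:
            payload = json.load(fh)
        genes = payload["genes"]
        conds = payload["conditions"]
        classes = pd.DataFrame(
            {c: payload["classes"][c] for c in conds}, index=genes
        )
        selection = pd.DataFrame(
            {c: payload["selection"][c] for c in conds}, index=genes
        )
        eff = pd.Series(
            payload["guide_efficacy"], index=payload["guide_ids"], dtype=float
        )
        return cls(classes, selection, eff, seed=payload.get("seed"))


def assign_fitness(
    library: GuideLibrary,
    design: ScreenDesign,
    class_spec: Mapping[str, Mapping[str, float]] | None = None,
    shared_sick_genes: int = 0,
    seed: int = 0,
    efficacy_alpha: float = 8.0,
    efficacy_beta: float = 2.0,
    s_shared_sick: float | None = None,
) -> FitnessTruth:
    """Draw gene classes, selection coefficients, and guide efficacies.

    ``class_spec`` maps condition -> ``{n_suppressors, n_sick, s_suppressor,
    s_sick}``.  A shared synthetic-sick gene set (emulating e.g. a
    glycolysis-like signature sick in every drug arm) receives each arm's
    ``s_sick`` -- or ``s_shared_sick`` for arms without a class_spec entry --
    in every non-reference condition.  The reference condition is always
    all-neutral.  Guide efficacies are Beta(8, 2) by default.
    """
    class_spec = dict(class_spec or {})
    genes = library.genes
    conditions = list(design.conditions)
    if design.reference_condition in class_spec:
        raise ValueError("reference condition must remain all-neutral")
    rng = np.random.default_rng(seed)

    classes = pd.DataFrame("neutral", index=genes, columns=conditions)
    selection = pd.DataFrame(0.0, index=genes, columns=conditions)

    shared: list[str] = []
    if shared_sick_genes:
        if shared_sick_genes > len(genes):
            raise ValueError("shared sick set larger than gene universe")
        shared = list(rng.choice(genes, size=shared_sick_genes, replace=False))
        for cond in conditions:
            if cond == design.reference_condition:
                continue
            spec = class_spec.get(cond) or {}
            s_sick = spec.get("s_sick", s_shared_sick)
            if s_sick is None or not s_sick < 0:
                raise ValueError(
                    f"shared sick genes need a negative s_sick for condition {cond!r}"
                )
            classes.loc[shared, cond] = "synthetic_sick"
            selection.loc[shared, cond] = s_sick

    pool = [g for g in genes if g not in set(shared)]
    for cond in conditions:
        spec = class_spec.get(cond)
        if spec is None:
            continue
        n_sup = int(spec.get("n_suppressors", 0))
        n_sick = int(spec.get("n_sick", 0))
        if n_sup + n_sick > len(pool):
            raise ValueError(
                f"condition {cond!r} requests {n_sup + n_sick} classed genes, "
                f"only {len(pool)} available"
            )
        if n_sup and not spec.get("s_suppressor", 0) > 0:
            raise ValueError("s_suppressor must be > 0")
        if n_sick and not spec.get("s_sick", 0) < 0:
            raise ValueError("s_sick must be < 0")
        picked = rng.choice(pool, size=n_sup + n_sick, replace=False)
        sup, sick = picked[:n_sup], picked[n_sup:]
        if n_sup:
            classes.loc[sup, cond] = "suppressor"
            selection.loc[sup, cond] = spec["s_suppressor"]
        if n_sick:
            classes.loc[sick, cond] = "synthetic_sick"
            selection.loc[sick, cond] = spec["s_sick"]

    efficacy = pd.Series(
        rng.beta(efficacy_alpha, efficacy_beta, size=library.n_guides),
        index=library.guide_ids,
    )
    return FitnessTruth(classes, selection, efficacy, seed=seed)


def neutral_truth(library: GuideLibrary, design: ScreenDesign) -> FitnessTruth:
    """All-neutral ground truth with fully effective guides (null screen)."""
    genes = library.genes
    conds = list(design.conditions)
    return FitnessTruth(
        pd.DataFrame("neutral", index=genes, columns=conds),
        pd.DataFrame(0.0, index=genes, columns=conds),
        pd.Series(1.0, index=library.guide_ids),
    )


# ---------------------------------------------------------------------------
# Passaging
# ---------------------------------------------------------------------------
@dataclass
class AbundanceTrajectory:
    """Relative guide abundances per (condition, replicate, passage).

    ``abundance[(c, r)]`` is an ``(n_passages + 1, n_guides)`` array whose
    rows sum to 1; row 0 is the shared T0 abundance vector.  ``growth`` holds
    per-passage seeded/harvested cell numbers and population doublings.
    """

    design: ScreenDesign
    guide_ids: np.ndarray
    initial: np.ndarray
    abundance: dict[tuple[str, int], np.ndarray]
    growth: pd.DataFrame

    def final(self, condition: str, replicate: int) -> np.ndarray:
        return self.abundance[(condition, replicate)][-1]

    def cumulative_doublings(self, condition: str, replicate: int) -> float:
        sub = self.growth[
            (self.growth["condition"] == condition)
            & (self.growth["replicate"] == replicate)
        ]
        return float(sub["doublings"].sum())

    def validate(self, tol: float = 1e-9) -> None:
        for key, arr in self.abundance.items():
            if (arr < 0).any():
                raise ValueError(f"negative abundance in {key}")
            if np.abs(arr.sum(axis=1) - 1.0).max() > tol:
                raise ValueError(f"abundance rows of {key} do not sum to 1")


def simulate_passaging(
    library: GuideLibrary,
    truth: FitnessTruth,
    design: ScreenDesign,
    seed: int = 0,
    initial_sigma_log2: float = 0.5,
    passage_noise_sd: float = 0.0,
    bottleneck_sampling: bool = False,
) -> AbundanceTrajectory:
    """Deterministic exponential competition between 72 h bottlenecks.

    The initial plasmid-pool skew is lognormal (sigma in log2 units);
    optional per-passage lognormal jitter and multinomial bottleneck
    sampling are off by default, making replicate trajectories identical and
    every downstream expectation available in closed form.
    """
    n = library.n_guides
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(1 + len(design.conditions) * design.n_replicates)
    rng_init = np.random.default_rng(child[0])

    if initial_sigma_log2 > 0:
        p0 = np.exp2(rng_init.normal(0.0, initial_sigma_log2, size=n))
    else:
        p0 = np.ones(n)
    p0 = p0 / p0.sum()

    s_eff = truth.s_eff(library)
    records = []
    abundance: dict[tuple[str, int], np.ndarray] = {}
    idx = 1
    for cond in design.conditions:
        d_c = design.doublings_per_passage(cond)
        factor = np.exp2(d_c * (1.0 + s_eff[cond].to_numpy()))
        for rep in range(1, design.n_replicates + 1):
            rng = np.random.default_rng(child[idx])
            idx += 1
            p = p0
            rows = [p0]
            bottleneck = float(design.bottleneck_cells)
            for passage in range(1, design.n_passages + 1):
                w = p * factor
                if passage_noise_sd > 0:
                    w = w * np.exp2(rng.normal(0.0, passage_noise_sd, size=n))
                harvested = bottleneck * w.sum()
                p = w / w.sum()
                if bottleneck_sampling:
                    c = rng.multinomial(design.bottleneck_cells, p)
                    p = c / c.sum()
                rows.append(p)
                records.append(
                    {
                        "condition": cond,
                        "replicate": rep,
                        "passage": passage,
                        "time_days": passage * design.passage_interval_h / 24.0,
                        "seeded": bottleneck,
                        "harvested": harvested,
                        "doublings": np.log2(harvested / bottleneck),
                    }
                )
            abundance[(cond, rep)] = np.vstack(rows)

    growth = pd.DataFrame.from_records(records)
    growth["cumulative_doublings"] = growth.groupby(
        ["condition", "replicate"], sort=False
    )["doublings"].cumsum()
    traj = AbundanceTrajectory(design, library.guide_ids, p0, abundance, growth)
    traj.validate()
    return traj


# ---------------------------------------------------------------------------
# Sequencing
# ---------------------------------------------------------------------------
def sample_counts(
    trajectory: AbundanceTrajectory,
    design: ScreenDesign,
    seed: int = 0,
    overdispersion: float = 0.0,
) -> CountTable:
    """Multinomial sequencing of T0 and day-15 samples.

    One T0 sample per replicate is drawn from the shared pre-treatment
    abundance vector and serves as the baseline for every condition of that
    replicate.  ``overdispersion`` > 0 draws sample probabilities from a
    Dirichlet with concentration ``p / overdispersion`` first.
    """
    n = len(trajectory.guide_ids)
    reads = design.n_reads(n)
    if reads < 1:
        raise ValueError("reads_per_sample must be >= 1")

    layout: list[tuple[str, str, int, str, np.ndarray]] = []
    for rep in range(1, design.n_replicates + 1):
        layout.append(
            (f"T0_R{rep}", "T0", rep, design.baseline_timepoint, trajectory.initial)
        )
    for cond in design.conditions:
        for rep in range(1, design.n_replicates + 1):
            layout.append(
                (
                    f"{cond}_R{rep}",
                    cond,
                    rep,
                    design.treated_timepoint,
                    trajectory.final(cond, rep),
                )
            )

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(layout))
    counts = {}
    meta = []
    for (name, cond, rep, tp, p), ch in zip(layout, children):
        rng = np.random.default_rng(ch)
        prob = p
        if overdispersion > 0:
            prob = rng.dirichlet(p / overdispersion)
        counts[name] = rng.multinomial(reads, prob)
        meta.append({"sample": name, "condition": cond, "replicate": rep, "timepoint": tp})

    count_frame = pd.DataFrame(counts, index=trajectory.guide_ids)
    samples = pd.DataFrame(meta).set_index("sample")
    return CountTable(count_frame, samples)


def simulate_screen(
    n_genes: int = 1000,
    guides_per_gene: int = 4,
    n_controls: int = 100,
    design: ScreenDesign | None = None,
    class_spec: Mapping[str, Mapping[str, float]] | None = None,
    shared_sick_genes: int = 0,
    s_shared_sick: float | None = None,
    seed: int = 0,
    **passaging_kwargs,
) -> tuple[GuideLibrary, FitnessTruth, AbundanceTrajectory, CountTable]:
    """Convenience: library -> truth -> passaging -> counts from one seed."""
    design = design or ScreenDesign()
    ss = np.random.SeedSequence(seed)
    s_lib, s_truth, s_pass, s_count = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)
    ]
    library = build_library(n_genes, guides_per_gene, n_controls, seed=s_lib)
    truth = assign_fitness(
        library, design, class_spec, shared_sick_genes=shared_sick_genes,
        seed=s_truth, s_shared_sick=s_shared_sick,
    )
    traj = simulate_passaging(library, truth, design, seed=s_pass, **passaging_kwargs)
    table = sample_counts(traj, design, seed=s_count)
    return library, truth, traj, table


# ---------------------------------------------------------------------------
# FASTQ emission
# ---------------------------------------------------------------------------
_OTHER_BASES = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}


def emit_fastq(
    counts: Mapping[str, int] | pd.Series,
    library: GuideLibrary,
    handle: IO[str],
    prefix: str = "TTGTGGAAAGGACGAAACACCG",
    suffix: str = "GTTTTAGAGCTAGAAATAGCAAG",
    phred_high: int = 37,
    phred_low: int = 12,
    fraction_low: float = 0.0,
    error_rate: float = 0.0,
    seed: int = 0,
) -> int:
    """Write synthetic Phred+33 reads (prefix + protospacer + suffix).

    A ``fraction_low`` share of reads receives uniformly low base qualities
    (mean Phred below a >20 filter); per-base substitution errors occur at
    ``error_rate``.  The read multiset matches ``counts`` before corruption.
    Returns the number of reads written; byte-identical for a fixed seed.
    """
    for q in (phred_high, phred_low):
        if not 2 <= q <= 41:
            raise ValueError("Phred values must be in [2, 41]")
    proto = dict(zip(library.frame["guide_id"], library.frame["protospacer"]))
    order: list[str] = []
    if isinstance(counts, pd.Series):
        counts = counts.to_dict()
    for gid in library.frame["guide_id"]:
        c = int(counts.get(gid, 0))
        if c < 0:
            raise ValueError(f"negative count for guide {gid!r}")
        order.extend([gid] * c)
    rng = np.random.default_rng(seed)
    if order:
        order = [order[i] for i in rng.permutation(len(order))]
    low = rng.random(len(order)) < fraction_low
    qual_high = chr(33 + phred_high)
    qual_low = chr(33 + phred_low)
    for i, gid in enumerate(order):
        seq = prefix + proto[gid] + suffix
        if error_rate > 0:
            hits = np.nonzero(rng.random(len(seq)) < error_rate)[0]
            if hits.size:
                chars = list(seq)
                for j in hits:
                    chars[j] = _OTHER_BASES[chars[j]][rng.integers(0, 3)]
                seq = "".join(chars)
        qual = (qual_low if low[i] else qual_high) * len(seq)
        handle.write(f"@read{i + 1:07d} guide={gid}\n{seq}\n+\n{qual}\n")
    return len(order)
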