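# Methods

## Scope and model overview

`sigmascreen` implements the analysis chain of a genome-wide pooled CRISPR
knockout fitness screen run under drugs that perturb mitochondrial
translation (a mistranslation inducer, a translation inhibitor, their
combination, and a solvent reference), plus two satellite calculations:
growth/MOI bookkeeping and [1,2-¹³C₂]-glucose tracing arithmetic. Because
real screen data are not bundled, a generative model of the screen is a
first-class, tested component: it fixes the study conditions and supplies
exact ground truth against which every downstream stage is validated.

## The screen generative model

**Design.** Defaults mirror the emulated screen: ~19,000 genes × 4 guides
plus 1,000 non-targeting controls; four conditions with an ethanol
reference; three replicates per condition; 15 days of 72 h passages at a
4×10⁷-cell bottleneck; a 24 h untreated doubling time; 40% growth
inhibition in every drug arm (drug doses in the emulated design were
titrated to comparable low-dose inhibition); sequencing at 150× guide
coverage. At these settings the drug arms traverse 15 × 0.6 = 9 population
doublings, inside the 8–12 doubling window the design targets, and guide
representation at the bottleneck is 4×10⁷ / 77,441 ≈ 517 cells per guide.

**Growth.** Between bottlenecks, guide *g* in condition *c* multiplies
deterministically by `2^(D_c (1 + s_eff(g,c)))`, with
`D_c = (passage_interval / doubling_time) (1 − inhibition_c)` and
`s_eff = efficacy(g) · s(gene(g), c)`. The drug acts as a global
doubling-rate multiplier on top of per-gene selection. The bottleneck is an
exact renormalization by default; multinomial sampling at the bottleneck
cell number and per-passage lognormal jitter are available for drift
studies but off by default, so closed-form expectations hold exactly and
replicate variation comes only from sequencing.

**Unstated quantities, fixed once.** The initial library skew is lognormal
with σ = 0.5 log₂ units (typical plasmid-pool inequality); guide efficacy
is Beta(8, 2) per guide (mean 0.8, occasional weak guides); simulator
selection coefficients are free parameters (the emulated screen reports
only enrichment/depletion classes, not effect sizes in natural units), with
±0.4 used as the standard planted effect. T0 is sampled from the
pre-treatment pool after the expansion phase, i.e. T0 probabilities equal
the initial abundances.

**Sequencing.** Counts are multinomial at the sample's read budget
(coverage × guides, ~150× by default), with optional Dirichlet
overdispersion. One T0 sample per replicate is drawn from the shared
pre-treatment pool and serves as the baseline for *every* condition of that
replicate — the screen splits a single selected pool into arms at T0. This
pairing matters quantitatively: it induces a ≈0.5 correlation between the
two arms' LFC noise, so the null ΔZ distribution has SD ≈ 1 rather than √2,
which is what keeps the fraction of null genes at |ΔZ| ≥ 3 below 1%.

**FASTQ emission** writes reads as vector-prefix + protospacer + suffix
with a configurable share of low-quality reads and per-base substitution
errors, enabling exact round-trip tests of quantification. The default
anchor sequence is a synthetic stand-in for the vector's integration
sequence (the real primer sequences live in the screen's supplementary
material and are a required configuration value for real data).

## Quantification

Reads are kept iff mean base Phred strictly exceeds 20 — the emulated
pipeline's "Phred score > 20" is read as a mean-read criterion (a per-base
variant can be configured). The protospacer is the 20-mer after the
leftmost exact anchor match; matching is an exact hash lookup by default,
with a unique-best 1-mismatch rescue behind a flag (ambiguous neighbors are
discarded as unmatched). Exact matching is the conservative choice for
20-mers at 150× coverage. The accounting identity
`mapped + filtered + unmatched = total` is enforced per sample. No
gene-expression-level filter is applied anywhere.

## Sigma scoring

Normalization is total-count relative abundance with pseudocount 0.5
(median-ratio size factors available); the normalization scheme of the
emulated pipeline is unstated, so it is exposed as configuration. LFCs are
taken versus the replicate's shared T0, never versus the day-15 reference
arm; cross-condition comparison happens only at the Z level.

Aggregation order: guides and replicates are averaged first, then gene
scores are Z-transformed within each condition (population SD over
gene-targeting genes; controls are excluded from μ/σ and serve as an
empirical-null diagnostic instead). The alternative order — Z-scoring
guide-level LFCs first, then averaging per gene — is available via
`z_before_average` for sensitivity analysis; the two orders correlate
strongly but are not identical.

ΔZ is the simple difference `z_drug − z_reference` ("relative difference"
read as a difference; a ratio is unstable near 0 and cannot give one
symmetric dot per gene). Hits use the inclusive ΔZ ≥ 3 rule, two-sided by
default with one-sided options; ranking ties break lexicographically so
exports are byte-stable.

## Enrichment

Right-tailed Fisher's exact test per gene set: the upper hypergeometric
tail is summed in log space via log-gamma, exact to ~1e-13 against full
enumeration (unit-tested exhaustively for all tables with N ≤ 60).
The universe is the set of scored gene-targeting genes (screen universe,
not genome universe — the screen itself recovers ~19k genes), sets smaller
than 3 after intersection are dropped, and BH adjustment runs across the
retained sets. The odds ratio uses the Haldane–Anscombe +0.5 correction
when a margin cell is zero.

## Growth kinetics

Population doubling is `(log N_end − log N_start)/log 2` (log base
irrelevant; natural logs internally), additive across intervals, negative
under cell loss. Infection efficiency is the with/without-selection
survivor ratio, clipped to 1 with a warning if inverted. MOI uses single-hit
Poisson inversion `−ln(1 − eff)`: 30–50% efficiency maps to MOI
[0.357, 0.693]; whether the emulated design's "MOI > 0.3" bound derives
from the Poisson model or vendor guidance is unrecorded, so both the target
window and the Poisson-implied interval are reported without asserting
either as that design's method.

## Isotope tracing

The correction matrix for an *n*-carbon metabolite has columns
`Binomial(j, purity) ⊛ Binomial(n−j, p13)` — purity loss over the *j*
tracer-labeled carbons convolved with natural enrichment
(p13 = 0.0107) over the rest. Only carbon isotopes are modeled, matching a
minimal carbon-only correction; inversion is by NNLS so noisy inputs cannot
yield negative fractions, and corrected vectors are renormalized to sum
to 1 with the residual reported. Fraction-mode conversion retains the total
intensity as a pool-size statistic; a sample whose summed intensity falls
below 20% (configurable) of the batch median is excluded with a logged
warning, mirroring low-yield replicate exclusion practice.

The forward simulator uses the classic single-pass [1,2-¹³C₂]
approximation: a glycolytic glucose yields one m+2 and one m+0 lactate; an
oxPPP glucose loses its labeled C1 as CO₂ and yields one m+1 and one m+0
lactate. Hence the labeled-lactate fractions satisfy `m1/(m1+m2) = f_PPP`
and the m+1/m+2 ratio is `f/(1−f)`. Non-oxidative PPP recycling, TCA
exchange fluxes and compartmentation are deliberately excluded — the
simulator is an arithmetic test harness, not a flux-balance model, and the
recovered `f_PPP` should be read as the single-pass index, not a fitted
flux.

## Numerical and reproducibility choices

- One master seed per run; per-stage child seeds derive deterministically
  via `numpy.random.SeedSequence.spawn`, so every output (counts, FASTQ,
  TSVs) is byte-identical across reruns and manifests record SHA-256
  checksums of every file.
- Abundance vectors are validated to sum to 1 within 1e-9; Z columns to
  mean 0 / SD 1 within 1e-8; degenerate screens (zero SD) raise rather
  than emit NaN.
- Zero-depth samples, all-zero MIDs, non-positive cell counts and
  malformed FASTQ records raise errors naming the offending sample/record.
- Pipeline stages write into a `.partial` directory renamed on success, so
  failures leave no partial outputs.

## Problem sizes used in the test suite

Tests run on scaled-down screens chosen to keep the statistical properties
of the full design: null calibration uses 20 screens of 1,000 genes × 4
guides + 100 controls at 150× coverage (the spec-level operating point for
that check); recovery tests plant 50 suppressors at s = +0.4 in the drug
arm only; oracle tests enumerate exhaustively (all 2×2 tables with N ≤ 60,
all per-carbon label assignments for n ≤ 6 carbons).

## Known limitations

- The simulator omits lentiviral integration-site effects, cell-cycle
  structure, clone-level lineage barcoding, and PCR amplification bias;
  passing tests demonstrate correctness of the arithmetic and calibration
  under multinomial sampling, not robustness to those real-data artifacts.
- Planted effect sizes are not calibrated to any published effect-size
  scale; recovery AUROCs on synthetic data should not be read as expected
  sensitivity on real screens.
- Hit calling is the fixed ΔZ ≥ 3 rule; no FDR model (MAGeCK/BAGEL-style
  likelihoods are out of scope). The control-guide empirical null is a
  diagnostic only.
- The tracing model is single-pass; recycling through non-oxidative PPP
  biases the m+1/m+2 index upward in real cells.
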