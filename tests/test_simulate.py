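"""Simulator: fitness assignment, passaging dynamics, sequencing, FASTQ."""

import io

import numpy as np
import pandas as pd
import pytest

import sigmascreen as sg
from sigmascreen.simulate import emit_fastq


# ---------------------------------------------------------------------------
# assign_fitness
# ---------------------------------------------------------------------------
def test_assign_fitness_null_spec_is_all_neutral(small_library, two_arm_design):
    truth = sg.assign_fitness(small_library, two_arm_design, {}, seed=0)
    assert (truth.classes.to_numpy() == "neutral").all()
    assert (truth.selection.to_numpy() == 0).all()
    assert truth.guide_efficacy.between(0, 1).all()


def test_assign_fitness_bookkeeping_counts():
    lib = sg.build_library(1000, 4, 50, seed=0)
    design = sg.ScreenDesign(conditions=("ETOH", "ACT"), growth_inhibition={"ACT": 0.4})
    truth = sg.assign_fitness(
        lib, design,
        {"ACT": {"n_suppressors": 50, "n_sick": 50,
                 "s_suppressor": 0.4, "s_sick": -0.4}},
        shared_sick_genes=20, seed=1,
    )
    counts = truth.classes["ACT"].value_counts()
    assert counts["suppressor"] == 50
    assert counts["synthetic_sick"] == 70  # 50 condition-specific + 20 shared
    assert counts["neutral"] == 880
    # reference condition all-neutral
    assert (truth.classes["ETOH"] == "neutral").all()
    # sign convention s > 0 <=> suppressor
    sup = truth.classes["ACT"] == "suppressor"
    assert (truth.selection.loc[sup, "ACT"] > 0).all()
    assert (truth.selection.loc[truth.classes["ACT"] == "synthetic_sick", "ACT"] < 0).all()


def test_assign_fitness_seed_changes_identities_not_counts():
    lib = sg.build_library(200, 2, 10, seed=0)
    design = sg.ScreenDesign(conditions=("ETOH", "ACT"), growth_inhibition={"ACT": 0.4})
    spec = {"ACT": {"n_suppressors": 20, "n_sick": 10,
                    "s_suppressor": 0.3, "s_sick": -0.3}}
    t1 = sg.assign_fitness(lib, design, spec, seed=1)
    t2 = sg.assign_fitness(lib, design, spec, seed=2)
    assert t1.classes["ACT"].value_counts().equals(t2.classes["ACT"].value_counts())
    assert not t1.classes["ACT"].equals(t2.classes["ACT"])


def test_assign_fitness_overflow_and_reference_errors(small_library, two_arm_design):
    with pytest.raises(ValueError, match="available"):
        sg.assign_fitness(
            small_library, two_arm_design,
            {"ACT": {"n_suppressors": 20, "n_sick": 20,
                     "s_suppressor": 0.4, "s_sick": -0.4}}, seed=0,
        )
    with pytest.raises(ValueError, match="neutral"):
        sg.assign_fitness(
            small_library, two_arm_design,
            {"ETOH": {"n_suppressors": 1, "n_sick": 0, "s_suppressor": 0.4}},
        )


def test_fitness_truth_json_round_trip(tmp_path, small_library, two_arm_design):
    truth = sg.assign_fitness(
        small_library, two_arm_design,
        {"ACT": {"n_suppressors": 3, "n_sick": 2,
                 "s_suppressor": 0.4, "s_sick": -0.4}}, seed=9,
    )
    path = tmp_path / "truth.json"
    truth.to_json(path)
    back = sg.FitnessTruth.from_json(path)
    pd.testing.assert_frame_equal(back.classes, truth.classes)
    pd.testing.assert_frame_equal(back.selection, truth.selection)
    pd.testing.assert_series_equal(
        back.guide_efficacy, truth.guide_efficacy, check_names=False
    )


# ---------------------------------------------------------------------------
# simulate_passaging
# ---------------------------------------------------------------------------
def test_neutral_passaging_preserves_abundances(small_library, two_arm_design, null_screen):
    _, traj, _ = null_screen
    for key, arr in traj.abundance.items():
        np.testing.assert_allclose(arr[-1], traj.initial, rtol=1e-12)


def test_passaging_closed_form_selection_factor():
    # one effective suppressor at s_eff = +0.5 over 3 total doublings in the
    # drug arm changes its abundance ratio vs a neutral guide by 2**1.5
    lib = sg.build_library(10, 1, 0, seed=3)
    design = sg.ScreenDesign(
        conditions=("ETOH", "ACT"), growth_inhibition={"ACT": 0.0},
        duration_days=3.0, passage_interval_h=24.0,
        untreated_doubling_time_h=24.0,  # 1 doubling per passage, 3 passages
    )
    genes = lib.genes
    classes = pd.DataFrame("neutral", index=genes, columns=["ETOH", "ACT"])
    selection = pd.DataFrame(0.0, index=genes, columns=["ETOH", "ACT"])
    classes.loc[genes[0], "ACT"] = "suppressor"
    selection.loc[genes[0], "ACT"] = 0.5
    truth = sg.FitnessTruth(classes, selection, pd.Series(1.0, index=lib.guide_ids))
    traj = sg.simulate_passaging(lib, truth, design, seed=0)
    final = traj.final("ACT", 1)
    ratio = (final[0] / final[1]) / (traj.initial[0] / traj.initial[1])
    assert ratio == pytest.approx(2 ** 1.5, rel=1e-12)


def test_untreated_arm_cumulative_doublings(small_library, two_arm_design, null_screen):
    # 15 days at a 24 h doubling time with no inhibition: 15 doublings
    _, traj, _ = null_screen
    assert traj.cumulative_doublings("ETOH", 1) == pytest.approx(15.0, abs=1e-12)
    assert traj.cumulative_doublings("ACT", 1) == pytest.approx(9.0, abs=1e-12)


def test_abundance_conservation_and_nonnegativity(null_screen):
    _, traj, _ = null_screen
    traj.validate(tol=1e-9)


def test_selection_monotonicity_in_s():
    # larger suppressor s strictly increases the day-15/T0 abundance ratio
    lib = sg.build_library(20, 1, 0, seed=3)
    design = sg.ScreenDesign(conditions=("ETOH", "ACT"), growth_inhibition={"ACT": 0.4})
    genes = lib.genes
    ratios = []
    for s in (0.1, 0.2, 0.4, 0.8):
        classes = pd.DataFrame("neutral", index=genes, columns=["ETOH", "ACT"])
        selection = pd.DataFrame(0.0, index=genes, columns=["ETOH", "ACT"])
        classes.loc[genes[0], "ACT"] = "suppressor"
        selection.loc[genes[0], "ACT"] = s
        truth = sg.FitnessTruth(classes, selection, pd.Series(1.0, index=lib.guide_ids))
        traj = sg.simulate_passaging(lib, truth, design, seed=0)
        ratios.append(traj.final("ACT", 1)[0] / traj.initial[0])
    assert all(a < b for a, b in zip(ratios, ratios[1:]))


def test_design_validation():
    with pytest.raises(ValueError, match="whole passages"):
        sg.ScreenDesign(duration_days=14.0)
    with pytest.raises(ValueError, match=r"\[0, 1\)"):
        sg.ScreenDesign(growth_inhibition={"ACT": 1.0})
    with pytest.raises(ValueError, match="reference"):
        sg.ScreenDesign(conditions=("ACT",))


# ---------------------------------------------------------------------------
# sample_counts
# ---------------------------------------------------------------------------
def test_counts_sum_to_reads_per_sample(two_arm_design, null_screen):
    _, traj, table = null_screen
    reads = two_arm_design.n_reads(len(traj.guide_ids))
    assert (table.counts.sum(axis=0) == reads).all()
    # layout: one T0 per replicate plus each condition x replicate
    assert len(table.sample_names) == 3 + 2 * 3


def test_uniform_coverage_expectation():
    lib = sg.build_library(25, 4, 0, seed=0)
    design = sg.ScreenDesign(conditions=("ETOH",), growth_inhibition={},
                             n_replicates=1, coverage=150.0)
    truth = sg.neutral_truth(lib, design)
    traj = sg.simulate_passaging(lib, truth, design, seed=0, initial_sigma_log2=0.0)
    table = sg.sample_counts(traj, design, seed=0)
    assert table.counts["T0_R1"].mean() == pytest.approx(150.0, abs=1e-9)


def test_multinomial_marginal_variance_matches_binomial():
    # empirical variance of one guide's count over many draws ~ n p (1-p)
    lib = sg.build_library(10, 1, 0, seed=0)
    design = sg.ScreenDesign(conditions=("ETOH",), growth_inhibition={},
                             n_replicates=1, reads_per_sample=1500)
    truth = sg.neutral_truth(lib, design)
    traj = sg.simulate_passaging(lib, truth, design, seed=0, initial_sigma_log2=0.0)
    n_draws = 1500
    draws = np.empty(n_draws)
    for i in range(n_draws):
        table = sg.sample_counts(traj, design, seed=1000 + i)
        draws[i] = table.counts["T0_R1"].iloc[0]
    p = 1.0 / 10
    expected_var = 1500 * p * (1 - p)
    se_var = expected_var * np.sqrt(2.0 / (n_draws - 1))
    assert abs(draws.var(ddof=1) - expected_var) < 3 * se_var
    assert abs(draws.mean() - 150.0) < 3 * np.sqrt(expected_var / n_draws)


def test_count_determinism(two_arm_design, null_screen):
    truth, traj, table = null_screen
    again = sg.sample_counts(traj, two_arm_design, seed=7)
    pd.testing.assert_frame_equal(again.counts, table.counts)
    other = sg.sample_counts(traj, two_arm_design, seed=8)
    assert not other.counts.equals(table.counts)


# ---------------------------------------------------------------------------
# emit_fastq
# ---------------------------------------------------------------------------
def test_emit_fastq_verbatim_reads(small_library):
    gid = small_library.guide_ids[0]
    proto = small_library.frame["protospacer"].iloc[0]
    buf = io.StringIO()
    n = emit_fastq({gid: 3}, small_library, buf, seed=0)
    assert n == 3
    lines = buf.getvalue().splitlines()
    assert len(lines) == 12
    for seq in lines[1::4]:
        assert proto in seq


def test_emit_fastq_empty_counts(small_library):
    buf = io.StringIO()
    assert emit_fastq({}, small_library, buf, seed=0) == 0
    assert buf.getvalue() == ""


def test_emit_fastq_low_quality_fraction_by_independent_parser(small_library):
    from Bio import SeqIO

    gid = small_library.guide_ids[0]
    buf = io.StringIO()
    n_reads = 10_000
    emit_fastq({gid: n_reads}, small_library, buf, fraction_low=0.1, seed=4)
    buf.seek(0)
    n_low = 0
    for rec in SeqIO.parse(buf, "fastq"):
        if np.mean(rec.letter_annotations["phred_quality"]) <= 20:
            n_low += 1
    sd = np.sqrt(n_reads * 0.1 * 0.9)
    assert abs(n_low - 1000) < 4 * sd


def test_emit_fastq_deterministic_and_validates_phred(small_library):
    counts = {small_library.guide_ids[0]: 5, small_library.guide_ids[3]: 2}
    a, b = io.StringIO(), io.StringIO()
    emit_fastq(counts, small_library, a, error_rate=0.05, fraction_low=0.3, seed=12)
    emit_fastq(counts, small_library, b, error_rate=0.05, fraction_low=0.3, seed=12)
    assert a.getvalue() == b.getvalue()
    with pytest.raises(ValueError, match="Phred"):
        emit_fastq(counts, small_library, io.StringIO(), phred_high=50)
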