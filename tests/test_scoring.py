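"""Sigma scoring: normalization, LFC, gene scores, Z transform, hits."""

import numpy as np
import pandas as pd
import pytest

import sigmascreen as sg
from sigmascreen.scoring import (
    call_hits,
    export_sigma_table,
    gene_score,
    guide_lfc,
    normalize_counts,
    read_sigma_table,
    sigma_diff,
    zscore,
)
from conftest import make_sample_sheet


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------
def test_normalize_counts_hand_examples():
    counts = pd.DataFrame({"s1": [10, 10], "s2": [0, 100]}, index=["g1", "g2"])
    ab0 = normalize_counts(counts, pseudocount=0.0)
    np.testing.assert_allclose(ab0["s1"], [0.5, 0.5])
    ab = normalize_counts(counts, pseudocount=0.5)
    np.testing.assert_allclose(ab["s2"], [0.5 / 101, 100.5 / 101])
    # scale invariance: doubling all counts leaves abundances unchanged
    doubled = normalize_counts(counts * 2, pseudocount=0.0)
    pd.testing.assert_frame_equal(doubled, ab0)
    assert np.allclose(ab.sum(axis=0), 1.0)


def test_normalize_counts_zero_depth_names_sample():
    counts = pd.DataFrame({"ok": [5, 5], "empty": [0, 0]}, index=["g1", "g2"])
    with pytest.raises(ValueError, match="empty"):
        normalize_counts(counts, pseudocount=0.5)


def test_median_ratio_normalization_removes_depth():
    rng = np.random.default_rng(1)
    base = rng.integers(50, 200, size=30)
    counts = pd.DataFrame({"a": base, "b": base * 4}, index=[f"g{i}" for i in range(30)])
    norm = normalize_counts(counts, pseudocount=0.5, method="median-ratio")
    np.testing.assert_allclose(norm["a"], norm["b"], rtol=1e-2)


# ---------------------------------------------------------------------------
# LFC
# ---------------------------------------------------------------------------
def _abundance_fixture():
    sheet = make_sample_sheet(["ACT"], 1)
    ab = pd.DataFrame(
        {"T0_R1": [0.25, 0.25, 0.5], "ACT_R1": [0.25, 0.5, 0.25]},
        index=["g1", "g2", "g3"],
    )
    return ab, sheet


def test_guide_lfc_hand_values():
    ab, sheet = _abundance_fixture()
    lfc = guide_lfc(ab, sheet)
    assert lfc.loc["g1", ("ACT", 1)] == 0.0
    assert lfc.loc["g2", ("ACT", 1)] == 1.0
    assert lfc.loc["g3", ("ACT", 1)] == -1.0


def test_guide_lfc_missing_baseline():
    ab, sheet = _abundance_fixture()
    with pytest.raises(ValueError, match="baseline"):
        guide_lfc(ab, sheet.drop(index="T0_R1"))


def test_guide_lfc_matches_passaging_closed_form():
    # s_eff = +0.5 over 3 condition-doublings: lfc - median(neutral) = 1.5
    lib = sg.build_library(10, 1, 0, seed=3)
    design = sg.ScreenDesign(
        conditions=("ETOH", "ACT"), growth_inhibition={"ACT": 0.0},
        duration_days=3.0, passage_interval_h=24.0,
        untreated_doubling_time_h=24.0, n_replicates=1,
    )
    genes = lib.genes
    classes = pd.DataFrame("neutral", index=genes, columns=["ETOH", "ACT"])
    sel = pd.DataFrame(0.0, index=genes, columns=["ETOH", "ACT"])
    classes.loc[genes[0], "ACT"] = "suppressor"
    sel.loc[genes[0], "ACT"] = 0.5
    truth = sg.FitnessTruth(classes, sel, pd.Series(1.0, index=lib.guide_ids))
    traj = sg.simulate_passaging(lib, truth, design, seed=0)
    ab = pd.DataFrame(
        {"T0_R1": traj.initial, "ACT_R1": traj.final("ACT", 1)},
        index=lib.guide_ids,
    )
    lfc = guide_lfc(ab, make_sample_sheet(["ACT"], 1))[("ACT", 1)]
    neutral_median = lfc.iloc[1:].median()
    assert lfc.iloc[0] - neutral_median == pytest.approx(1.5, abs=1e-9)


# ---------------------------------------------------------------------------
# gene aggregation
# ---------------------------------------------------------------------------
def test_gene_score_hand_and_oracle(small_library):
    reps = [1, 2, 3]
    cols = pd.MultiIndex.from_product([["ACT"], reps],
                                      names=["condition", "replicate"])
    ones = pd.DataFrame(1.0, index=small_library.guide_ids, columns=cols)
    score = gene_score(ones, small_library)
    assert (score["ACT"] == 1.0).all()

    rng = np.random.default_rng(7)
    rand = pd.DataFrame(rng.normal(size=(small_library.n_guides, 3)),
                        index=small_library.guide_ids, columns=cols)
    score = gene_score(rand, small_library)
    # independent brute-force nested mean
    gene_map = small_library.gene_of_guide()
    for gene in small_library.genes:
        guides = [g for g in small_library.guide_ids
                  if gene_map[g] == gene]
        per_guide = [np.mean([rand.loc[g, ("ACT", r)] for r in reps]) for g in guides]
        assert score.loc[gene, "ACT"] == pytest.approx(np.mean(per_guide), abs=1e-12)
    # controls excluded from gene scores
    assert "CONTROL" not in score.index


def test_gene_score_two_guides_mean():
    frame = pd.DataFrame(
        {
            "guide_id": ["gA_1", "gA_2"],
            "gene": ["GA", "GA"],
            "protospacer": ["A" * 20, "C" * 20],
            "is_control": [False, False],
        }
    )
    lib = sg.GuideLibrary(frame)
    cols = pd.MultiIndex.from_tuples([("ACT", 1)], names=["condition", "replicate"])
    lfc = pd.DataFrame([[0.0], [2.0]], index=lib.guide_ids, columns=cols)
    assert gene_score(lfc, lib).loc["GA", "ACT"] == 1.0


# ---------------------------------------------------------------------------
# Z transform
# ---------------------------------------------------------------------------
def test_zscore_population_sd_hand_values():
    scores = pd.DataFrame({"ACT": [-1.0, 0.0, 1.0]}, index=["a", "b", "c"])
    z = zscore(scores)
    np.testing.assert_allclose(z["ACT"], [-1.2247448714, 0.0, 1.2247448714],
                               atol=1e-9)


def test_zscore_identity_and_degenerate():
    rng = np.random.default_rng(0)
    scores = pd.DataFrame({"ACT": rng.normal(2.0, 3.0, 500)})
    z = zscore(scores)
    assert abs(z["ACT"].mean()) < 1e-8
    assert abs(z["ACT"].std(ddof=0) - 1.0) < 1e-8
    with pytest.raises(ValueError, match="degenerate"):
        zscore(pd.DataFrame({"ACT": [1.0, 1.0, 1.0]}))


# ---------------------------------------------------------------------------
# sigma differences and hits
# ---------------------------------------------------------------------------
def test_sigma_diff_self_contrast_and_unknown():
    z = pd.DataFrame({"ACT": [1.0, -2.0], "ETOH": [0.5, 0.5]}, index=["a", "b"])
    assert (sigma_diff(z, "ACT", "ACT") == 0).all()
    delta = sigma_diff(z, "ACT", "ETOH")
    np.testing.assert_allclose(delta, [0.5, -2.5])
    with pytest.raises(ValueError, match="unknown"):
        sigma_diff(z, "ACT", "CAP")


def test_call_hits_threshold_inclusive_and_sorted():
    delta = pd.Series({"a": 3.0, "b": -3.5, "c": 2.9, "d": -2.9, "e": 3.5})
    hits = call_hits(delta, threshold=3.0)
    assert set(hits["gene"]) == {"a", "b", "e"}  # 3.0 is called (>= 3)
    assert list(hits["gene"]) == ["b", "e", "a"]  # |dZ| desc, ties by symbol
    assert call_hits(pd.Series({"x": 2.99, "y": -2.5})).empty
    sup_only = call_hits(delta, threshold=3.0, direction="suppressor")
    assert set(sup_only["gene"]) == {"a", "e"}


def test_export_sigma_table_round_trip_and_determinism(tmp_path):
    z = pd.DataFrame(
        {"ACT": [2.0, -1.0, 4.0], "ETOH": [0.0, 0.0, 0.0]},
        index=["g1", "g2", "g3"],
    )
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    frame = export_sigma_table(z, "ACT", "ETOH", p1)
    export_sigma_table(z, "ACT", "ETOH", p2)
    assert p1.read_bytes() == p2.read_bytes()
    assert frame.loc[0, "gene"] == "g3" and frame.loc[0, "rank"] == 1
    back = read_sigma_table(p1)
    np.testing.assert_allclose(back["delta_z"], frame["delta_z"])


def test_gene_relabelling_equivariance(two_arm_design):
    # swapping two gene labels swaps their scores and nothing else
    lib = sg.build_library(12, 4, 2, seed=5)
    truth = sg.neutral_truth(lib, two_arm_design)
    traj = sg.simulate_passaging(lib, truth, two_arm_design, seed=2)
    table = sg.sample_counts(traj, two_arm_design, seed=2)
    scores = sg.score_screen(table, lib)

    g1, g2 = lib.genes[0], lib.genes[1]
    swapped = lib.frame.copy()
    swapped["gene"] = swapped["gene"].map({g1: g2, g2: g1}).fillna(swapped["gene"])
    lib2 = sg.GuideLibrary(swapped)
    scores2 = sg.score_screen(table, lib2)
    assert scores2.z.loc[g2, "ACT"] == pytest.approx(scores.z.loc[g1, "ACT"])
    assert scores2.z.loc[g1, "ACT"] == pytest.approx(scores.z.loc[g2, "ACT"])
    other = [g for g in lib.genes if g not in (g1, g2)]
    pd.testing.assert_frame_equal(scores2.z.loc[other], scores.z.loc[other])


def test_z_before_average_alternative_order(null_screen, small_library):
    _, _, table = null_screen
    default = sg.score_screen(table, small_library)
    alt = sg.score_screen(table, small_library, z_before_average=True)
    # both orders produce finite gene scores for the same genes
    assert list(alt.z.index) == list(default.z.index)
    assert np.isfinite(alt.z.to_numpy()).all()
    # the two aggregation orders are correlated but not identical
    r = np.corrcoef(alt.z["ACT"], default.z["ACT"])[0, 1]
    assert r > 0.9
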