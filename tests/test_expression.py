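import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ribofit as rf
from ribofit.annotation import reverse_complement_annotation


def _single_gene_setup(gene_reads_per_nt=1.0, gene_len=1000, total=1e6):
    """One 1 kb mRNA plus an rRNA absorbing the rest of the library."""
    genes = pd.DataFrame(
        {
            "gene_id": ["g1", "rrn"],
            "chrom": "c",
            "strand": "+",
            "start": [100, 3000],
            "end": [100 + gene_len, 3000 + 2000],
            "gene_class": ["mRNA", "rRNA"],
            "stop_codon": ["UAA", ""],
            "stop_tetra": "",
            "regulons": "",
        }
    )
    ann = rf.GeneAnnotation(genes, chrom_sizes={"c": 6000})
    vec = np.zeros(6000)
    vec[100 : 100 + gene_len] = gene_reads_per_nt
    gene_total = gene_reads_per_nt * gene_len
    vec[3000:5000] = 7.0  # rRNA reads, excluded from the rpkm denominator
    extra = total - gene_total
    vec[5500] = extra  # intergenic reads make up the rest of the library
    track = rf.PileupTrack({("c", "+"): vec, ("c", "-"): np.zeros(6000)})
    return ann, track


def test_gene_density_rpkm_arithmetic():
    """Uniform 1 read/nt over 1 kb with a 1 M non-rRNA library -> rpkm 1000."""
    ann, track = _single_gene_setup()
    expr = rf.gene_density(track, ann)
    g1 = expr.set_index("gene_id").loc["g1"]
    assert g1["reads"] == pytest.approx(960)  # 20 nt trimmed per edge
    assert g1["density"] == pytest.approx(1.0)
    assert g1["rpkm"] == pytest.approx(1000.0)


def test_edge_trim_excludes_gene_ends():
    ann, track = _single_gene_setup()
    vec = track.counts[("c", "+")]
    vec[100:1100] = 0.0
    vec[100:120] = 50.0  # reads only within the first 20 nt
    expr = rf.gene_density(track, ann)
    assert expr.set_index("gene_id").loc["g1", "density"] == 0.0


def test_gene_density_matches_position_loop(sim_annotation):
    ann, _ = sim_annotation
    rng = np.random.default_rng(3)
    counts = {
        (c, s): rng.poisson(2.0, size=n).astype(float)
        for c, n in ann.chrom_sizes.items()
        for s in "+-"
    }
    track = rf.PileupTrack(counts)
    expr = rf.gene_density(track, ann).set_index("gene_id")
    for row in ann.genes.sample(10, random_state=0).itertuples():
        vec = track.counts[(row.chrom, row.strand)]
        total = 0.0
        for pos in range(row.start + 20, row.end - 20):
            total += vec[pos]
        assert expr.loc[row.gene_id, "reads"] == pytest.approx(total)


def test_short_gene_excluded_with_flag():
    genes = pd.DataFrame(
        {
            "gene_id": ["tiny", "ok"],
            "chrom": "c",
            "strand": "+",
            "start": [0, 100],
            "end": [35, 400],
            "gene_class": "mRNA",
            "stop_codon": "UAA",
            "stop_tetra": "",
            "regulons": "",
        }
    )
    ann = rf.GeneAnnotation(genes, chrom_sizes={"c": 600})
    track = rf.PileupTrack({("c", "+"): np.ones(600), ("c", "-"): np.zeros(600)})
    expr = rf.gene_density(track, ann).set_index("gene_id")
    assert expr.loc["tiny", "flag"] == "too_short"
    assert np.isnan(expr.loc["tiny", "density"])


# -------------------------------------------------------- synthesis fraction
def test_synthesis_fraction_examples_and_normalization():
    expr = pd.DataFrame(
        {"gene_id": ["a", "b"], "reads": [300.0, 700.0], "flag": ["", ""]}
    )
    fr = rf.synthesis_fraction(expr)
    assert fr["a"] == pytest.approx(0.30)
    assert fr["b"] == pytest.approx(0.70)
    assert fr.sum() == pytest.approx(1.0, abs=1e-9)


def test_synthesis_fraction_single_gene_and_counts_oracle():
    single = pd.DataFrame({"gene_id": ["only"], "reads": [42.0], "flag": [""]})
    assert rf.synthesis_fraction(single)["only"] == 1.0
    rng = np.random.default_rng(5)
    expr = pd.DataFrame(
        {"gene_id": [f"g{i}" for i in range(30)], "reads": rng.uniform(1, 100, 30), "flag": ""}
    )
    fr = rf.synthesis_fraction(expr)
    assert np.allclose(fr.to_numpy(), expr["reads"] / expr["reads"].sum())


def test_regulon_fraction_edge_cases():
    fr = pd.Series([0.2, 0.3, 0.5], index=["a", "b", "c"])
    assert rf.regulon_fraction(fr, ["a", "b", "c"])[0] == pytest.approx(1.0)
    assert rf.regulon_fraction(fr, [])[0] == 0.0
    val, missing = rf.regulon_fraction(fr, ["a", "zzz"])
    assert val == pytest.approx(0.2)
    assert missing == ["zzz"]


# -------------------------------------------------------------- calibration
def test_calibrate_sector_arithmetic():
    model = rf.CalibrationModel()
    assert rf.calibrate_sector(0.35, model, "translation") == pytest.approx(0.385)
    model2 = rf.CalibrationModel(psi0_sigb=0.02, phi0_sigb=0.02)
    # delta psi = 0.10 with alpha 1.41 and phi0 = 0.02
    assert rf.calibrate_sector(0.12, model2, "sigB") == pytest.approx(0.161)
    # at the basal point the calibration returns the basal proteome fraction
    assert rf.calibrate_sector(model2.psi0_sigb, model2, "sigB") == pytest.approx(
        model2.phi0_sigb
    )


@given(psi=st.floats(min_value=0.0, max_value=0.6))
@settings(max_examples=50, derandomize=True)
def test_calibration_round_trip(psi):
    model = rf.CalibrationModel()
    for sector in ("translation", "sigB"):
        phi = rf.calibrate_sector(psi, model, sector)
        assert rf.invert_sector(phi, model, sector) == pytest.approx(psi, abs=1e-12)


def test_translation_efficiency_and_correction():
    assert rf.translation_efficiency(300.0, 100.0) == pytest.approx(3.0)
    assert np.isnan(rf.translation_efficiency(300.0, 0.0))
    model = rf.CalibrationModel()
    assert model.te_foldchange["RF2"] == pytest.approx(3.0)
    assert model.te_foldchange["RF1"] == pytest.approx(0.66)
    assert rf.corrected_proteome_fraction(1e-3, 2.0, 3.0) == pytest.approx(6e-3)


# --------------------------------------------------------------- stop usage
def test_stop_usage_sums_to_one(sim_annotation):
    ann, _ = sim_annotation
    rng = np.random.default_rng(8)
    fr = pd.Series(
        rng.dirichlet(np.ones(len(ann.genes))), index=ann.genes["gene_id"]
    )
    usage = rf.stop_usage(fr, ann)
    assert usage.sum() == pytest.approx(1.0, abs=1e-9)
    assert set(usage.index) == {"UAA", "UAG", "UGA"}


def test_stop_usage_equal_split():
    genes = pd.DataFrame(
        {
            "gene_id": ["a", "b"],
            "chrom": "c",
            "strand": "+",
            "start": [0, 200],
            "end": [90, 290],
            "gene_class": "mRNA",
            "stop_codon": ["UAA", "UGA"],
            "stop_tetra": ["UAAG", "UGAC"],
            "regulons": "",
        }
    )
    ann = rf.GeneAnnotation(genes, chrom_sizes={"c": 400})
    fr = pd.Series([0.5, 0.5], index=["a", "b"])
    usage = rf.stop_usage(fr, ann)
    assert usage["UAA"] == pytest.approx(0.5)
    assert usage["UGA"] == pytest.approx(0.5)
    assert usage["UAG"] == 0.0
    tetra = rf.stop_usage(fr, ann, by="stop_tetra")
    assert tetra["UGAC"] == pytest.approx(0.5)


# ------------------------------------------------------------------- qPCR
def test_qpcr_outlier_rule_and_levels():
    ct = pd.DataFrame(
        {
            "sample": ["s"] * 6,
            "target": ["gyrA"] * 3 + ["ygxB"] * 3,
            "ct": [18.0, 18.0, 18.0, 20.0, 20.05, 20.5],
            "no_rt_ct": [30.0] * 6,
        }
    )
    levels = rf.qpcr_relative_level(ct)
    row = levels.set_index("target").loc["ygxB"]
    assert row["n_dropped"] == 1  # 20.5 deviates > 0.2 from its companions
    assert row["mean_ct"] == pytest.approx(20.025)
    assert row["relative_level"] == pytest.approx(2 ** (18.0 - 20.025))
    assert row["flag"] == ""


def test_qpcr_equal_and_shifted_ct():
    ct = pd.DataFrame(
        {
            "sample": ["s"] * 4,
            "target": ["gyrA", "gyrA", "x", "y"],
            "ct": [20.0, 20.0, 20.0, 30.0],
        }
    )
    levels = rf.qpcr_relative_level(ct).set_index("target")
    assert levels.loc["x", "relative_level"] == pytest.approx(1.0)
    assert levels.loc["y", "relative_level"] == pytest.approx(2**-10)


def test_qpcr_no_rt_gap_flagged():
    ct = pd.DataFrame(
        {
            "sample": ["s"] * 2,
            "target": ["gyrA", "x"],
            "ct": [20.0, 22.0],
            "no_rt_ct": [35.0, 25.0],  # gap of 3 Ct only for x
        }
    )
    levels = rf.qpcr_relative_level(ct).set_index("target")
    assert levels.loc["x", "flag"] == "no_rt_gap"


# --------------------------------------------------------- strand symmetry
def test_strand_symmetry_of_gene_quantities(sim_annotation):
    ann, genome = sim_annotation
    rng = np.random.default_rng(10)
    counts = {
        (c, s): rng.poisson(1.5, size=n).astype(float)
        for c, n in ann.chrom_sizes.items()
        for s in "+-"
    }
    track = rf.PileupTrack(counts)
    flipped_ann, _ = reverse_complement_annotation(ann, genome)
    flipped_track = track.flipped(ann.chrom_sizes)
    a = rf.gene_density(track, ann).set_index("gene_id")
    b = rf.gene_density(flipped_track, flipped_ann).set_index("gene_id")
    pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())
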