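"""Genome scan: ancestral inference, masks, VCF round trips, and
equivalence between the scan pipeline and direct classification."""

from __future__ import annotations

import io

import numpy as np
import pytest

from sweepshape.features import build_feature_vector
from sweepshape.samples import HaplotypeSample
from sweepshape.scan import (
    MaskTrack,
    infer_ancestral,
    load_variants,
    polarize,
    scan,
    write_intervals,
    write_vcf,
)
from sweepshape.simulate import SimulationConfig, build_training_scenarios, simulate_region

L = 2_200_000
WINDOW = 200_000


@pytest.fixture(scope="module")
def sim_sample():
    cfg = SimulationConfig(
        demography="equilibrium", alpha_range=(2500.0, 25_000.0), reps=1, seed=123
    )
    scenario = build_training_scenarios(cfg)["hard"][0]
    return simulate_region(scenario)


def _to_bp(sample: HaplotypeSample):
    """Map unit-interval positions to distinct 1-based bp coordinates."""
    bp = np.unique((sample.positions * L).astype(int) + 1)
    if bp.size < sample.n_sites:  # collisions: drop duplicates consistently
        keep = np.unique((sample.positions * L).astype(int) + 1, return_index=True)[1]
        matrix = sample.matrix[:, keep]
    else:
        matrix = sample.matrix
    return matrix, bp


class TestInferAncestral:
    def test_outgroup_agreement(self):
        assert infer_ancestral(("A", "G"), "A", "A") == "A"

    def test_single_outgroup(self):
        assert infer_ancestral(("A", "G"), "A", None) == "A"
        assert infer_ancestral(("A", "G"), None, "G") == "G"

    def test_disagreement_discards(self):
        assert infer_ancestral(("A", "G"), "C", "T") is None

    def test_must_match_a_human_allele(self):
        assert infer_ancestral(("A", "G"), "C", "C") is None

    def test_no_outgroup_discards(self):
        assert infer_ancestral(("A", "G"), None, "N") is None

    def test_invalid_base_rejected(self):
        with pytest.raises(ValueError, match="invalid base"):
            infer_ancestral(("A", "G"), "Z", "A")


def test_mask_track_from_bed(tmp_path):
    bed = tmp_path / "mask.bed"
    bed.write_text("chr1\t100\t200\nchr1\t500\t600\n")
    track = MaskTrack.from_bed(bed, 0, 1000, masked=True)
    assert track.count(0, 1000) == 800
    assert not track.is_accessible(150)
    assert track.is_accessible(250)
    # masking elsewhere never affects other bases
    before = track.accessible[:100].copy()
    track.mask_position(550)
    assert np.array_equal(track.accessible[:100], before)


def test_polarize_flips_and_discards():
    matrix = np.array([[0, 0, 1], [1, 1, 0]], dtype=np.uint8)
    positions = np.array([10, 20, 30])
    refs, alts = ["A", "C", "G"], ["G", "T", "A"]
    ancestral = {10: "A", 20: "T", 30: "C"}  # site 30 matches neither allele
    out, pos, discarded = polarize(matrix, positions, refs, alts, ancestral)
    assert pos.tolist() == [10, 20]
    assert out[:, 0].tolist() == [0, 1]  # REF ancestral: unchanged
    assert out[:, 1].tolist() == [1, 0]  # ALT ancestral: flipped
    assert discarded.tolist() == [30]


def test_load_variants_filters_and_logs_bad_records(tmp_path):
    vcf = tmp_path / "mixed.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=1>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\ts1\n"
        "1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0|1\t1|1\n"
        "1\t200\t.\tA\tT,G\t.\tPASS\t.\tGT\t0|1\t0|2\n"  # multi-allelic
        "1\t300\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\t0|1\n"  # unphased
        "1\t400\t.\tA\tT\t.\tPASS\t.\tGT\t.|.\t0|1\n"  # missing -> site dropped
        "1\t500\t.\tAC\tA\t.\tPASS\t.\tGT\t0|1\t0|1\n"  # indel
        "1\t600\t.\tA\tT\t.\tPASS\t.\tGT\t1|0\t0|1\n"
    )
    matrix, positions, refs, alts, skipped = load_variants(vcf)
    assert positions.tolist() == [100, 600]
    assert matrix.shape == (4, 2)
    assert skipped == {"multiallelic": 1, "non_snp": 1, "unphased": 1, "missing": 1}
    with pytest.raises(ValueError, match="drop-site"):
        load_variants(vcf, missing="impute")


def test_vcf_round_trip(tmp_path, sim_sample):
    matrix, bp = _to_bp(sim_sample)
    path = tmp_path / "sim.vcf"
    with open(path, "w") as fh:
        write_vcf(HaplotypeSample(matrix, bp / (bp.max() + 1)), bp, fh, chrom="18")
    loaded, positions, refs, alts, skipped = load_variants(path)
    assert np.array_equal(loaded, matrix)
    assert np.array_equal(positions, bp)
    assert sum(skipped.values()) == 0


def test_scan_matches_direct_classification(tmp_path, sim_sample, small_model):
    """Writing a simulated region to VCF, reloading it and scanning yields
    the same call as classifying the same feature vector directly."""
    matrix, bp = _to_bp(sim_sample)
    path = tmp_path / "sim.vcf"
    with open(path, "w") as fh:
        write_vcf(HaplotypeSample(matrix, bp / (bp.max() + 1)), bp, fh, chrom="18")
    loaded, positions, _, _, _ = load_variants(path)
    mask = MaskTrack.fully_accessible(0, L)
    results = scan(loaded, positions, mask, small_model, chrom="18", window_bp=WINDOW)
    assert len(results) == 11  # every window reported
    classified = [r for r in results if not r.omitted]
    assert len(classified) == 1 and classified[0].start == 5 * WINDOW
    assert all(r.reason == "incomplete_frame" for r in results if r.omitted)
    # direct path on the identical (bp-quantized) data
    direct = HaplotypeSample(loaded, (positions - 1) / L)
    fv = build_feature_vector(direct)
    assert classified[0].label == small_model.predict(fv.reshape(1, -1))[0]
    post = small_model.predict_proba(fv.reshape(1, -1))[0]
    assert classified[0].posteriors[classified[0].label] == pytest.approx(max(post))
    assert sum(classified[0].posteriors.values()) == pytest.approx(1.0)


def test_scan_omits_masked_frames(sim_sample, small_model):
    matrix, bp = _to_bp(sim_sample)
    mask = MaskTrack.fully_accessible(0, L)
    # mask 60% of subwindow 3
    mask.accessible[3 * WINDOW : 3 * WINDOW + int(0.6 * WINDOW)] = False
    results = scan(matrix, bp, mask, small_model, chrom="18", window_bp=WINDOW)
    central = results[5]
    assert central.omitted and central.reason == "masked"
    assert len(results) == 11


def test_write_intervals_format(sim_sample, small_model):
    matrix, bp = _to_bp(sim_sample)
    mask = MaskTrack.fully_accessible(0, L)
    results = scan(matrix, bp, mask, small_model, chrom="chr18", window_bp=WINDOW)
    bed, tsv = io.StringIO(), io.StringIO()
    write_intervals(results, bed, tsv)
    bed_lines = bed.getvalue().strip().split("\n")
    assert len(bed_lines) == 1
    chrom, start, end, name, score, strand = bed_lines[0].split("\t")
    assert (chrom, start, end, strand) == ("chr18", "1000000", "1200000", ".")
    assert name in ("hard", "hard-linked", "soft", "soft-linked", "neutral")
    assert 0 <= int(score) <= 1000
    tsv_lines = tsv.getvalue().strip().split("\n")
    assert len(tsv_lines) == 12  # header + all 11 windows, omitted included
    header = tsv_lines[0].split("\t")
    p_cols = [i for i, h in enumerate(header) if h.startswith("p_")]
    row = tsv_lines[6].split("\t")  # the classified central window
    assert sum(float(row[i]) for i in p_cols) == pytest.approx(1.0, abs=1e-6)


def test_write_intervals_requires_results():
    with pytest.raises(ValueError, match="no scan results"):
        write_intervals([], io.StringIO(), io.StringIO())
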