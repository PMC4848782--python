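"""Feature assignment, UMI collapsing and collision correction."""

import math

import numpy as np
import pandas as pd
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from celseq2pipe.umi_count import (
    AMBIGUOUS,
    NO_FEATURE,
    CountMatrix,
    FeatureModel,
    assign_read_to_feature,
    collapse_umis,
    count_run,
    umis_to_molecules,
)


# ---------------------------------------------------------------- correction
@pytest.mark.parametrize(
    "k,K,expected",
    [
        (0, 4096, 0.0),
        (1, 4096, 1.0),
        # ln(1/2) / ln(4095/4096), frozen from independent high-precision evaluation
        (2048, 4096, pytest.approx(2838.7842638794186, rel=1e-12)),
    ],
)
def test_umis_to_molecules_reference_values(k, K, expected):
    assert umis_to_molecules(k, K) == expected


def test_umis_to_molecules_saturation_is_capped():
    capped = umis_to_molecules(4096, 4096)
    assert capped == umis_to_molecules(4095, 4096)
    assert math.isfinite(capped)


@pytest.mark.parametrize("k,K", [(-1, 4096), (5, 4), (1, 1)])
def test_umis_to_molecules_domain_errors(k, K):
    with pytest.raises(ValueError):
        umis_to_molecules(k, K)


@given(st.integers(min_value=1, max_value=4095))
@settings(max_examples=200, derandomize=True)
def test_correction_monotone_convex_and_at_least_k(k):
    K = 4096
    f = umis_to_molecules
    assert f(k, K) >= k
    assert f(k, K) > f(k - 1, K)
    if k < K - 1:
        # convexity: second difference nonnegative
        assert f(k + 1, K) - 2 * f(k, K) + f(k - 1, K) >= -1e-9


def test_collision_oracle_recovers_true_molecule_numbers():
    """Drawing m labels from K and correcting the distinct count recovers m (2 SE, 1000 reps)."""
    rng = np.random.default_rng(42)
    K = 4096
    for m in (10, 500, 2000):
        distinct = np.array(
            [len(np.unique(rng.integers(0, K, size=m))) for _ in range(1000)]
        )
        corrected = np.array([umis_to_molecules(int(k), K) for k in distinct])
        se = corrected.std(ddof=1) / math.sqrt(len(corrected))
        assert abs(corrected.mean() - m) <= 2 * se
    # the raw distinct count meanwhile underestimates heavily at high occupancy
    assert (2000 - distinct.mean()) / 2000 > 0.15


# ---------------------------------------------------------------- collapsing
def test_collapse_umis_counts_distinct_sequences():
    stream = [("c1", "g1", "AAAAAA")] * 3 + [("c1", "g1", "CCCCCC")] * 2
    assert collapse_umis(stream) == {("c1", "g1"): 2}


def test_collapse_umis_no_cross_gene_collapse():
    stream = [("c1", "g1", "AAAAAA"), ("c1", "g2", "AAAAAA")]
    assert collapse_umis(stream) == {("c1", "g1"): 1, ("c1", "g2"): 1}


def test_collapse_umis_empty():
    assert collapse_umis([]) == {}


# ---------------------------------------------------------------- assignment
@pytest.fixture()
def toy_model():
    # two genes on +, one overlapping pair, one gene on -
    return FeatureModel(
        [
            ("gA", "chr1", 100, 500, "+"),
            ("gB", "chr1", 450, 900, "+"),  # overlaps gA in [450, 500)
            ("gC", "chr1", 1000, 1400, "-"),
        ]
    )


def _aln(header, name="r1:UMI:AAAAAA:CELL:AACCGG", start=200, reverse=False, mapq=42):
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.flag = 16 if reverse else 0
    a.reference_id = 0
    a.reference_start = start
    a.mapping_quality = mapq
    a.cigarstring = "36M"
    a.query_sequence = "A" * 36
    return a


@pytest.fixture()
def sam_header():
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 2000}]}
    )


def test_assignment_unique_overlap(toy_model, sam_header):
    assert assign_read_to_feature(_aln(sam_header, start=200), toy_model) == "gA"


def test_assignment_ambiguous_overlap(toy_model, sam_header):
    assert assign_read_to_feature(_aln(sam_header, start=460), toy_model) == AMBIGUOUS


def test_assignment_is_strand_specific(toy_model, sam_header):
    # gC is on '-'; a forward read over it finds nothing
    assert assign_read_to_feature(_aln(sam_header, start=1100), toy_model) == NO_FEATURE
    assert assign_read_to_feature(_aln(sam_header, start=1100, reverse=True), toy_model) == "gC"


def test_feature_model_rejects_malformed_intervals():
    with pytest.raises(ValueError):
        FeatureModel([("g", "chr1", 500, 100, "+")])
    with pytest.raises(ValueError):
        FeatureModel([("g", "chr1", 100, 500, ".")])


# ---------------------------------------------------------------- count_run
def _write_sam(path, header_dict, records):
    with pysam.AlignmentFile(str(path), "w", header=header_dict) as fh:
        for rec in records:
            fh.write(rec)


def test_count_run_hand_computed(tmp_path, toy_model):
    header_dict = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 2000}]}
    header = pysam.AlignmentHeader.from_dict(header_dict)
    records = [
        _aln(header, "r1:UMI:AAAAAA:CELL:cell1", start=200),
        _aln(header, "r2:UMI:AAAAAA:CELL:cell1", start=210),  # same UMI, collapses
        _aln(header, "r3:UMI:CCCCCC:CELL:cell1", start=220),
        _aln(header, "r4:UMI:AAAAAA:CELL:cell2", start=1100, reverse=True),
        _aln(header, "r5:UMI:GGGGGG:CELL:cell2", start=460),  # ambiguous
        _aln(header, "r6:UMI:GGGGGG:CELL:cell2", start=200, mapq=0),  # multimapped
        _aln(header, "r7:UMI:NNNNNN:CELL:cell2", start=200),  # N in UMI, dropped
    ]
    sam = tmp_path / "a.sam"
    _write_sam(sam, header_dict, records)
    matrix, report = count_run(sam, toy_model, umi_length=6)
    assert report.assigned == 4  # r1-r3 on gA, r4 on gC; UMI collapse happens later
    assert report.ambiguous == 1
    assert report.multimapped == 1
    assert report.umi_with_n == 1
    assert report.total == sum(report.per_file.values()) == 7
    assert matrix.umi_counts.at["gA", "cell1"] == 2
    assert matrix.umi_counts.at["gC", "cell2"] == 1
    assert matrix.umi_counts.at["gB", "cell2"] == 0


def test_count_run_requires_tag(tmp_path, toy_model):
    header_dict = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 2000}]}
    header = pysam.AlignmentHeader.from_dict(header_dict)
    sam = tmp_path / "a.sam"
    _write_sam(sam, header_dict, [_aln(header, "untagged_read", start=200)])
    with pytest.raises(ValueError, match="suffix"):
        count_run(sam, toy_model)


def test_count_run_order_invariant(tmp_path, toy_model):
    header_dict = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 2000}]}
    header = pysam.AlignmentHeader.from_dict(header_dict)
    records = [
        _aln(header, f"r{i}:UMI:{umi}:CELL:cell1", start=200)
        for i, umi in enumerate(["AAAAAA", "CCCCCC", "GGGGGG", "AAAAAA"])
    ]
    a, b = tmp_path / "a.sam", tmp_path / "b.sam"
    _write_sam(a, header_dict, records)
    _write_sam(b, header_dict, records[::-1])
    ma, _ = count_run(a, toy_model)
    mb, _ = count_run(b, toy_model)
    pd.testing.assert_frame_equal(ma.umi_counts, mb.umi_counts)


def test_count_matrix_layer_invariants(clean_sim):
    model = FeatureModel.from_gtf(clean_sim.annotation_gtf)
    matrix, _ = count_run(clean_sim.alignments_sam, model)
    umis = matrix.umi_counts.to_numpy()
    mols = matrix.molecule_estimates.to_numpy()
    assert (umis >= 0).all() and (umis <= matrix.K).all()
    assert (mols >= umis - 1e-9).all()
    assert ((mols == 0) == (umis == 0)).all()


def test_error_free_count_round_trip_matches_truth(clean_sim):
    truth = clean_sim.truth
    model = FeatureModel.from_gtf(clean_sim.annotation_gtf)
    matrix, report = count_run(clean_sim.alignments_sam, model)
    assert report.ambiguous == report.no_feature == report.unmapped == 0
    got = matrix.umi_counts.reindex(index=truth.feature_ids, columns=truth.cell_barcodes)
    assert got.to_numpy().tolist() == truth.distinct_umis.to_numpy().tolist()


def test_high_occupancy_molecule_estimates_beat_raw_counts():
    """Near K/2 distinct UMIs, correction recovers truth within 5% while raw counts undershoot."""
    from celseq2pipe.simulate import SimConfig, simulate_counts

    rel_errors, raw_errors = [], []
    for rep in range(20):
        cfg = SimConfig(
            n_cells=2,
            n_genes=2,
            n_spikeins=2,
            gene_mean_range=(2000.0, 2100.0),
            spike_mean_range=(1.0, 2.0),
            capture_efficiency=1.0,
            seed=300 + rep,
        )
        truth = simulate_counts(cfg)
        genes = [f for f in truth.feature_ids if f.startswith("GSIM")]
        captured = truth.captured_molecules.loc[genes].to_numpy().astype(float)
        distinct = truth.distinct_umis.loc[genes].to_numpy().astype(float)
        corrected = np.vectorize(lambda k: umis_to_molecules(int(k), cfg.umi_space))(distinct)
        rel_errors.append(np.abs(corrected - captured) / captured)
        raw_errors.append((captured - distinct) / captured)
    assert np.mean(rel_errors) < 0.05
    assert np.mean(raw_errors) > 0.1  # raw distinct counts are systematically low


def test_mtx_export_round_trip(clean_sim, tmp_path):
    from scipy import io as spio

    model = FeatureModel.from_gtf(clean_sim.annotation_gtf)
    matrix, _ = count_run(clean_sim.alignments_sam, model)
    matrix.to_mtx(tmp_path)
    back = spio.mmread(tmp_path / "umi_counts.mtx").toarray()
    assert (back == matrix.umi_counts.to_numpy()).all()
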