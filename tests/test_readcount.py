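"""Assignment, target counting, depth gating, pileups and error profiling."""

import numpy as np
import pytest

from plasmacall import (
    Amplicon,
    AmpliconCount,
    ErrorModel,
    Panel,
    PanelVariant,
    SimulationParams,
    apply_depth_filter,
    assign_reads,
    build_pileup,
    count_variant_reads,
    make_panel,
    nonref_rate_profile,
    revcomp,
    sam_variant_counts,
    simulate_reads,
)
from plasmacall.pipeline import merge_read_set
from plasmacall.readcount import Pileup, classify_read


@pytest.fixture(scope="module")
def snv_amplicon():
    panel, _ = make_panel(1, insert_length_range=(60, 100), seed=71)
    return panel.amplicons[0]


def _read_with_base(amplicon, base):
    p = amplicon.product_seq
    off = amplicon.variant_product_offset
    return p[:off] + base + p[off + 1 :]


class TestAssignReads:
    def test_exact_primer_prefix_assigns(self):
        panel, _ = make_panel(3, seed=73)
        amp = panel.amplicons[1]
        groups, unassigned = assign_reads([amp.product_seq], panel)
        assert groups[amp.id] == [amp.product_seq]
        assert unassigned == []

    def test_ambiguous_read_is_unassigned(self):
        panel, _ = make_panel(2, seed=73)
        a, b = panel.amplicons
        twin = Amplicon(
            id="TWIN",
            chrom=b.chrom,
            insert_start=b.insert_start,
            insert_end=b.insert_end,
            fwd_primer=a.fwd_primer,  # same forward primer as amplicon a
            rev_primer=b.rev_primer,
            insert_seq=b.insert_seq,
            variant=b.variant,
        )
        shared = Panel(patient_id="p", amplicons=[a, twin])
        _, unassigned = assign_reads([a.product_seq], shared)
        assert len(unassigned) == 1

    def test_no_primer_match_is_unassigned(self):
        panel, _ = make_panel(2, seed=73)
        _, unassigned = assign_reads(["T" * 100], panel)
        assert len(unassigned) == 1

    def test_perfect_assignment_on_error_free_reads(self):
        panel, _ = make_panel(5, seed=79)
        params = SimulationParams(depth_per_amplicon=100, ctdna_fraction=0.1, seed=83)
        rs = simulate_reads(panel, params, ErrorModel(substitution_rate=0))
        merged = merge_read_set(rs).merged
        groups, unassigned = assign_reads(merged, panel)
        assert not unassigned
        for amp in panel:
            assert all(m.id.startswith(amp.id + "|") for m in groups[amp.id])
            assert len(groups[amp.id]) == 100


class TestCountVariantReads:
    def test_all_reference(self, snv_amplicon):
        reads = [snv_amplicon.product_seq] * 10
        c = count_variant_reads(reads, snv_amplicon)
        assert (c.variant_reads, c.depth, c.vaf) == (0, 10, 0.0)

    def test_n_excluded_from_denominator(self, snv_amplicon):
        amp = snv_amplicon
        reads = (
            [_read_with_base(amp, amp.variant.alt)] * 3
            + [amp.product_seq] * 6
            + [_read_with_base(amp, "N")]
        )
        c = count_variant_reads(reads, amp)
        assert c.variant_reads == 3
        assert c.depth == 9
        assert c.vaf == pytest.approx(1 / 3)
        assert c.n_masked_reads == 1

    def test_third_allele_counts_in_depth_only(self, snv_amplicon):
        amp = snv_amplicon
        third = next(b for b in "ACGT" if b not in (amp.variant.ref, amp.variant.alt))
        c = count_variant_reads([_read_with_base(amp, third)] * 4, amp)
        assert c.variant_reads == 0
        assert c.reference_reads == 0
        assert c.depth == 4

    def test_uncovered_position(self, snv_amplicon):
        c = count_variant_reads([snv_amplicon.product_seq[:10]], snv_amplicon)
        assert (c.variant_reads, c.depth) == (0, 0)

    def test_matches_ground_truth_without_errors(self):
        panel, _ = make_panel(3, seed=89)
        params = SimulationParams(depth_per_amplicon=400, ctdna_fraction=0.05, seed=97)
        rs = simulate_reads(panel, params, ErrorModel(substitution_rate=0))
        merged = merge_read_set(rs).merged
        groups, _ = assign_reads(merged, panel)
        for amp in panel:
            c = count_variant_reads(groups[amp.id], amp)
            assert c.variant_reads == rs.mutant_read_count(amp.id)

    def test_indel_counting_matches_ground_truth(self):
        panel, _ = make_panel(4, seed=101, indel_fraction=1.0)
        params = SimulationParams(depth_per_amplicon=300, ctdna_fraction=0.3, seed=103)
        rs = simulate_reads(panel, params, ErrorModel(substitution_rate=0))
        merged = merge_read_set(rs).merged
        groups, _ = assign_reads(merged, panel)
        for amp in panel:
            c = count_variant_reads(groups[amp.id], amp)
            assert c.variant_reads == rs.mutant_read_count(amp.id)
            assert c.depth == 300


class TestDepthFilter:
    @pytest.mark.parametrize(
        "depth,expected",
        [(999, "not_called"), (1000, "evaluable"), (0, "not_called")],
    )
    def test_thousand_x_boundary(self, depth, expected):
        c = AmpliconCount("A", variant_reads=0, depth=depth, reference_reads=depth)
        assert apply_depth_filter(c) == expected


class TestPileup:
    def test_column_sums_equal_covering_reads(self):
        panel, _ = make_panel(2, seed=107)
        params = SimulationParams(depth_per_amplicon=150, ctdna_fraction=0.1, seed=109)
        rs = simulate_reads(panel, params)
        merged = merge_read_set(rs).merged
        groups, _ = assign_reads(merged, panel)
        for amp in panel:
            pile = build_pileup(groups[amp.id], amp)
            fwd = len(amp.fwd_primer)
            expected = np.zeros(amp.insert_length, dtype=int)
            for m in groups[amp.id]:
                covered = max(0, min(amp.insert_length, len(m.sequence) - fwd))
                expected[:covered] += 1
            assert np.array_equal(pile.coverage(), expected)

    def test_count_partition_at_target(self, snv_amplicon):
        amp = snv_amplicon
        reads = (
            [_read_with_base(amp, amp.variant.alt)] * 2
            + [amp.product_seq] * 5
            + [_read_with_base(amp, "N")] * 3
        )
        c = count_variant_reads(reads, amp)
        assert c.variant_reads + c.reference_reads + c.other_reads + c.n_masked_reads == 10

    def test_indel_read_classification(self):
        panel, _ = make_panel(1, seed=113, indel_fraction=1.0)
        amp = panel.amplicons[0]
        assert classify_read(amp.product_seq, amp) == "ref"
        assert classify_read(amp.alt_product_seq(), amp) == "alt"


class TestErrorProfile:
    def _pileup(self, amp, reads):
        return build_pileup(reads, amp)

    def test_error_free_profile(self, snv_amplicon):
        pile = self._pileup(snv_amplicon, [snv_amplicon.product_seq] * 20)
        profile = nonref_rate_profile([pile])
        assert profile.mean_rate == 0.0
        assert profile.zero_error_fraction == 1.0

    def test_direct_arithmetic(self):
        # 10 positions at depth 1000, one non-reference call at one position
        amp = make_panel(1, insert_length_range=(60, 60), seed=127)[0].amplicons[0]
        pile = Pileup.empty(amp)
        row = {b: i for i, b in enumerate("ACGTN")}
        for j, base in enumerate(amp.insert_seq[:10]):
            pile.base_counts[row[base], j] = 1000
        j_err = 4
        ref_base = amp.insert_seq[j_err]
        err_base = next(b for b in "ACGT" if b != ref_base)
        pile.base_counts[row[ref_base], j_err] -= 1
        pile.base_counts[row[err_base], j_err] += 1
        profile = nonref_rate_profile([pile])
        assert profile.n_positions == 10
        assert profile.mean_rate == pytest.approx(1e-4)
        assert profile.zero_error_fraction == pytest.approx(0.9)

    def test_exclusion_list_removes_sites(self):
        amp = make_panel(1, seed=131)[0].amplicons[0]
        pile = build_pileup([amp.product_seq] * 5, amp)
        profile_all = nonref_rate_profile([pile])
        first_pos = (amp.chrom, amp.insert_start + 1)
        profile_ex = nonref_rate_profile([pile], exclude_sites=[first_pos])
        assert profile_ex.n_positions == profile_all.n_positions - 1

    def test_all_excluded_warns(self):
        amp = make_panel(1, seed=131)[0].amplicons[0]
        pile = build_pileup([amp.product_seq], amp)
        sites = [(amp.chrom, amp.insert_start + 1 + j) for j in range(amp.insert_length)]
        with pytest.warns(UserWarning):
            profile = nonref_rate_profile([pile], exclude_sites=sites)
        assert profile.n_positions == 0


class TestSamIngestion:
    def _write_sam(self, path, panel, records):
        import pysam

        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": a.chrom, "LN": len(a.product_seq)} for a in panel
            ],
        }
        with pysam.AlignmentFile(str(path), "w", header=header) as fh:
            for name, chrom, seq, cigar in records:
                rec = pysam.AlignedSegment(fh.header)
                rec.query_name = name
                rec.reference_name = chrom
                rec.reference_start = 0
                rec.query_sequence = seq
                rec.cigarstring = cigar
                rec.mapping_quality = 60
                fh.write(rec)

    def test_snv_counts_from_sam(self, tmp_path, snv_amplicon):
        amp = snv_amplicon
        panel = Panel(patient_id="p", amplicons=[amp])
        alt_read = _read_with_base(amp, amp.variant.alt)
        n_read = _read_with_base(amp, "N")
        length = len(amp.product_seq)
        records = (
            [("r%d" % i, amp.chrom, amp.product_seq, f"{length}M") for i in range(5)]
            + [("a%d" % i, amp.chrom, alt_read, f"{length}M") for i in range(3)]
            + [("n0", amp.chrom, n_read, f"{length}M")]
        )
        sam = tmp_path / "sample.sam"
        self._write_sam(sam, panel, records)
        counts = sam_variant_counts(sam, panel)
        c = counts[amp.id]
        assert (c.variant_reads, c.reference_reads, c.depth, c.n_masked_reads) == (3, 5, 8, 1)

    def test_deletion_counts_from_sam(self, tmp_path):
        panel_full, _ = make_panel(4, seed=101, indel_fraction=1.0)
        amp = next(a for a in panel_full if len(a.variant.ref) > len(a.variant.alt))
        panel = Panel(patient_id="p", amplicons=[amp])
        dlen = len(amp.variant.ref) - len(amp.variant.alt)
        anchor = amp.variant_product_offset
        alt_seq = amp.alt_product_seq()
        cigar_alt = f"{anchor + 1}M{dlen}D{len(alt_seq) - anchor - 1}M"
        length = len(amp.product_seq)
        records = [
            ("ref0", amp.chrom, amp.product_seq, f"{length}M"),
            ("alt0", amp.chrom, alt_seq, cigar_alt),
        ]
        sam = tmp_path / "indel.sam"
        self._write_sam(sam, panel, records)
        counts = sam_variant_counts(sam, panel)
        assert counts[amp.id].variant_reads == 1
        assert counts[amp.id].reference_reads == 1
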