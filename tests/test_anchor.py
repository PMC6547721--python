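"""CIGAR anchoring, alignment filtering and truth labeling."""

import numpy as np
import pysam
import pytest

from modcaller.anchor import (
    BisulfiteSite,
    anchor_read,
    filter_alignments,
    label_from_bisulfite,
    label_from_motifs,
    revcomp,
)
from modcaller.events import MergedEvents


def _merged_from_seq(seq: str) -> MergedEvents:
    n = len(seq)
    return MergedEvents(
        np.frombuffer(seq.encode(), dtype="S1").copy(),
        np.zeros(n), np.zeros(n), np.ones(n, np.int64),
    )


def _record(query, cigar, pos, reverse=False, name="r", contig="c1", mapq=60,
            reflen=200, flag_extra=0):
    header = pysam.AlignmentHeader.from_references([contig], [reflen])
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.query_sequence = query
    rec.flag = (16 if reverse else 0) | flag_extra
    rec.reference_id = 0
    rec.reference_start = pos
    rec.mapping_quality = mapq
    rec.cigarstring = cigar
    return rec


class TestAnchorRead:
    def test_forward_all_match_walk(self):
        ref = {"c1": "A" * 100 + "ACGTACGTAC" + "A" * 90}
        read = "ACGTACGTAC"
        ar = anchor_read(read, _merged_from_seq(read), _record(read, "10M", 100), ref)
        events = list(ar)
        assert [e.ref_pos for e in events] == list(range(100, 110))
        assert all(e.is_match for e in events)
        assert len(ar) == 10

    def test_mixed_cigar_matches_pysam_aligned_pairs(self):
        # 4M 1I 3M 2D 3M: 10 anchored bases, reference span 12
        ref_seq = "T" * 50 + "ACGTGGGTTAAA" + "T" * 50
        ref = {"c1": ref_seq}
        read = "ACGTCGGGAAA"  # 11 bases, base 4 (C) is the insertion
        rec = _record(read, "4M1I3M2D3M", 50)
        ar = anchor_read(read, _merged_from_seq(read), rec, ref)
        events = list(ar)
        assert len(events) == 10
        assert max(e.ref_pos for e in events) - min(e.ref_pos for e in events) + 1 == 12
        # oracle: pysam's own CIGAR interpretation
        expected = {q: r for q, r in rec.get_aligned_pairs(matches_only=True)}
        got = {e.read_offset: e.ref_pos for e in events}
        assert got == expected

    def test_reverse_strand_maps_descending(self):
        ref = {"c1": "G" * 50 + "AACGT" + "G" * 50}
        read = "ACGTT"  # molecule sense; revcomp = AACGT aligns at 50
        rec = _record(revcomp(read), "5M", 50, reverse=True)
        ar = anchor_read(read, _merged_from_seq(read), rec, ref)
        by_offset = {e.read_offset: e for e in ar}
        assert by_offset[0].ref_pos == 54
        assert by_offset[4].ref_pos == 50
        assert ar.strand == "-"
        # read-sense reference base is the complement of the forward base
        assert by_offset[0].ref_base == "A"  # forward base at 54 is T

    def test_anchor_count_equals_match_columns(self):
        ref = {"c1": "ACGT" * 50}
        read = "ACGTACGTACG"
        for cigar, n_match in [("11M", 11), ("2S9M", 9), ("5M1I5M", 10), ("3M2D8M", 11)]:
            rec = _record(read, cigar, 10)
            ar = anchor_read(read, _merged_from_seq(read), rec, ref)
            assert len(ar) == n_match, cigar

    def test_spliced_cigar_rejected(self):
        ref = {"c1": "ACGT" * 50}
        read = "ACGTAC"
        with pytest.raises(ValueError, match="N operator"):
            anchor_read(read, _merged_from_seq(read), _record(read, "3M100N3M", 10), ref)

    def test_length_mismatch_and_missing_contig(self):
        ref = {"c1": "ACGT" * 50}
        read = "ACGTAC"
        with pytest.raises(ValueError, match="length"):
            anchor_read(read, _merged_from_seq(read), _record(read, "5M", 10), ref)
        with pytest.raises(KeyError):
            anchor_read(read, _merged_from_seq(read), _record(read, "6M", 10), {"other": "A" * 99})


class TestFilterAlignments:
    def test_mapq_boundary_is_strict_less_than(self):
        read = "ACGTAC"
        recs = [
            _record(read, "6M", 0, mapq=9, name="low"),
            _record(read, "6M", 0, mapq=10, name="boundary"),
            _record(read, "6M", 0, mapq=60, name="high"),
        ]
        kept = filter_alignments(recs)
        assert [r.query_name for r in kept] == ["boundary", "high"]

    def test_unmapped_secondary_supplementary_dropped(self):
        read = "ACGTAC"
        recs = [
            _record(read, "6M", 0, flag_extra=4, name="unmapped"),
            _record(read, "6M", 0, flag_extra=256, name="secondary"),
            _record(read, "6M", 0, flag_extra=2048, name="supplementary"),
            _record(read, "6M", 0, name="primary"),
        ]
        assert [r.query_name for r in filter_alignments(recs)] == ["primary"]

    def test_empty_input(self):
        assert filter_alignments([]) == []


def _scan_oracle(seq, motif):
    """Exhaustive substring scan."""
    return [i for i in range(len(seq) - len(motif) + 1) if seq[i : i + len(motif)] == motif]


class TestLabelFromMotifs:
    def test_palindromic_cg_gives_one_site_per_strand(self):
        labels = label_from_motifs({"c": "ACGT"}, "CG", 0)
        assert labels == {("c", 1, "+"): 1, ("c", 2, "-"): 1}

    def test_overlapping_occurrences_counted(self):
        labels = label_from_motifs({"c": "GCGCGC"}, "GCGC", 1, strands="+")
        assert sorted(p for (_, p, _) in labels) == [1, 3]
        # oracle: exhaustive scan
        assert sorted(i + 1 for i in _scan_oracle("GCGCGC", "GCGC")) == [1, 3]

    def test_negative_control_flips_labels_only(self):
        ref = {"c": "TTGCGCAA"}
        pos = label_from_motifs(ref, "GCGC", 1)
        neg = label_from_motifs(ref, "GCGC", 1, control="negative")
        assert pos.keys() == neg.keys()
        assert set(pos.values()) == {1} and set(neg.values()) == {0}

    def test_palindromic_motif_strand_balance(self):
        rng = np.random.default_rng(5)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
        labels = label_from_motifs({"c": seq}, "CG", 0)
        strands = [s for (_, _, s) in labels]
        assert strands.count("+") == strands.count("-")

    def test_invalid_motif_rejected(self):
        with pytest.raises(ValueError):
            label_from_motifs({"c": "ACGT"}, "CN", 0)


class TestLabelFromBisulfite:
    def _site(self, p1, p2, c1=12, c2=15):
        return BisulfiteSite("c", 10, "+", c1, c2, p1, p2)

    def test_complete_methylation_requires_both_replicates(self):
        labels = label_from_bisulfite([self._site(0.92, 0.95)], min_cov=10)
        assert labels == {("c", 10, "+"): 1}
        assert label_from_bisulfite([self._site(0.92, 0.80)], min_cov=10) == {}

    def test_zero_in_both_replicates_is_unmodified_regardless_of_coverage(self):
        labels = label_from_bisulfite([self._site(0.0, 0.0, c1=1, c2=1)], min_cov=10)
        assert labels == {("c", 10, "+"): 0}

    def test_intermediate_sites_excluded(self):
        assert label_from_bisulfite([self._site(0.50, 0.60)]) == {}

    def test_coverage_gate_applies_to_methylated_label(self):
        assert label_from_bisulfite([self._site(0.95, 0.95, c1=5, c2=20)], min_cov=10) == {}

    def test_threshold_inclusive_by_default_strict_by_flag(self):
        site = self._site(0.90, 0.90)
        assert label_from_bisulfite([site], min_cov=1) == {("c", 10, "+"): 1}
        assert label_from_bisulfite([site], min_cov=1, inclusive=False) == {}

    def test_never_labels_both_ways_and_subset_of_input(self):
        rng = np.random.default_rng(3)
        sites = [
            BisulfiteSite("c", i, "+", int(rng.integers(1, 30)), int(rng.integers(1, 30)),
                          float(rng.random()), float(rng.random()))
            for i in range(200)
        ]
        labels = label_from_bisulfite(sites, min_cov=5)
        keys = {(s.contig, s.ref_pos, s.strand) for s in sites}
        assert set(labels) <= keys
        assert set(labels.values()) <= {0, 1}
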