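"""Finger detection, linker arithmetic, array grouping, set labels."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from famsurvey.core import Alphabet, SequenceRecord
from famsurvey.synthetic import gen_proteome
from famsurvey.zf_family import (
    ZincFingerHit,
    classify_set,
    compile_pattern,
    group_arrays,
    linker_lengths,
    scan_fingers,
    scan_proteome,
    summarize_family,
)


def prot(seq, pid="p"):
    return SequenceRecord(pid, seq, Alphabet.protein)


def hit(start, end, pid="p"):
    return ZincFingerHit(pid, start, end, "X" * (end - start + 1), "pat")


class TestScanFingers:
    def test_planted_canonical_motif(self):
        # C-x2-C-x12-H-x3-H planted at position 4
        hits = scan_fingers(prot("AAACAACAAAAAAAAAAAAHAAAHAAA"))
        assert [(h.start, h.end) for h in hits] == [(4, 24)]
        assert hits[0].matched_subsequence == "CAACAAAAAAAAAAAAHAAAH"

    def test_no_anchors_no_hits(self):
        assert scan_fingers(prot("AAAAAAAA")) == []

    def test_anchor_residues_are_c_and_h(self):
        hits = scan_fingers(prot("AAACAACAAAAAAAAAAAAHAAAHAAA"))
        m = hits[0].matched_subsequence
        assert m[0] == "C" and m[-1] == "H"

    def test_position_equivariance(self):
        base = "AAACAACAAAAAAAAAAAAHAAAHAAA"
        h0 = scan_fingers(prot(base))
        h1 = scan_fingers(prot("A" * 100 + base))
        assert [(h.start + 100, h.end + 100) for h in h0] == [
            (h.start, h.end) for h in h1
        ]

    def test_planted_proteome_counts_match_truth(self):
        records, truth = gen_proteome(10, 5, 35, seed=2)
        for rec in records:
            hits = scan_fingers(rec)
            planted = truth.data["proteins"][rec.id]["finger_coords"]
            assert [(h.start, h.end) for h in hits] == [tuple(c) for c in planted]

    def test_relaxed_pattern_catches_degenerate_finger(self):
        # C-x1-C-x10-H-x2-H: outside the canonical spacing
        seq = "AAACACAAAAAAAAAAHAAHAAA"
        assert scan_fingers(prot(seq)) == []
        hits = scan_fingers(prot(seq), "C-x(1,5)-C-x(9,14)-H-x(2,6)-H")
        assert len(hits) == 1

    def test_bad_pattern_spec_rejected(self):
        with pytest.raises(ValueError, match="cannot parse"):
            compile_pattern("C-y(2)-H")


class TestLinkersAndArrays:
    def test_consensus_five_residue_linker(self):
        assert linker_lengths([hit(1, 21), hit(27, 47)]) == [5]

    def test_single_finger_no_linkers(self):
        assert linker_lengths([hit(1, 21)]) == []

    def test_linker_arithmetic(self):
        assert linker_lengths([hit(1, 21), hit(33, 53)]) == [11]

    def test_overlapping_hits_error(self):
        with pytest.raises(ValueError, match="overlap"):
            linker_lengths([hit(1, 21), hit(20, 40)])

    @pytest.mark.parametrize(
        "linkers,array_sizes,n_dispersed",
        [
            ([5, 5], [3], 0),
            ([5, 30], [2], 1),
            ([5, 30, 7], [2, 2], 0),
            ([30, 30], [], 3),
        ],
    )
    def test_run_grouping(self, linkers, array_sizes, n_dispersed):
        hits, pos = [], 1
        for i in range(len(linkers) + 1):
            hits.append(hit(pos, pos + 20))
            pos += 21 + (linkers[i] if i < len(linkers) else 0)
        arrays, dispersed = group_arrays(hits)
        assert [len(a.finger_indices) for a in arrays] == array_sizes
        assert len(dispersed) == n_dispersed
        # partition: every finger in exactly one array or dispersed
        members = sorted(i for a in arrays for i in a.finger_indices) + sorted(dispersed)
        assert sorted(members) == list(range(len(hits)))


class TestClassifySet:
    def test_one_array_plus_dispersed_is_A(self):
        hits = [hit(1, 21), hit(27, 47), hit(100, 120)]
        arrays, dispersed = group_arrays(hits)
        assert classify_set(arrays, dispersed) == "A"

    def test_two_arrays_is_B(self):
        hits = [hit(1, 21), hit(27, 47), hit(100, 120), hit(126, 146)]
        arrays, dispersed = group_arrays(hits)
        assert classify_set(arrays, dispersed) == "B"

    def test_all_dispersed_is_C(self):
        hits = [hit(1, 21), hit(50, 70), hit(100, 120)]
        arrays, dispersed = group_arrays(hits)
        assert classify_set(arrays, dispersed) == "C"

    def test_zero_fingers_unclassified(self):
        assert classify_set([], []) is None


class TestSummarize:
    def test_planted_set_counts(self, small_proteome):
        records, truth = small_proteome
        summary = summarize_family(scan_proteome(records))
        assert summary["set_counts"] == {"A": 5, "B": 2, "C": 10}

    def test_empty_input_all_zero(self):
        summary = summarize_family([])
        assert summary["n_proteins"] == 0
        assert summary["set_counts"] == {"A": 0, "B": 0, "C": 0}

    def test_linker_mode_five(self):
        # all linkers exactly 5
        seq = "CAACAAAAAAAAAAAAHAAAH"
        rec = prot("AA" + seq + "AAAAA" + seq + "AAAAA" + seq + "AA")
        summary = summarize_family(scan_proteome([rec]))
        assert summary["linker_mode"] == 5

    def test_partition_invariant(self, small_proteome):
        records, _ = small_proteome
        for a in scan_proteome(records):
            assert a.n_fingers == sum(
                len(arr.finger_indices) for arr in a.arrays
            ) + len(a.dispersed)


@given(st.integers(0, 2**31 - 1))
def test_planted_labels_always_recovered(seed):
    """Noise-free planted proteomes are recovered with 100% agreement."""
    records, truth = gen_proteome(2, 1, 3, seed=seed)
    for a in scan_proteome(records):
        assert a.set_label == truth.data["proteins"][a.protein_id]["set_label"]
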