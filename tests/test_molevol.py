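"""NG86 Ka/Ks: exhaustive-enumeration oracles, JC correction, symmetry."""

import math

import pytest
from Bio.Seq import Seq
from hypothesis import given
from hypothesis import strategies as st

from famsurvey.molevol import (
    SENSE_CODONS,
    CodonPair,
    classify_selection,
    codon_path_differences,
    codon_site_counts,
    jukes_cantor,
    ng86,
    ratio_from_printed,
    round_half_up,
)
from famsurvey.synthetic import gen_codon_pair


def oracle_site_counts(codon):
    """Independent enumeration of the 9 single-base mutants via Bio.Seq."""
    aa = str(Seq(codon).translate())
    syn = 0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if str(Seq(mut).translate()) == aa:  # '*' for stops never equals aa
                syn += 1
    return syn / 3.0, 3.0 - syn / 3.0


class TestSiteCounts:
    def test_phenylalanine(self):
        assert codon_site_counts("TTT") == pytest.approx((1 / 3, 8 / 3))

    def test_tryptophan_no_synonymous_mutant(self):
        assert codon_site_counts("TGG") == (0.0, 3.0)

    def test_all_sense_codons_match_enumeration_oracle(self):
        for codon in SENSE_CODONS:
            s, n = codon_site_counts(codon)
            so, no = oracle_site_counts(codon)
            assert s == pytest.approx(so) and n == pytest.approx(no)
            assert s + n == pytest.approx(3.0)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            codon_site_counts("TAA")


class TestPathDifferences:
    def test_identity(self):
        assert codon_path_differences("TTT", "TTT") == (0.0, 0.0)

    def test_single_nonsynonymous_step(self):
        assert codon_path_differences("TTT", "TTA") == (0.0, 1.0)  # Phe -> Leu

    def test_single_synonymous_step(self):
        assert codon_path_differences("TTT", "TTC") == (1.0, 0.0)  # both Phe

    def test_two_step_pathway_average(self):
        # TTT->GTA: paths TTT->GTT->GTA (nonsyn, syn since GTT/GTA both Val)
        # and TTT->TTA->GTA (nonsyn Phe->Leu, nonsyn Leu->Val): average (0.5, 1.5)
        assert codon_path_differences("TTT", "GTA") == pytest.approx((0.5, 1.5))

    def test_stop_pathways_excluded_and_renormalized(self):
        # TGT->TGG? one diff.  Use TCA->TGT: paths via TGA (stop) excluded
        sd, nd = codon_path_differences("TCA", "TGT")
        # only TCA->TCT->TGT survives: Ser->Ser (syn), Ser->Cys (nonsyn)
        assert (sd, nd) == (1.0, 1.0)

    def test_difference_counts_bounded_by_differing_positions(self):
        sd, nd = codon_path_differences("AAA", "CCC")
        assert sd + nd == pytest.approx(3.0)


class TestNg86:
    def test_identical_sequences(self):
        r = ng86(CodonPair("a", "b", "ATGAAA", "ATGAAA"))
        assert r.ka == 0 and r.ks == 0 and r.ratio is None
        assert r.selection == "undefined"

    def test_site_partition_identity(self):
        pair = CodonPair("a", "b", "ATGAAACCCGGG", "ATGAAACCTGGG")
        r = ng86(pair)
        assert r.n_sites + r.s_sites == pytest.approx(12.0, abs=1e-9)

    def test_jc_closed_form(self):
        assert jukes_cantor(0.1) == pytest.approx(0.1073, abs=0.0001)
        assert jukes_cantor(0.0) == 0.0
        with pytest.raises(ValueError, match="saturated"):
            jukes_cantor(0.75)

    def test_symmetry(self):
        pair, _ = gen_codon_pair(200, 0.5, target_ks=0.3, seed=12)
        r1 = ng86(pair)
        r2 = ng86(CodonPair("y", "x", pair.cds_b, pair.cds_a))
        assert r1.ka == pytest.approx(r2.ka) and r1.ks == pytest.approx(r2.ks)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            CodonPair("a", "b", "ATGTAAAAA", "ATGAAAAAA")

    def test_unequal_length_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            CodonPair("a", "b", "ATGAAA", "ATG")

    def test_cross_checked_against_biopython_ng86(self):
        """Biopython's cal_dn_ds (NG86) as independent oracle on one pair."""
        codonalign = pytest.importorskip("Bio.codonalign")
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        pair, _ = gen_codon_pair(300, 0.4, target_ks=0.2, seed=9)
        dn, ds = cal_dn_ds(CodonSeq(pair.cds_a), CodonSeq(pair.cds_b), method="NG86")
        r = ng86(pair)
        assert r.ka == pytest.approx(dn, abs=0.005)
        assert r.ks == pytest.approx(ds, abs=0.005)


class TestSelectionAndRounding:
    @pytest.mark.parametrize(
        "ratio,call",
        [(0.7320, "purifying"), (1.0, "neutral"), (1.5, "positive"), (None, "undefined")],
    )
    def test_classify(self, ratio, call):
        assert classify_selection(ratio) == call

    def test_negative_ratio_error(self):
        with pytest.raises(ValueError):
            classify_selection(-0.1)

    def test_half_up_rounding(self):
        assert round_half_up(0.73195, 4) == 0.7320
        assert round_half_up(0.00005, 4) == 0.0001

    def test_printed_ratio_path(self):
        assert ratio_from_printed(0.2930, 0.4003) == 0.7320
        assert ratio_from_printed(0.0026, 0.0) is None
        assert ratio_from_printed(0.0026, 0.0, compat_zero=True) == 0.0


@given(st.integers(0, 2**31 - 1))
def test_omega_zero_limit(seed):
    """With omega = 0 every accepted change is synonymous, so Ka stays at
    (essentially) zero.  Pathway averaging can attribute a tiny
    nonsynonymous fraction when one codon takes synonymous hits at two
    positions, so the bound is near-zero rather than exact."""
    pair, _ = gen_codon_pair(200, 0.0, target_ks=0.2, seed=seed)
    r = ng86(pair)
    assert r.ka < 0.01
    assert r.ks > 0.1


def test_sequence_site_sum_exact():
    """Sum over codons of (s + n) equals the sequence length, exactly."""
    pair, _ = gen_codon_pair(500, 0.5, target_ks=0.3, seed=4)
    total = sum(sum(codon_site_counts(pair.cds_a[i : i + 3]))
                for i in range(0, len(pair.cds_a), 3))
    assert total == pytest.approx(len(pair.cds_a), abs=1e-9)
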