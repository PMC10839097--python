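"""Promoter extraction coordinates and IUPAC cis-element scanning."""

import pytest

from famsurvey.core import Alphabet, GeneModel, SequenceRecord, reverse_complement
from famsurvey.regulatory import (
    CisElementDef,
    Promoter,
    categorize,
    extract_promoter,
    iupac_regex,
    scan_elements,
)
from famsurvey.synthetic import gen_promoters


def genome_of(seq, chrom="chr1"):
    return {chrom: SequenceRecord(chrom, seq, Alphabet.dna)}


def gene(strand, cds_start, start=1, end=9000):
    return GeneModel("g1", "chr1", start, end, strand, exons=[(start, end)],
                     cds_start=cds_start)


class TestExtractPromoter:
    def test_plus_strand_window(self):
        import random

        random.seed(1)
        seq = "".join(random.choices("ACGT", k=9000))
        prom = extract_promoter(gene("+", 5000), genome_of(seq))
        assert (prom.genomic_start, prom.genomic_end) == (3000, 4999)
        assert prom.seq == seq[2999:4999]
        assert not prom.clipped

    def test_minus_strand_reverse_complement(self):
        import random

        random.seed(2)
        seq = "".join(random.choices("ACGT", k=9000))
        prom = extract_promoter(gene("-", 5000), genome_of(seq))
        assert (prom.genomic_start, prom.genomic_end) == (5001, 7000)
        assert prom.seq == reverse_complement(seq[5000:7000])

    def test_edge_clipping_flagged(self):
        prom = extract_promoter(gene("+", 100), genome_of("A" * 9000))
        assert len(prom.seq) == 99 and prom.clipped

    def test_missing_cds_start_error(self):
        g = GeneModel("g1", "chr1", 1, 100, "+", exons=[(1, 100)])
        with pytest.raises(ValueError, match="CDS"):
            extract_promoter(g, genome_of("A" * 9000))

    def test_roundtrip_interval_identity(self):
        prom = extract_promoter(gene("+", 5000), genome_of("A" * 9000))
        assert prom.genomic_end - prom.genomic_start + 1 == len(prom.seq) == 2000


ELS = [
    CisElementDef("Gbox", "CACGTG", "transcription", "light"),
    CisElementDef("TGACG", "TGACG", "hormone", "MeJA-responsive"),
    CisElementDef("ABRE-like", "ACGTGKC", "hormone", "ABA-responsive"),
]


class TestScanElements:
    def test_palindrome_deduplicated(self):
        prom = Promoter("g", "AAACACGTGAAA", False, 1, 12)
        hits = scan_elements(prom, [ELS[0]])
        assert len(hits) == 1
        assert (hits[0].offset, hits[0].strand) == (4, "+")

    def test_no_match(self):
        prom = Promoter("g", "AAAAA", False, 1, 5)
        assert scan_elements(prom, [ELS[1]]) == []

    def test_reverse_strand_hit_mapped_to_forward_coords(self):
        # revcomp of TGACG is CGTCA; plant it so the '-' strand matches
        prom = Promoter("g", "AACGTCAAAA", False, 1, 10)
        hits = scan_elements(prom, [ELS[1]])
        assert len(hits) == 1
        assert hits[0].strand == "-" and hits[0].offset == 3

    def test_iupac_degeneracy(self):
        rx = iupac_regex("ACGTGKC")
        assert rx.fullmatch("ACGTGGC") and rx.fullmatch("ACGTGTC")
        assert not rx.fullmatch("ACGTGAC")

    def test_n_in_sequence_never_matches(self):
        prom = Promoter("g", "AAACACGNGAAA", False, 1, 12)
        assert scan_elements(prom, [ELS[0]]) == []

    def test_invalid_pattern_rejected_at_load(self):
        with pytest.raises(ValueError, match="IUPAC"):
            CisElementDef("bad", "ACGTZ", "stress")

    def test_strand_symmetry(self, element_table):
        """Scanning a promoter's reverse complement yields mirrored intervals."""
        records, _ = gen_promoters(
            1, category_mix={"hormone": 5, "stress": 3}, seed=21
        )
        seq = records[0].seq
        n = len(seq)
        fwd = scan_elements(Promoter("g", seq, False, 1, n), element_table)
        rev = scan_elements(
            Promoter("g", reverse_complement(seq), False, 1, n), element_table
        )
        plen = {el.element_name: len(el.pattern) for el in element_table}

        def intervals(hits, flip):
            out = set()
            for h in hits:
                s, e = h.offset, h.offset + plen[h.element_name] - 1
                out.add((h.element_name, n - e + 1, n - s + 1) if flip else
                        (h.element_name, s, e))
            return out

        assert intervals(fwd, False) == intervals(rev, True)

    def test_planted_counts_recovered(self, element_table):
        records, truth = gen_promoters(
            4, category_mix={"transcription": 8, "stress": 6}, seed=13
        )
        for rec in records:
            hits = scan_elements(
                Promoter(rec.id, rec.seq, False, 1, len(rec.seq)), element_table
            )
            got: dict = {}
            for h in hits:
                got[h.element_name] = got.get(h.element_name, 0) + 1
            assert got == truth.data["per_gene_element_counts"][rec.id]


class TestCategorize:
    def test_percentage_arithmetic(self):
        hits = (
            [_hit("Gbox")] * 5 + [_hit("TGACG")] * 3 + [_hit("ABRE-like")] * 2
        )
        report = categorize(hits, ELS)
        assert report["category_percentages"] == {"transcription": 50.0, "hormone": 50.0}
        assert report["category_counts"] == {"transcription": 5, "hormone": 5}

    def test_zero_hits_no_division(self):
        report = categorize([], ELS)
        assert report["total_hits"] == 0 and report["category_percentages"] == {}

    def test_count_consistency_invariant(self, element_table):
        records, _ = gen_promoters(3, category_mix={"hormone": 9}, seed=17)
        hits = []
        for rec in records:
            hits += scan_elements(
                Promoter(rec.id, rec.seq, False, 1, len(rec.seq)), element_table
            )
        report = categorize(hits, element_table)
        assert sum(report["subcategory_counts"].values()) == report["total_hits"]
        assert sum(report["category_counts"].values()) == report["total_hits"]

    def test_unknown_element_error(self):
        with pytest.raises(ValueError, match="not in table"):
            categorize([_hit("mystery")], ELS)


def _hit(name, gene_id="g", offset=1, strand="+"):
    from famsurvey.regulatory import CisElementHit

    return CisElementHit(gene_id, name, offset, strand)
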