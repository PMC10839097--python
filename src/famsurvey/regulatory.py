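"""Promoter extraction and IUPAC cis-regulatory element scanning.

Promoters are the 2000 bp immediately upstream of the CDS start, taken
strand-aware from the genome and clipped at chromosome ends. Elements
are short IUPAC motifs (PlantCARE-style) grouped into five functional
categories: transcription, hormone, stress, development and cell cycle.
A bundled table of common plant elements ships with the package; users
may supply their own.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .core import GeneModel, SequenceRecord, reverse_complement

DEFAULT_PROMOTER_LENGTH = 2000

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class CisElementDef:
    element_name: str
    pattern: str
    category: str
    subcategory: str = ""

    def __post_init__(self):
        if not self.pattern:
            raise ValueError(f"{self.element_name}: empty pattern")
        for ch in self.pattern:
            if ch not in IUPAC:
                raise ValueError(
                    f"{self.element_name}: invalid IUPAC code {ch!r} in pattern"
                )


@dataclass(frozen=True)
class CisElementHit:
    gene_id: str
    element_name: str
    offset: int  # 1-based position within the promoter (forward coordinates)
    strand: str


@dataclass(frozen=True)
class Promoter:
    gene_id: str
    seq: str
    clipped: bool
    genomic_start: int  # 1-based inclusive genomic interval of the promoter
    genomic_end: int


def load_element_table(path: str | Path | None = None) -> list[CisElementDef]:
    """Load an element table TSV (name, pattern, category, subcategory).

    With no path, the bundled PlantCARE-style table is used.
    """
    if path is None:
        with resources.files("famsurvey.data").joinpath("cis_elements.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return [
        CisElementDef(
            element_name=row["element_name"],
            pattern=str(row["pattern"]).upper(),
            category=row["category"],
            subcategory=row.get("subcategory", "") or "",
        )
        for _, row in df.iterrows()
    ]


def iupac_regex(pattern: str) -> re.Pattern:
    """Regex for an IUPAC motif. N in the *sequence* never matches."""
    parts = []
    for ch in pattern.upper():
        bases = IUPAC[ch]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("".join(parts))


def extract_promoter(
    gene: GeneModel,
    genome: dict[str, SequenceRecord],
    length: int = DEFAULT_PROMOTER_LENGTH,
) -> Promoter:
    """Strand-aware upstream sequence anchored at the CDS start.

    '+' strand: genomic [cds_start - length, cds_start - 1];
    '-' strand: genomic [cds_start + 1, cds_start + length],
    reverse-complemented. Clipped (and flagged) at chromosome ends.
    """
    if gene.cds_start is None:
        raise ValueError(f"{gene.gene_id}: no CDS start; cannot anchor the promoter")
    if gene.chrom not in genome:
        raise ValueError(f"{gene.gene_id}: chromosome {gene.chrom} not in genome")
    chrom_seq = genome[gene.chrom].seq
    chrom_len = len(chrom_seq)
    if gene.strand == "+":
        lo = gene.cds_start - length
        hi = gene.cds_start - 1
    else:
        lo = gene.cds_start + 1
        hi = gene.cds_start + length
    clipped_lo, clipped_hi = max(lo, 1), min(hi, chrom_len)
    if clipped_hi < clipped_lo:
        raise ValueError(f"{gene.gene_id}: promoter has zero length after clipping")
    seq = chrom_seq[clipped_lo - 1 : clipped_hi]
    if gene.strand == "-":
        seq = reverse_complement(seq)
    return Promoter(
        gene_id=gene.gene_id,
        seq=seq,
        clipped=(clipped_lo, clipped_hi) != (lo, hi),
        genomic_start=clipped_lo,
        genomic_end=clipped_hi,
    )


def scan_elements(
    promoter: Promoter | SequenceRecord,
    element_table: list[CisElementDef],
    both_strands: bool = True,
) -> list[CisElementHit]:
    """All IUPAC matches of every element, on one or both strands.

    Overlapping matches of the same element are all reported. Offsets are
    1-based forward-strand positions of the match start (leftmost base of
    the matched interval, regardless of strand). Palindromic patterns
    matching the identical interval on both strands are reported once, as
    a forward hit.
    """
    if isinstance(promoter, SequenceRecord):
        promoter = Promoter(promoter.id, promoter.seq, False, 1, len(promoter.seq))
    seq = promoter.seq
    n = len(seq)
    hits: list[CisElementHit] = []
    seen: set[tuple[str, int, int]] = set()
    for el in element_table:
        rx = iupac_regex(el.pattern)
        plen = len(el.pattern)
        pos = 0
        while True:
            m = rx.search(seq, pos)
            if m is None:
                break
            key = (el.element_name, m.start() + 1, m.start() + plen)
            seen.add(key)
            hits.append(CisElementHit(promoter.gene_id, el.element_name, m.start() + 1, "+"))
            pos = m.start() + 1
        if both_strands:
            rc = reverse_complement(seq)
            pos = 0
            while True:
                m = rx.search(rc, pos)
                if m is None:
                    break
                # map back to forward coordinates
                fwd_start = n - (m.start() + plen) + 1
                key = (el.element_name, fwd_start, fwd_start + plen - 1)
                if key not in seen:
                    seen.add(key)
                    hits.append(CisElementHit(promoter.gene_id, el.element_name, fwd_start, "-"))
                pos = m.start() + 1
    hits.sort(key=lambda h: (h.element_name, h.offset, h.strand))
    return hits


def categorize(
    hits: list[CisElementHit], element_table: list[CisElementDef]
) -> dict:
    """Per-gene and global counts by category and subcategory.

    Global percentages per category = category hits / total hits x 100,
    rounded to 1 decimal, half-up.
    """
    from .molevol import round_half_up

    by_name = {el.element_name: el for el in element_table}
    for h in hits:
        if h.element_name not in by_name:
            raise ValueError(f"hit element {h.element_name!r} not in table")
    cat_counts: dict[str, int] = {}
    sub_counts: dict[tuple[str, str], int] = {}
    per_gene: dict[str, dict[str, int]] = {}
    for h in hits:
        el = by_name[h.element_name]
        cat_counts[el.category] = cat_counts.get(el.category, 0) + 1
        key = (el.category, el.subcategory)
        sub_counts[key] = sub_counts.get(key, 0) + 1
        g = per_gene.setdefault(h.gene_id, {})
        g[el.category] = g.get(el.category, 0) + 1
    total = len(hits)
    percentages = {
        cat: round_half_up(100.0 * c / total, 1) for cat, c in cat_counts.items()
    } if total else {}
    return {
        "total_hits": total,
        "category_counts": cat_counts,
        "category_percentages": percentages,
        "subcategory_counts": {f"{c}/{s}": n for (c, s), n in sorted(sub_counts.items())},
        "per_gene_category_counts": per_gene,
    }


def hits_table(hits: list[CisElementHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"gene_id": h.gene_id, "element_name": h.element_name,
             "offset": h.offset, "strand": h.strand}
            for h in hits
        ],
        columns=["gene_id", "element_name", "offset", "strand"],
    )


def category_summary_table(report: dict) -> pd.DataFrame:
    rows = [
        {"category": cat, "n_hits": n,
         "percent": report["category_percentages"].get(cat, 0.0)}
        for cat, n in sorted(report["category_counts"].items())
    ]
    return pd.DataFrame(rows, columns=["category", "n_hits", "percent"])
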