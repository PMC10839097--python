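"""Shared domain types and readers/writers for sequences and annotations.

Coordinates are 1-based inclusive at every public interface (GFF3
convention). Internal arithmetic may use 0-based offsets but that
convention never appears in reports.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
DNA_ALPHABET = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class Alphabet(str, Enum):
    protein = "protein"
    dna = "dna"


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence with a declared alphabet."""

    id: str
    seq: str
    alphabet: Alphabet

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")
        allowed = PROTEIN_ALPHABET if self.alphabet == Alphabet.protein else DNA_ALPHABET
        for pos, ch in enumerate(self.seq, start=1):
            if ch not in allowed:
                raise ValueError(
                    f"illegal residue {ch!r} at position {pos} in record {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.seq)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneModel:
    """One gene with its primary-transcript exon chain.

    ``cds_start`` is the genomic coordinate of the first coding base in
    translation order: min CDS coordinate on '+', max on '-'. It is None
    when the annotation carries no CDS for the gene.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_start: int | None = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        self.exons = sorted(self.exons)
        prev_end = None
        for s, e in self.exons:
            if s > e or s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside gene span")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.gene_id}: overlapping exons")
            prev_end = e

    @property
    def n_introns(self) -> int:
        return max(len(self.exons) - 1, 0)


@dataclass
class AnnotationSet:
    genes: list[GeneModel]
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene id {g.gene_id!r}")
            seen.add(g.gene_id)
            if g.chrom in self.chrom_lengths and g.end > self.chrom_lengths[g.chrom]:
                raise ValueError(
                    f"{g.gene_id}: end {g.end} beyond {g.chrom} length "
                    f"{self.chrom_lengths[g.chrom]}"
                )

    def by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, alphabet: Alphabet | str) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords.

    Sequence lines are concatenated, whitespace stripped and case folded
    to upper. Duplicate IDs and illegal residues are errors.
    """
    alphabet = Alphabet(alphabet)
    records: list[SequenceRecord] = []
    ids: list[str] = []
    cur_id: str | None = None
    chunks: list[str] = []

    def flush():
        if cur_id is not None:
            records.append(SequenceRecord(cur_id, "".join(chunks).upper(), alphabet))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                cur_id = line[1:].split()[0]
                ids.append(cur_id)
                chunks = []
            else:
                if cur_id is None:
                    raise ValueError(f"{path}: sequence before first header")
                chunks.append(re.sub(r"\s+", "", line))
    flush()

    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValueError(f"{path}: duplicate sequence IDs: {', '.join(dupes)}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def _attr(attrs: str, key: str) -> str | None:
    for part in attrs.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            if k.strip() == key:
                return v.strip()
    return None


def read_gff3(path: str | Path) -> AnnotationSet:
    """Parse a GFF3 file into an AnnotationSet.

    One GeneModel per gene feature; exons and CDS come from the first
    listed mRNA of each gene. Genes with no CDS are kept with
    ``cds_start`` unset. ``##sequence-region`` pragmas populate
    chromosome lengths.
    """
    chrom_lengths: dict[str, int] = {}
    genes: dict[str, dict] = {}
    mrna_parent: dict[str, str] = {}
    first_mrna: dict[str, str] = {}

    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    chrom_lengths[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                continue
            rows.append(cols)

    for cols in rows:
        chrom, _src, ftype, start, end, _score, strand, _phase, attrs = cols
        start, end = int(start), int(end)
        if ftype == "gene":
            gid = _attr(attrs, "ID") or f"gene_{len(genes)}"
            genes[gid] = {
                "chrom": chrom, "start": start, "end": end, "strand": strand,
                "exons": [], "cds": [],
            }
        elif ftype == "mRNA":
            mid = _attr(attrs, "ID")
            parent = _attr(attrs, "Parent")
            if mid and parent:
                mrna_parent[mid] = parent
                first_mrna.setdefault(parent, mid)

    for cols in rows:
        chrom, _src, ftype, start, end, _score, strand, _phase, attrs = cols
        if ftype not in ("exon", "CDS"):
            continue
        parent = _attr(attrs, "Parent")
        if parent is None:
            continue
        gid = mrna_parent.get(parent, parent)
        if gid not in genes:
            continue
        # keep only features of the chosen (first) mRNA; direct gene children pass
        if parent in mrna_parent and first_mrna.get(gid) != parent:
            continue
        key = "exons" if ftype == "exon" else "cds"
        genes[gid][key].append((int(cols[3]), int(cols[4])))

    models = []
    for gid, info in genes.items():
        cds = info["cds"]
        if cds:
            cds_start = (
                min(s for s, _ in cds) if info["strand"] == "+" else max(e for _, e in cds)
            )
        else:
            cds_start = None
        exons = sorted(info["exons"]) or ([(info["start"], info["end"])] if cds else [])
        for s, e in exons:
            if s < info["start"] or e > info["end"]:
                raise ValueError(f"{gid}: exon ({s},{e}) outside gene span")
        models.append(
            GeneModel(
                gene_id=gid, chrom=info["chrom"], start=info["start"],
                end=info["end"], strand=info["strand"], exons=exons,
                cds_start=cds_start,
            )
        )
    return AnnotationSet(genes=models, chrom_lengths=chrom_lengths)
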