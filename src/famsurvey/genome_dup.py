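"""Chromosomal distribution, tandem duplication and collinearity chaining.

Genes are ranked by start coordinate within each chromosome. A homologous
pair is called a *tandem* duplication when both genes sit on the same
chromosome within a small gene-rank distance (default 2, i.e. at most one
intervening gene). *Segmental* duplications are homologous pairs whose
members anchor the same collinear (syntenic) block: a gap-bounded monotone
chain of genome-wide homologous anchors between two chromosomal regions.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .core import AnnotationSet

DEFAULT_MAX_RANK_GAP = 2
DEFAULT_MAX_GAP = 25
DEFAULT_MIN_BLOCK_ANCHORS = 5


@dataclass
class GeneRankIndex:
    """Per-chromosome gene order: rank 1..n by start coordinate."""

    rank: dict[str, tuple[str, int]] = field(default_factory=dict)  # gene -> (chrom, rank)

    @classmethod
    def from_annotation(cls, annotation: AnnotationSet) -> "GeneRankIndex":
        idx = cls()
        by_chrom: dict[str, list] = defaultdict(list)
        for g in annotation.genes:
            by_chrom[g.chrom].append(g)
        for chrom, genes in by_chrom.items():
            for r, g in enumerate(sorted(genes, key=lambda g: (g.start, g.gene_id)), 1):
                idx.rank[g.gene_id] = (chrom, r)
        return idx


@dataclass(frozen=True)
class DuplicationPair:
    gene_a: str
    gene_b: str
    mode: str  # tandem | segment | unclassified
    evidence: str | int | None = None


@dataclass
class CollinearBlock:
    block_id: int
    chrom_a: str
    chrom_b: str
    anchors: list[tuple[str, str, int, int]]  # (gene_a, gene_b, rank_a, rank_b)
    orientation: str  # same | inverted

    @property
    def genes(self) -> set[str]:
        out = set()
        for ga, gb, _, _ in self.anchors:
            out.add(ga)
            out.add(gb)
        return out


def chromosome_distribution(
    annotation: AnnotationSet, family_ids: list[str]
) -> tuple[dict[str, int], int]:
    """Counts of family genes per chromosome, plus the unplaced count."""
    by_id = annotation.by_id()
    counts: Counter = Counter()
    unplaced = 0
    for gid in family_ids:
        g = by_id.get(gid)
        if g is None:
            unplaced += 1
        else:
            counts[g.chrom] += 1
    return dict(counts), unplaced


def find_tandem(
    homolog_pairs: list[tuple[str, str]],
    rank_index: GeneRankIndex,
    max_rank_gap: int = DEFAULT_MAX_RANK_GAP,
) -> list[DuplicationPair]:
    """Tandem = same chromosome and gene-rank distance <= max_rank_gap."""
    out = []
    for a, b in homolog_pairs:
        if a not in rank_index.rank or b not in rank_index.rank:
            continue  # unplaced gene: skipped
        chrom_a, ra = rank_index.rank[a]
        chrom_b, rb = rank_index.rank[b]
        if chrom_a == chrom_b and a != b and abs(ra - rb) <= max_rank_gap:
            out.append(DuplicationPair(a, b, "tandem", evidence=abs(ra - rb)))
    return out


def _chain_anchors(
    anchors: list[tuple[str, str, int, int]],
    max_gap: int,
    min_block_anchors: int,
    direction: int,
) -> list[list[tuple[str, str, int, int]]]:
    """Gap-bounded monotone chains by longest-path DP, extracted greedily.

    direction +1 chains rank_b increasing (same orientation), -1
    decreasing (inverted). Each anchor joins at most one chain.
    """
    anchors = sorted(anchors, key=lambda t: (t[2], t[3]))
    used = [False] * len(anchors)
    chains = []
    while True:
        n = len(anchors)
        best_len = [1] * n
        pred = [-1] * n
        for j in range(n):
            if used[j]:
                continue
            for i in range(j):
                if used[i]:
                    continue
                da = anchors[j][2] - anchors[i][2]
                db = direction * (anchors[j][3] - anchors[i][3])
                if 0 < da <= max_gap and 0 < db <= max_gap:
                    if best_len[i] + 1 > best_len[j]:
                        best_len[j] = best_len[i] + 1
                        pred[j] = i
        cand = [j for j in range(n) if not used[j]]
        if not cand:
            break
        # longest chain; ties broken by leftmost start
        end = max(cand, key=lambda j: (best_len[j], -anchors[j][2]))
        if best_len[end] < min_block_anchors:
            break
        chain = []
        k = end
        while k != -1:
            chain.append(anchors[k])
            used[k] = True
            k = pred[k]
        chains.append(list(reversed(chain)))
    return chains


def chain_collinear(
    homolog_pairs: list[tuple[str, str]],
    rank_index: GeneRankIndex,
    max_gap: int = DEFAULT_MAX_GAP,
    min_block_anchors: int = DEFAULT_MIN_BLOCK_ANCHORS,
) -> list[CollinearBlock]:
    """Chain genome-wide homologous anchors into collinear blocks.

    Anchors are grouped per ordered chromosome pair; within each group,
    maximal monotone chains with consecutive rank gaps <= max_gap on both
    axes and >= min_block_anchors members become blocks. Both same and
    inverted orientations are searched; longer chains claim anchors first.
    """
    per_pair: dict[tuple[str, str], list] = defaultdict(list)
    for a, b in homolog_pairs:
        if a == b or a not in rank_index.rank or b not in rank_index.rank:
            continue
        ca, ra = rank_index.rank[a]
        cb, rb = rank_index.rank[b]
        # canonical orientation of the chromosome pair
        if (cb, b) < (ca, a):
            a, b, ca, ra, cb, rb = b, a, cb, rb, ca, ra
        per_pair[(ca, cb)].append((a, b, ra, rb))

    blocks: list[CollinearBlock] = []
    bid = 0
    for (ca, cb), anchors in sorted(per_pair.items()):
        anchors = sorted(set(anchors))
        cands = []
        for direction, orient in ((1, "same"), (-1, "inverted")):
            for chain in _chain_anchors(anchors, max_gap, min_block_anchors, direction):
                cands.append((orient, chain))
        # longer chains claim anchors first
        cands.sort(key=lambda t: (-len(t[1]), t[1][0][2]))
        claimed: set = set()
        for orient, chain in cands:
            if any(a in claimed for a in chain):
                continue
            claimed.update(chain)
            bid += 1
            blocks.append(CollinearBlock(bid, ca, cb, chain, orient))
    return blocks


def classify_duplications(
    family_pairs: list[tuple[str, str]],
    tandem_calls: list[DuplicationPair],
    blocks: list[CollinearBlock],
) -> list[DuplicationPair]:
    """Label each family homolog pair tandem, segment or unclassified.

    Tandem takes precedence over block co-membership; a pair is segmental
    when both genes anchor the same collinear block.
    """
    tandem_set = {frozenset((p.gene_a, p.gene_b)) for p in tandem_calls}
    out = []
    for a, b in family_pairs:
        key = frozenset((a, b))
        if key in tandem_set:
            out.append(DuplicationPair(a, b, "tandem"))
            continue
        block_id = None
        for blk in blocks:
            genes = blk.genes
            if a in genes and b in genes:
                block_id = blk.block_id
                break
        if block_id is not None:
            out.append(DuplicationPair(a, b, "segment", evidence=block_id))
        else:
            out.append(DuplicationPair(a, b, "unclassified"))
    return out


def duplication_table(pairs: list[DuplicationPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"gene_a": p.gene_a, "gene_b": p.gene_b, "mode": p.mode,
             "evidence": "" if p.evidence is None else p.evidence}
            for p in pairs
        ],
        columns=["gene_a", "gene_b", "mode", "evidence"],
    )


def block_table(blocks: list[CollinearBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"block_id": b.block_id, "chrom_a": b.chrom_a, "chrom_b": b.chrom_b,
             "n_anchors": len(b.anchors), "orientation": b.orientation}
            for b in blocks
        ],
        columns=["block_id", "chrom_a", "chrom_b", "n_anchors", "orientation"],
    )
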