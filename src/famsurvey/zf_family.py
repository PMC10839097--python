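"""C2H2 zinc-finger detection, array grouping and A/B/C set classification.

A C2H2 finger is two cysteines and two histidines coordinating a zinc
ion, with canonical spacing C-x(2,4)-C-x(12)-H-x(3,5)-H. Fingers joined
by short linkers (at most ``max_linker`` residues, default 10) form a
tandem array; proteins with exactly one array are set A, with two or
more arrays set B, and with only single or dispersed fingers set C.
Dispersed fingers alongside an array do not change A/B membership.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .core import Alphabet, SequenceRecord

#: canonical C2H2 spacing
DEFAULT_PATTERN = "C-x(2,4)-C-x(12)-H-x(3,5)-H"
#: relaxed spacing covering degenerate fingers
RELAXED_PATTERN = "C-x(1,5)-C-x(9,14)-H-x(2,6)-H"

DEFAULT_MAX_LINKER = 10

_AA = "A-Z"


def compile_pattern(spec: str = DEFAULT_PATTERN) -> re.Pattern:
    """Compile a PROSITE-like pattern string to a lazy regex.

    Supported elements: single residue letters and x(n) / x(n,m) gaps,
    joined by '-'. Lazy quantifiers give the leftmost-shortest greedy
    semantics used for overlap resolution.
    """
    parts = spec.split("-")
    out = []
    for part in parts:
        part = part.strip()
        m = re.fullmatch(r"x\((\d+)(?:,(\d+))?\)", part)
        if m:
            lo, hi = m.group(1), m.group(2)
            if hi is None:
                out.append(f"[{_AA}]{{{lo}}}")
            else:
                out.append(f"[{_AA}]{{{lo},{hi}}}?")
        elif re.fullmatch(r"[A-Z]", part):
            out.append(part)
        elif part == "x":
            out.append(f"[{_AA}]")
        else:
            raise ValueError(f"cannot parse pattern element {part!r} in {spec!r}")
    return re.compile("".join(out))


@dataclass(frozen=True)
class ZincFingerHit:
    protein_id: str
    start: int  # 1-based inclusive
    end: int
    matched_subsequence: str
    pattern_id: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("finger start must precede end")


@dataclass
class FingerArray:
    finger_indices: list[int]
    linkers: list[int]


@dataclass
class FamilyAssignment:
    protein_id: str
    n_fingers: int
    arrays: list[FingerArray]
    dispersed: list[int] = field(default_factory=list)
    set_label: str | None = None
    hits: list[ZincFingerHit] = field(default_factory=list)


def scan_fingers(
    protein: SequenceRecord,
    pattern: str | re.Pattern = DEFAULT_PATTERN,
    pattern_id: str | None = None,
) -> list[ZincFingerHit]:
    """Find all non-overlapping C2H2 finger matches, left to right.

    At each candidate cysteine anchor the shortest legal match is taken
    (first gap minimised, then the last), and scanning resumes after its
    final histidine, so shared histidines are never double counted.
    """
    if protein.alphabet != Alphabet.protein:
        raise ValueError("scan_fingers requires a protein record")
    if isinstance(pattern, str):
        pattern_id = pattern_id or pattern
        pattern = compile_pattern(pattern)
    else:
        pattern_id = pattern_id or pattern.pattern
    seq = protein.seq
    hits: list[ZincFingerHit] = []
    pos = 0
    while True:
        m = pattern.search(seq, pos)
        if m is None:
            break
        hits.append(
            ZincFingerHit(
                protein_id=protein.id,
                start=m.start() + 1,
                end=m.end(),
                matched_subsequence=m.group(0),
                pattern_id=pattern_id,
            )
        )
        pos = m.end()
    return hits


def linker_lengths(hits: list[ZincFingerHit]) -> list[int]:
    """Residues strictly between consecutive fingers of one protein."""
    linkers = []
    for prev, nxt in zip(hits, hits[1:]):
        if nxt.start <= prev.end:
            raise ValueError(
                f"{prev.protein_id}: overlapping fingers at {prev.start}-{prev.end} "
                f"and {nxt.start}-{nxt.end}"
            )
        linkers.append(nxt.start - prev.end - 1)
    return linkers


def group_arrays(
    hits: list[ZincFingerHit], max_linker: int = DEFAULT_MAX_LINKER
) -> tuple[list[FingerArray], list[int]]:
    """Partition fingers into tandem arrays (runs of linkers <= max_linker).

    Returns (arrays, dispersed finger indices). Runs of length 1 are
    dispersed, not arrays.
    """
    if not hits:
        return [], []
    linkers = linker_lengths(hits)
    arrays: list[FingerArray] = []
    dispersed: list[int] = []
    run = [0]
    run_linkers: list[int] = []
    for i, lk in enumerate(linkers):
        if lk <= max_linker:
            run.append(i + 1)
            run_linkers.append(lk)
        else:
            if len(run) >= 2:
                arrays.append(FingerArray(run, run_linkers))
            else:
                dispersed.extend(run)
            run = [i + 1]
            run_linkers = []
    if len(run) >= 2:
        arrays.append(FingerArray(run, run_linkers))
    else:
        dispersed.extend(run)
    return arrays, dispersed


def classify_set(arrays: list[FingerArray], dispersed: list[int]) -> str | None:
    """A = one tandem array, B = several arrays, C = dispersed/single only.

    Dispersed fingers never demote an A or B protein. Returns None for
    zero fingers (the protein is outside the family).
    """
    if len(arrays) == 1:
        return "A"
    if len(arrays) >= 2:
        return "B"
    if dispersed:
        return "C"
    return None


def assign_family(
    protein: SequenceRecord,
    pattern: str | re.Pattern = DEFAULT_PATTERN,
    max_linker: int = DEFAULT_MAX_LINKER,
) -> FamilyAssignment | None:
    """Scan one protein and classify it; None when no finger is found."""
    hits = scan_fingers(protein, pattern)
    if not hits:
        return None
    arrays, dispersed = group_arrays(hits, max_linker)
    return FamilyAssignment(
        protein_id=protein.id,
        n_fingers=len(hits),
        arrays=arrays,
        dispersed=dispersed,
        set_label=classify_set(arrays, dispersed),
        hits=hits,
    )


def scan_proteome(
    proteins: list[SequenceRecord],
    pattern: str | re.Pattern = DEFAULT_PATTERN,
    max_linker: int = DEFAULT_MAX_LINKER,
) -> list[FamilyAssignment]:
    out = []
    for prot in proteins:
        asg = assign_family(prot, pattern, max_linker)
        if asg is not None:
            out.append(asg)
    return out


def summarize_family(assignments: list[FamilyAssignment]) -> dict:
    """Per-set counts plus finger-count and linker-length histograms.

    The linker histogram pools all inter-finger linkers, exposing the
    consensus linker mode (five residues in canonical C2H2 arrays).
    """
    set_counts = Counter(a.set_label for a in assignments)
    finger_hist = Counter(a.n_fingers for a in assignments)
    linker_hist: Counter = Counter()
    for a in assignments:
        linker_hist.update(linker_lengths(a.hits))
    return {
        "n_proteins": len(assignments),
        "set_counts": {s: set_counts.get(s, 0) for s in "ABC"},
        "finger_count_histogram": dict(sorted(finger_hist.items())),
        "linker_length_histogram": dict(sorted(linker_hist.items())),
        "linker_mode": (max(linker_hist, key=lambda k: (linker_hist[k], -k))
                        if linker_hist else None),
    }


def family_table(assignments: list[FamilyAssignment]) -> pd.DataFrame:
    rows = []
    for a in assignments:
        rows.append(
            {
                "protein_id": a.protein_id,
                "n_fingers": a.n_fingers,
                "n_arrays": len(a.arrays),
                "n_dispersed": len(a.dispersed),
                "set_label": a.set_label,
                "finger_coords": ";".join(f"{h.start}-{h.end}" for h in a.hits),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["protein_id", "n_fingers", "n_arrays", "n_dispersed",
                 "set_label", "finger_coords"],
    )
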