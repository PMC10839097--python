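"""Gene-structure statistics, SSR detection and primer QC.

Intron counts come straight from the exon chains of the annotation and
are binned the way family surveys summarise them ({0, 1-2, 3-10, >10}).
SSRs are maximal perfect tandem repeats of a primitive 1-6 bp unit with
MISA-style minimum repeat numbers. Primer QC reports length, GC% and a
nearest-neighbor melting temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.SeqUtils import MeltingTemp

from .core import AnnotationSet
from .molevol import round_half_up

#: MISA-style minimum repeat numbers per unit length
DEFAULT_SSR_THRESHOLDS = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}

INTRON_BINS = ("0", "1-2", "3-10", ">10")


@dataclass(frozen=True)
class SsrHit:
    seq_id: str
    unit: str
    n_repeats: int
    start: int  # 1-based
    length_bp: int


@dataclass(frozen=True)
class PrimerQc:
    name: str
    sequence: str
    length_nt: int
    gc_percent: float
    tm_celsius: float


def intron_stats(
    annotation: AnnotationSet, family_ids: list[str] | None = None
) -> tuple[dict[str, int], dict[str, dict]]:
    """Per-gene intron counts and the binned distribution.

    Returns (counts, distribution) where distribution maps each bin to
    {"n": count, "percent": share to 1 decimal}.
    """
    by_id = annotation.by_id()
    ids = family_ids if family_ids is not None else sorted(by_id)
    counts = {}
    for gid in ids:
        g = by_id.get(gid)
        if g is None or not g.exons:
            continue
        counts[gid] = g.n_introns
    bins = {b: 0 for b in INTRON_BINS}
    for n in counts.values():
        if n == 0:
            bins["0"] += 1
        elif n <= 2:
            bins["1-2"] += 1
        elif n <= 10:
            bins["3-10"] += 1
        else:
            bins[">10"] += 1
    total = len(counts)
    dist = {
        b: {"n": c, "percent": round_half_up(100.0 * c / total, 1) if total else 0.0}
        for b, c in bins.items()
    }
    return counts, dist


def _is_primitive(unit: str) -> bool:
    """True unless the unit is itself a repetition of a shorter unit."""
    n = len(unit)
    for k in range(1, n):
        if n % k == 0 and unit[:k] * (n // k) == unit:
            return False
    return True


def canonical_unit(unit: str) -> str:
    """Lexicographically smallest rotation of a primitive unit."""
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def find_ssrs(
    seq_id: str,
    seq: str,
    thresholds: dict[int, int] | None = None,
) -> list[SsrHit]:
    """Maximal perfect SSRs meeting per-unit-length repeat thresholds.

    Units are reported canonically (smallest rotation of the primitive
    unit). Runs nested inside or overlapping a longer run of the same
    locus are merged to the maximal run.
    """
    thresholds = thresholds or DEFAULT_SSR_THRESHOLDS
    seq = seq.upper()
    n = len(seq)
    raw: list[SsrHit] = []
    for k, min_rep in thresholds.items():
        i = 0
        while i + k <= n:
            unit = seq[i : i + k]
            if not _is_primitive(unit) or "N" in unit:
                i += 1
                continue
            j = i + k
            while j + k <= n and seq[j : j + k] == unit:
                j += k
            reps = (j - i) // k
            if reps >= min_rep:
                raw.append(
                    SsrHit(seq_id, canonical_unit(unit), reps, i + 1, reps * k)
                )
                i = j  # jump past the run
            else:
                i += 1
    # merge: drop hits whose interval overlaps a longer (or equal, shorter-unit) hit
    raw.sort(key=lambda h: (-h.length_bp, len(h.unit), h.start))
    kept: list[SsrHit] = []
    for h in raw:
        span = (h.start, h.start + h.length_bp - 1)
        if any(
            not (span[1] < k.start or span[0] > k.start + k.length_bp - 1)
            for k in kept
        ):
            continue
        kept.append(h)
    kept.sort(key=lambda h: h.start)
    return kept


def gc_percent(sequence: str) -> float:
    seq = sequence.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"ambiguity codes not allowed in primers: {sorted(bad)}")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def primer_qc(name: str, sequence: str) -> PrimerQc:
    """Length, GC% and SantaLucia-1998 nearest-neighbor Tm for one primer.

    Tm assumes 50 mM monovalent salt and 500 nM total oligo and is
    informational only.
    """
    seq = sequence.upper()
    gc = gc_percent(seq)
    tm = MeltingTemp.Tm_NN(
        seq, nn_table=MeltingTemp.DNA_NN3, Na=50, dnac1=250, dnac2=250
    )
    return PrimerQc(
        name=name,
        sequence=seq,
        length_nt=len(seq),
        gc_percent=gc,
        tm_celsius=round(float(tm), 2),
    )


def format_gc(gc: float) -> str:
    """Integral GC% prints without decimals (as primer tables do)."""
    if abs(gc - round(gc)) < 1e-9:
        return str(int(round(gc)))
    return f"{round_half_up(gc, 1):.1f}"


def primer_table(primers: list[tuple[str, str]]) -> pd.DataFrame:
    rows = []
    for name, seq in primers:
        qc = primer_qc(name, seq)
        rows.append(
            {
                "name": qc.name,
                "sequence": qc.sequence,
                "tm_celsius": qc.tm_celsius,
                "gc_percent": format_gc(qc.gc_percent),
                "length_nt": qc.length_nt,
            }
        )
    return pd.DataFrame(
        rows, columns=["name", "sequence", "tm_celsius", "gc_percent", "length_nt"]
    )


def ssr_table(hits: list[SsrHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"seq_id": h.seq_id, "unit": h.unit, "unit_length": len(h.unit),
             "n_repeats": h.n_repeats, "start": h.start, "length_bp": h.length_bp}
            for h in hits
        ],
        columns=["seq_id", "unit", "unit_length", "n_repeats", "start", "length_bp"],
    )


def intron_table(counts: dict[str, int]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gene_id": g, "n_introns": n} for g, n in sorted(counts.items())],
        columns=["gene_id", "n_introns"],
    )
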