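"""Physicochemical profiling of predicted proteins.

Computes the standard descriptors used in gene-family surveys: average
molecular weight, theoretical isoelectric point (Henderson-Hasselbalch
bisection), Guruprasad instability index, aliphatic index and the
Kyte-Doolittle grand average of hydropathy (GRAVY), together with the
derived stable/unstable (II <= 40) and hydrophilic (GRAVY < 0) calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.SeqUtils import molecular_weight as _bio_mw
from Bio.SeqUtils.ProtParamData import DIWV, kd

from .core import Alphabet, SequenceRecord

STABILITY_THRESHOLD = 40.0

# pKa sets for the charged groups used in the net-charge function.
# 'emboss' is the default; 'bjellqvist' mirrors the ExPASy server values.
PKA_TABLES: dict[str, dict[str, float]] = {
    "emboss": {
        "Nterm": 8.6, "Cterm": 3.6,
        "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5,
        "K": 10.8, "R": 12.5, "Y": 10.1,
    },
    "bjellqvist": {
        "Nterm": 7.5, "Cterm": 3.55,
        "C": 9.0, "D": 4.05, "E": 4.45, "H": 5.98,
        "K": 10.0, "R": 12.0, "Y": 10.0,
    },
}

_POSITIVE = ("K", "R", "H")
_NEGATIVE = ("D", "E", "C", "Y")


@dataclass(frozen=True)
class PhysicoProfile:
    protein_id: str
    length_aa: int
    mw_da: float
    pi: float
    instability_index: float
    is_stable: bool
    aliphatic_index: float
    gravy: float
    is_hydrophilic: bool


def _check_protein(protein: SequenceRecord, allow_x: bool = True) -> str:
    if protein.alphabet != Alphabet.protein:
        raise ValueError("expected a protein record")
    if not allow_x:
        pos = protein.seq.find("X")
        if pos != -1:
            raise ValueError(
                f"{protein.id}: residue 'X' at position {pos + 1} has undefined mass"
            )
    return protein.seq


def molecular_weight(protein: SequenceRecord, monoisotopic: bool = False) -> float:
    """Average (or monoisotopic) molecular weight in Daltons.

    Sum of residue masses plus one water (18.015 Da average); 'X' is an
    error since its mass is undefined.
    """
    seq = _check_protein(protein, allow_x=False)
    return float(_bio_mw(seq, seq_type="protein", monoisotopic=monoisotopic))


def net_charge(seq: str, ph: float, pka: dict[str, float]) -> float:
    """Protein net charge at a given pH (Henderson-Hasselbalch)."""
    charge = 1.0 / (1.0 + 10 ** (ph - pka["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (pka["Cterm"] - ph))
    for aa in _POSITIVE:
        n = seq.count(aa)
        if n:
            charge += n / (1.0 + 10 ** (ph - pka[aa]))
    for aa in _NEGATIVE:
        n = seq.count(aa)
        if n:
            charge -= n / (1.0 + 10 ** (pka[aa] - ph))
    return charge


def isoelectric_point(
    protein: SequenceRecord, pka_set: str = "emboss", tol: float = 0.001
) -> float:
    """pH of zero net charge, by bisection on [0, 14].

    The net charge is strictly decreasing in pH, positive at pH 0 and
    negative at pH 14, so the bracket is always valid.
    """
    seq = _check_protein(protein)
    pka = PKA_TABLES[pka_set]
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(seq, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def instability_index(protein: SequenceRecord) -> tuple[float, bool]:
    """Guruprasad dipeptide instability index; II <= 40 predicts stable."""
    seq = _check_protein(protein)
    if len(seq) < 2:
        raise ValueError(f"{protein.id}: instability index needs length >= 2")
    total = 0.0
    for a, b in zip(seq, seq[1:]):
        total += DIWV.get(a, {}).get(b, 0.0)
    ii = 10.0 / len(seq) * total
    return ii, ii <= STABILITY_THRESHOLD


def aliphatic_index(protein: SequenceRecord) -> float:
    """AI = X_Ala + 2.9 X_Val + 3.9 (X_Ile + X_Leu), X in mole percent."""
    seq = _check_protein(protein)
    n = len(seq)
    return 100.0 * (
        seq.count("A") + 2.9 * seq.count("V") + 3.9 * (seq.count("I") + seq.count("L"))
    ) / n


def gravy(protein: SequenceRecord) -> tuple[float, bool]:
    """Mean Kyte-Doolittle hydropathy; negative values are hydrophilic."""
    seq = _check_protein(protein)
    score = sum(kd.get(aa, 0.0) for aa in seq) / len(seq)
    return score, score < 0


def profile(protein: SequenceRecord, pka_set: str = "emboss") -> PhysicoProfile:
    ii, stable = instability_index(protein)
    g, hydrophilic = gravy(protein)
    return PhysicoProfile(
        protein_id=protein.id,
        length_aa=len(protein.seq),
        mw_da=molecular_weight(protein),
        pi=isoelectric_point(protein, pka_set=pka_set),
        instability_index=ii,
        is_stable=stable,
        aliphatic_index=aliphatic_index(protein),
        gravy=g,
        is_hydrophilic=hydrophilic,
    )


def profile_table(
    proteins: list[SequenceRecord], pka_set: str = "emboss"
) -> pd.DataFrame:
    rows = []
    for p in proteins:
        pr = profile(p, pka_set=pka_set)
        rows.append(
            {
                "protein_id": pr.protein_id,
                "length_aa": pr.length_aa,
                "mw_da": round(pr.mw_da, 2),
                "pi": round(pr.pi, 2),
                "instability_index": round(pr.instability_index, 2),
                "is_stable": pr.is_stable,
                "aliphatic_index": round(pr.aliphatic_index, 2),
                "gravy": round(pr.gravy, 3),
                "is_hydrophilic": pr.is_hydrophilic,
            }
        )
    return pd.DataFrame(rows)
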