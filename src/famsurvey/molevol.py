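"""Nei-Gojobori (1986) Ka/Ks estimation for aligned coding-sequence pairs.

The counting method: each codon position contributes synonymous and
nonsynonymous *sites* in proportion to the fraction of its nine possible
single-nucleotide mutations that preserve the encoded amino acid
(mutations to stop codons count as nonsynonymous). Observed differences
between two codons are split into synonymous and nonsynonymous counts by
averaging over all mutational pathways (orderings of the differing
positions); pathways passing through a stop codon are excluded and the
average renormalised. Proportions are corrected for multiple hits with
the Jukes-Cantor formula d = -(3/4) ln(1 - 4p/3). A Ka/Ks ratio below 1
indicates purifying selection, 1 neutral evolution, above 1 positive
selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from functools import lru_cache
from itertools import permutations
from math import log

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

GENETIC_CODE: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS = set(standard_dna_table.stop_codons)
SENSE_CODONS = sorted(GENETIC_CODE)

_BASES = "ACGT"


def round_half_up(x: float, ndigits: int = 4) -> float:
    """Decimal round-half-up, the convention used in printed Ka/Ks tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CodonPair:
    id_a: str
    id_b: str
    cds_a: str
    cds_b: str

    def __post_init__(self):
        a, b = self.cds_a.upper(), self.cds_b.upper()
        if len(a) != len(b):
            raise ValueError(f"{self.id_a}/{self.id_b}: unequal CDS lengths")
        if len(a) == 0 or len(a) % 3:
            raise ValueError(f"{self.id_a}/{self.id_b}: length not a positive multiple of 3")
        for name, s in ((self.id_a, a), (self.id_b, b)):
            for i in range(0, len(s), 3):
                codon = s[i : i + 3]
                if codon in STOP_CODONS:
                    raise ValueError(f"{name}: internal stop codon {codon} at codon {i // 3 + 1}")
                if codon not in GENETIC_CODE:
                    raise ValueError(f"{name}: invalid codon {codon!r} at codon {i // 3 + 1}")
        object.__setattr__(self, "cds_a", a)
        object.__setattr__(self, "cds_b", b)

    @property
    def codons(self) -> list[tuple[str, str]]:
        return [
            (self.cds_a[i : i + 3], self.cds_b[i : i + 3])
            for i in range(0, len(self.cds_a), 3)
        ]


@dataclass(frozen=True)
class KaKsResult:
    id_a: str
    id_b: str
    ka: float
    ks: float
    ratio: float | None  # None = undefined (ks == 0)
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    mode: str | None = None
    selection: str = "undefined"


@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Each of the nine single-base mutants is classified; mutations to stop
    codons are nonsynonymous. The two counts always sum to 3.
    """
    codon = codon.upper()
    if codon not in GENETIC_CODE:
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = GENETIC_CODE[codon]
    syn = 0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if GENETIC_CODE.get(mut) == aa:
                syn += 1
    s = syn / 3.0
    return s, 3.0 - s


def _step_type(c_from: str, c_to: str) -> str:
    """'syn' or 'nonsyn' for a single-base codon change between sense codons."""
    return "syn" if GENETIC_CODE[c_from] == GENETIC_CODE[c_to] else "nonsyn"


@lru_cache(maxsize=None)
def codon_path_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(sd, nd): pathway-averaged synonymous/nonsynonymous differences.

    All orderings of the differing positions are enumerated; orderings
    that pass through a stop codon are dropped and the average taken over
    the rest. If every ordering hits a stop, all are kept (the standard
    fallback so the pair is still countable).
    """
    a, b = codon_a.upper(), codon_b.upper()
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return 0.0, 0.0

    paths: list[tuple[int, int, bool]] = []  # (sd, nd, passes_stop)
    for order in permutations(diff_pos):
        cur = a
        sd = nd = 0
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS or cur in STOP_CODONS:
                # steps into or out of a stop are counted nonsynonymous in
                # the all-paths-blocked fallback
                hit_stop = True
                nd += 1
                cur = nxt
                continue
            if _step_type(cur, nxt) == "syn":
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, hit_stop))

    clean = [(s, n) for s, n, stop in paths if not stop]
    use = clean if clean else [(s, n) for s, n, _ in paths]
    sd = sum(s for s, _ in use) / len(use)
    nd = sum(n for _, n in use) / len(use)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction d = -(3/4) ln(1 - 4p/3)."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        raise ValueError(f"proportion {p:.4f} >= 3/4: distance saturated/undefined")
    if p == 0:
        return 0.0
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


def ng86(pair: CodonPair, mode: str | None = None) -> KaKsResult:
    """Nei-Gojobori Ka/Ks with Jukes-Cantor correction for one pair.

    Site counts are averaged over the two sequences; the ratio is
    rounded half-up to 4 decimals when Ks > 0 and undefined otherwise.
    """
    s_a = n_a = s_b = n_b = 0.0
    sd = nd = 0.0
    for ca, cb in pair.codons:
        sa, na = codon_site_counts(ca)
        sb, nb = codon_site_counts(cb)
        s_a += sa
        n_a += na
        s_b += sb
        n_b += nb
        d_s, d_n = codon_path_differences(ca, cb)
        sd += d_s
        nd += d_n
    s_sites = (s_a + s_b) / 2.0
    n_sites = (n_a + n_b) / 2.0
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    ratio = round_half_up(ka / ks, 4) if ks > 0 else None
    return KaKsResult(
        id_a=pair.id_a, id_b=pair.id_b, ka=ka, ks=ks, ratio=ratio,
        n_sites=n_sites, s_sites=s_sites, nd=nd, sd=sd,
        mode=mode, selection=classify_selection(ratio),
    )


def classify_selection(ratio: float | None, tol: float = 1e-9) -> str:
    """purifying (< 1), neutral (= 1), positive (> 1) or undefined."""
    if ratio is None:
        return "undefined"
    if ratio < 0:
        raise ValueError("Ka/Ks ratio cannot be negative")
    if abs(ratio - 1.0) <= tol:
        return "neutral"
    return "purifying" if ratio < 1.0 else "positive"


def ratio_from_printed(ka: float, ks: float, compat_zero: bool = False) -> float | None:
    """Ka/Ks as printed tables report it: 4 decimals, half-up.

    With ``compat_zero`` a Ks of 0 prints 0.0000 (the convention some
    toolboxes use); the default reports it as undefined (None).
    """
    if ks > 0:
        return round_half_up(ka / ks, 4)
    return 0.0 if compat_zero else None


def kaks_table(results: list[KaKsResult], compat_zero: bool = False) -> pd.DataFrame:
    rows = []
    for r in results:
        ratio = r.ratio
        if ratio is None and compat_zero:
            ratio = 0.0
        rows.append(
            {
                "gene1": r.id_a,
                "gene2": r.id_b,
                "Ka": round_half_up(r.ka, 4),
                "Ks": round_half_up(r.ks, 4),
                "Ka/Ks": "NA" if ratio is None else f"{ratio:.4f}",
                "mode": r.mode or "NA",
                "selection": r.selection,
                "method": "NG86+JC69",
            }
        )
    return pd.DataFrame(
        rows, columns=["gene1", "gene2", "Ka", "Ks", "Ka/Ks", "mode", "selection", "method"]
    )
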