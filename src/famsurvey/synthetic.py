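"""Synthetic-data generators with recorded ground truth.

Every input the survey pipeline consumes can be generated here:
proteomes with planted C2H2 fingers in arrays of controlled linker
length, codon-sequence pairs diverged at a known dN/dS, annotated
genomes with planted tandem clusters and collinear duplicated segments,
promoters with planted cis-elements at known counts, and two-phenotype
four-stage expression matrices (plus qPCR CT tables) with planted bias.
Each generator is a pure function of its parameters and seed, and
returns the generated objects together with a TruthBundle recording
what was planted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Alphabet, SequenceRecord, reverse_complement
from .molevol import GENETIC_CODE, SENSE_CODONS, STOP_CODONS, codon_site_counts
from .regulatory import IUPAC, CisElementDef, Promoter, load_element_table, scan_elements

# background alphabet without C or H: planted fingers are the only anchors
_BG_AA = "ADEFGIKLMNPQRSTVWY"
_FULL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: default linker-length weights (1..40); mode at the five-residue
#: consensus linker of canonical C2H2 arrays
DEFAULT_LINKER_WEIGHTS = {2: 1, 3: 2, 4: 4, 5: 8, 6: 4, 7: 2, 8: 1, 9: 1, 10: 1,
                          **{k: 1 for k in range(11, 41)}}


@dataclass
class TruthBundle:
    """Planted ground truth serialized alongside generated files."""

    scenario: str
    seed: int
    params: dict = field(default_factory=dict)
    data: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"scenario": self.scenario, "seed": self.seed,
             "params": self.params, "data": self.data},
            indent=2, sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthBundle":
        d = json.loads(text)
        return cls(d["scenario"], d["seed"], d["params"], d["data"])

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _bg(rng: np.random.Generator, n: int, alphabet: str = _BG_AA) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


def _draw_linker(rng: np.random.Generator, weights: dict[int, float], short: bool) -> int:
    """Sample a linker length conditioned on tandem (<=10) or dispersed (>10)."""
    keys = [k for k in sorted(weights) if (k <= 10) == short]
    w = np.array([weights[k] for k in keys], dtype=float)
    return int(rng.choice(keys, p=w / w.sum()))


# ---------------------------------------------------------------------------
# proteome


def _make_finger(rng: np.random.Generator) -> str:
    g1 = int(rng.integers(2, 5))
    g3 = int(rng.integers(3, 6))
    return "C" + _bg(rng, g1) + "C" + _bg(rng, 12) + "H" + _bg(rng, g3) + "H"


def gen_proteome(
    n_a: int,
    n_b: int,
    n_c: int,
    linker_weights: dict[int, float] | None = None,
    seed: int = 0,
) -> tuple[list[SequenceRecord], TruthBundle]:
    """Proteome with planted finger arrays realising A/B/C set labels.

    Set A proteins carry one tandem array of 2-4 fingers (a dispersed
    extra finger is added to some, which must not change the label);
    set B carry 2-3 arrays; set C a single finger or 2-3 dispersed
    fingers. Background residues exclude C and H, so the planted fingers
    are the only detectable motifs.
    """
    rng = np.random.default_rng(seed)
    weights = linker_weights or DEFAULT_LINKER_WEIGHTS
    records: list[SequenceRecord] = []
    truth: dict[str, dict] = {}

    def build(label: str, idx: int) -> None:
        pid = f"ZFP{label}{idx:03d}"
        if label == "A":
            arrays = [int(rng.integers(2, 5))]
            extra_dispersed = int(rng.random() < 0.3)
        elif label == "B":
            arrays = [int(rng.integers(2, 4)) for _ in range(int(rng.integers(2, 4)))]
            extra_dispersed = int(rng.random() < 0.3)
        else:
            if rng.random() < 0.5:
                arrays = []
                extra_dispersed = 1
            else:
                arrays = []
                extra_dispersed = int(rng.integers(2, 4))
        parts = [_bg(rng, int(rng.integers(5, 31)))]
        coords: list[tuple[int, int]] = []
        pos = len(parts[0])

        def plant(finger: str):
            nonlocal pos
            coords.append((pos + 1, pos + len(finger)))
            parts.append(finger)
            pos += len(finger)

        def pad(n: int):
            nonlocal pos
            parts.append(_bg(rng, n))
            pos += n

        first = True
        for size in arrays:
            if not first:
                pad(_draw_linker(rng, weights, short=False))
            for j in range(size):
                if j > 0:
                    pad(_draw_linker(rng, weights, short=True))
                plant(_make_finger(rng))
            first = False
        for _ in range(extra_dispersed):
            if not first:
                pad(_draw_linker(rng, weights, short=False))
            plant(_make_finger(rng))
            first = False
        pad(int(rng.integers(5, 31)))
        records.append(SequenceRecord(pid, "".join(parts), Alphabet.protein))
        truth[pid] = {
            "set_label": label,
            "n_fingers": sum(arrays) + extra_dispersed,
            "array_sizes": arrays,
            "n_dispersed": extra_dispersed,
            "finger_coords": coords,
        }

    for i in range(n_a):
        build("A", i)
    for i in range(n_b):
        build("B", i)
    for i in range(n_c):
        build("C", i)

    bundle = TruthBundle(
        "proteome", seed,
        {"n_a": n_a, "n_b": n_b, "n_c": n_c},
        {"proteins": truth},
    )
    return records, bundle


# ---------------------------------------------------------------------------
# codon pairs


def gen_codon_pair(
    n_codons: int,
    omega: float,
    target_ks: float = 0.3,
    seed: int = 0,
    id_a: str = "anc",
    id_b: str = "der",
) -> tuple["CodonPair", TruthBundle]:
    """A codon-sequence pair diverged at a known dN/dS (omega).

    One copy of a random sense-codon ancestor accumulates mutations:
    proposals are uniform over sites and alternative bases, accepted with
    probability 1 if synonymous, omega if nonsynonymous, never if the
    mutant codon is a stop. Mutation is stopped once the accepted
    synonymous events reach target_ks x (synonymous sites of the
    ancestor), so the realised Ks tracks target_ks.
    """
    from .molevol import CodonPair

    if not 0 < target_ks < 0.75:
        raise ValueError("target_ks must be in (0, 0.75)")
    rng = np.random.default_rng(seed)
    codons = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons)]
    anc = "".join(codons)
    s_sites = sum(codon_site_counts(c)[0] for c in codons)
    n_syn_target = max(1, round(target_ks * s_sites))

    seq = list(anc)
    length = len(seq)
    syn_events = nonsyn_events = 0
    max_proposals = 2000 * n_syn_target + 10000
    proposals = 0
    bases = "ACGT"
    while syn_events < n_syn_target and proposals < max_proposals:
        proposals += 1
        site = int(rng.integers(0, length))
        cur = seq[site]
        alt = bases[int(rng.integers(0, 4))]
        if alt == cur:
            continue
        ci = site - site % 3
        codon = "".join(seq[ci : ci + 3])
        mut = codon[: site - ci] + alt + codon[site - ci + 1 :]
        if mut in STOP_CODONS:
            continue
        if GENETIC_CODE[codon] == GENETIC_CODE[mut]:
            seq[site] = alt
            syn_events += 1
        elif omega > 0 and rng.random() < omega:
            seq[site] = alt
            nonsyn_events += 1

    pair = CodonPair(id_a, id_b, anc, "".join(seq))
    bundle = TruthBundle(
        "codon_pair", seed,
        {"n_codons": n_codons, "omega": omega, "target_ks": target_ks},
        {"syn_events": syn_events, "nonsyn_events": nonsyn_events,
         "s_sites_ancestor": s_sites},
    )
    return pair, bundle


# ---------------------------------------------------------------------------
# genome with planted duplications


def gen_genome(
    n_chroms: int = 9,
    genes_per_chrom: int = 50,
    n_tandem_pairs: int = 2,
    n_segment_blocks: int = 9,
    block_size: int = 6,
    n_noise_pairs: int = 0,
    seed: int = 0,
) -> tuple["AnnotationSet", list[SequenceRecord], list[tuple[str, str]],
           list[tuple[str, str]], TruthBundle]:
    """Annotated genome with planted tandem clusters and collinear segments.

    Returns (annotation, genome, all_homolog_pairs, family_pairs, truth).
    Tandem pairs sit at adjacent gene ranks on one chromosome; each
    duplicated segment is a run of ``block_size`` consecutive genes whose
    anchors map, in order, onto a run on another chromosome. One anchor
    pair per segment is a family pair; the rest are background anchors.
    """
    from .core import AnnotationSet, GeneModel

    rng = np.random.default_rng(seed)
    spacing = 4000
    chrom_names = [f"chr{i + 1}" for i in range(n_chroms)]
    chrom_lengths = {c: genes_per_chrom * spacing + 6000 for c in chrom_names}

    genes: list[GeneModel] = []
    gene_name: dict[tuple[str, int], str] = {}  # (chrom, rank) -> id
    for c_i, chrom in enumerate(chrom_names):
        for r in range(1, genes_per_chrom + 1):
            gid = f"g{c_i + 1:02d}_{r:03d}"
            start = 3000 + (r - 1) * spacing + int(rng.integers(0, 500))
            glen = int(rng.integers(1200, 2401))
            end = start + glen - 1
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(1, 5))
            bounds = sorted(rng.choice(np.arange(1, glen - 1), 2 * (n_exons - 1),
                                       replace=False)) if n_exons > 1 else []
            edges = [0] + [int(b) for b in bounds] + [glen - 1]
            exons = [(start + edges[2 * k], start + edges[2 * k + 1])
                     for k in range(n_exons)]
            # CDS anchor stays inside the terminal exon
            if strand == "+":
                cds_start = min(exons[0][0] + 3, exons[0][1])
            else:
                cds_start = max(exons[-1][1] - 3, exons[-1][0])
            genes.append(GeneModel(gid, chrom, start, end, strand, exons, cds_start))
            gene_name[(chrom, r)] = gid

    used: dict[str, set[int]] = {c: set() for c in chrom_names}

    def take_run(chrom: str, size: int) -> list[int]:
        for _ in range(200):
            r0 = int(rng.integers(1, genes_per_chrom - size + 2))
            run = list(range(r0, r0 + size))
            if not any(r in used[chrom] for r in run):
                used[chrom].update(run)
                return run
        raise RuntimeError("could not place a gene run; genome too small")

    homolog_pairs: list[tuple[str, str]] = []
    family_pairs: list[tuple[str, str]] = []
    tandem_truth: list[list[str]] = []
    segment_truth: list[list[str]] = []
    block_truth: list[dict] = []

    for _ in range(n_tandem_pairs):
        chrom = chrom_names[int(rng.integers(0, n_chroms))]
        r = take_run(chrom, 2)
        a, b = gene_name[(chrom, r[0])], gene_name[(chrom, r[1])]
        homolog_pairs.append((a, b))
        family_pairs.append((a, b))
        tandem_truth.append([a, b])

    pair_choices = [(i, j) for i in range(n_chroms) for j in range(n_chroms) if i != j]
    rng.shuffle(pair_choices)
    for bi in range(n_segment_blocks):
        ca, cb = (chrom_names[k] for k in pair_choices[bi % len(pair_choices)])
        run_a = take_run(ca, block_size)
        run_b = take_run(cb, block_size)
        anchors = []
        for ra, rb in zip(run_a, run_b):
            a, b = gene_name[(ca, ra)], gene_name[(cb, rb)]
            homolog_pairs.append((a, b))
            anchors.append((a, b))
        fam_idx = int(rng.integers(0, block_size))
        fa, fb = anchors[fam_idx]
        family_pairs.append((fa, fb))
        segment_truth.append([fa, fb])
        block_truth.append({"chrom_a": ca, "chrom_b": cb,
                            "ranks_a": run_a, "ranks_b": run_b})

    for _ in range(n_noise_pairs):
        ca, cb = rng.choice(chrom_names, 2, replace=False)
        ra = int(rng.integers(1, genes_per_chrom + 1))
        rb = int(rng.integers(1, genes_per_chrom + 1))
        homolog_pairs.append((gene_name[(ca, ra)], gene_name[(cb, rb)]))

    family_ids = sorted({g for p in family_pairs for g in p})

    genome = [
        SequenceRecord(c, _bg(rng, chrom_lengths[c], "ACGT"), Alphabet.dna)
        for c in chrom_names
    ]
    annotation = AnnotationSet(genes=genes, chrom_lengths=chrom_lengths)
    bundle = TruthBundle(
        "genome", seed,
        {"n_chroms": n_chroms, "genes_per_chrom": genes_per_chrom,
         "n_tandem_pairs": n_tandem_pairs, "n_segment_blocks": n_segment_blocks,
         "block_size": block_size, "n_noise_pairs": n_noise_pairs},
        {"tandem_pairs": tandem_truth, "segment_pairs": segment_truth,
         "blocks": block_truth, "family_ids": family_ids},
    )
    return annotation, genome, homolog_pairs, family_pairs, bundle


# ---------------------------------------------------------------------------
# promoters with planted elements


def _concretize(rng: np.random.Generator, pattern: str) -> str:
    return "".join(IUPAC[ch][int(rng.integers(0, len(IUPAC[ch])))] for ch in pattern)


def _clean_background(
    rng: np.random.Generator, length: int, table: list[CisElementDef]
) -> str:
    """Random ACGT with no match of any table pattern on either strand."""
    seq = list(_bg(rng, length, "ACGT"))
    for _ in range(60):
        prom = Promoter("bg", "".join(seq), False, 1, length)
        hits = scan_elements(prom, table, both_strands=True)
        if not hits:
            return "".join(seq)
        plens = {el.element_name: len(el.pattern) for el in table}
        for h in hits:
            k = int(rng.integers(0, plens[h.element_name]))
            pos = h.offset - 1 + k
            cur = seq[pos]
            seq[pos] = "ACGT"[("ACGT".index(cur) + 1 + int(rng.integers(0, 3))) % 4]
    raise RuntimeError("could not scrub accidental motif matches from background")


def gen_promoters(
    n_genes: int,
    category_mix: dict[str, int] | None = None,
    element_mix: dict[str, int] | None = None,
    promoter_length: int = 2000,
    element_table: list[CisElementDef] | None = None,
    seed: int = 0,
) -> tuple[list[SequenceRecord], TruthBundle]:
    """Promoter set with planted elements at exactly known counts.

    ``category_mix`` gives total planted occurrences per category
    (spread over that category's elements and over genes);
    ``element_mix`` pins counts of specific named elements instead.
    Background sequence is scrubbed of accidental matches of every table
    pattern, so a scan recovers exactly the planted counts.
    """
    table = element_table or load_element_table()
    by_name = {el.element_name: el for el in table}
    by_cat: dict[str, list[CisElementDef]] = {}
    for el in table:
        by_cat.setdefault(el.category, []).append(el)

    rng = np.random.default_rng(seed)
    plant_list: list[str] = []  # element names, one per planted occurrence
    if element_mix:
        for name, count in element_mix.items():
            if name not in by_name:
                raise ValueError(f"unknown element {name!r}")
            plant_list.extend([name] * count)
    if category_mix:
        for cat, count in category_mix.items():
            els = by_cat.get(cat)
            if not els:
                raise ValueError(f"no elements of category {cat!r} in table")
            for k in range(count):
                plant_list.append(els[k % len(els)].element_name)

    # spread occurrences over genes
    gene_ids = [f"prom{g + 1:03d}" for g in range(n_genes)]
    assignment: dict[str, list[str]] = {g: [] for g in gene_ids}
    order = rng.permutation(len(plant_list))
    for k, idx in enumerate(order):
        assignment[gene_ids[k % n_genes]].append(plant_list[idx])

    records: list[SequenceRecord] = []
    truth_counts: dict[str, dict[str, int]] = {}
    for gid in gene_ids:
        names = assignment[gid]
        need = sum(len(by_name[n].pattern) for n in names)
        if need + len(names) > promoter_length:
            raise ValueError(f"{gid}: cannot plant {len(names)} elements in "
                             f"{promoter_length} bp")
        for attempt in range(50):
            sub = np.random.default_rng(rng.integers(0, 2**31))
            seq = list(_clean_background(sub, promoter_length, table))
            # non-overlapping offsets, longest patterns first
            placed = []
            ok = True
            for name in sorted(names, key=lambda n: -len(by_name[n].pattern)):
                plen = len(by_name[name].pattern)
                for _ in range(300):
                    off = int(sub.integers(0, promoter_length - plen + 1))
                    if all(off + plen <= s or off >= s + l for s, l in placed):
                        placed.append((off, plen))
                        inst = _concretize(sub, by_name[name].pattern)
                        if sub.random() < 0.5:
                            inst = reverse_complement(inst)
                        seq[off : off + plen] = inst
                        break
                else:
                    ok = False
                    break
            if not ok:
                continue
            prom = Promoter(gid, "".join(seq), False, 1, promoter_length)
            hits = scan_elements(prom, table, both_strands=True)
            got = pd.Series([h.element_name for h in hits]).value_counts().to_dict() \
                if hits else {}
            want: dict[str, int] = {}
            for n in names:
                want[n] = want.get(n, 0) + 1
            if got == want:
                records.append(SequenceRecord(gid, "".join(seq), Alphabet.dna))
                truth_counts[gid] = want
                break
        else:
            raise RuntimeError(f"{gid}: planting did not converge")

    cat_totals: dict[str, int] = {}
    for counts in truth_counts.values():
        for name, c in counts.items():
            cat = by_name[name].category
            cat_totals[cat] = cat_totals.get(cat, 0) + c
    bundle = TruthBundle(
        "promoters", seed,
        {"n_genes": n_genes, "promoter_length": promoter_length,
         "category_mix": category_mix or {}, "element_mix": element_mix or {}},
        {"per_gene_element_counts": truth_counts, "category_totals": cat_totals},
    )
    return records, bundle


# ---------------------------------------------------------------------------
# expression + qPCR


def gen_expression_qpcr(
    n_genes: int = 100,
    n_f_biased: int = 23,
    n_m_biased: int = 15,
    n_silent: int = 13,
    fold: float = 4.0,
    noise_cv: float = 0.2,
    n_replicates: int = 3,
    n_qpcr_genes: int = 6,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthBundle]:
    """Expression matrix, sample sheet and qPCR CT table with planted bias.

    Biased genes are ``fold`` times higher in the favoured phenotype
    across all four stages; silent genes stay below the expression floor;
    the rest are unbiased. qPCR CTs are derived from the phenotype means
    of a subset of biased genes with 0.1-cycle noise, calibrated on the
    M-type group.
    """
    if n_f_biased + n_m_biased + n_silent > n_genes:
        raise ValueError("bias counts exceed n_genes")
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log(1.0 + noise_cv**2)))

    gene_ids = [f"ZFP{i + 1:03d}" for i in range(n_genes)]
    labels = (["F_biased"] * n_f_biased + ["M_biased"] * n_m_biased
              + ["not_expressed"] * n_silent
              + ["unbiased"] * (n_genes - n_f_biased - n_m_biased - n_silent))
    order = rng.permutation(n_genes)
    truth_label = {gene_ids[i]: labels[order[i]] for i in range(n_genes)}

    samples = []
    for pheno in ("F", "M"):
        for stage in (1, 2, 3, 4):
            for rep in range(1, n_replicates + 1):
                samples.append({"sample": f"{pheno}{stage}r{rep}",
                                "phenotype": pheno, "stage": stage, "replicate": rep})
    sample_df = pd.DataFrame(samples)

    values = np.zeros((n_genes, len(samples)))
    baseline = np.exp(rng.normal(3.0, 0.5, n_genes))  # ~20 TPM typical
    stage_factor = np.exp(rng.normal(0.0, 0.1, (n_genes, 4)))
    for gi, gid in enumerate(gene_ids):
        lab = truth_label[gid]
        for si, s in enumerate(samples):
            if lab == "not_expressed":
                values[gi, si] = rng.uniform(0.0, 0.8)
                continue
            v = baseline[gi] * stage_factor[gi, s["stage"] - 1]
            if lab == "F_biased" and s["phenotype"] == "F":
                v *= fold
            elif lab == "M_biased" and s["phenotype"] == "M":
                v *= fold
            values[gi, si] = v * np.exp(rng.normal(0.0, sigma))
    matrix = pd.DataFrame(values, index=gene_ids,
                          columns=[s["sample"] for s in samples])

    # qPCR panel: biased genes, CT from phenotype means, M group calibrator
    biased = [g for g in gene_ids if truth_label[g] in ("F_biased", "M_biased")]
    panel = sorted(rng.choice(biased, min(n_qpcr_genes, len(biased)), replace=False))
    qpcr_rows = []
    true_rq = {}
    for gid in panel:
        lab = truth_label[gid]
        f_fold = fold if lab == "F_biased" else 1.0 / fold
        true_rq[gid] = f_fold
        for pheno, rel in (("M", 1.0), ("F", f_fold)):
            for rep in range(1, n_replicates + 1):
                qpcr_rows.append({
                    "gene_id": gid,
                    "sample": f"{gid}_{pheno}r{rep}",
                    "target_ct": 28.0 - np.log2(rel) + rng.normal(0.0, 0.1),
                    "reference_ct": 20.0 + rng.normal(0.0, 0.1),
                    "group": pheno,
                    "calibrator": pheno == "M",
                })
    qpcr_df = pd.DataFrame(qpcr_rows)

    bundle = TruthBundle(
        "expression", seed,
        {"n_genes": n_genes, "n_f_biased": n_f_biased, "n_m_biased": n_m_biased,
         "n_silent": n_silent, "fold": fold, "noise_cv": noise_cv},
        {"labels": truth_label, "qpcr_true_rq_f_vs_m": true_rq},
    )
    return matrix, sample_df, qpcr_df, bundle
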