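"""Pipeline orchestration: config-driven stage execution and simulation.

The configuration is a flat document (YAML on disk) with an ``inputs``
section naming files, an optional section of parameters per stage, a
single global ``seed`` and an ``out_dir``. Stage order is fixed:
family -> protparam -> kaks -> duplication -> regulatory -> features ->
expression. Missing required inputs for any requested stage fail before
anything runs; the same config and seed always produce byte-identical
reports.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from . import (
    core,
    datasets,
    expression as expr_mod,
    genome_dup,
    molevol,
    protparam,
    regulatory,
    reporting,
    seq_features,
    synthetic,
    zf_family,
)

STAGE_ORDER = ["family", "protparam", "kaks", "duplication", "regulatory",
               "features", "expression"]

REQUIRED_INPUTS = {
    "family": ["proteome"],
    "protparam": ["proteome"],
    "kaks": ["cds_pairs"],
    "duplication": ["gff3", "homolog_pairs"],
    "regulatory": [],  # promoters OR genome+gff3, checked specially
    "features": ["gff3"],
    "expression": ["expression", "samples"],
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _read_pairs_tsv(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return list(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def validate_config(config: dict, stages: list[str]) -> None:
    inputs = config.get("inputs", {})
    problems = []
    for stage in stages:
        for key in REQUIRED_INPUTS.get(stage, []):
            if key not in inputs:
                problems.append(f"stage {stage!r} requires input {key!r}")
            elif not Path(inputs[key]).exists():
                problems.append(f"input {key!r} file not found: {inputs[key]}")
        if stage == "regulatory":
            if "promoters" not in inputs and not (
                "genome" in inputs and "gff3" in inputs
            ):
                problems.append(
                    "stage 'regulatory' requires input 'promoters' or both "
                    "'genome' and 'gff3'"
                )
    if problems:
        raise ValueError("config validation failed:\n  " + "\n  ".join(problems))


def run_pipeline(config: dict, stages: list[str] | None = None) -> dict[str, pd.DataFrame]:
    """Run the requested stages and write the report bundle.

    Returns the per-stage DataFrames keyed by report-table name.
    """
    requested = stages or config.get("stages") or STAGE_ORDER
    if requested == "all" or requested == ["all"]:
        requested = STAGE_ORDER
    requested = [s for s in STAGE_ORDER if s in requested]
    validate_config(config, requested)

    inputs = config.get("inputs", {})
    out: dict[str, pd.DataFrame] = {}

    if "family" in requested:
        params = config.get("family", {})
        proteins = core.read_fasta(inputs["proteome"], core.Alphabet.protein)
        assignments = zf_family.scan_proteome(
            proteins,
            pattern=params.get("pattern", zf_family.DEFAULT_PATTERN),
            max_linker=params.get("max_linker", zf_family.DEFAULT_MAX_LINKER),
        )
        out["family"] = zf_family.family_table(assignments)

    if "protparam" in requested:
        params = config.get("protparam", {})
        proteins = core.read_fasta(inputs["proteome"], core.Alphabet.protein)
        out["protparam"] = protparam.profile_table(
            proteins, pka_set=params.get("pka_set", "emboss")
        )

    if "kaks" in requested:
        params = config.get("kaks", {})
        df = pd.read_csv(inputs["cds_pairs"], sep="\t")
        results = []
        for _, row in df.iterrows():
            pair = molevol.CodonPair(row["id_a"], row["id_b"], row["cds_a"], row["cds_b"])
            results.append(molevol.ng86(pair, mode=row.get("mode")))
        out["kaks"] = molevol.kaks_table(
            results, compat_zero=params.get("compat_zero", False)
        )

    if "duplication" in requested:
        params = config.get("duplication", {})
        annotation = core.read_gff3(inputs["gff3"])
        homologs = _read_pairs_tsv(inputs["homolog_pairs"])
        family_pairs = (
            _read_pairs_tsv(inputs["family_pairs"])
            if "family_pairs" in inputs else homologs
        )
        rank_index = genome_dup.GeneRankIndex.from_annotation(annotation)
        tandem = genome_dup.find_tandem(
            homologs, rank_index,
            max_rank_gap=params.get("max_rank_gap", genome_dup.DEFAULT_MAX_RANK_GAP),
        )
        blocks = genome_dup.chain_collinear(
            homologs, rank_index,
            max_gap=params.get("max_gap", genome_dup.DEFAULT_MAX_GAP),
            min_block_anchors=params.get(
                "min_block_anchors", genome_dup.DEFAULT_MIN_BLOCK_ANCHORS
            ),
        )
        calls = genome_dup.classify_duplications(family_pairs, tandem, blocks)
        out["duplication"] = genome_dup.duplication_table(calls)
        out["blocks"] = genome_dup.block_table(blocks)
        family_ids = sorted({g for p in family_pairs for g in p})
        dist, unplaced = genome_dup.chromosome_distribution(annotation, family_ids)
        out["distribution"] = pd.DataFrame(
            [{"chrom": c, "n_genes": n} for c, n in sorted(dist.items())]
            + [{"chrom": "unplaced", "n_genes": unplaced}],
            columns=["chrom", "n_genes"],
        )

    if "regulatory" in requested:
        params = config.get("regulatory", {})
        table = regulatory.load_element_table(inputs.get("element_table"))
        if "promoters" in inputs:
            proms = [
                regulatory.Promoter(r.id, r.seq, False, 1, len(r.seq))
                for r in core.read_fasta(inputs["promoters"], core.Alphabet.dna)
            ]
        else:
            annotation = core.read_gff3(inputs["gff3"])
            genome = {
                r.id: r for r in core.read_fasta(inputs["genome"], core.Alphabet.dna)
            }
            length = params.get("promoter_length", regulatory.DEFAULT_PROMOTER_LENGTH)
            proms = [
                regulatory.extract_promoter(g, genome, length)
                for g in annotation.genes
                if g.cds_start is not None
            ]
        all_hits = []
        for prom in proms:
            all_hits.extend(regulatory.scan_elements(prom, table))
        report = regulatory.categorize(all_hits, table)
        out["cis_hits"] = regulatory.hits_table(all_hits)
        out["cis_summary"] = regulatory.category_summary_table(report)

    if "features" in requested:
        annotation = core.read_gff3(inputs["gff3"])
        family_ids = None
        if "family_pairs" in inputs:
            family_ids = sorted({g for p in _read_pairs_tsv(inputs["family_pairs"]) for g in p})
        counts, _dist = seq_features.intron_stats(annotation, family_ids)
        out["introns"] = seq_features.intron_table(counts)
        if "genome" in inputs:
            genome = {
                r.id: r for r in core.read_fasta(inputs["genome"], core.Alphabet.dna)
            }
            ssrs = []
            targets = family_ids or [g.gene_id for g in annotation.genes]
            by_id = annotation.by_id()
            for gid in targets:
                g = by_id.get(gid)
                if g is None or g.chrom not in genome:
                    continue
                seq = genome[g.chrom].seq[g.start - 1 : g.end]
                ssrs.extend(seq_features.find_ssrs(gid, seq))
            out["ssrs"] = seq_features.ssr_table(ssrs)
        if "primers" in inputs:
            pdf = pd.read_csv(inputs["primers"], sep="\t")
            out["primers"] = seq_features.primer_table(
                list(zip(pdf.iloc[:, 0].astype(str), pdf["sequence"]))
            )

    if "expression" in requested:
        params = config.get("expression", {})
        matrix = pd.read_csv(inputs["expression"], sep="\t", index_col=0)
        samples = pd.read_csv(inputs["samples"], sep="\t")
        calls = expr_mod.classify_expression_bias(
            matrix, samples,
            min_expr=params.get("min_expr", expr_mod.DEFAULT_MIN_EXPR),
            fold_threshold=params.get("fold_threshold", expr_mod.DEFAULT_FOLD_THRESHOLD),
        )
        out["expression_bias"] = expr_mod.bias_table(calls)
        out["heatmap_matrix"] = expr_mod.export_heatmap_matrix(matrix, samples)
        if "qpcr" in inputs:
            qdf = pd.read_csv(inputs["qpcr"], sep="\t")
            rq_frames = []
            for gid, grp in qdf.groupby("gene_id"):
                records = [
                    expr_mod.QpcrRecord(
                        r["sample"], r["target_ct"], r["reference_ct"],
                        r["group"], bool(r["calibrator"]),
                    )
                    for _, r in grp.iterrows()
                ]
                rq = expr_mod.delta_delta_ct(records)
                rq.insert(0, "gene_id", gid)
                rq_frames.append(rq)
            out["qpcr_rq"] = pd.concat(rq_frames, ignore_index=True)

    out_dir = config.get("out_dir", "report")
    provenance = {
        "seed": config.get("seed"),
        "stages": ",".join(requested),
        "inputs": "; ".join(f"{k}={v}" for k, v in sorted(inputs.items())),
    }
    reporting.build_report(out, out_dir, provenance)
    return out


# ---------------------------------------------------------------------------
# simulation scenarios


def simulate(scenario: str, out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Generate a named scenario's input files plus truth sidecar JSONs.

    Scenarios: family, kaks, genome, promoters, expression, all. Returns
    the paths written, keyed by the config input name they serve.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def want(name: str) -> bool:
        return scenario in (name, "all")

    if want("family"):
        records, truth = synthetic.gen_proteome(27, 3, 70, seed=seed)
        p = out_dir / "proteome.fasta"
        core.write_fasta(records, p)
        truth.save(out_dir / "proteome.truth.json")
        paths["proteome"] = p

    if want("kaks"):
        rows = []
        omegas = [0.7, 0.68, 0.1, 0.2, 0.3, 0.34, 0.28, 0.13, 0.25, 0.24, 0.22]
        modes = ["tandem"] * 2 + ["segment"] * 9
        for i, (om, mode) in enumerate(zip(omegas, modes)):
            pair, _ = synthetic.gen_codon_pair(
                600, om, target_ks=0.3, seed=seed + i,
                id_a=f"dup{i + 1}a", id_b=f"dup{i + 1}b",
            )
            rows.append({"id_a": pair.id_a, "id_b": pair.id_b,
                         "cds_a": pair.cds_a, "cds_b": pair.cds_b, "mode": mode})
        p = out_dir / "cds_pairs.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        paths["cds_pairs"] = p

    if want("genome"):
        annotation, genome, homologs, family_pairs, truth = synthetic.gen_genome(seed=seed)
        p_gff = out_dir / "annotation.gff3"
        write_gff3(annotation, p_gff)
        p_genome = out_dir / "genome.fasta"
        core.write_fasta(genome, p_genome)
        p_hom = out_dir / "homolog_pairs.tsv"
        pd.DataFrame(homologs, columns=["gene_a", "gene_b"]).to_csv(
            p_hom, sep="\t", index=False
        )
        p_fam = out_dir / "family_pairs.tsv"
        pd.DataFrame(family_pairs, columns=["gene_a", "gene_b"]).to_csv(
            p_fam, sep="\t", index=False
        )
        truth.save(out_dir / "genome.truth.json")
        paths.update({"gff3": p_gff, "genome": p_genome,
                      "homolog_pairs": p_hom, "family_pairs": p_fam})

    if want("promoters"):
        records, truth = synthetic.gen_promoters(
            20,
            category_mix={"transcription": 97, "stress": 26, "hormone": 12,
                          "development": 41, "cell_cycle": 24},
            seed=seed,
        )
        p = out_dir / "promoters.fasta"
        core.write_fasta(records, p)
        truth.save(out_dir / "promoters.truth.json")
        paths["promoters"] = p

    if want("expression"):
        matrix, samples, qpcr, truth = synthetic.gen_expression_qpcr(seed=seed)
        p_expr = out_dir / "expression.tsv"
        matrix.to_csv(p_expr, sep="\t", index_label="gene_id")
        p_samp = out_dir / "samples.tsv"
        samples.to_csv(p_samp, sep="\t", index=False)
        p_qpcr = out_dir / "qpcr.tsv"
        qpcr.to_csv(p_qpcr, sep="\t", index=False)
        truth.save(out_dir / "expression.truth.json")
        paths.update({"expression": p_expr, "samples": p_samp, "qpcr": p_qpcr})

    if scenario == "all":
        p = out_dir / "primers.tsv"
        panel = datasets.load_primer_panel()
        panel.insert(0, "name", panel["gene"] + "_" + panel["direction"])
        panel[["name", "sequence"]].to_csv(p, sep="\t", index=False)
        paths["primers"] = p

    if not paths:
        raise ValueError(f"unknown scenario {scenario!r}")
    return paths


def write_gff3(annotation: "core.AnnotationSet", path: str | Path) -> None:
    """Minimal GFF3 writer: gene/mRNA/exon/CDS with one mRNA per gene."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(annotation.chrom_lengths):
            fh.write(f"##sequence-region {chrom} 1 {annotation.chrom_lengths[chrom]}\n")
        for g in annotation.genes:
            base = f"{g.chrom}\tfamsurvey\t"
            tail = f"\t.\t{g.strand}\t.\t"
            fh.write(f"{base}gene\t{g.start}\t{g.end}{tail}ID={g.gene_id}\n")
            mid = f"{g.gene_id}.t1"
            fh.write(f"{base}mRNA\t{g.start}\t{g.end}{tail}ID={mid};Parent={g.gene_id}\n")
            for s, e in g.exons:
                fh.write(f"{base}exon\t{s}\t{e}{tail}Parent={mid}\n")
            if g.cds_start is not None:
                if g.strand == "+":
                    cds = [(max(s, g.cds_start), e) for s, e in g.exons
                           if e >= g.cds_start]
                else:
                    cds = [(s, min(e, g.cds_start)) for s, e in g.exons
                           if s <= g.cds_start]
                for s, e in cds:
                    fh.write(f"{base}CDS\t{s}\t{e}{tail}Parent={mid}\n")
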