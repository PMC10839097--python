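"""Assemble per-stage outputs into the survey's report bundle."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

STAGE_FILES = {
    "family": "family.tsv",
    "protparam": "protparam.tsv",
    "kaks": "kaks.tsv",
    "duplication": "duplication.tsv",
    "blocks": "blocks.tsv",
    "distribution": "distribution.tsv",
    "cis_hits": "cis_hits.tsv",
    "cis_summary": "cis_summary.tsv",
    "introns": "introns.tsv",
    "ssrs": "ssrs.tsv",
    "primers": "primers.tsv",
    "expression_bias": "expression_bias.tsv",
    "qpcr_rq": "qpcr_rq.tsv",
    "heatmap_matrix": "heatmap_matrix.tsv",
}

_ID_COLS = {"family": "protein_id", "protparam": "protein_id"}


def _check_universes(outputs: dict[str, pd.DataFrame]) -> None:
    """Stages that share an id column must overlap in ids."""
    keyed = {
        s: set(df[_ID_COLS[s]])
        for s, df in outputs.items()
        if s in _ID_COLS and not df.empty
    }
    names = sorted(keyed)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if keyed[a] and keyed[b] and not keyed[a] & keyed[b]:
                raise ValueError(
                    f"stages {a!r} and {b!r} have disjoint gene universes: "
                    f"e.g. {sorted(keyed[a])[:3]} vs {sorted(keyed[b])[:3]}"
                )


def build_report(
    outputs: dict[str, pd.DataFrame],
    out_dir: str | Path,
    provenance: dict | None = None,
) -> Path:
    """Write every stage table plus a human-readable SUMMARY.md.

    Missing stages appear in the summary as explicitly empty sections.
    Regeneration from the same stage outputs is byte-identical.
    """
    if not outputs:
        raise ValueError("no stage outputs to report")
    _check_universes(outputs)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    for stage, fname in STAGE_FILES.items():
        if stage in outputs:
            df = outputs[stage]
            if stage == "heatmap_matrix":
                df.to_csv(out_dir / fname, sep="\t", index=True,
                          index_label="gene_id", float_format="%.6g")
            else:
                df.to_csv(out_dir / fname, sep="\t", index=False)

    lines = ["# Family survey report", ""]
    if provenance:
        lines.append("## Provenance")
        for k in sorted(provenance):
            lines.append(f"- {k}: {provenance[k]}")
        lines.append("")
    for stage, fname in STAGE_FILES.items():
        lines.append(f"## {stage}")
        if stage in outputs:
            df = outputs[stage]
            lines.append(f"{len(df)} rows -> `{fname}`")
            if stage == "family" and not df.empty:
                counts = df["set_label"].value_counts().to_dict()
                lines.append(
                    "set counts: " + ", ".join(f"{s}={counts.get(s, 0)}" for s in "ABC")
                )
            if stage == "duplication" and not df.empty:
                counts = df["mode"].value_counts().to_dict()
                lines.append(
                    "modes: " + ", ".join(f"{m}={n}" for m, n in sorted(counts.items()))
                )
        else:
            lines.append("(empty: stage not run)")
        lines.append("")
    (out_dir / "SUMMARY.md").write_text("\n".join(lines))
    return out_dir
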