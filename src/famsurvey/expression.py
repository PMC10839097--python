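"""Floral expression-bias classification and qPCR relative quantification.

Bias calls compare a gene's mean abundance between two floral phenotypes
(F-type: long pistil / short stamens; M-type: short pistil / long
stamens) across four developmental stages: replicates are averaged per
(phenotype, stage), stages averaged per phenotype, and the F/M fold
(with a small pseudocount) decides F-biased / M-biased / unbiased. Genes
never reaching the expression floor in any sample are 'not expressed'.

qPCR relative expression uses the 2^-ddCT method: per-sample dCT =
CT_target - CT_reference, ddCT subtracts the calibrator group's mean
dCT, and RQ = 2^-ddCT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PHENOTYPES = ("F", "M")
STAGES = (1, 2, 3, 4)

DEFAULT_MIN_EXPR = 1.0
DEFAULT_FOLD_THRESHOLD = 1.5


@dataclass(frozen=True)
class BiasCall:
    gene_id: str
    call: str  # F_biased | M_biased | unbiased | not_expressed
    mean_f: float
    mean_m: float
    fold: float


@dataclass(frozen=True)
class QpcrRecord:
    sample_id: str
    target_ct: float
    reference_ct: float
    group: str
    calibrator: bool = False

    def __post_init__(self):
        for ct in (self.target_ct, self.reference_ct):
            if not 0 < ct < 45:
                raise ValueError(f"{self.sample_id}: CT {ct} outside (0, 45)")


def _phenotype_means(
    matrix: pd.DataFrame, samples: pd.DataFrame
) -> tuple[pd.Series, pd.Series]:
    """Replicate-averaged per stage, then stage-averaged per phenotype."""
    means = {}
    for pheno in PHENOTYPES:
        stage_means = []
        for stage in STAGES:
            cols = samples.loc[
                (samples["phenotype"] == pheno) & (samples["stage"] == stage),
                "sample",
            ]
            if cols.empty:
                raise ValueError(f"no samples for phenotype {pheno} stage {stage}")
            stage_means.append(matrix[list(cols)].mean(axis=1))
        means[pheno] = pd.concat(stage_means, axis=1).mean(axis=1)
    return means["F"], means["M"]


def classify_expression_bias(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    min_expr: float = DEFAULT_MIN_EXPR,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
) -> list[BiasCall]:
    """Classify every gene as F_biased / M_biased / unbiased / not_expressed.

    ``matrix`` is genes x samples (TPM-like, >= 0); ``samples`` has
    columns sample, phenotype, stage, replicate. A pseudocount of
    min_expr/10 is added to both phenotype means before the fold.
    """
    if (matrix < 0).any().any():
        raise ValueError("expression values must be non-negative")
    mean_f, mean_m = _phenotype_means(matrix, samples)
    pseudo = min_expr / 10.0
    calls = []
    max_per_gene = matrix.max(axis=1)
    for gene in matrix.index:
        mf, mm = float(mean_f[gene]), float(mean_m[gene])
        fold = (mf + pseudo) / (mm + pseudo)
        if max_per_gene[gene] < min_expr:
            call = "not_expressed"
        elif fold >= fold_threshold:
            call = "F_biased"
        elif fold <= 1.0 / fold_threshold:
            call = "M_biased"
        else:
            call = "unbiased"
        calls.append(BiasCall(gene, call, mf, mm, fold))
    return calls


def delta_delta_ct(records: list[QpcrRecord]) -> pd.DataFrame:
    """Per-sample RQ = 2^-ddCT plus per-group mean and sd.

    The calibrator group's mean dCT is the ddCT baseline, so the RQ at
    the calibrator group's mean is exactly 1.
    """
    if not any(r.calibrator for r in records):
        raise ValueError("at least one calibrator sample is required")
    dct = {r.sample_id: r.target_ct - r.reference_ct for r in records}
    cal_mean = float(np.mean([dct[r.sample_id] for r in records if r.calibrator]))
    rows = []
    for r in records:
        ddct = dct[r.sample_id] - cal_mean
        rows.append(
            {
                "sample": r.sample_id,
                "group": r.group,
                "calibrator": r.calibrator,
                "dct": dct[r.sample_id],
                "ddct": ddct,
                "rq": 2.0 ** (-ddct),
            }
        )
    df = pd.DataFrame(rows)
    grp = df.groupby("group")["rq"].agg(["mean", "std"]).rename(
        columns={"mean": "group_mean_rq", "std": "group_sd_rq"}
    )
    return df.merge(grp, on="group")


def export_heatmap_matrix(
    matrix: pd.DataFrame, samples: pd.DataFrame, transform: str = "log2p1_rowz"
) -> pd.DataFrame:
    """Genes x (phenotype, stage) matrix for heatmap rendering.

    Replicates are averaged per (phenotype, stage); values are
    log2(x + 1) then z-scored per gene. Constant genes get all-zero rows.
    """
    if transform != "log2p1_rowz":
        raise ValueError(f"unknown transform {transform!r}")
    cols = {}
    for pheno in PHENOTYPES:
        for stage in STAGES:
            names = samples.loc[
                (samples["phenotype"] == pheno) & (samples["stage"] == stage),
                "sample",
            ]
            cols[f"{pheno}{stage}"] = matrix[list(names)].mean(axis=1)
    out = pd.DataFrame(cols)
    out = np.log2(out + 1.0)
    centered = out.sub(out.mean(axis=1), axis=0)
    sd = out.std(axis=1, ddof=0)
    z = centered.div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)
    return z


def bias_table(calls: list[BiasCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"gene_id": c.gene_id, "call": c.call,
             "mean_f": round(c.mean_f, 4), "mean_m": round(c.mean_m, 4),
             "fold_f_over_m": round(c.fold, 4)}
            for c in calls
        ],
        columns=["gene_id", "call", "mean_f", "mean_m", "fold_f_over_m"],
    )
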