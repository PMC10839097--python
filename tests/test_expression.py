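"""Expression-bias calls, 2^-ddCT quantification, heatmap export."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from famsurvey.expression import (
    QpcrRecord,
    bias_table,
    classify_expression_bias,
    delta_delta_ct,
    export_heatmap_matrix,
)


def tiny_matrix(values_f, values_m):
    """One gene, one replicate per (phenotype, stage)."""
    samples = []
    data = {}
    for pheno, vals in (("F", values_f), ("M", values_m)):
        for stage in (1, 2, 3, 4):
            name = f"{pheno}{stage}r1"
            samples.append({"sample": name, "phenotype": pheno,
                            "stage": stage, "replicate": 1})
            data[name] = [vals[stage - 1]]
    return pd.DataFrame(data, index=["g1"]), pd.DataFrame(samples)


class TestBiasCalls:
    def test_below_floor_not_expressed(self):
        m, s = tiny_matrix([0.2] * 4, [0.2] * 4)
        assert classify_expression_bias(m, s)[0].call == "not_expressed"

    def test_fourfold_f_bias(self):
        m, s = tiny_matrix([20] * 4, [5] * 4)
        call = classify_expression_bias(m, s)[0]
        assert call.call == "F_biased" and call.fold > 1.5

    def test_equal_means_unbiased(self):
        m, s = tiny_matrix([10] * 4, [10] * 4)
        assert classify_expression_bias(m, s)[0].call == "unbiased"

    def test_rescaling_invariance_with_floor(self):
        """Calls are invariant under global rescaling when the expression
        floor scales with the data (the fold rule itself is scale-free)."""
        m, s = tiny_matrix([20, 18, 22, 21], [5, 6, 4, 5])
        base = classify_expression_bias(m, s, min_expr=1.0)[0].call
        scaled = classify_expression_bias(m * 50, s, min_expr=50.0)[0].call
        assert base == scaled == "F_biased"

    def test_planted_split_recovered(self, expression_bundle):
        matrix, samples, _, truth = expression_bundle
        calls = classify_expression_bias(matrix, samples)
        counts = Counter(c.call for c in calls)
        assert counts["F_biased"] == 23
        assert counts["M_biased"] == 15
        assert counts["not_expressed"] == 13
        # diagonal confusion matrix at this noise level
        for c in calls:
            assert c.call == truth.data["labels"][c.gene_id]

    def test_negative_values_rejected(self):
        m, s = tiny_matrix([1] * 4, [1] * 4)
        m.iloc[0, 0] = -1
        with pytest.raises(ValueError, match="non-negative"):
            classify_expression_bias(m, s)


def qrec(sample, tct, rct, group, cal=False):
    return QpcrRecord(sample, tct, rct, group, cal)


class TestDeltaDeltaCt:
    def test_single_calibrator_rq_exactly_one(self):
        recs = [qrec("c1", 25.0, 20.0, "ctrl", cal=True),
                qrec("t1", 24.0, 20.0, "trt")]
        df = delta_delta_ct(recs)
        assert df.loc[df["sample"] == "c1", "rq"].iloc[0] == 1.0

    def test_one_cycle_doubling(self):
        recs = [qrec("c1", 25.0, 20.0, "ctrl", cal=True),
                qrec("t1", 24.0, 20.0, "trt")]
        df = delta_delta_ct(recs)
        assert df.loc[df["sample"] == "t1", "rq"].iloc[0] == pytest.approx(2.0)

    def test_calibrator_group_mean_ddct_zero(self):
        recs = [qrec(f"c{i}", 25.0 + d, 20.0, "ctrl", cal=True)
                for i, d in enumerate((-0.2, 0.0, 0.2))]
        recs.append(qrec("t1", 23.0, 20.0, "trt"))
        df = delta_delta_ct(recs)
        assert df.loc[df["calibrator"], "ddct"].mean() == pytest.approx(0.0, abs=1e-12)

    def test_no_calibrator_error(self):
        with pytest.raises(ValueError, match="calibrator"):
            delta_delta_ct([qrec("a", 25, 20, "x")])

    def test_ct_range_validated(self):
        with pytest.raises(ValueError, match="CT"):
            QpcrRecord("s", 50.0, 20.0, "g")

    def test_planted_fold_recovered(self, expression_bundle):
        _, _, qpcr, truth = expression_bundle
        for gid, grp in qpcr.groupby("gene_id"):
            recs = [
                QpcrRecord(r["sample"], r["target_ct"], r["reference_ct"],
                           r["group"], bool(r["calibrator"]))
                for _, r in grp.iterrows()
            ]
            df = delta_delta_ct(recs)
            mean_f = df.loc[df["group"] == "F", "rq"].mean()
            true = truth.data["qpcr_true_rq_f_vs_m"][gid]
            # 0.1-cycle triplicate noise: 2^(+-0.3) envelope
            assert true * 2**-0.3 < mean_f < true * 2**0.3


class TestHeatmapExport:
    def test_constant_gene_zero_row(self, expression_bundle):
        matrix, samples, _, _ = expression_bundle
        m = matrix.copy()
        m.iloc[0] = 7.0
        z = export_heatmap_matrix(m, samples)
        assert (z.iloc[0] == 0).all()

    def test_rows_are_zscored(self, expression_bundle):
        matrix, samples, _, _ = expression_bundle
        z = export_heatmap_matrix(matrix, samples)
        nonconst = z[(z != 0).any(axis=1)]
        assert np.allclose(nonconst.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(nonconst.std(axis=1, ddof=0), 1, atol=1e-9)

    def test_eight_columns_for_two_phenotypes_four_stages(self, expression_bundle):
        matrix, samples, _, _ = expression_bundle
        z = export_heatmap_matrix(matrix, samples)
        assert list(z.columns) == ["F1", "F2", "F3", "F4", "M1", "M2", "M3", "M4"]


def test_bias_table_columns(expression_bundle):
    matrix, samples, _, _ = expression_bundle
    df = bias_table(classify_expression_bias(matrix, samples))
    assert list(df.columns) == ["gene_id", "call", "mean_f", "mean_m", "fold_f_over_m"]
    assert len(df) == len(matrix)
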