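import numpy as np
import pandas as pd
import pytest

from neurocycle.enrichment import (
    anova_tukey_bh,
    bh_adjust,
    classify_common_circadian,
    classify_group_specific,
    expression_filter,
    flag_candidate_neuropeptide_genes,
    is_expressed,
    pair_significant,
    run_enrichment,
)
from neurocycle.io_formats import GeneModel
from neurocycle.reference_data import common_enrichment_table
from neurocycle.synthetic_data import SimulationConfig, generate_expression

from conftest import build_matrix


def _matrix_with_set_means(set1_mean, set2_mean):
    vals = np.concatenate([np.full(6, set1_mean), np.full(6, set2_mean)])
    return build_matrix({"LNv": vals[None, :]})


class TestThresholds:
    @pytest.mark.parametrize(
        "m1,m2,expected",
        [(12, 11, True), (12, 9, False), (10, 10, True)],
    )
    def test_expression_filter_requires_both_replicate_sets(self, m1, m2, expected):
        m = _matrix_with_set_means(m1, m2)
        assert expression_filter(m, "LNv").iloc[0] is np.bool_(expected)

    @pytest.mark.parametrize("mean,expected", [(5.0, False), (5.1, True), (0.0, False)])
    def test_is_expressed_strictly_above_five(self, mean, expected):
        m = build_matrix({"LNv": np.full((1, 12), mean)})
        assert is_expressed(m, "LNv").iloc[0] is np.bool_(expected)


class TestStatisticsChain:
    def test_bh_hand_example(self):
        # step-up by hand: q_i = min_j>=i p_(j) * m / j -> all 0.04
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_bh_is_monotone_in_raw_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_null_type_one_error_near_nominal(self):
        cfg = SimulationConfig(n_genes=600, seed=13, frac_cyclers=0.0,
                               frac_group_restricted=0.0, frac_low_expression=0.0)
        matrix, _ = generate_expression(cfg)
        stats_table = anova_tukey_bh(matrix, prescreen_fold=None)
        frac = (stats_table["anova_p"] < 0.05).mean()
        assert 0.02 <= frac <= 0.09

    def test_shifted_group_flags_only_its_tukey_pairs(self):
        rng = np.random.default_rng(21)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            base = {g: 100 + rng.normal(0, 2, size=(1, 12)) for g in
                    ["LNv", "LNd", "DN1", "TH"]}
            base["LNv"] += 20  # 10 SD shift
            m = build_matrix(base)
            st = anova_tukey_bh(m, prescreen_fold=None)
            for pair, col in {
                ("LNv", "LNd"): True, ("LNv", "DN1"): True, ("LNv", "TH"): True,
                ("LNd", "DN1"): False, ("LNd", "TH"): False, ("DN1", "TH"): False,
            }.items():
                p = st[f"tukey_p:{pair[0]}|{pair[1]}"].iloc[0]
                assert (p < 0.05) == col, (seed, pair, p)

    def test_degenerate_zero_variance_reported_na(self):
        m = build_matrix({g: np.full((1, 12), 10.0) for g in
                          ["LNv", "LNd", "DN1", "TH"]})
        st = anova_tukey_bh(m, prescreen_fold=None)
        assert st["anova_p"].isna().all()
        assert st["bh_q"].isna().all()


class TestClassRules:
    def test_published_rows_classified_common(self):
        tab = common_enrichment_table()
        kept = classify_common_circadian(tab)
        # all-significant row enriched in all three groups
        assert "cry" in kept
        # enriched via only LNv + DN1 (LNd cell below threshold)
        assert "Dh31" in kept
        # LR in one group still qualifies via the other two
        assert "per" in kept and "CG6912" in kept

    def test_single_qualifying_group_rejected(self):
        tab = pd.DataFrame(
            {"LNv": [np.log2(8)], "LNd": [-1.0], "DN1": [-1.0]},
            index=["distractor"],
        )
        assert len(classify_common_circadian(tab)) == 0

    def test_lr_cells_never_qualify(self):
        tab = pd.DataFrame(
            {"LNv": [np.log2(8)], "LNd": [np.nan], "DN1": [1.0]},
            index=["g"],
        )
        assert len(classify_common_circadian(tab)) == 0

    def test_group_specific_fold_rules(self):
        idx = ["hit", "weak_second"]
        means = pd.DataFrame(
            {"LNv": [100.0, 100.0], "LNd": [15.0, 15.0], "DN1": [40.0, 60.0]},
            index=idx,
        )
        expressed = pd.DataFrame(True, index=idx, columns=means.columns)
        sig = {pair: pd.Series(True, index=idx) for pair in
               [("LNv", "LNd"), ("LNv", "DN1"), ("LNd", "DN1")]}
        labels = classify_group_specific(means, expressed, sig)
        assert labels["hit"] == "LNv"  # 6.7x and 2.5x
        assert pd.isna(labels["weak_second"])  # only 1.67x vs DN1

    def test_pdf_like_pattern_is_lnv_specific(self):
        means = pd.DataFrame({"LNv": [500.0], "LNd": [0.0], "DN1": [0.0]},
                             index=["pdf_like"])
        expressed = pd.DataFrame([[True, False, False]], index=["pdf_like"],
                                 columns=means.columns)
        sig = {pair: pd.Series(True, index=["pdf_like"]) for pair in
               [("LNv", "LNd"), ("LNv", "DN1"), ("LNd", "DN1")]}
        assert classify_group_specific(means, expressed, sig)["pdf_like"] == "LNv"

    def test_insignificant_pairs_block_label(self):
        means = pd.DataFrame({"LNv": [100.0], "LNd": [10.0], "DN1": [10.0]},
                             index=["g"])
        expressed = pd.DataFrame([[True, True, True]], index=["g"],
                                 columns=means.columns)
        sig = {("LNv", "LNd"): pd.Series(True, index=["g"]),
               ("LNv", "DN1"): pd.Series(False, index=["g"]),
               ("LNd", "DN1"): pd.Series(True, index=["g"])}
        assert classify_group_specific(means, expressed, sig).isna().all()


class TestNeuropeptideFlag:
    MODELS = [
        GeneModel("short_intronless", "chr1", "+", (((100, 600),),)),
        GeneModel("two_exon", "chr1", "+", (((100, 400), (600, 900)),)),
        GeneModel("long_intronless", "chr1", "+", (((1000, 5000),),)),
    ]

    def test_structural_prefilter(self):
        enriched = {m.gene_id for m in self.MODELS}
        out = flag_candidate_neuropeptide_genes(
            self.MODELS, enriched, max_length_bp=2000, require_intronless=True
        )
        assert out == {"short_intronless"}

    def test_intron_requirement_optional(self):
        enriched = {m.gene_id for m in self.MODELS}
        out = flag_candidate_neuropeptide_genes(
            self.MODELS, enriched, max_length_bp=2000, require_intronless=False
        )
        assert out == {"short_intronless", "two_exon"}

    def test_unenriched_never_flagged(self):
        out = flag_candidate_neuropeptide_genes(self.MODELS, set(), 2000, True)
        assert out == set()


class TestPipelineProperties:
    def test_classification_invariant_under_column_permutation(self):
        cfg = SimulationConfig(n_genes=120, seed=17, frac_cyclers=0.0)
        matrix, _ = generate_expression(cfg)
        out1 = run_enrichment(matrix)

        rng = np.random.default_rng(0)
        perm = rng.permutation(len(matrix.samples))
        from neurocycle.io_formats import ExpressionMatrix

        shuffled = ExpressionMatrix(
            matrix.values.iloc[:, perm], [matrix.samples[i] for i in perm]
        )
        out2 = run_enrichment(shuffled)
        assert list(out1.common_circadian) == list(out2.common_circadian)
        assert out1.specific.fillna("-").equals(out2.specific.fillna("-"))

    def test_pair_significance_requires_both_gates(self):
        st = pd.DataFrame(
            {"bh_q": [0.01, 0.2, 0.01], "tukey_p:LNv|TH": [0.01, 0.01, 0.2]}
        )
        sig = pair_significant(st, "LNv", "TH")
        assert sig.tolist() == [True, False, False]
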