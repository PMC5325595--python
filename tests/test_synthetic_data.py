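import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neurocycle.io_formats import DEFAULT_ZT_GRIDS
from neurocycle.quantify3p import build_windows
from neurocycle.synthetic_data import (
    GroupTruth,
    SimulationConfig,
    TruthRecord,
    cosine_mean_model,
    generate_expression,
    generate_gene_models,
    generate_ls_ratio_table,
    generate_reads,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"frac_cyclers": 1.5},
            {"amplitude_fold": 0.5},
            {"library_size": 0},
            {"zt_grids": {"LNv": (2.0, 6.0, 10.0)}},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestMeanModel:
    def test_cosine_closed_form(self):
        t = np.linspace(0, 24, 4801)
        m = cosine_mean_model(baseline=50.0, amplitude_fold=4.0, phase=8.0, t=t)
        assert m.max() / m.min() == pytest.approx(4.0, abs=1e-6)
        assert m.mean() == pytest.approx(50.0, rel=1e-3)
        assert t[np.argmax(m)] == pytest.approx(8.0, abs=0.01)

    def test_amplitude_one_is_flat(self):
        m = cosine_mean_model(10.0, 1.0, 3.0, np.arange(0, 24, 4.0))
        np.testing.assert_allclose(m, 10.0)


class TestGenerateExpression:
    def test_determinism(self):
        cfg = SimulationConfig(n_genes=50, seed=42)
        m1, t1 = generate_expression(cfg)
        m2, t2 = generate_expression(cfg)
        assert m1.values.equals(m2.values)
        from neurocycle.synthetic_data import truth_to_frame

        pd_frame1, pd_frame2 = truth_to_frame(t1), truth_to_frame(t2)
        assert pd_frame1.equals(pd_frame2)
        m3, _ = generate_expression(SimulationConfig(n_genes=50, seed=43))
        assert not m1.values.equals(m3.values)

    def test_default_design_matches_study(self):
        cfg = SimulationConfig(n_genes=10)
        matrix, truth = generate_expression(cfg)
        assert matrix.groups == ["LNv", "LNd", "DN1", "TH"]
        assert matrix.values.shape == (10, 4 * 2 * 6)
        for g in matrix.groups:
            matrix.require_complete_grid(g)
        assert matrix.zt_grid("DN1") == tuple(np.array(matrix.zt_grid("LNv")) + 1)
        assert {t.gene_id for t in truth} == set(matrix.genes)

    def test_noiseless_noncyclers_are_constant(self):
        cfg = SimulationConfig(n_genes=40, seed=3, frac_cyclers=0.0, dispersion=0.0)
        matrix, _ = generate_expression(cfg)
        for g in matrix.groups:
            vals = matrix.group_values(g).to_numpy()
            np.testing.assert_allclose(
                vals, np.repeat(vals[:, :1], vals.shape[1], axis=1), rtol=1e-9
            )

    def test_noiseless_cycler_peaks_at_nearest_gridpoint(self):
        cfg = SimulationConfig(n_genes=400, seed=9, frac_cyclers=0.05,
                               dispersion=0.0)
        matrix, truth = generate_expression(cfg)
        checked = 0
        for rec in truth:
            t = rec.groups["LNv"]
            if not t.is_cycler or t.baseline < 20:
                continue
            vals, zts, _ = matrix.series(rec.gene_id, "LNv")
            uz = np.unique(zts)
            per_zt = np.array([vals[zts == z].mean() for z in uz])
            grid_dist = np.abs((uz - t.phase + 12) % 24 - 12)
            assert uz[np.argmax(per_zt)] == uz[np.argmin(grid_dist)]
            # peak/trough ~ amplitude fold; renormalization across the
            # library perturbs the ratio only at the percent level
            assert per_zt.max() / per_zt.min() == pytest.approx(
                cosine_mean_model(1, 4, t.phase, uz).max()
                / cosine_mean_model(1, 4, t.phase, uz).min(),
                rel=0.05,
            )
            checked += 1
        assert checked >= 3

    def test_rpm_columns_sum_to_one_million(self):
        cfg = SimulationConfig(n_genes=100, seed=5)
        matrix, _ = generate_expression(cfg)
        np.testing.assert_allclose(matrix.values.sum(axis=0), 1e6, atol=1e-3)

    def test_unexpressed_truth_below_threshold(self):
        cfg = SimulationConfig(n_genes=200, seed=6, frac_group_restricted=0.5)
        _, truth = generate_expression(cfg)
        saw_restricted = False
        for rec in truth:
            for t in rec.groups.values():
                if not t.expressed:
                    saw_restricted = True
                    assert t.baseline < 5.0
                if not t.is_cycler:
                    assert t.amplitude_fold == 1.0
        assert saw_restricted


class TestGenerateReads:
    def test_sharp_decay_concentrates_reads_in_terminal_windows(self):
        models = generate_gene_models(40, rng=1)
        cfg = SimulationConfig(n_genes=40, seed=1, library_size=40_000,
                               three_prime_decay_bp=20.0)
        targets = {m.gene_id: 100.0 for m in models}
        reads = generate_reads(models, targets, cfg)
        # brute-force oracle: enumerate every genomic position within 300
        # transcript-bases of any isoform 3' end
        in_window = {m.gene_id: set() for m in models}
        by_key = {}
        for m in models:
            for exons in m.isoforms:
                flat = [p for s, e in exons for p in range(s, e)]
                tail = flat[-300:] if m.strand == "+" else flat[:300]
                in_window[m.gene_id].update(tail)
            for pos_set in (in_window[m.gene_id],):
                by_key[(m.chrom, m.strand, m.gene_id)] = pos_set
        exonic = {}
        for m in models:
            exonic[m.gene_id] = {
                p for exons in m.isoforms for s, e in exons for p in range(s, e)
            }
        pos_by_gene: dict[str, list[int]] = {m.gene_id: [] for m in models}
        model_by_loc = {(m.chrom, m.strand): m for m in models}
        # genes don't overlap in these models: locate by exon membership
        for r in reads:
            hit = [m.gene_id for m in models
                   if m.chrom == r.chrom and m.strand == r.strand
                   and r.pos in exonic[m.gene_id]]
            assert len(hit) == 1, "read outside every gene's exons"
            pos_by_gene[hit[0]].append(r.pos)
        fracs = []
        for m in models:
            positions = pos_by_gene[m.gene_id]
            if len(positions) < 50:
                continue
            frac = np.mean([p in in_window[m.gene_id] for p in positions])
            fracs.append(frac)
        assert len(fracs) >= 20
        assert np.mean(fracs) >= 0.95

    def test_zero_target_yields_zero_reads(self):
        models = generate_gene_models(3, rng=2)
        cfg = SimulationConfig(n_genes=3, seed=2, library_size=1000)
        targets = {models[0].gene_id: 0.0, models[1].gene_id: 10.0,
                   models[2].gene_id: 10.0}
        reads = generate_reads(models, targets, cfg)
        zero_exons = {p for exons in models[0].isoforms
                      for s, e in exons for p in range(s, e)}
        assert not any(r.pos in zero_exons and r.strand == models[0].strand
                       for r in reads)
        assert len(reads) == 1000

    def test_missing_model_reported(self):
        models = generate_gene_models(2, rng=3)
        cfg = SimulationConfig(n_genes=2, seed=3)
        with pytest.raises(ValueError, match="ghost"):
            generate_reads(models, {"ghost": 5.0}, cfg)


def _truth_with_lnv_phases(phases):
    recs = []
    for i, ph in enumerate(phases):
        recs.append(
            TruthRecord(
                gene_id=f"g{i}",
                groups={"LNv": GroupTruth(expressed=True, is_cycler=True,
                                          phase=float(ph), amplitude_fold=4.0,
                                          baseline=100.0)},
            )
        )
    return recs


class TestLsRatioTable:
    def test_ratio_semantics_morning_below_one(self):
        # programmed effect: morning-phase cyclers biased toward s-LNvs
        truth = _truth_with_lnv_phases([5.0] * 200 + [16.0] * 200)
        cfg = SimulationConfig(n_genes=400, seed=0)
        tab = generate_ls_ratio_table(truth, cfg, effect_log2=2.0, rng=7)
        assert (tab["ls_ratio"] > 0).all()
        logr = np.log2(tab["ls_ratio"].to_numpy())
        assert logr[:200].mean() < 0 < logr[200:].mean()

    def test_zero_effect_identical_distributions(self):
        truth = _truth_with_lnv_phases([5.0] * 300 + [16.0] * 300)
        cfg = SimulationConfig(n_genes=600, seed=0)
        rejections = 0
        for seed in range(100):
            tab = generate_ls_ratio_table(truth, cfg, effect_log2=0.0, rng=seed)
            logr = np.log2(tab["ls_ratio"].to_numpy())
            p = stats.ttest_ind(logr[:300], logr[300:], equal_var=False).pvalue
            rejections += p < 0.05
        assert rejections <= 12  # ~5% nominal

    def test_programmed_shift_detected(self):
        # 1 log2-unit shift, 50 genes per bin: detected at p < 0.01 in
        # >= 95% of seeds (Monte-Carlo over 200 seeds)
        truth = _truth_with_lnv_phases([5.0] * 50 + [16.0] * 50)
        cfg = SimulationConfig(n_genes=100, seed=0)
        hits = 0
        for seed in range(200):
            tab = generate_ls_ratio_table(truth, cfg, effect_log2=1.0,
                                          sd_log2=0.8, rng=seed)
            logr = np.log2(tab["ls_ratio"].to_numpy())
            p = stats.ttest_ind(logr[:50], logr[50:], equal_var=False).pvalue
            hits += p < 0.01
        assert hits >= 190
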