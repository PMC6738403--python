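"""Differential expression: size factors, dispersions, Wald test, BH,
independent filtering, rlog, clustering diagnostic, subsampling curve."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from t2dbrain import de as de_mod
from t2dbrain.de import (
    bh_adjust,
    cluster_status_test,
    estimate_dispersions,
    independent_filter,
    nb_wald_test,
    rlog_transform,
    run_de,
    size_factors,
    subsample_dag_curve,
)


class TestSizeFactors:
    def test_hand_computed_median_of_ratios(self):
        K = np.array([[2.0, 4.0], [10.0, 20.0]])
        s = size_factors(K)
        assert s == pytest.approx([0.7071, 1.4142], abs=1e-4)

    def test_identical_columns_give_unit_factors(self):
        K = np.tile(np.array([[3.0], [7.0], [11.0]]), (1, 4))
        assert size_factors(K) == pytest.approx([1, 1, 1, 1])

    def test_single_sample_factor_one(self):
        assert size_factors(np.array([[5.0], [9.0]])) == pytest.approx([1.0])

    def test_no_all_positive_gene_raises(self):
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(np.array([[0.0, 3.0], [4.0, 0.0]]))


class TestDispersions:
    def test_poisson_counts_shrink_to_tiny_alpha(self, rng):
        mu = rng.lognormal(4, 1, 200)
        K = rng.poisson(mu[:, None], size=(200, 100)).astype(float)
        dm = estimate_dispersions(K, np.ones(100), np.ones((100, 1)))
        assert np.nanmedian(dm.final) <= 0.01

    def test_nb_alpha_recovered(self, rng):
        alpha = 0.2
        mu = rng.lognormal(4, 1, 200)
        lam = rng.gamma(1 / alpha, alpha * mu[:, None], size=(200, 100))
        K = rng.poisson(lam).astype(float)
        dm = estimate_dispersions(K, np.ones(100), np.ones((100, 1)))
        assert 0.1 <= np.nanmedian(dm.genewise) <= 0.4

    def test_all_zero_gene_flagged(self):
        K = np.array([[0.0] * 6, [5.0] * 6, [3.0] * 6, [8.0] * 6])
        dm = estimate_dispersions(K, np.ones(6), np.ones((6, 1)))
        assert dm.flagged[0]
        assert np.isnan(dm.final[0])
        assert np.isfinite(dm.final[1:]).all()


class TestWald:
    def test_null_type_one_error_calibrated(self, null_cohort):
        counts, samples, _ = null_cohort
        st = samples["status"].to_numpy(float)
        X = np.column_stack([np.ones(st.size), st])
        res = run_de(counts, X)
        frac = float(np.nanmean(res["wald_p"] < 0.05))
        assert 0.02 <= frac <= 0.08

    def test_planted_lfc_recovered(self, small_cohort):
        counts, samples, truth = small_cohort
        st = samples["status"].to_numpy(float)
        X = np.column_stack([np.ones(st.size), st])
        res = run_de(counts, X)
        de_genes = sorted(truth.de_genes)
        signed = res.loc[de_genes, "log2fc"].to_numpy() * np.sign(
            [truth.effect_sizes[g] for g in de_genes])
        assert 0.7 <= np.median(signed) <= 1.3

    def test_constant_gene_has_no_fold_change(self):
        rng = np.random.default_rng(0)
        K = np.vstack([np.full(20, 50.0), rng.poisson(100, (5, 20))])
        st = np.array([1.0] * 10 + [0.0] * 10)
        X = np.column_stack([np.ones(20), st])
        disp = np.full(6, 1e-8)
        res = nb_wald_test(K, np.ones(20), disp, X)
        assert abs(res["log2fc"].iloc[0]) < 1e-6

    def test_rank_deficient_design_rejected(self, null_cohort):
        counts, samples, _ = null_cohort
        st = samples["status"].to_numpy(float)
        X = np.column_stack([np.ones(st.size), st, st])
        with pytest.raises(ValueError, match="rank deficient"):
            nb_wald_test(counts.to_numpy()[:5], np.ones(st.size), np.full(5, 0.1), X)

    def test_direction_consistent_with_sign(self, small_cohort):
        counts, samples, _ = small_cohort
        st = samples["status"].to_numpy(float)
        X = np.column_stack([np.ones(st.size), st])
        res = run_de(counts, X)
        ok = res["log2fc"].notna()
        assert (res.loc[ok & (res["log2fc"] > 0), "direction"] == "up").all()
        assert (res.loc[ok & (res["log2fc"] < 0), "direction"] == "down").all()


class TestBH:
    def test_step_up_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37]) == pytest.approx([0.37])

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_matches_exhaustive_step_up_oracle(self, rng):
        def oracle(p):
            p = np.asarray(p)
            n = len(p)
            order = np.argsort(p)
            adj = np.empty(n)
            prev = 1.0
            for rank in range(n, 0, -1):
                i = order[rank - 1]
                prev = min(prev, p[i] * n / rank)
                adj[i] = prev
            return adj

        for _ in range(5):
            p = rng.random(rng.integers(1, 1000))
            assert bh_adjust(p) == pytest.approx(oracle(p), abs=1e-12)

    def test_padj_at_least_p(self, rng):
        p = rng.random(200)
        assert (bh_adjust(p) >= p - 1e-12).all()


class TestIndependentFilter:
    @staticmethod
    def _oracle_theta(base, p, alpha):
        best_th, best_rej = 0.0, -1
        for th in np.round(np.arange(0.0, 0.951, 0.01), 4):
            cut = np.quantile(base, th)
            mask = base >= cut
            padj = bh_adjust(np.where(mask, p, np.nan))
            rej = int(np.nansum(padj < alpha))
            if rej > best_rej:
                best_rej, best_th = rej, th
        return best_th

    def test_uniform_p_high_counts_choose_theta_zero(self, rng):
        res = pd.DataFrame({"base_mean": rng.uniform(100, 200, 50),
                            "wald_p": rng.random(50)})
        out = independent_filter(res)
        assert out.attrs["filter_theta"] == 0.0

    def test_filtering_never_loses_rejections(self, rng):
        # low-count genes carry pure-noise p; high-count genes carry signal
        base = np.concatenate([rng.uniform(0, 1, 100), rng.uniform(100, 200, 100)])
        p = np.concatenate([rng.random(100), rng.random(100) * 1e-4])
        res = pd.DataFrame({"base_mean": base, "wald_p": p})
        out = independent_filter(res, alpha=0.05)
        rej_chosen = int((out["padj"] < 0.05).sum())
        rej_nofilter = int((bh_adjust(p) < 0.05).sum())
        assert rej_chosen >= rej_nofilter

    def test_ten_gene_fixture_matches_scan_oracle(self):
        base = np.array([0.5, 1.0, 2.0, 3.0, 150.0, 160.0, 170.0, 180.0, 190.0, 200.0])
        p = np.array([0.9, 0.8, 0.7, 0.6, 1e-4, 2e-4, 5e-3, 0.2, 0.01, 0.03])
        res = pd.DataFrame({"base_mean": base, "wald_p": p})
        out = independent_filter(res, alpha=0.05)
        assert out.attrs["filter_theta"] == self._oracle_theta(base, p, 0.05)


class TestRlog:
    def test_zero_count_maps_to_zero(self):
        assert rlog_transform(np.array([[0.0]]), np.array([1.0]))[0, 0] == 0.0

    def test_log2_of_four(self):
        assert rlog_transform(np.array([[3.0]]), np.array([1.0]))[0, 0] == pytest.approx(2.0)

    def test_scale_invariance_and_monotonicity(self, rng):
        K = rng.poisson(50, (20, 6)).astype(float)
        s = rng.uniform(0.5, 2.0, 6)
        a = rlog_transform(K, s)
        b = rlog_transform(2 * K, 2 * s)
        assert np.allclose(a, b)
        K2 = K.copy()
        K2[0, 0] += 10
        assert rlog_transform(K2, s)[0, 0] > a[0, 0]


class TestClusterStatus:
    def test_perfect_separation_gives_extreme_table(self, rng):
        # two sample groups with disjoint expression programs, aligned w/ status
        Y = rng.normal(0, 0.1, (50, 16))
        Y[:25, :8] += 5.0
        Y[25:, 8:] += 5.0
        status = np.array([1] * 8 + [0] * 8)
        labels, p = cluster_status_test(Y, status)
        tab = pd.crosstab(labels, status).to_numpy()
        assert sorted(tab.ravel(), reverse=True)[:2] == [8, 8]  # diagonal table
        assert p < 1e-3

    def test_fisher_two_sided_hand_value(self):
        # the 2x2 table (4,0;0,4) has exact two-sided p = 2/70
        _, pval = stats.fisher_exact([[4, 0], [0, 4]], alternative="two-sided")
        assert pval == pytest.approx(2 / 70)
        # and the full operation reproduces it on data realising that table
        rng = np.random.default_rng(1)
        Y = rng.normal(0, 0.05, (30, 8))
        Y[:15, :4] += 3.0
        Y[15:, 4:] += 3.0
        status = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        _, p = cluster_status_test(Y, status)
        assert p == pytest.approx(2 / 70)

    def test_requires_two_per_group(self):
        with pytest.raises(ValueError):
            cluster_status_test(np.random.default_rng(0).normal(size=(5, 4)),
                                np.array([1, 0, 0, 0]))


class TestSubsampleCurve:
    def test_deterministic_with_seed(self, small_cohort):
        counts, samples, _ = small_cohort
        a = subsample_dag_curve(counts, samples, min_cases=8, step_cases=5,
                                n_boot=1, seed=3)
        b = subsample_dag_curve(counts, samples, min_cases=8, step_cases=5,
                                n_boot=1, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_null_cohort_has_near_zero_discoveries(self, null_cohort):
        # BH alone rejects ~0 genes under the global null; the argmax scan of
        # the independent filter can add a handful, so the bound is 1% of genes
        counts, samples, _ = null_cohort
        tab = subsample_dag_curve(counts, samples, min_cases=10, step_cases=10,
                                  n_boot=3, seed=4)
        assert (tab["mean_dags"] <= 0.01 * counts.shape[0]).all()

    def test_power_grows_with_size(self, small_cohort):
        counts, samples, _ = small_cohort
        tab = subsample_dag_curve(counts, samples, min_cases=5, step_cases=5,
                                  n_boot=5, seed=5)
        assert len(tab) >= 3
        rho = stats.spearmanr(tab["n_cases"], tab["mean_dags"]).statistic
        assert rho > 0

    def test_oversized_request_truncated(self, null_cohort):
        counts, samples, _ = null_cohort
        tab = subsample_dag_curve(counts, samples, min_cases=500, step_cases=5,
                                  n_boot=1, seed=6)
        assert len(tab) == 1


class TestReferenceCrossCheck:
    def test_agrees_with_reference_nb_glm_implementation(self):
        """Independent route: the reference DESeq2-style implementation
        (pydeseq2) run on the same counts gives the same size factors,
        near-identical fold changes and strongly concordant p-values."""
        import t2dbrain as tb
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        cfg = tb.CohortConfig(n_genes=300, n_cases=15, n_controls=30,
                              n_modules=0, module_size=0, de_fraction=0.2,
                              lfc=1.0, de_in_target_module=False, seed=77)
        counts, samples, _ = tb.generate_cohort(cfg)
        st = samples["status"].to_numpy(float)
        X = np.column_stack([np.ones(st.size), st])
        s = size_factors(counts)
        disp = estimate_dispersions(counts, s, X)
        res = nb_wald_test(counts, s, disp, X)

        meta = pd.DataFrame({"condition": np.where(st == 1, "B", "A")},
                            index=counts.columns)
        dds = DeseqDataSet(counts=counts.T, metadata=meta,
                           design="~condition", quiet=True)
        dds.deseq2()
        stat = DeseqStats(dds, contrast=["condition", "B", "A"], quiet=True)
        stat.summary()
        ref = stat.results_df

        assert np.abs(dds.obs["size_factors"].to_numpy() - s).max() < 1e-8
        assert (res["log2fc"] - ref["log2FoldChange"]).abs().median() < 0.05
        ok = res["wald_p"].notna() & ref["pvalue"].notna()
        r = np.corrcoef(-np.log10(res.loc[ok, "wald_p"].clip(lower=1e-30)),
                        -np.log10(ref.loc[ok, "pvalue"].clip(lower=1e-30)))[0, 1]
        assert r > 0.99
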