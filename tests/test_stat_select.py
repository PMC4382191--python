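"""Unit and property tests for the statistical selection stage."""
import math
import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bicrules.datatypes import LabeledMatrix, PipelineConfig
from bicrules.simulate import simulate_two_class
from bicrules.stat_select import (
    _variance_table,
    bayes_t,
    jarque_bera,
    limma_moderated_t,
    partition_by_normality,
    pearson_class_corr,
    permuted_t,
    sam_stat,
    select_genes,
    t_test,
    variance_filter,
    welch_t,
    wilcoxon_ranksum,
    zscore_normalize,
)


def _matrix(values: np.ndarray, n1: int, n2: int) -> LabeledMatrix:
    cols = [f"E{i}" for i in range(n1)] + [f"C{i}" for i in range(n2)]
    genes = [f"G{i}" for i in range(values.shape[0])]
    labels = pd.Series(["d"] * n1 + ["c"] * n2, index=cols)
    return LabeledMatrix(pd.DataFrame(values, index=genes, columns=cols), labels, ("d", "c"))


# ---------------------------------------------------------------------------
# variance filter & normalization
# ---------------------------------------------------------------------------

class TestVarianceFilter:
    def test_zero_quantile_is_identity(self):
        m = _matrix(np.random.default_rng(0).normal(size=(10, 8)), 4, 4)
        assert variance_filter(m, 0.0) is m

    def test_constant_gene_removed_first(self):
        vals = np.random.default_rng(0).normal(size=(10, 8))
        vals[3] = 5.0
        m = _matrix(vals, 4, 4)
        out = variance_filter(m, 0.1)
        assert "G3" not in out.gene_ids

    def test_median_cut_halves_gene_count(self):
        # oracle: direct variance sort
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(100, 10)) * rng.uniform(0.1, 5, size=(100, 1))
        m = _matrix(vals, 5, 5)
        out = variance_filter(m, 0.5)
        variances = np.var(vals, axis=1, ddof=1)
        expected = int((variances >= np.quantile(variances, 0.5)).sum())
        assert len(out.gene_ids) == expected == 50
        # survivor order preserved
        assert out.gene_ids == [g for g in m.gene_ids if g in set(out.gene_ids)]


class TestZscore:
    def test_simple_row(self):
        m = _matrix(np.array([[1.0, 2.0, 3.0]]), 2, 1)
        out = zscore_normalize(m)
        np.testing.assert_allclose(out.values.iloc[0].to_numpy(), [-1, 0, 1])

    def test_mean_zero_sd_one(self):
        m = _matrix(np.random.default_rng(2).normal(3, 7, size=(20, 12)), 6, 6)
        out = zscore_normalize(m)
        assert np.abs(out.values.mean(axis=1)).max() < 1e-10
        np.testing.assert_allclose(out.values.std(axis=1, ddof=1), 1.0)

    def test_constant_gene_raises(self):
        vals = np.random.default_rng(0).normal(size=(3, 6))
        vals[1] = 2.0
        with pytest.raises(ValueError, match="G1"):
            zscore_normalize(_matrix(vals, 3, 3))


# ---------------------------------------------------------------------------
# Jarque-Bera and the normality partition
# ---------------------------------------------------------------------------

class TestJarqueBera:
    def test_hand_value(self):
        # direct transcription: n=5, S=0, K=1.7 -> JB = 5/6 * (1.3^2/4)
        res = jarque_bera(np.array([-2.0, -1.0, 0.0, 1.0, 2.0]))
        assert res.statistic == pytest.approx(5 / 6 * (1.3**2 / 4))

    def test_matches_scipy_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(size=rng.integers(5, 60))
            mine = jarque_bera(x)
            ref = stats.jarque_bera(x)
            assert mine.statistic == pytest.approx(ref.statistic, rel=1e-12)
            assert mine.pvalue == pytest.approx(ref.pvalue, rel=1e-12)

    def test_level_on_large_normal_samples(self):
        rng = np.random.default_rng(4)
        hits = sum(
            jarque_bera(rng.normal(size=5000)).pvalue > 0.05 for _ in range(100)
        )
        assert hits >= 90

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            jarque_bera(np.array([1.0, 2.0, 3.0]))


class TestNormalityPartition:
    def test_gaussian_genes_mostly_normal(self):
        m = _matrix(np.random.default_rng(5).normal(size=(60, 40)), 20, 20)
        normal, _ = partition_by_normality(zscore_normalize(m), 0.05)
        assert normal is not None and len(normal.gene_ids) >= 54

    def test_exponential_genes_mostly_nonnormal(self):
        m = _matrix(np.random.default_rng(6).exponential(size=(60, 50)), 25, 25)
        _, nonnormal = partition_by_normality(zscore_normalize(m), 0.05)
        assert nonnormal is not None and len(nonnormal.gene_ids) > 30

    def test_alpha_zero_sends_all_to_normal(self):
        m = _matrix(np.random.default_rng(7).exponential(size=(10, 30)), 15, 15)
        normal, nonnormal = partition_by_normality(zscore_normalize(m), 1e-300)
        assert nonnormal is None or len(nonnormal.gene_ids) < 10
        # partition is exhaustive and disjoint
        n = len(normal.gene_ids) if normal else 0
        nn = len(nonnormal.gene_ids) if nonnormal else 0
        assert n + nn == 10


# ---------------------------------------------------------------------------
# the two-sample tests
# ---------------------------------------------------------------------------

class TestPooledT:
    def test_identical_groups(self):
        res = t_test([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0 and res.pvalue == 1 and res.direction is None

    def test_hand_value(self):
        res = t_test([1, 2, 3], [4, 5, 6])
        assert res.statistic == pytest.approx(-3.6742346141747673)
        assert res.pvalue == pytest.approx(2 * stats.t.sf(3.6742346141747673, 4))
        assert res.direction == "down"

    def test_scale_invariance(self):
        a, b = np.array([1.0, 2, 3, 5]), np.array([4.0, 5, 6])
        assert t_test(a, b).statistic == pytest.approx(t_test(10 * a, 10 * b).statistic)

    def test_matches_scipy(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            a, b = rng.normal(size=9), rng.normal(size=13)
            mine = t_test(a, b)
            ref = stats.ttest_ind(a, b)
            assert mine.statistic == pytest.approx(ref.statistic)
            assert mine.pvalue == pytest.approx(ref.pvalue)


class TestWelch:
    def test_equal_variances_fall_back_to_pooled(self):
        a = np.array([1.0, 2, 3, 4])
        b = np.array([2.0, 3, 4, 5])
        assert welch_t(a, b).statistic == pytest.approx(t_test(a, b).statistic)

    def test_hand_value_unequal(self):
        # direct transcription: zero variance vs variance 2
        res = welch_t([0.0, 0.0, 0.0, 0.0], [1.0, 3.0])
        assert res.statistic == pytest.approx(-2.0)

    def test_identical_groups(self):
        assert welch_t([1, 2, 3], [1, 2, 3]).statistic == 0

    def test_matches_scipy_when_unequal(self):
        rng = np.random.default_rng(9)
        hit = 0
        for _ in range(50):
            a, b = rng.normal(size=8), rng.normal(scale=6, size=10)
            mine = welch_t(a, b)
            ref = stats.ttest_ind(a, b, equal_var=False)
            if mine.statistic == pytest.approx(ref.statistic):
                hit += 1
                assert mine.pvalue == pytest.approx(ref.pvalue)
        assert hit > 30  # variance pretest routes most 1:36-variance pairs to Welch


class TestBayesT:
    def test_zero_prior_df_equals_pooled_t(self):
        rng = np.random.default_rng(10)
        a, b = rng.normal(size=6), rng.normal(size=7)
        table = pd.DataFrame({"mean": [0.0], "variance": [4.0]}, index=["G0"])
        res = bayes_t(a, b, prior_df=0, neighborhood=1, all_gene_variances=table)
        assert res.statistic == pytest.approx(t_test(a, b).statistic)

    def test_large_prior_df_pins_variance_to_prior(self):
        a = np.array([1.0, 2, 3, 2, 1, 2])
        b = np.array([4.0, 5, 6, 5, 4, 5])
        table = pd.DataFrame({"mean": [0.0], "variance": [2.5]}, index=["G0"])
        res = bayes_t(a, b, prior_df=10**9, neighborhood=1, all_gene_variances=table)
        expected = (a.mean() - b.mean()) / (math.sqrt(2.5) * math.sqrt(1 / 6 + 1 / 6))
        assert res.statistic == pytest.approx(expected, rel=1e-4)

    def test_oversized_neighborhood_warns_and_clamps(self):
        rng = np.random.default_rng(11)
        table = pd.DataFrame(
            {"mean": rng.normal(size=5), "variance": rng.uniform(0.5, 2, 5)},
            index=[f"G{i}" for i in range(5)],
        )
        with pytest.warns(UserWarning, match="clamping"):
            bayes_t(rng.normal(size=5), rng.normal(size=5), 10, 50, table)


class TestPearsonClassCorr:
    def test_refuses_unequal_groups(self):
        res = pearson_class_corr([1, 2, 3], [1, 2])
        assert not res.applicable and math.isnan(res.pvalue)

    def test_matches_pointbiserial(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(1, 1, 15), rng.normal(0, 1, 15)
        mine = pearson_class_corr(a, b)
        x = np.concatenate([a, b])
        y = np.concatenate([np.ones(15), np.zeros(15)])
        rho, p = stats.pearsonr(x, y)
        assert mine.statistic == pytest.approx(rho)
        assert mine.pvalue == pytest.approx(p)

    def test_pvalue_agrees_with_pooled_t(self):
        # the class-indicator correlation is the point-biserial form of the
        # pooled t-test, so the two p-values coincide
        rng = np.random.default_rng(13)
        a, b = rng.normal(size=10), rng.normal(size=10)
        assert pearson_class_corr(a, b).pvalue == pytest.approx(t_test(a, b).pvalue)

    def test_direction_follows_mean_difference(self):
        assert pearson_class_corr([5.0, 6, 7], [1.0, 2, 3]).direction == "up"
        assert pearson_class_corr([1.0, 2, 3], [5.0, 6, 7]).direction == "down"


class TestModeratedT:
    def _null(self, n_genes=60, n1=6, n2=6, seed=14):
        return _matrix(np.random.default_rng(seed).normal(size=(n_genes, n1 + n2)), n1, n2)

    def test_forced_zero_prior_reduces_to_pooled_t(self):
        m = self._null()
        res = limma_moderated_t(m, d0=0.0)
        for gene in m.gene_ids:
            g1, g2 = m.group_arrays(gene)
            assert res[gene].statistic == pytest.approx(t_test(g1, g2).statistic)

    def test_forced_infinite_prior_pins_posterior_variance(self):
        m = self._null()
        res = limma_moderated_t(m, d0=math.inf, s0_2=1.0)
        for gene in m.gene_ids:
            g1, g2 = m.group_arrays(gene)
            beta = g1.mean() - g2.mean()
            expected = beta / math.sqrt(1.0 * (1 / 6 + 1 / 6))
            assert res[gene].statistic == pytest.approx(expected)

    def test_needs_enough_genes(self):
        with pytest.raises(ValueError, match="10 genes"):
            limma_moderated_t(self._null(n_genes=5))

    @pytest.mark.parametrize("heteroscedastic", [False, True])
    def test_agrees_with_bioconductor_limma(self, tmp_path, heteroscedastic):
        # dual route: same moderated t from the independent R implementation;
        # the homoscedastic ensemble exercises the infinite-prior branch and
        # the heteroscedastic one a finite fitted prior df
        m = self._null(n_genes=80, seed=15)
        if heteroscedastic:
            scales = np.random.default_rng(42).uniform(0.2, 3.0, size=(80, 1))
            m = _matrix(m.values.to_numpy() * scales, 6, 6)
        mat = tmp_path / "m.tsv"
        m.values.to_csv(mat, sep="\t")
        rscript = (
            "suppressMessages(library(limma));"
            f"x <- as.matrix(read.table('{mat}', sep='\\t', header=TRUE, row.names=1));"
            "design <- cbind(Intercept=1, Group=c(rep(1,6), rep(0,6)));"
            "fit <- eBayes(lmFit(x, design));"
            "cat(fit$df.prior, fit$s2.prior, '\\n');"
            "write.table(data.frame(t=fit$t[,2], p=fit$p.value[,2]),"
            f" '{tmp_path}/out.tsv', sep='\\t')"
        )
        subprocess.run(["Rscript", "-e", rscript], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        mine = limma_moderated_t(m)
        t_mine = np.array([mine[g].statistic for g in m.gene_ids])
        np.testing.assert_allclose(t_mine, ref["t"].to_numpy(), rtol=1e-5)


class TestSam:
    def test_zero_fudge_equals_pooled_t(self):
        rng = np.random.default_rng(16)
        a, b = rng.normal(size=8), rng.normal(size=8)
        assert sam_stat(a, b, s0=0.0, permutations=10).statistic == pytest.approx(
            t_test(a, b).statistic
        )

    def test_positive_fudge_shrinks_statistic(self):
        rng = np.random.default_rng(17)
        a, b = rng.normal(1, 1, 8), rng.normal(0, 1, 8)
        t0 = abs(sam_stat(a, b, s0=0.0, permutations=10).statistic)
        t1 = abs(sam_stat(a, b, s0=0.5, permutations=10).statistic)
        assert t1 <= t0

    def test_permutation_null_p_roughly_uniform(self):
        rng = np.random.default_rng(18)
        ps = []
        for i in range(120):
            a, b = rng.normal(size=10), rng.normal(size=10)
            ps.append(sam_stat(a, b, s0=0.1, permutations=200, seed=i).pvalue)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_rejects_bad_permutations(self):
        with pytest.raises(ValueError):
            sam_stat([1.0, 2], [3.0, 4], permutations=0)


class TestWilcoxon:
    def test_hand_values(self):
        res = wilcoxon_ranksum([1, 2, 3], [4, 5, 6])
        # T=6, meanw1=10.5, varw1=5.25
        assert res.statistic == pytest.approx((abs(6 - 10.5) - 0.5) / math.sqrt(5.25))

    def test_interleaved_groups_near_zero(self):
        res = wilcoxon_ranksum([1, 3, 5, 7], [2, 4, 6, 8])
        assert abs(res.statistic) < 0.5

    def test_variance_identity(self):
        # n2 * meanw1 / 6 equals the textbook rank-sum variance
        for n1, n2 in [(3, 5), (7, 7), (4, 9)]:
            meanw1 = n1 * (n1 + n2 + 1) / 2
            assert n2 * meanw1 / 6 == pytest.approx(n1 * n2 * (n1 + n2 + 1) / 12)

    def test_matches_mannwhitney_z_on_random_inputs(self):
        rng = np.random.default_rng(19)
        for _ in range(100):
            n1, n2 = rng.integers(5, 20, size=2)
            a, b = rng.normal(size=n1), rng.normal(0.4, 1, size=n2)
            mine = wilcoxon_ranksum(a, b)
            u = stats.mannwhitneyu(a, b, method="asymptotic").statistic
            z_ref = (abs(u - n1 * n2 / 2) - 0.5) / math.sqrt(
                n1 * n2 * (n1 + n2 + 1) / 12
            )
            assert abs(mine.statistic - z_ref) < 1e-9


class TestPermutedT:
    def test_identical_groups_give_p_one(self):
        assert permuted_t([1.0, 2, 3], [1.0, 2, 3], permutations=50).pvalue == 1

    def test_p_bounded_below_by_estimator(self):
        rng = np.random.default_rng(20)
        for i in range(10):
            a = rng.normal(5, 1, 12)
            b = rng.normal(0, 1, 12)
            p = permuted_t(a, b, permutations=99, seed=i).pvalue
            assert 1 / 100 <= p <= 1

    def test_exact_enumeration_matches_large_montecarlo(self):
        rng = np.random.default_rng(21)
        a, b = rng.normal(1, 1, 3), rng.normal(0, 1, 3)
        exact = permuted_t(a, b, permutations=100).pvalue  # C(6,3)=20 <= 100
        mc = permuted_t(a, b, permutations=100000, seed=5).pvalue
        assert abs(exact - mc) < 0.01


# ---------------------------------------------------------------------------
# the full selection stage
# ---------------------------------------------------------------------------

class TestSelectGenes:
    def test_pure_null_with_tiny_cutoff_selects_nothing(self):
        m = _matrix(np.random.default_rng(22).normal(size=(120, 24)), 12, 12)
        cfg = PipelineConfig(p_cutoff=1e-6, permutations=200, seed=0)
        with pytest.warns(UserWarning, match="empty total"):
            sel = select_genes(m, cfg)
        assert not sel.total

    def test_up_down_disjoint_and_unions_consistent(self):
        m, _ = simulate_two_class(n_genes=150, delta=2.5, seed=23)
        sel = select_genes(m, PipelineConfig(p_cutoff=0.05, permutations=200, seed=23))
        assert not (sel.up_N & sel.down_N)
        assert not (sel.up_NN & sel.down_NN)
        assert sel.total == sel.total_N | sel.total_NN
        assert sel.total_N <= sel.normal_genes
        assert sel.total_NN <= sel.nonnormal_genes

    def test_total_monotone_in_cutoff(self):
        m, _ = simulate_two_class(n_genes=150, delta=1.5, seed=24)
        sel_tight = select_genes(m, PipelineConfig(p_cutoff=0.005, permutations=400, seed=24))
        sel_loose = select_genes(m, PipelineConfig(p_cutoff=0.1, permutations=400, seed=24))
        assert sel_tight.total <= sel_loose.total

    def test_intersection_never_larger_than_single_test(self):
        # requiring all tests to agree can only shrink the called set
        m, _ = simulate_two_class(n_genes=200, delta=2.0, seed=25)
        cfg = PipelineConfig(p_cutoff=0.05, permutations=200, seed=25)
        sel = select_genes(m, cfg)
        tbl = sel.table
        n_sel = len(sel.total)
        for col in ("ttest_p", "limma_p"):
            if col in tbl:
                single = int((tbl[col] < cfg.p_cutoff).sum())
                assert n_sel <= single + (tbl[col].isna().sum())


def test_variance_table_matches_groupsummary():
    m, _ = simulate_two_class(n_genes=30, seed=26)
    table = _variance_table(m)
    gene = m.gene_ids[7]
    g1, g2 = m.group_arrays(gene)
    from bicrules.datatypes import GroupSummary

    assert table.loc[gene, "variance"] == pytest.approx(
        GroupSummary.from_groups(g1, g2).pooled_sd ** 2
    )
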