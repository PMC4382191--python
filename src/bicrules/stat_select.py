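"""Distribution-aware selection of differentially expressed/methylated genes.

The stage removes low-variance genes, z-score normalizes each gene, splits
genes into a normally and a non-normally distributed partition with the
Jarque-Bera test, then calls differential genes per partition: four
parametric tests (pooled t, Welch t, a Bayes-regularized t, and the
gene-versus-class Pearson correlation) on the normal partition and four
rank/permutation/moderated tests (moderated t, SAM, Wilcoxon rank-sum,
permuted t) on the non-normal partition.  A gene is selected only when every
applicable test in its partition agrees at the p cutoff with a consistent
direction; the per-partition up/down sets are then unioned.
"""
from __future__ import annotations

import itertools
import math
import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import special, stats

from .datatypes import (
    GroupSummary,
    LabeledMatrix,
    PipelineConfig,
    SelectionResult,
    TestResult,
)

__all__ = [
    "variance_filter",
    "zscore_normalize",
    "jarque_bera",
    "partition_by_normality",
    "t_test",
    "welch_t",
    "bayes_t",
    "pearson_class_corr",
    "limma_moderated_t",
    "sam_s0",
    "sam_stat",
    "wilcoxon_ranksum",
    "permuted_t",
    "select_genes",
    "PARAMETRIC_TESTS",
    "NONPARAMETRIC_TESTS",
]

PARAMETRIC_TESTS = ("ttest", "welch", "bayes_t", "pearson")
NONPARAMETRIC_TESTS = ("limma", "sam", "wilcoxon", "permuted")


# ---------------------------------------------------------------------------
# filtering and normalization
# ---------------------------------------------------------------------------

def variance_filter(m: LabeledMatrix, quantile: float) -> LabeledMatrix:
    """Drop genes whose variance falls below the empirical ``quantile``."""
    if not (0 <= quantile < 1):
        raise ValueError("quantile must lie in [0, 1)")
    if quantile == 0:
        return m
    variances = m.values.var(axis=1, ddof=1)
    cut = variances.quantile(quantile)
    keep = m.values.index[variances >= cut]
    if len(keep) == 0:
        raise ValueError("variance filter removed every gene")
    return m.subset_genes(list(keep))


def zscore_normalize(m: LabeledMatrix) -> LabeledMatrix:
    """Per-gene zero-mean, unit-sd scaling (sample sd, n-1 denominator)."""
    vals = m.values
    mu = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"gene {zero.index[0]!r} has zero variance; cannot normalize")
    normed = vals.sub(mu, axis=0).div(sd, axis=0)
    return LabeledMatrix(normed, m.labels.copy(), m.classes)


# ---------------------------------------------------------------------------
# normality
# ---------------------------------------------------------------------------

def jarque_bera(x: np.ndarray) -> TestResult:
    """Jarque-Bera normality statistic n/6 * (S^2 + (K-3)^2 / 4).

    S is the sample skewness and K the (non-excess) sample kurtosis, both
    computed from population moments; the p-value uses the chi-square
    reference with 2 degrees of freedom.
    """
    x = np.asarray(x, float)
    n = len(x)
    if n < 4:
        raise ValueError("Jarque-Bera needs at least 4 observations")
    centered = x - x.mean()
    m2 = np.mean(centered**2)
    if m2 == 0:
        jb = 0.0  # constant vector: define S=0, K=3 limit as exactly normal-shaped
    else:
        s = np.mean(centered**3) / m2**1.5
        k = np.mean(centered**4) / m2**2
        jb = n / 6.0 * (s**2 + (k - 3.0) ** 2 / 4.0)
    p = float(stats.chi2.sf(jb, 2))
    return TestResult(method="jarque_bera", statistic=float(jb), pvalue=p)


def partition_by_normality(
    m: LabeledMatrix, alpha: float
) -> tuple[LabeledMatrix | None, LabeledMatrix | None]:
    """Split genes into (normal, nonnormal) by JB on the full per-gene row.

    Either element is None when its partition is empty.
    """
    normal, nonnormal = [], []
    for gene in m.gene_ids:
        p = jarque_bera(m.values.loc[gene].to_numpy()).pvalue
        (normal if p >= alpha else nonnormal).append(gene)
    mn = m.subset_genes(normal) if normal else None
    mnn = m.subset_genes(nonnormal) if nonnormal else None
    return mn, mnn


# ---------------------------------------------------------------------------
# parametric tests
# ---------------------------------------------------------------------------

def _direction(mean1: float, mean2: float) -> str | None:
    if mean1 > mean2:
        return "up"
    if mean1 < mean2:
        return "down"
    return None


def _pooled_t(summ: GroupSummary) -> float:
    diff = summ.mean1 - summ.mean2
    se = summ.se
    if se == 0:
        return 0.0 if diff == 0 else math.copysign(math.inf, diff)
    return diff / se


def t_test(g1: np.ndarray, g2: np.ndarray) -> TestResult:
    """Two-sample pooled-variance t-test, two-sided."""
    g1, g2 = np.asarray(g1, float), np.asarray(g2, float)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 observations")
    summ = GroupSummary.from_groups(g1, g2)
    t = _pooled_t(summ)
    if math.isinf(t):
        p = 0.0
    else:
        p = float(2 * stats.t.sf(abs(t), summ.df))
    return TestResult("ttest", float(t), p, _direction(summ.mean1, summ.mean2))


def _variances_equal(g1: np.ndarray, g2: np.ndarray, alpha: float = 0.05) -> bool:
    """Two-sided F-test decision used by the Welch branch."""
    v1 = float(np.var(g1, ddof=1))
    v2 = float(np.var(g2, ddof=1))
    if v1 == v2:
        return True
    if v1 == 0 or v2 == 0:
        return False
    f = v1 / v2
    d1, d2 = len(g1) - 1, len(g2) - 1
    p = 2 * min(stats.f.sf(f, d1, d2), stats.f.cdf(f, d1, d2))
    return p >= alpha


def welch_t(g1: np.ndarray, g2: np.ndarray) -> TestResult:
    """Welch's t-test; falls back to the pooled t when variances test equal."""
    g1, g2 = np.asarray(g1, float), np.asarray(g2, float)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 observations")
    if _variances_equal(g1, g2):
        res = t_test(g1, g2)
        return TestResult("welch", res.statistic, res.pvalue, res.direction)
    n1, n2 = len(g1), len(g2)
    m1, m2 = float(np.mean(g1)), float(np.mean(g2))
    v1, v2 = float(np.var(g1, ddof=1)), float(np.var(g2, ddof=1))
    se2 = v1 / n1 + v2 / n2
    diff = m1 - m2
    if se2 == 0:
        t = 0.0 if diff == 0 else math.copysign(math.inf, diff)
        p = 1.0 if diff == 0 else 0.0
        return TestResult("welch", t, p, _direction(m1, m2))
    t = diff / math.sqrt(se2)
    # Welch-Satterthwaite degrees of freedom
    denom = 0.0
    if v1 > 0:
        denom += (v1 / n1) ** 2 / (n1 - 1)
    if v2 > 0:
        denom += (v2 / n2) ** 2 / (n2 - 1)
    df = se2**2 / denom
    p = float(2 * stats.t.sf(abs(t), df))
    return TestResult("welch", float(t), p, _direction(m1, m2))


def bayes_t(
    g1: np.ndarray,
    g2: np.ndarray,
    prior_df: int = 10,
    neighborhood: int = 101,
    all_gene_variances: pd.DataFrame | None = None,
) -> TestResult:
    """Conjugate-prior regularized t-test (Baldi-Long family).

    The pooled variance is shrunk toward a prior variance estimated as the
    mean pooled variance of the ``neighborhood`` genes whose overall mean
    expression is nearest to this gene's; the degrees of freedom are
    inflated by ``prior_df``.  ``all_gene_variances`` is a frame indexed by
    gene with columns ``mean`` (overall mean expression) and ``variance``
    (pooled within-group variance); with no frame, the gene's own pooled
    variance is the prior (no shrinkage of the scale, df still inflated).
    """
    g1, g2 = np.asarray(g1, float), np.asarray(g2, float)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 observations")
    summ = GroupSummary.from_groups(g1, g2)
    s2 = summ.pooled_sd**2
    if all_gene_variances is not None and len(all_gene_variances):
        k = neighborhood
        if k > len(all_gene_variances):
            warnings.warn(
                "bayes_t neighborhood larger than gene count; clamping",
                stacklevel=2,
            )
            k = len(all_gene_variances)
        own_mean = float(np.mean(np.concatenate([g1, g2])))
        dist = (all_gene_variances["mean"] - own_mean).abs()
        nearest = dist.nsmallest(k).index
        v_prior = float(all_gene_variances.loc[nearest, "variance"].mean())
    else:
        v_prior = s2
    df = summ.df
    if prior_df + df <= 0:
        raise ValueError("nonpositive total degrees of freedom")
    s2_reg = (prior_df * v_prior + df * s2) / (prior_df + df)
    se = math.sqrt(s2_reg) * math.sqrt(1.0 / summ.n1 + 1.0 / summ.n2)
    diff = summ.mean1 - summ.mean2
    if se == 0:
        t = 0.0 if diff == 0 else math.copysign(math.inf, diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        t = diff / se
        p = float(2 * stats.t.sf(abs(t), df + prior_df))
    return TestResult("bayes_t", float(t), p, _direction(summ.mean1, summ.mean2))


def pearson_class_corr(g1: np.ndarray, g2: np.ndarray) -> TestResult:
    """Pearson correlation between a gene's values and class membership.

    The gene's pooled value vector is correlated against the 1/0 class
    indicator (experimental = 1), i.e. the point-biserial correlation; a
    positive rho means higher expression in the experimental class.  As in
    the source methodology the test refuses unequal group sizes and then
    reports a non-applicable result rather than a p-value.
    """
    g1, g2 = np.asarray(g1, float), np.asarray(g2, float)
    if len(g1) != len(g2):
        return TestResult("pearson", math.nan, math.nan, None, applicable=False)
    x = np.concatenate([g1, g2])
    y = np.concatenate([np.ones(len(g1)), np.zeros(len(g2))])
    n = len(x)
    sx = x.std(ddof=1)
    if sx == 0:
        return TestResult("pearson", 0.0, 1.0, None)
    rho = float(np.corrcoef(x, y)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1 - rho**2))
        p = float(2 * stats.t.sf(abs(t), n - 2))
    direction = "up" if rho > 0 else "down" if rho < 0 else None
    return TestResult("pearson", rho, p, direction)


# ---------------------------------------------------------------------------
# moderated t (empirical-Bayes variance shrinkage)
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the monotone branch)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def _fit_f_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) to an ensemble of sample variances.

    Matches the mean and variance of log s^2 to the scaled-F model via
    digamma/trigamma identities; returns (inf, geometric-mean-based s0^2)
    when the observed spread is no larger than the chi-square spread.
    """
    s2 = np.maximum(np.asarray(s2, float), 0.0)
    if len(s2) < 2:
        return math.inf, float(np.mean(s2)) if len(s2) else 1.0
    m = float(np.median(s2))
    if m == 0:
        m = 1.0
    s2 = np.maximum(s2, 1e-5 * m)  # offset exact zeros away from log(0)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        # observed spread no wider than the chi-square spread: infinite
        # prior df, prior variance at the plain mean of the variances
        return math.inf, float(np.mean(s2))
    d0 = 2.0 * _trigamma_inverse(evar)
    if not math.isfinite(d0):
        return math.inf, float(np.mean(s2))
    s0_2 = math.exp(
        emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
    )
    return d0, s0_2


def limma_moderated_t(
    m: LabeledMatrix,
    d0: float | None = None,
    s0_2: float | None = None,
) -> dict[str, TestResult]:
    """Per-gene moderated t with empirical-Bayes pooled-variance shrinkage.

    The posterior variance is (d0*s0^2 + dg*sg^2) / (d0 + dg) with the prior
    (d0, s0^2) fitted to the ensemble of pooled variances by moment matching
    on log variances; ``d0``/``s0_2`` may be forced for diagnostics.  The
    two-sided p-value uses d0 + dg degrees of freedom.
    """
    exp_cols = m.class_columns(m.experimental)
    ctl_cols = m.class_columns(m.control)
    n1, n2 = len(exp_cols), len(ctl_cols)
    if n1 < 2 or n2 < 2:
        raise ValueError("each class needs at least 2 samples")
    if m.values.shape[0] < 10 and d0 is None:
        raise ValueError("prior estimation needs at least 10 genes")
    x1 = m.values[exp_cols].to_numpy()
    x2 = m.values[ctl_cols].to_numpy()
    beta = x1.mean(axis=1) - x2.mean(axis=1)
    dg = n1 + n2 - 2
    sg2 = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    sg2 += ((x2 - x2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    sg2 /= dg
    if d0 is None:
        d0, s0_fit = _fit_f_prior(sg2, dg)
        if s0_2 is None:
            s0_2 = s0_fit
        if not math.isfinite(d0):
            warnings.warn(
                "moderated-t prior df estimate non-finite; using large-d0 limit",
                stacklevel=2,
            )
    elif s0_2 is None:
        s0_2 = float(np.mean(sg2[sg2 > 0])) if (sg2 > 0).any() else 1.0
    if math.isinf(d0):
        s2_post = np.full_like(sg2, s0_2)
        df_total = math.inf
    else:
        s2_post = (d0 * s0_2 + dg * sg2) / (d0 + dg)
        df_total = d0 + dg
    scale = math.sqrt(1.0 / n1 + 1.0 / n2)
    out: dict[str, TestResult] = {}
    for i, gene in enumerate(m.gene_ids):
        se = math.sqrt(s2_post[i]) * scale
        if se == 0:
            t = 0.0 if beta[i] == 0 else math.copysign(math.inf, beta[i])
            p = 1.0 if beta[i] == 0 else 0.0
        else:
            t = beta[i] / se
            if math.isinf(df_total):
                p = float(2 * stats.norm.sf(abs(t)))
            else:
                p = float(2 * stats.t.sf(abs(t), df_total))
        out[gene] = TestResult("limma", float(t), p, _direction(beta[i], 0.0))
    return out


# ---------------------------------------------------------------------------
# SAM and permutation tests
# ---------------------------------------------------------------------------

def sam_s0(m: LabeledMatrix) -> float:
    """Matrix-wide SAM fudge factor: median standard error across genes."""
    ses = []
    for gene in m.gene_ids:
        g1, g2 = m.group_arrays(gene)
        ses.append(GroupSummary.from_groups(g1, g2).se)
    return float(np.median(ses))


def _sam_statistics(pooled: np.ndarray, n1: int, s0: float) -> np.ndarray:
    """Vectorized SAM statistic over rows of ``pooled`` (each a permutation)."""
    g1 = pooled[:, :n1]
    g2 = pooled[:, n1:]
    n2 = pooled.shape[1] - n1
    m1 = g1.mean(axis=1)
    m2 = g2.mean(axis=1)
    v1 = g1.var(axis=1, ddof=1)
    v2 = g2.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    sp = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / df)
    se = sp * math.sqrt(1.0 / n1 + 1.0 / n2)
    denom = se + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (m1 - m2) / np.where(denom > 0, denom, 1.0), 0.0)
    return t


def sam_stat(
    g1: np.ndarray,
    g2: np.ndarray,
    s0: float = 0.0,
    permutations: int = 1000,
    seed: int = 0,
) -> TestResult:
    """SAM statistic (pooled t with a fudge factor) with a permutation p.

    p = (1 + #{permuted |t_sam| >= observed}) / (permutations + 1) over
    seeded label permutations.
    """
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    if s0 < 0:
        raise ValueError("s0 must be nonnegative")
    g1, g2 = np.asarray(g1, float), np.asarray(g2, float)
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("groups must be nonempty")
    pooled = np.concatenate([g1, g2])
    n1 = len(g1)
    observed = float(_sam_statistics(pooled[None, :], n1, s0)[0])
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(pooled, (permutations, 1)), axis=1)
    t_perm = _sam_statistics(perms, n1, s0)
    count = int(np.sum(np.abs(t_perm) >= abs(observed) - 1e-12))
    p = (1 + count) / (permutations + 1)
    m1, m2 = float(np.mean(g1)), float(np.mean(g2))
    return TestResult("sam", observed, p, _direction(m1, m2))


def wilcoxon_ranksum(g1: np.ndarray, g2: np.ndarray) -> TestResult:
    """Rank-sum z-test on the smaller of the two rank sums.

    Pooled ascending ranks with average ties; T is the smaller rank sum,
    its mean n1*(n1+n2+1)/2 is taken with n1 the size of the group that
    attained the minimum; the z statistic carries a 0.5 continuity
    correction and is referred to the standard normal, two-sided.
    """
    g1, g2 = np.asarray(g1, float), np.asarray(g2, float)
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("groups must be nonempty")
    pooled = np.concatenate([g1, g2])
    ranks = stats.rankdata(pooled)
    r1 = float(ranks[: len(g1)].sum())
    r2 = float(ranks[len(g1):].sum())
    if r1 <= r2:
        t_min, n1, n2 = r1, len(g1), len(g2)
    else:
        t_min, n1, n2 = r2, len(g2), len(g1)
    meanw1 = n1 * (n1 + n2 + 1) / 2.0
    varw1 = n2 * meanw1 / 6.0
    if varw1 == 0:
        return TestResult("wilcoxon", 0.0, 1.0, None)
    z = (abs(t_min - meanw1) - 0.5) / math.sqrt(varw1)
    p = min(1.0, float(2 * stats.norm.sf(z)))
    m1, m2 = float(np.mean(g1)), float(np.mean(g2))
    return TestResult("wilcoxon", float(z), p, _direction(m1, m2))


def _pooled_t_rows(pooled: np.ndarray, n1: int) -> np.ndarray:
    return _sam_statistics(pooled, n1, 0.0)


def permuted_t(
    g1: np.ndarray,
    g2: np.ndarray,
    permutations: int = 10000,
    seed: int = 0,
) -> TestResult:
    """Pooled t with a label-permutation p-value.

    When the number of distinct label arrangements C(n, n1) is at most
    ``permutations`` the null is enumerated exactly (p = fraction of
    arrangements at least as extreme, the identity included); otherwise a
    seeded Monte-Carlo sample with the add-one estimator is used.
    """
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    g1, g2 = np.asarray(g1, float), np.asarray(g2, float)
    pooled = np.concatenate([g1, g2])
    n1, n = len(g1), len(g1) + len(g2)
    observed = float(_pooled_t_rows(pooled[None, :], n1)[0])
    total = math.comb(n, n1)
    m1, m2 = float(np.mean(g1)), float(np.mean(g2))
    if total <= permutations:
        rows = np.empty((total, n))
        idx_all = np.arange(n)
        for r, combo in enumerate(itertools.combinations(range(n), n1)):
            sel = np.array(combo)
            rest = np.setdiff1d(idx_all, sel, assume_unique=True)
            rows[r, :n1] = pooled[sel]
            rows[r, n1:] = pooled[rest]
        t_perm = _pooled_t_rows(rows, n1)
        count = int(np.sum(np.abs(t_perm) >= abs(observed) - 1e-12))
        p = count / total
    else:
        rng = np.random.default_rng(seed)
        perms = rng.permuted(np.tile(pooled, (permutations, 1)), axis=1)
        t_perm = _pooled_t_rows(perms, n1)
        count = int(np.sum(np.abs(t_perm) >= abs(observed) - 1e-12))
        p = (1 + count) / (permutations + 1)
    return TestResult("permuted", observed, p, _direction(m1, m2))


# ---------------------------------------------------------------------------
# the full selection stage
# ---------------------------------------------------------------------------

def _variance_table(m: LabeledMatrix) -> pd.DataFrame:
    """Per-gene overall mean and pooled within-group variance."""
    exp_cols = m.class_columns(m.experimental)
    ctl_cols = m.class_columns(m.control)
    x1 = m.values[exp_cols].to_numpy()
    x2 = m.values[ctl_cols].to_numpy()
    dg = x1.shape[1] + x2.shape[1] - 2
    sg2 = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    sg2 += ((x2 - x2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    sg2 /= dg
    return pd.DataFrame(
        {"mean": m.values.mean(axis=1).to_numpy(), "variance": sg2},
        index=m.values.index,
    )


def select_genes(m: LabeledMatrix, cfg: PipelineConfig) -> SelectionResult:
    """Run the full selection stage on a raw matrix.

    Pipeline: variance filter -> z-score normalization -> Jarque-Bera
    partition -> per-partition test batteries -> directional intersection.
    """
    filtered = variance_filter(m, cfg.variance_quantile)
    normed = zscore_normalize(filtered)
    normal_m, nonnormal_m = partition_by_normality(normed, cfg.normality_alpha)

    rows: list[dict] = []
    up_N: set[str] = set()
    down_N: set[str] = set()
    up_NN: set[str] = set()
    down_NN: set[str] = set()

    seed_seq = np.random.SeedSequence(cfg.seed)

    if normal_m is not None:
        var_table = _variance_table(normal_m)
        for gene in normal_m.gene_ids:
            g1, g2 = normal_m.group_arrays(gene)
            results = {
                "ttest": t_test(g1, g2),
                "welch": welch_t(g1, g2),
                "bayes_t": bayes_t(
                    g1,
                    g2,
                    prior_df=cfg.bayes_prior_df,
                    neighborhood=min(cfg.bayes_neighborhood, len(var_table)),
                    all_gene_variances=var_table,
                ),
                "pearson": pearson_class_corr(g1, g2),
            }
            direction = _direction(float(np.mean(g1)), float(np.mean(g2)))
            row = _assemble_row(
                gene, "N", direction, results, PARAMETRIC_TESTS, cfg.p_cutoff
            )
            rows.append(row)
            if row["selected"] and direction == "up":
                up_N.add(gene)
            elif row["selected"] and direction == "down":
                down_N.add(gene)

    if nonnormal_m is not None:
        limma_results = limma_moderated_t(nonnormal_m) if len(
            nonnormal_m.gene_ids
        ) >= 10 else {
            g: t_test(*nonnormal_m.group_arrays(g)) for g in nonnormal_m.gene_ids
        }
        s0 = sam_s0(nonnormal_m)
        child_seeds = seed_seq.spawn(len(nonnormal_m.gene_ids))
        for gene, child in zip(nonnormal_m.gene_ids, child_seeds):
            g1, g2 = nonnormal_m.group_arrays(gene)
            s_sam, s_perm = child.spawn(2)
            results = {
                "limma": limma_results[gene],
                "sam": sam_stat(
                    g1, g2, s0=s0, permutations=cfg.permutations,
                    seed=s_sam,
                ),
                "wilcoxon": wilcoxon_ranksum(g1, g2),
                "permuted": permuted_t(
                    g1, g2, permutations=cfg.permutations, seed=s_perm,
                ),
            }
            direction = _direction(float(np.mean(g1)), float(np.mean(g2)))
            row = _assemble_row(
                gene, "NN", direction, results, NONPARAMETRIC_TESTS, cfg.p_cutoff
            )
            rows.append(row)
            if row["selected"] and direction == "up":
                up_NN.add(gene)
            elif row["selected"] and direction == "down":
                down_NN.add(gene)
    table = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame()

    # stamp p_cutoff-dependent selection into the table for provenance
    if not (up_N | down_N | up_NN | down_NN):
        warnings.warn("selection produced an empty total gene set", stacklevel=2)
    result = SelectionResult(
        normal_genes=set(normal_m.gene_ids) if normal_m is not None else set(),
        nonnormal_genes=set(nonnormal_m.gene_ids) if nonnormal_m is not None else set(),
        table=table,
        up_N=up_N,
        down_N=down_N,
        up_NN=up_NN,
        down_NN=down_NN,
    )
    result.validate()
    return result


def _assemble_row(
    gene: str,
    partition: str,
    direction: str | None,
    results: Mapping[str, TestResult],
    battery: tuple[str, ...],
    p_cutoff: float,
) -> dict:
    """One table row; a gene is selected when every applicable test in its
    battery rejects at the cutoff with the gene's direction."""
    row: dict = {"gene": gene, "partition": partition, "direction": direction}
    selected = direction is not None
    for name in battery:
        res = results[name]
        row[f"{name}_stat"] = res.statistic
        row[f"{name}_p"] = res.pvalue
        row[f"{name}_applicable"] = res.applicable
        if not res.applicable:
            continue
        if not (res.pvalue < p_cutoff and res.direction == direction):
            selected = False
    row["selected"] = selected
    return row
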