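# Methods

This note records the modelling choices behind `bicrules`: what each stage
assumes, which knobs matter, what the synthetic generators do and do not
emulate, and where the design was genuinely open.

## Statistical selection

The selection stage assumes a two-class design with independent samples and
no covariates. All standard deviations use the sample (n−1) convention,
matching the pooled-variance formula the t family is built on.

*Normality partition.* The Jarque–Bera statistic is computed on each gene's
full row (both classes pooled) after z-score normalization, with d taken as
the number of observations and K as non-excess kurtosis, and referred to
χ²₂. Partitioning once, before any group comparison, keeps the test
batteries disjoint; the cost is that a strongly differential gene is itself
slightly non-Gaussian as a mixture, which at cohort sizes of a few dozen
samples is far below JB's detection threshold.

*The eight tests.*

- Pooled t and Welch t are textbook transcriptions. "Check whether the
  variances are equal" is made concrete as a two-sided F pretest at
  α = 0.05; on equality the pooled statistic is returned.
- The Bayes-regularized t replaces the pooled variance with
  (d₀·v_prior + df·s²)/(d₀ + df) and inflates the reference-t degrees of
  freedom by the prior df (default 10). v_prior is the mean pooled variance
  of the `neighborhood` (default 101) genes nearest in overall mean
  expression — a local shrinkage target in the spirit of
  expression-dependent variance trends.
- The Pearson test correlates a gene's pooled value vector with the binary
  class indicator (point-biserial), which is the correlation form of the
  pooled t; it is gated to equal group sizes, reporting a non-applicable
  result otherwise, and that gating is honoured by the intersection logic.
- The moderated t fits its prior (d₀, s₀²) to the ensemble of pooled
  variances by moment matching on log variances (digamma/trigamma
  identities, trigamma inverse by Newton). When the observed log-variance
  spread does not exceed the χ² spread the prior df is infinite and the
  posterior variance pins to the mean variance; a test cross-checks both
  branches against the independent Bioconductor implementation.
- SAM adds a fudge factor s₀ to the pooled standard error; the default s₀
  is the median standard error across the matrix's genes. Its p-value, and
  the permuted t's, come from seeded label permutations with the add-one
  estimator p = (1+k)/(B+1); the permuted t switches to exact enumeration
  whenever C(n, n₁) ≤ B.
- The rank-sum z uses average ranks for ties, takes T as the smaller rank
  sum with n₁ the size of the group attaining it, and applies a 0.5
  continuity correction. Its |z| equals the continuity-corrected
  Mann–Whitney z, which the tests verify to 1e-9.

*Intersection.* A gene enters an up/down set only when every applicable
test of its partition gives p below the cutoff with direction matching the
sign of (experimental − control) mean on normalized data. Exact zero
differences leave the gene unselected. No multiple-testing correction is
applied by default because the method thresholds raw p-values; the
intersection of eight correlated tests is itself a conservative filter.

Defaults: p cutoff 0.05, normality α 0.05, variance-filter quantile 0.1,
1000 permutations. Permutation p-values resolve no finer than 1/(B+1), so
cutoffs below ~1e-3 require raising B.

## Discretization

Binarization thresholds the normalized matrix at zero, so '1' means
strictly above the gene's mean; exact zeros (measure zero on continuous
data) map to 0. Sign-doubling then gives each gene a '+' and a complement
'−' column, making both regulation directions minable as 1s. Methylation
matrices use identical code; '+' reads hyper-methylated and '−'
hypo-methylated.

## Bicluster mining

An inclusion-maximal all-1 bicluster corresponds one-to-one to a closed
itemset with its full support set. The enumerator walks the closed-itemset
lattice with prefix-preserving closure extensions, visiting each closed set
exactly once, pruning on minimum support, and reporting sets meeting both
thresholds in a deterministic order (support desc, item count desc,
lexicographic). Correctness is anchored by a brute-force oracle over all
sample subsets on small random matrices; any enumeration strategy with the
same output set would be conformant. A result cap (10⁶) aborts explosive
runs with advice to raise min_support — on half-dense boolean matrices the
closed-set count grows very quickly as min_support approaches 1.

Homogeneity filtering keeps a bicluster only when all its samples share one
class; heterogeneous biclusters are discarded outright, never trimmed to a
homogeneous subset.

min_items defaults to 2; min_support defaults to 8, i.e. 20% of the default
40-sample synthetic cohort — large enough that chance same-class support
sets (probability ≈ 2·0.5^s for support s on balanced classes) are rare,
small enough that class-wide planted structure survives 4-fold training
splits. min_support is an absolute sample count; analysts should scale it
with cohort size.

## Rules, measures, ranking, weights

One rule per homogeneous bicluster: antecedent = its items, consequent =
its class. The 23 literature measures follow their canonical survey forms
(confidence, coverage, prevalence, sensitivity, specificity, accuracy,
lift, leverage = confidence − P(A)P(C), added value, relative risk,
Jaccard, Yule's Q, Klösgen, Laplace, Gini gain, two-way support, φ, cosine,
least contradiction, Zhang, Piatetsky–Shapiro, kappa), with the 24th being
the number of samples of the source bicluster. A measure whose denominator
(or logarithm argument) vanishes is *undefined*, a first-class value that
ranks worst for that measure — a rule that cannot be scored should not
benefit.

Fractional ranking averages the ordinal ranks of ties. For measures,
larger is uniformly better (applied even where taste might argue otherwise,
e.g. prevalence or coverage — uniformity was chosen over per-measure
judgement); the classic ascending illustration ({1,2,2} → 1, 2.5, 2.5) is
available through `larger_is_better=False`. The final rank is the mean of
the 24 fractional ranks; ties in final rank break by discovery id so that
positions 1..p are total. Weights follow w_j = (p − (r_j − 1))/p with r_j
the ordinal position, which guarantees the stated properties (top weight 1,
equal gaps of 1/p). An optional zero-mean normalization of the weight
vector is provided but off by default: centred weights make half the votes
negative, which contradicts the direct weighted-sum voting mechanism.

## Classification

Folds are stratified by class (class-blind splitting is available) so small
cohorts cannot produce class-empty training folds. Rules are mined, scored,
ranked and weighted on each training fold alone. Prediction compares
class-wise weight sums over satisfying rules; exact ties go to the
best-positioned satisfying rule; a point satisfied by no rule receives the
class of the fallback rule — the rule satisfying the most test points of
the current fold (ties again by position). The fallback is a printed part
of the voting scheme and is known to be weak: orphaned points are exactly
those whose class's rules are damaged, so the fallback's class is close to
a coin flip for them. A training fold yielding zero rules predicts the
training-majority class with a logged warning. Per-repeat metrics are
computed from fold-pooled confusion counts, not averaged per-fold rates;
MCC takes the 0/0 convention of 0. One-way ANOVA (`anova_compare`) serves
pairwise accuracy-series comparisons against external classifiers; the
comparators themselves are out of scope.

## Synthetic data

The generators are pure functions of their parameters and seed, and every
fixture carries its ground truth.

*Two-class numeric matrices* mix Gaussian genes with shifted-lognormal(0,1)
genes rescaled to zero mean and unit variance (skewness ≈ 6.2, enough for
JB to separate the partitions from ~30 samples). Differential genes shift
the experimental class mean by ±δ within-group sd, split evenly up/down.
Defaults: 1000 genes, 20 vs 20 samples, 10% differential, δ = 2, 30%
non-normal — a small two-arm microarray cohort with a strong planted
signal.

*Item matrices* start from i.i.d. fair random bits per gene, plant k all-1
signed blocks and apply symmetric bit-flip noise (default 2%) on the '+'
domain, recomputing '−' columns as complements so the item-matrix invariant
is preserved. Defaults plant one whole-class signature block per class
(3 signed items, as in the method's worked example where each class is
characterized by one three-gene bicluster). Two structural guarantees are
enforced constructively, and matter: (a) *class confinement with a Hamming
margin* — every other-class sample is made to mismatch each block's
signature in at least two items, so neither the signature nor its long
sub-itemsets reach across the class boundary, and at zero noise every
planted block closes to a homogeneous maximal bicluster; (b) when several
blocks per class are requested they tile the class in a circulant design
rather than as independent random subsets. The latter is necessary because
same-class blocks that overlap on most of their samples do not survive as
separate closed itemsets — each block's closure absorbs the sibling's items
and the merged antecedent covers only the intersection. Even with the
circulant layout, multi-block-per-class configurations remain harder for
the classifier than the single-signature default; users planting many
blocks should expect merged closures unless block sample sets differ on a
substantial fraction of the class.

*Paired matrices* plant k genes with a +δ expression / −δ methylation shift
(and mirrored) in the experimental class over a shared gene/sample universe;
all other genes are null in both. Defaults: 300 genes, 20 vs 20, 10 inverse
genes, δ = 3.

What passing on these fixtures does **not** show: robustness to batch
effects, probe-level noise, unbalanced designs, class overlap, or
correlated gene modules — none of which the generators emulate. Real
two-channel data also violates the generators' independence of genes.

## Numerical choices and degenerate inputs

- Zero-variance genes: rejected by normalization (by name); the variance
  filter removes them first at any positive quantile.
- Both groups constant and equal: t-statistics return 0 with p = 1 rather
  than erroring; constant-but-different groups return ±∞ with p = 0.
- Permutation comparisons use a 1e-12 absolute slack so the identity
  permutation always counts.
- The trigamma inverse runs Newton from limma's starting point with a
  large-argument fallback; exact-zero variances are offset to 1e-5 × median
  before taking logs.
- The rank-sum z may be negative when |T − meanw1| < 0.5; the two-sided p
  is clipped at 1.
- Weight z-normalization of a single rule returns a centred 0.

## Problem sizes

The shipped test-suite and acceptance checks run at the scales the defaults
describe: 2000-gene null matrices for calibration, 1000-gene selection
cohorts, 40-sample item matrices under 10 × 4-fold CV, and 100 random 8 × 10
matrices against the brute-force oracles. These sizes were chosen so the
full suite completes in about a minute on one core while keeping every
binomial acceptance band meaningful.

## Known limitations

- The eight-test intersection is conservative by construction; its false
  negative rate rises quickly for effects below ~1.5 sd at n = 20/20.
- Support thresholds are absolute counts; there is no per-class minimum,
  so a homogeneous rule can be supported entirely by one class's majority
  subcluster.
- The BiMax enumeration is noise-intolerant by definition (a single flipped
  cell splits a block); noise-tolerant biclustering variants are explicitly
  out of scope.
- The fallback rule of the voting scheme degrades toward chance for
  samples outside all mined rules (see above).
- Only two-class designs are supported; no covariates, pairing, or
  multi-class voting.
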