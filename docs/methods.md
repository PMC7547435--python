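# Methods

This note records the models, estimators, defaults and numerical choices
behind `wrassepop`, and what the synthetic-data tests do and do not show
about real data.

## Balding–Nichols genotype simulation

Background loci draw an ancestral frequency p ~ Uniform(0.05, 0.5) (an
ascertainment-aware law: discovery panels exclude rare variants, which
inflates heterozygosity relative to a neutral site-frequency spectrum) and
per-population frequencies p_i ~ Beta(p(1−F)/F, (1−p)(1−F)/F), whose
variance is exactly p(1−p)F; genotypes are Binomial(2, p_i). F is therefore
the target Weir–Cockerham F_ST, which makes estimator-recovery tests
self-calibrating. Defaults mirror a four-population discovery design
(4 × 15 diploids) and a two-population validation design (2 × 47); the
missingness default of 2% is a free parameter, not an empirical claim.

**Planted outliers** use a deterministic frequency displacement
p ± sqrt(F_out·p(1−p)) (alternating across populations; ancestral p redrawn
from [0.25, 0.5] so the displaced frequencies stay in (0,1)) rather than a
Beta draw at elevated F. A Beta draw's realized per-locus divergence is
strongly right-skewed — at target 0.3 the median realized locus F_ST is
roughly 0.1 — so half of nominally "planted" loci would carry
near-background divergence and recovery rates would measure simulation luck
rather than the scan. The deterministic displacement realizes the stated
locus F_ST at every planted locus.

The linked-pair generator draws two-locus haplotypes with equal allele
frequencies and disequilibrium D = sqrt(r²_target)·p(1−p), giving genotype
pairs whose expected squared correlation is the target.

## K-mer spectrum model

A k-mer multiplicity histogram is modelled as a mixture over distinct
k-mers of: error (negative binomial, mean ≈ 1, overdispersed), haploid
(Poisson(λ): k-mers on one haplotype only, spanning heterozygous sites),
diploid (Poisson(2λ)), and repeat classes (Poisson(2λc), c = 2…5 by
default, weights free, copies beyond the last class truncated). All Poisson
means share one coverage parameter λ — the three genomic classes differ
only by copy number, and unconstrained means are unidentifiable on noisy
spectra. Component pmfs are zero-truncated (counters never report
multiplicity 0) and multiplicities above 10× the initial λ are pooled into
a single tail bin carrying the exact pooled observation mass.

Fitting is generalized EM on the count-weighted categorical likelihood:
weights update in closed form; λ and the NB mean/dispersion update by
bounded 1-D maximizations of the expected complete-data log-likelihood,
accepted only when they improve it, so the observed log-likelihood is
monotone non-decreasing (asserted per iteration in tests). Convergence:
relative log-likelihood change < 1e-8, max 2000 iterations. λ is
initialized from the spectrum's local maxima above multiplicity 4: two
prominent peaks at a ~1:2 position ratio identify the haploid mode directly
(heterozygous genomes); a single peak is read as the diploid mode. The NB
mean initializes from the sub-λ/2 region.

Derived quantities:

* genome size G = Σ_m m·count(m)·P(non-error | m) / (2λ). Every haploid
  genome-equivalent position contributes 2λ sequenced k-mer copies
  regardless of class (a heterozygous site splits its copies across two
  haploid k-mers; a c-copy repeat concentrates them on 1/c as many distinct
  k-mers), so no per-class correction is needed.
* heterozygous sites = (distinct k-mers attributed to the haploid class)
  / (2k): an isolated SNP creates k novel k-mers on each haplotype. The
  divisor is exposed (`kmers_per_site`) because other conversions exist in
  the wild (clustered SNPs share novel k-mers and deflate the divisor); the
  2k convention is exact for the generator's isolated-site model, where
  recovery is within 10%.

Limitations: the generator draws independent multiplicities per distinct
k-mer, so it reproduces class means and weights but not the positional
correlation of real coverage (GC bias, repeat mosaicism); passing recovery
tests show the fitter inverts its own generative model, not that real
spectra are this clean.

## Filters

Site acceptance applies per-population aggregates against bounds
(defaults QUAL ≥ 600, 20 ≤ DP ≤ 999, 0 ≤ MQ ≤ 90). QUAL and MQ are
site-level and shared by every population; DP is the per-population mean of
per-sample depths when FORMAT/DP is present, else the site depth.
Rejections are attributed to the first failing criterion (qual, dp, mq) so
tallies conserve loci. MAF filtering removes loci with pooled minor-allele
frequency strictly below the cutoff (0.01), computed over non-missing
genotypes. HWE uses the exact conditional test on the heterozygote count
by default (two-sided, summing configurations no more probable than the
observed one; exactness matters at n = 15 per population) with a chi-square
variant available; p-values are BH-adjusted per population and a locus is
removed when adjusted p < 0.05 in ≥ 2 populations. Distance thinning is a
greedy left-to-right per-contig scan keeping a locus iff it lies ≥ 1000 bp
(inclusive) beyond the last kept one.

## Diversity and differentiation

Per-locus gene diversity uses Hs = 2p̂(1−p̂)·n/(n−1) with n the number of
genotyped individuals, averaged over loci; Ho is the heterozygote fraction;
F_IS = 1 − H̄o/H̄s with a percentile bootstrap-over-loci CI. The n/(n−1)
correction overshoots the unbiased 2n/(2n−1) factor slightly, leaving a
positive F_IS bias of ≈ 1/(2n) on Hardy–Weinberg data (≈ 0.03 at n = 15,
0.01 at n = 50); it is kept as the package's documented estimator and the
null-recovery test budgets for it. The heterozygote-deficit test is a
paired t-test of per-locus (Hs − Ho) with df = n_loci − 1.

Weir–Cockerham (1984) variance components a (among populations), b (among
individuals within populations) and c (within individuals) are computed
per locus, vectorized, with pairwise deletion of missing genotypes;
multi-locus θ is the ratio of sums Σa/Σ(a+b+c) (the estimator's standard
combination), never the mean of per-locus ratios. Monomorphic or
single-population loci are excluded from the sums; negative θ estimates are
reported as computed. 95% CIs are percentile intervals over 1000 bootstrap
resamples of loci; a pair is "significantly differentiated" when its CI
excludes zero. Bootstrapping loci treats loci as exchangeable and
independent — measured coverage of the simulation truth is ≈ 94–95% at
20,000 loci (the acceptance check uses 400 replicates because a 200-draw
binary coverage proportion has ~1.6-point Monte-Carlo noise of its own).

LD surveys compute composite genotype r² (squared Pearson correlation of
dosages over pairwise-complete individuals, ≥ 3 required) for all
same-contig pairs and a seeded random sample of cross-contig pairs
(100,000 by default); "excluding the nearest n SNPs" drops pairs within n
positions in per-contig sorted order (index distance, not bp — the bp
variant is a one-line change but index distance is the documented choice).

## Structure and assignment

Individual distances are Provesti / allele-sharing: mean over shared
non-missing loci of |dosage difference|/2. UPGMA is an O(n³) average-
linkage agglomeration with ultrametric heights; ties break on the lowest
active-cluster index pair, making topologies deterministic. Bootstrap
support resamples loci with replacement, rebuilds the tree and counts the
percentage of replicates containing each clade's leaf set; the Newick
writer can suppress labels below 50%.

Genotype scaling for all PCA-based steps: center by locus mean dosage,
scale by sqrt(p̂(1−p̂)), replace missing values by the locus mean (PCA
only — statistics never impute). Cluster number is chosen by k-means
(10 seeded restarts) on PCs retaining ≥ 95% variance, scored by
BIC = n·ln(WSS/n) + K·ln(n), K = 1…10. DAPC retains a user-set number of
PCs (a-score optimization provided: observed self-reassignment rate minus
its mean over label-permuted refits, 10 permutations by default, optimum =
argmax), then solves the generalized eigenproblem of between- vs
within-group scatter on PC scores for ≤ (groups−1) discriminant axes.
Membership probabilities are softmax(−½·D²) with D the Mahalanobis
distance to group centroids in discriminant space under the pooled
within-group covariance (ridge 1e-8 against singularity) — the
Gaussian-posterior reading of the discriminant model; downstream checks use
aggregate assignment behavior, not exact probabilities.

Monte-Carlo cross-validation: for each cell of training fraction
{0.5, 0.7, 0.9} × locus fraction {10, 25, 50, 100%} × 30 repeats
(= 360 evaluations), a stratified training sample is drawn, loci are
ranked by training-set pairwise θ (monomorphic-in-training loci rank 0 —
the ranking never sees held-out individuals, asserted by a leakage test),
the top fraction is kept, DAPC is fitted and held-out individuals are
assigned by maximum membership.

## Outlier scan and panel design

The scan: MAF ≥ 0.05 filter, scaling, PCA, per-locus multiple regression
of the genotype on the K retained PC score vectors (orthogonal scores, so
coefficients decouple; z = t-statistics), robust Mahalanobis D² of the
z-vector via minimum covariance determinant, genomic inflation factor
gif = median(D²)/median(χ²_K), p = upper tail of χ²_K at D²/gif, Storey
q-values, outlier iff q < 0.1. K defaults to the largest drop in the
explained-variance series (elbow); the series is returned so K can be
chosen from a scree plot instead, which is the recommended practice.
Storey's π₀ is estimated on the λ-grid 0.05…0.95 with a cubic-polynomial
smoother read off at λ = 0.95, clipped to (0, 1], falling back to π₀ = 1
below 100 p-values; q = π₀ × BH, enforced monotone. Null calibration on
structureless data: gif ∈ [0.8, 1.2], near-uniform p-values, flag rate
below 2× the q-threshold.

Panel design takes, per scaffold, the SNP with maximal pairwise θ for the
target pair (ties → lowest position), ranks candidates by θ descending
(ties → contig, position) and truncates at the floor (0.15). The floor is
applied to the cross-scaffold ranked list; the result is invariant to
locus input order. Locus-wise significance is a label-permutation test
(p = (1 + #{θ_perm ≥ θ_obs})/(n_perm + 1), monomorphic → 1), chosen
because it is assumption-free and uncorrected by design. Genotype
concordance counts matching/missing/non-matching cells over the shared
individual × locus intersection, a cell missing in either matrix counting
as missing, the three percentages summing to 100. The robust subset keeps
panel loci whose per-population mean mapping quality strictly exceeds every
population's threshold; loci with absent quality records are excluded and
logged. A selection-scan comparison list from an external Bayesian method
can be supplied as a plain locus-id file to `outlier_concordance`; that
method itself is out of scope.

## Problem sizes and runtime

The test suite and `scripts/acceptance.py` size their simulations so the
whole suite runs in minutes on one CPU: F_ST recovery uses 4 × 15 × 20,000
loci with 400 coverage replicates; k-mer
recovery a 6 Mb genome over λ ∈ {10, 15, 30, 60} with 5 seeds each;
the outlier scan 10,000 loci × 60 individuals over 10 seeds; assignment the
full 2 × 47 × 173 design with the complete 360-cell CV grid; and the filter
chain the full 33,866-locus constructed input. Larger sizes change none of
the code paths.

## Known limitations

* The generator produces unlinked loci (contig assignments are labels, not
  linkage); LD surveys on simulated data therefore test the null and the
  planted-pair path, not genome-scale linkage decay.
* Bootstrap-over-loci CIs ignore the shared sampling of individuals across
  loci; at small locus counts they can under-cover.
* The Hs small-sample factor and the membership-probability formula are
  documented conventions, not the only defensible ones; both are isolated
  behind single functions.
* The exact HWE test enumerates the heterozygote-count distribution per
  locus and population in Python; at ~10⁵ tests this costs seconds, and a
  vectorized variant would be the first optimization target.
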