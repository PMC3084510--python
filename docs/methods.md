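# Methods

`lineagesort` studies a failure mode of Bayesian multilocus inference
of population structure: with few loci, different random marker panels
frequently yield *different* clustering solutions, each individually
carrying high posterior support. The cause is genealogical lineage
sorting — unlinked loci realize independent outcomes of post-split
drift, so a small panel can, by sampling chance, carry a majority
signal for the wrong grouping. This note records the models, the
defaults and why, the numerical choices, and what the synthetic data
do and do not establish.

## Clustering model

Populations (not individuals) are the units being clustered. Given a
partition S of the P population samples into k non-empty clusters, the
allele counts n_{c,l,a} pooled within cluster c at locus l are
multinomial with cluster-specific frequencies, integrated against a
symmetric Dirichlet prior with hyperparameter α_l per allele. The
marginal likelihood is available in closed form:

    log ml(S) = Σ_c Σ_l [ lnΓ(A_l α_l) − lnΓ(A_l α_l + M_{c,l})
                          + Σ_a ( lnΓ(α_l + n_{c,l,a}) − lnΓ(α_l) ) ]

with A_l the number of alleles observed at locus l across the whole
dataset, M_{c,l} the cluster's locus total, and the multinomial
ordering constant omitted consistently (it cancels in every comparison
the package makes). Missing allele slots simply contribute no term
(ignorable missingness); a half-missing genotype contributes its known
slot.

**Hyperparameter.** α_l = 1/A_l by default — one pseudo-observation
spread over the observed alleles, the convention of the group-level
mixture software family this engine emulates; `PriorSpec(alpha=...)`
fixes a constant instead. Alleles are categorical here; their sizes
matter only to the mutation model and the θ estimators.

**Partition prior.** Uniform on the number of clusters k ∈ {1..K_max}
(K_max = P unless restricted), and uniform over set partitions within
each k: log prior(S) = −ln K_max − ln S(P, k) with S the Stirling
number of the second kind. This is the only self-consistent completion
of "uniform prior on the number of clusters" and is what the posterior
probabilities below normalize against. Because S(P, k) peaks at
intermediate k, the prior mildly favours the extreme partitions (one
cluster; all singletons); at the sample sizes used here the likelihood
dominates by orders of magnitude.

**Search.** Each run starts from singleton clusters, greedily applies
the merge with the largest gain in log ml + log prior (ties within
1e−9 broken uniformly at random from the run's seed), then hill-climbs
with two move types — relocating a single population (to another
cluster or to a new singleton) and splitting a cluster by a
locally-refined binary reassignment — until no move improves the
score. Runs (default 3, mirroring the triplicate-run practice for
headline analyses) differ in their randomized population order and
tie-breaking; every partition evaluated along the way enters a ledger
keyed by its label-free set-of-sets form. The reported best partition
maximizes log ml + log prior (the MAP under the stated prior).

**Posterior probabilities.** pp(S) = exp(log ml + log prior −
logsumexp over the normalization set). For P ≤ 10 the normalization
set is the *full enumeration* of set partitions (Bell(10) = 115,975;
subset-term caching makes this cheap), so pp is exact under the model;
above that it is the search ledger, i.e. the stochastic-search
approximation any sampler-based tool reports. The boundary at 10 is a
compute choice: Bell(12) ≈ 4.2 × 10⁶ partitions would dominate the
runtime of every subsampling experiment. The pp of the best partition
is therefore conservative in ledger mode only to the extent the search
missed competitive partitions.

## Comparing clustering solutions from different locus sets

Marginal likelihoods of different locus sets are not comparable (they
scale with locus number and information content), so a test set is
characterized by the distribution of differences d = ml_test −
ml_random computed on a *common* reference pool: per replicate, draw
as many loci as the test set holds (without replacement, from a pool
excluding the test loci), find the best partition of that random set
(ml_random), evaluate the test set's partition on the same random set
(ml_test), and record the difference. If both sets support the same
solution every d ≈ 0; d ≤ 0 up to search error because ml_random is
the maximum raw log ml over the partitions the replicate's search
visited. Distributions from different test sets are compared with
two-sample Kolmogorov–Smirnov tests (asymptotic p-values; at the
default 10,000 replicates the exact small-sample distribution is
irrelevant) under a Bonferroni correction whose divisor is the number
of pairwise comparisons actually performed. Within a replicate the
random-set search uses one run by default (a 10,000-replicate
distribution with triplicate searches would triple the dominant cost;
`n_runs_random` raises it).

The predictive-power ranking conditions the *full* dataset on each
candidate partition (`conditioned_ml`) — a locus set whose solution
explains all the data well ranks high — and `feature_regression` fits
one ordinary-least-squares model per region feature against that
conditioned likelihood (slope, R², F-test p; constant features are
flagged, never fitted).

## Subsampling stability

`stability_curve` draws, for each panel size n, many random n-locus
subsets (independent draws, each without replacement), clusters each,
and records whether the best partition equals the reference
(label-free equality), its pp, and its cluster count. Summaries:
frequency of the reference, number of distinct solutions, modal
cluster count, and the fraction of wrong solutions with pp > 0.95 —
the quantity that makes the lineage-sorting effect alarming, since a
wrong solution with pp ≈ 1 is indistinguishable, from the inside, from
a right one. Per-draw searches default to a single run: the draw-level
stochasticity being measured is that of the data, and diagnostic
checks show wrong solutions at large n are genuinely better-scoring on
the drawn loci, not search failures.

## Coalescent/SMM simulation

Genealogies are simulated per locus with msprime under divergence
trees (constant sizes, no migration, no recombination — loci are
independent by construction). Time is measured in coalescent units of
2N generations (population size 0.5 in msprime's diploid convention,
so one generation = one unit). Mutations are then dropped on each
genealogy as a Poisson process at rate θ/2 per unit branch length and
step the allele size by ±1 repeat unit with probability ½ — the
strictly symmetric single-step SMM, unbounded, from an arbitrary
ancestral size of 20 repeats (label-free clustering is invariant to
it). Validation: at θ → 0 loci are monomorphic; for a single
population the mean gene diversity matches the SMM equilibrium
He = 1 − 1/√(1 + 2θ) within Monte-Carlo error. An adapter
(`read_ms_output`) converts ms-style text output with the same
site-to-±1-step convention for users with their own simulator runs.

**F_ST calibration.** Divergence scenarios with a target mean pairwise
F_ST are solved by bisection (in log scale) on a multiplier of all
split times, evaluating each candidate with pilot simulations (default
3 × 200 loci, common random seeds so the response is monotone) and the
package's own Weir–Cockerham estimator — calibration and evaluation
are deliberately self-consistent. Stopping tolerance 0.005.

**Polytomy scenario.** K populations diverging simultaneously; the
study design is 5 populations × 50 diploids × 1000 loci with targets
F_ST ∈ {0.01, 0.05, 0.10, 0.15}, θ = 1 per locus.

**13-population scenario.** Two African, six European, two
North-American and three Asian populations. Split times (frozen
defaults, coalescent units) were calibrated so the realized pairwise
F_ST structure matches what is observed between natural D.
melanogaster populations: within-Europe ≈ 0.03 (shallow star), the
North-American pair nearly undifferentiated from each other (≈ 0.004)
but slightly more diverged from Europe (≈ 0.036) than Europe is
internally, two Asians at ≈ 0.05 with the third more distant (≈ 0.09),
Asia–Europe ≈ 0.12, Africa–everything ≈ 0.21, within-Africa ≈ 0.02.
θ = 1.5 (equilibrium He = 0.5, typical of the species' microsatellite
diversity) and 30 diploids per population (the natural samples average
≈ 27). The marginal Europe-vs-North-America distinction is what makes
the full-data solution only just resolvable at 137 loci — the regime
in which subsampling instability persists to large panels.

**Expected panel size.** The 95%-recovery crossing of a *single*
137-locus realization varies between genealogical realizations by
tens of loci (occasionally it is censored at the full panel):
whether the marginal splits end up in the full-data reference is
itself a lineage-sorting outcome.
`dmel_recovery_crossing` therefore simulates 5 independent
realizations, finds each one's crossing against its own full-data
reference, and reports the mean — an estimate of the expected panel
size the study design needs. Grid: n ∈ {20, 40, 60, 80, 85, …, 135,
137} (5-locus resolution where crossings fall, to keep discretization
bias small), 200 draws per n (a desk-scale reduction of the original
1000-draw design). Averaging the recovery *curves* instead would bias
the crossing toward the worst realization, because the curve is
concave near 1.

## Five-marker-class toy model

Three populations A, B, C; marker classes support A(BC) (class 1,
truth), (AB)C, (AC)B, (ABC), and (A)(B)(C); classes 2–5 are kept
equally frequent while f₁ varies. Panels of n loci are drawn
multinomially; the supported topology is the class with the strictly
largest count. Ties are reported as a sixth "unresolved" outcome,
never silently assigned (random tie-breaking sits behind a flag). The
exact companion (`analytic_majority_probability`) computes
P(class c strictly maximal) = Σ_k P(X_c = k) · P(all other counts
< k, summing to n − k) by convolving the other classes' truncated
f^a/a! polynomials — an O(n³) dynamic program, guarded at n ≤ 150
(float-range and cost limit). Together they show the defining
property: when f₁ exceeds the other classes the truth-recovery
probability climbs to 1 with n, but at f₁ = 0.2 (no net signal) it
stays pinned near 0.2 no matter how many loci are sampled.

## Summary statistics

* **Gene diversity**: Nei's unbiased He = N/(N−1)(1 − Σp²) per group
  and locus; undefined (NaN) below 2 observed slots.
* **Allele-dropping**: for inbred-line data, one of the two slots per
  individual per locus is discarded uniformly at random (per locus
  independently — the only choice that handles partially missing
  genotypes), He is computed on the haploidized counts, and the mean
  over replicates (default 200) is returned. On fully homozygous data
  this reproduces plain He exactly up to the known N/(N−1) factors
  evaluated at N = n vs N = 2n slots.
* **F_ST**: Weir & Cockerham (1984) θ, per-allele variance components
  summed as a ratio of sums over alleles and loci (less biased than
  averaging per-locus ratios); slightly negative estimates are
  reported as computed. Only complete genotypes enter (the c component
  needs observed heterozygosity). Permutation significance shuffles
  individuals between the pair, p = (b+1)/(m+1) to avoid zero
  p-values, Bonferroni-multiplied by the number of pairs, capped at 1.
  Pairs with a population below 2 individuals are NaN.
* **θ estimators**: θ_IAM = He/(1−He); θ_SMM = ½[(1/(1−He))² − 1],
  the inverse of the SMM equilibrium above.
* **Allelic richness**: hypergeometric rarefaction
  Σ_a [1 − C(N−n_a, g)/C(N, g)] at a stated depth g; NaN where g > N.

## What the synthetic data do and do not show

The generator reproduces the features that drive the phenomenon —
independent loci, SMM allele distributions, calibrated hierarchical
F_ST structure — and omits features of real data that are orthogonal
to it: migration and admixture, bottlenecks and growth, mutation-rate
heterogeneity across loci, genotyping error and allelic dropout, and
linkage (real microsatellites clustered within 100-kb regions are
treated as unlinked, defensible where linkage disequilibrium decays
within kilobases, as in D. melanogaster). Passing tests therefore
demonstrate the statistical mechanism and the engine's correctness,
not that any particular real dataset's solution is right or wrong.

## Numerical choices and degenerate inputs

Natural logs throughout; log-sum-exp for posterior normalization;
lgamma-based binomial coefficients in rarefaction; merge ties broken
within 1e−9; empty loci (no observed alleles) contribute zero to every
likelihood; a locus-less table has log ml = 0 (empty product).
Partition identity is always the label-free set-of-sets form. All
randomness flows from a single top-level seed through documented
stream splitting (`numpy.random.default_rng`; msprime seeds drawn from
the same stream), making every experiment bit-reproducible.

## Known limitations

* Posterior probabilities in ledger mode (P > 10) depend on what the
  search visited; they overestimate support exactly the way any
  stochastic-search tool's reported pp does.
* Equivalence with the original group-clustering software is
  approximate by construction: its exact search schedule and
  normalization set are not published.
* The F_ST permutation test is O(pairs × permutations × loci) in
  Python and is meant for the dataset sizes used here (hundreds of
  individuals, ≤ a few hundred loci).
* The regression stage is exercised on synthetic features only; real
  region annotations must be supplied by the user.
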