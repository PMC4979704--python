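# Methods

This note records the statistical models implemented in `panmix`, the
parameter defaults that matter, what the synthetic-data generators do and
do not emulate, and the numerical and design choices that were genuinely
open.

## Data model

Genotypes are unphased, unordered pairs of allele symbols at biallelic SNP
loci, with per-sample habitat (littoral/benthic/pelagic) and genotyping
batch labels. Missing calls are preserved at the I/O layer and never
imputed there; each analysis declares its own missing-data policy (listed
per stage below). Analyses run on the minor-allele dosage coding (0/1/2,
−1 missing); the minor allele is the rarer one over all non-missing calls,
with an exact 0.50 tie resolved to the alphabetically later symbol. All
downstream statistics are invariant to that tie-break, which only fixes a
reporting convention.

## Locus QC

Per-locus summaries use non-missing calls only, which is why call counts
vary by locus. Expected heterozygosity is He = 2p(1−p). The
Hardy–Weinberg test is the exact conditional test: given the allele
counts, the heterozygote count has a known distribution, and the two-sided
P sums the probabilities of all configurations no more probable than the
observed one (probability ordering). Computed with log-gamma arithmetic;
an exhaustive enumeration oracle in the test suite checks every
configuration up to n = 30. Exact tests are conservative: simulated HWE
data reject at ≤ α.

Linkage is screened with the composite r²: squared Pearson correlation of
dosage vectors over pairwise-complete samples. This is what unphased data
support; no haplotype-EM r² is attempted. A locus pair whose joint support
leaves one vector constant (a rare allele entirely inside the other
locus's missing rows) contributes r² = 0 — no correlation is estimable,
which is no evidence of linkage — while fewer than two jointly typed
samples is an error.

The filtering chain removes monomorphic loci first, then loci with exact
HWE P below a threshold. The threshold defaults to 0.001: gross violations
(assay artifacts produce P values many orders of magnitude smaller) are
removed while ordinary sampling variation at n ≈ 159 is not. It is
configurable because no universal value exists.

## Weir–Cockerham Fst

Per locus, the estimator computes the three variance components a (among
populations), b (among individuals within populations), c (within
individuals) in the unequal-sample-size formulation (n̄, n_c, p̄, s², h̄);
observed heterozygote proportions enter through dosage-1 counts, which is
all unphased data require. Individuals missing at a locus are dropped from
that locus only. The overall estimate is the ratio of sums
Σa / Σ(a+b+c) — not the mean of per-locus ratios; the suite asserts a case
where the two differ. Negative per-locus values are retained for
unbiasedness of the ratio. Loci contributing a zero denominator
(monomorphic in the analyzed sample, or fewer than two groups with data)
are excluded from both sums. A scalar, loop-based transliteration of the
component formulas serves as the oracle in the tests; the production path
is vectorized across loci.

## Island-model simulation and the Fst null

The reference population is a finite island model: d demes (default 3) of
N diploids (default 1,500), L unlinked biallelic loci (default 3,150),
conservative symmetric migration (each migrant's source is uniform over
the other demes) at rate m per generation. Because loci are unlinked and
mating is random within demes, the diploid Wright–Fisher dynamics are
simulated on deme allele frequencies directly — post-migration mixing
followed by a binomial draw of 2N gametes — and individual genotypes are
realized Hardy–Weinberg within demes at sampling time. For this model
class that is the exact marginal law of individual-based simulation, and
it makes paper-scale runs take seconds rather than hours.

Founding frequencies are drawn uniformly on [0.05, 0.95] (all demes
identical at generation zero); loci fixed during burn-in are excluded from
resampling. Burn-in defaults to 10 × deme size generations with a
trailing-window slope check on realized Fst ("equilibrium" = no trend),
extended at most three times. In practice the relaxation time is
≈ 1/(2m + 1/2N); the analyses here use 1,500 generations at m ≈ 0.04
(≈ 75 relaxation times) as their problem size. Realized Fst is the
large-sample limit of Weir–Cockerham θ computed from the deme frequency
matrix, combined across loci as a ratio of sums.

Migration calibration starts from Wright's closed form
m = (1/F − 1) / (4N(d/(d−1))²) — which for three demes lands within a
factor of two of the target — and refines by bisection on log m against
the mean realized Fst of three replicate runs (default tolerance ±15%).
A Balding–Nichols shortcut (deme frequencies Beta(p(1−F)/F, (1−p)(1−F)/F),
HWE within demes) provides the same target marginal structure without
burn-in where speed matters more than mechanistic fidelity.

The null distribution of the study statistic resamples the study design:
each replicate draws the group sizes (default 55/55/49) without
replacement per deme and a locus panel (default 32) without replacement
from the polymorphic loci, then computes overall θ with demes as groups.
The empirical P of an observed θ is the plug-in lower-tail fraction
(count/reps); an add-one variant is available. Fixing the seed reproduces
the replicate vector bit-identically.

At a fixed migration rate the across-population spread of realized Fst is
small (±3% relative), so the migration-rate → empirical-P mapping is
nearly deterministic and the choice of population realization matters.
The acceptance script therefore pools its replicate budget over ten
populations, each conditioned to realize the target within 2% (migration
recentered between batches through Fst ≈ 1/(1+cm)). With the defaults
above, the null's standard deviation at the 159 × 32 design is ≈ 0.0023;
an observed θ of 0.0002 against a population at Fst 0.0025 receives an
empirical P of ≈ 0.15, and against Fst 0.1 an empirical P of 0.

## Kinship matrix and PCA

Dosages are mean-imputed (imputation count reported), centered per locus,
and scaled by the locus empirical SD by default — the "standard score" —
with sqrt(2p(1−p)) binomial scaling as an option (the two agree under HWE
and the tests check it). K = MMᵀ/2L with L the number of loci; centered
columns force every row of K to sum to zero, and unit-variance scaling
puts the mean diagonal at ≈ 0.5. Mean imputation contributes exactly zero
to K, the least-assumption treatment of missingness here. Eigenvectors of
K are the structure axes; eigenvalues are returned in descending order and
each vector's sign is fixed (largest-magnitude loading positive) for
reproducibility. Group separation along a component is judged against a
label-permutation null of the one-way variance ratio (95th percentile),
not by eye.

## Pairwise coancestry and the permutation test

All estimators return relatedness r — twice the kinship coefficient —
from unphased genotypes and reference allele frequencies computed from the
full sample, focal dyad included (the bias at n = 159 is negligible and
covered by the recovery tests). Implemented: Queller–Goodnight (multilocus
ratio of summed numerators and denominators, symmetrized over the two
orderings), the Li et al. similarity index (r = Σ(S−S₀)/Σ(1−S₀)), Ritland's
kinship moment estimator × 2 (averaged over loci), Lynch–Ritland with
their inverse-variance locus weighting (averaged over the two reference
orderings), a Wang-style moment estimator, and dyadic maximum likelihood.

The Wang-style estimator is derived for the biallelic case: the
probabilities of the genotype-similarity categories — identical genotypes;
a homozygote–heterozygote pair sharing an allele — are linear in the
IBD-state probabilities (k₁, k₂) with coefficients in the allele-frequency
power sums, and the weighted least-squares solution of that system across
loci (locus weight 1/(2a₂−a₃)) gives r = k₂ + k₁/2. Being linear in
unbiased category indicators, it is unbiased; the dyad-simulation tests
confirm recovery at r = 0.5 and r = 0.

Dyadic ML assumes no inbreeding (three IBD states, not nine Jacquard
states — the study design's own null is an outbred population) and treats
the per-locus likelihood as a mixture over states; the mixture weights are
maximized by EM, vectorized across all dyads with an active-set so
converged dyads drop out (tolerance 1e−6 on the weights, cap 2,000
iterations). EM's monotonicity guarantees the returned likelihood is at
least that of any vertex up to the stopping tolerance. Constrained to
[0, 1], the estimator is upward-biased on unrelated dyads — a documented
property, not a defect. The triadic likelihood estimator (which needs a
reference third individual) is out of scope; the permutation machinery is
estimator-agnostic, so it can be added as another column.

Estimator variance differs widely: with a 32-locus panel containing
alleles at frequency 0.003–0.01, the Ritland and Wang estimators' means
over 500 dyads scatter by ±0.01–0.015 across cohorts even though both are
unbiased — a rare-allele tail effect worth knowing before reading single
cohorts.

The group test permutes individuals across groups (sizes fixed, default
55/55/49), recomputing each group's mean within-group r from the
precomputed pair matrix per permutation (2,500 by default). Empirical P is
(count+1)/(n_perm+1), so it is never zero and its granularity matches a
2,500-permutation design. With three groups and seven estimators the
family is 21 tests, hence the Bonferroni threshold 0.05/21 ≈ 0.002. Pairs
sharing no typed locus are dropped with a warning.

## Admixture model

The vanilla admixture model with independent cluster frequencies: each
individual's allele copies are assigned to one of K clusters with
probability ∝ Q_ik · P(allele | cluster); P has a uniform Beta prior, Q
rows a symmetric Dirichlet(α) prior with α inferred by a Metropolis step
(uniform prior on (0, 10], step 0.05). Missing dosages contribute no
copies — exact marginalization under multinomial sampling. Posterior means
of Q and P accumulate over post-burn-in cycles; seeded runs are
bit-reproducible.

No within-chain relabeling is applied, deliberately: under panmixia the
posterior is symmetric under label exchange, and a chain that traverses
the label modes averages Q to the uniform vector — the symmetry diagnostic
(max over individuals of the L∞ distance of the Q row from 1/K) directly
operationalizes "everyone equally admixed". The mixing consideration
matters at small K: at K = 2 a 7,000-cycle run can sit in one label mode
and show deviations ≈ 0.11, while 25,000 cycles (5,000 burn-in + 20,000
sampling — still an order of magnitude below the 250,000/50,000
production-scale setting available by flag) mixes to < 0.05. The reduced
default (5,000 + 2,000) is a desk-scale compromise for structured-data
work, where label switching is absent and convergence is fast. A
simplified sampling-location prior (one inferred Dirichlet parameter
vector per location) is available but off by default; under the no-structure
null it is immaterial. Cluster alignment across independent runs, when
needed, is greedy matching on column correlation.

## Synthetic data: what it emulates, what it does not

The built-in panel transcribes the study design this package targets:
32 biallelic loci across 20 linkage groups with their major/minor alleles,
frequencies and per-locus call counts, and a 55/55/49 habitat split of 159
individuals. Four panel rows carry frequency pairs that do not sum to one;
the minor frequency is repaired as 1 − major and the rows are flagged. One
row (31328) prints an expected heterozygosity (0.07) inconsistent with its
own frequency pair (2pq = 0.13); the frequencies are kept authoritative,
the row is flagged, and He-reproduction checks skip it. Because printed
frequencies are rounded to two decimals, He recomputed from them can
differ from a printed He by up to 0.015 (0.01 from frequency rounding
plus 0.005 from He rounding); the acceptance check uses exactly that
bound. The mean recomputed He over the panel is 0.29.

Missingness is placed uniformly at random per locus to match the panel's
call counts — only per-locus totals are known, so no informative pattern
is modeled. Pedigree generators transmit alleles Mendelianly from founders
at panel frequencies, recording exact IBD truth ((0.25, 0.5, 0.25) for
full sibs); a single-family sibship generator provides the planted
positive control for the permutation test. The QC fixture plants 22
monomorphic loci and one all-heterozygote locus (a gross HWE violation)
among 55, mirroring a realistic panel-attrition chain.

What passing tests on these generators shows: the estimators recover known
truth under HWE, island-model structure, and Mendelian pedigrees at the
study's sample sizes. What they do not show: robustness to genotyping
error, null alleles, batch-correlated missingness, linkage, or inbreeding
— none of which the generators emulate.

## Problem sizes and runtime

The test suite runs the full acceptance set at desk scale: 2,000–4,000
null replicates per Fst comparison (production default 10,000), 2,500
permutations, 25,000-cycle admixture chains, 500-dyad recovery cohorts,
200-seed unbiasedness sweeps. The acceptance script uses the full 10,000
replicates pooled over ten conditioned populations. Everything is seeded;
every stochastic assertion was sized against the spread observed across
seeds rather than a single lucky draw.

## Known limitations

- Biallelic SNPs only; multi-allelic sites, phase, likelihood-based
  genotype uncertainty and indels are out of scope.
- The coancestry module's reference frequencies come from the analyzed
  sample; with strong hidden structure they are mixture frequencies, which
  inflates within-group relatedness — the permutation test is the guard.
- The dyadic ML estimator ignores inbreeding; in inbred populations
  r = k₂ + k₁/2 is no longer the full story.
- The admixture sampler offers no model-choice criterion for K; the
  symmetry diagnostic addresses "is there structure at all", not "how many
  clusters".
- The island simulator's frequency-resampling form is exact only for
  unlinked loci under random mating within demes; linked loci or
  assortative mating would require an individual-based simulator.
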