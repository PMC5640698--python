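# Methods

This note documents the models implemented in `roostkin`, the assumptions
behind them, the parameter choices that matter, and what the synthetic data
do and do not establish.

## Relatedness estimation

Both estimators assume unlinked, codominant, error-free diploid markers and
non-inbred individuals, with allele frequencies estimated by counting from
the analysed sample (pooled globally by default; per-site pooling is a
flag). Loci that are missing in either member of a pair, or monomorphic in
the frequency pool, are excluded pair-wise.

**Queller–Goodnight (moment).** For reference individual x with genotype
(a, b) and partner y, the per-locus numerator is S − p_a − p_b, where S is
half the count of matching allele slots, and the denominator is
1 + δ_ab − p_a − p_b. Numerators and denominators are summed across loci
before dividing (the multilocus ratio-of-sums), and the two reference
directions are averaged. The estimator is unbounded and essentially
unbiased around the true r; for two-allele heterozygote pairs at p = 1/2
the denominator vanishes — such loci simply contribute zero weight, and a
pair usable in neither direction raises an estimation error.

**Dyadic maximum likelihood.** The unordered genotype pair at each locus
has probability P_s under s ∈ {0, 1, 2} alleles shared identical by
descent (the non-inbred condensed identity states); the likelihood is the
mixture Σ_s k_s P_s with mixing weights (k₀, k₁, k₂) on the simplex, and
r = k₁/2 + k₂. The mixture weights are maximised by EM — the update is the
standard posterior-responsibility average, monotone in likelihood and
automatically simplex-feasible — from four starts (near each vertex and
the barycentre, tolerance 1e-10 on k, 2000 iterations max), keeping the
best local optimum. An exhaustive 0.02-step simplex grid in the test suite
guards against missed maxima. Because estimates are confined to [0, 1],
unrelated pairs show the usual upward truncation bias (mean ≈ +0.02 at
100 loci / 8 alleles) where the moment estimator is centred on zero.

This is deliberately the *dyadic* member of the likelihood family whose
triadic variant (TrioML, with a reference individual) was used in the
original field analysis: the IBD-likelihood machinery is identical, the
downstream tests consume any pairwise matrix, and no numerical agreement
with published TrioML values is claimed. Genotyping-error mixing is
omitted (the study reported consistent re-genotyping), as are inbreeding
states and bootstrap confidence intervals.

**Kin network.** Undirected graph over individuals with an edge wherever
r strictly exceeds τ; τ = 0.44 by default, the conventional cut separating
putative first-degree kin (r ≈ 0.5) from second-degree and below.

## Population structure

**Weir–Cockerham θ.** Per allele and locus the three variance components
a (among populations), b (among individuals within populations) and c
(within individuals) follow the 1984 formulation with n_c the usual
sample-size correction; components are summed over alleles and loci and
θ = Σa / Σ(a+b+c). Monomorphic loci contribute zero components and are not
counted as used; negative θ is reported as-is (clamping would bias
summaries). The test suite checks the implementation to 1e-12 against an
independent ANOVA route (indicator-variable mean squares MSG/MSI/MSP) on
an exhaustive sweep of tiny two-population tables. Sites with fewer than
six genotyped individuals are dropped from the pairwise-F_ST/Mantel
pipeline by default, mirroring the study's "more than five individuals per
site" filter; `min_per_site=2` disables this.

**Mantel test.** Pearson correlation of the vectorised upper triangles;
the null jointly permutes rows and columns of one matrix; p uses the
add-one convention. One-sided "greater" is the default (isolation by
distance is a directional hypothesis); two-sided is a flag, as is
Rousset's F_ST/(1−F_ST) linearisation — raw F_ST is the default because
the original analysis does not state a linearisation.

**Hardy–Weinberg screening.** A Monte Carlo exact test: gene copies at a
(site, locus) are randomly re-paired into diploids, which samples genotype
configurations conditional on the observed allele counts under HWE; the
p-value is the add-one proportion of samples whose Levene conditional
probability is at most the observed one. Monomorphic cells and sites with
fewer than five individuals are reported as untestable rather than tested.

## The two Monte Carlo permutation tests

**Approach test.** The statistic is the across-animal mean number of
approaches per offered roost type. Each permutation replicate shuffles,
independently within each animal, the assignment of that animal's counts
to roost types — counts never move between animals, which is exactly the
exchangeability the design licenses. Default sidedness is "greater" (is a
roost type approached more than chance?); two-sided is available.

**Relatedness-by-roost test.** Observed statistics are the mean pairwise
relatedness within pitcher–pitcher, within leaf–leaf and across mixed
pairs, computed over all labelled individuals. The null is built from
balanced subsets: each replicate takes all pitcher-roosting individuals
plus an equal-sized random subsample of leaf-roosting individuals, permutes
roost labels within that subset, and records the three category means. The
asymmetry (observed on everyone, null on balanced subsets) follows the
original design, in which seven pitcher bats faced 36 leaf bats. The field
description mentions both 1,000 subsample draws and 10,000 permutations
without stating their composition; the default here draws one fresh
subsample per permutation replicate, which marginalises jointly over
subsampling and label permutation in a single loop — the nested variant
(fixed panels, several permutations each) is available via
`scheme="nested"`. Because the observed leaf–leaf mean averages far more
pairs than any null replicate, the test is exactly calibrated only under
the balanced design; under the unbalanced design it is valid but
conservative for the majority category, which the calibration tests
exercise in the balanced configuration. Default sidedness is two-sided
(2·min(P_low, P_high), capped at 1), since the original results flag
departures in both directions.

Both tests, and every other stochastic routine, take a mandatory seed and
are pure functions of (inputs, seed); the add-one convention bounds the
minimum attainable p at 1/(n_perm + 1).

## Choice statistics

Fisher's 2×2 test uses the point-probability two-sided rule (sum of
margin-fixed tables no more probable than the observed), delegated to
scipy and verified against exact integer enumeration on every table with
total ≤ 40. The r×c generalisation samples margin-conditioned tables by
the Patefield algorithm and applies the same rule with the add-one
convention; at the study's table sizes Monte Carlo error is negligible
compared with the decisions made on it. "Sequential Bonferroni" is read as
Holm's step-down procedure — the standard referent of that phrase — with
plain Bonferroni as a flag. Switching percentages are rounded to the
nearest integer to match the granularity of the published 21%, with raw
fractions retained. No-choice trials are excluded from final-choice tables
(with the exclusion counted) unless explicitly kept; the plastic-tube
control is an ordinary column.

## Synthetic data: what it emulates and what it does not

The simulator is a discrete-generation Wright–Fisher model of D demes on a
1-D transect (deme i at x = 5i km), random mating within demes, symmetric
nearest-neighbour migration (an island-model variant is a flag), and
k-allele mutation. It was chosen over coalescent machinery because the
forward pedigree is needed twice: for planted kin truth and for maternal
transmission of roost preference. Defaults — 10 demes × 100 diploids,
200 generations, 16 loci, 8 alleles, μ = 1e-3, 20 sampled per deme — are
sized to reproduce the study system's reported regime: pairwise F_ST with
mean ≈ 0.03 ± 0.02 and range ≈ 0.001–0.09, strongly distance-correlated
(Mantel r ≈ 0.9). The nearest-neighbour migration rate default is m = 0.2;
pilot runs showed that substantially smaller m produces differentiation
(mean θ ≈ 0.18) far stronger than the weak structure the package is meant
to emulate. Runtime at defaults is well under a second per run; a work
bound (N·D·G·L) refuses configurations that would not finish promptly.

Roost preferences propagate down maternal lines: founders are
pitcher-roosting with probability π (default 0.3) and every other
individual copies its mother's category with probability φ (default 0.9),
otherwise drawing afresh from the baseline. φ is a free artifact parameter
implementing the maternal-transmission hypothesis, not an estimate of the
real system; under this model mother–offspring concordance is
φ + (1−φ)(π² + (1−π)²), which the tests verify at φ = 0.5. Planted
families draw parents from the table's pooled allele frequencies and
produce offspring by Mendelian sampling, so parent–offspring and full-sib
dyads have expected r = 0.5 exactly and planted pairs sit in the same
frequency background as the rest of the sample. The kin-clustered-site
fixture (seven full sibs carrying the pitcher tradition at φ = 0.95 among
36 unrelated leaf-roosting individuals) reproduces the qualitative
within-site pattern: pitcher pairs more related than the permutation null,
mixed pairs less.

Choice trials draw per-roost approach counts as Poisson with mean
λ·w/Σw from per-origin preference weights and a multinomial final choice
proportional to the same weights, replaced by "no choice" with probability
q.

What passing tests therefore show: the estimators, tests and pipeline
behave correctly on data whose generating process matches their
assumptions. What they do not show: robustness to genotyping error, null
alleles, inbreeding, sex-biased dispersal, overlapping generations or 2-D
habitat structure — none of which the generator produces, and all of which
real microsatellite data may contain.

## Numerical conventions and degenerate inputs

* Missing genotypes are 000/00 pairs only; half-missing calls are rejected
  at load so every estimator sees complete diploid calls.
* Allele labels are categorical; all estimates are invariant to
  relabelling (property-tested).
* All Monte Carlo p-values use (1 + hits)/(n + 1) and tie comparisons use
  a 1e-9…1e-12 slack appropriate to each statistic's scale.
* Degenerate cases are reported, not silently computed: zero usable loci,
  all-zero approach counts, empty pair categories, constant distance
  matrices and zero Fisher margins each produce an error, a warning with
  p = 1, or an "untestable" status as documented per function.

## Problem sizes used in the checks

The acceptance script and the heavier tests run at deliberately modest
scale, chosen as the smallest sizes at which the targeted effects are
unambiguous: 100 planted dyads per relationship at 100 loci for estimator
recovery; 400 replicates at 999 permutations for each type-I calibration;
10 simulator seeds for the isolation-by-distance check; 10,000
permutations for the planted-effect test. The whole script completes in
about a minute on one CPU.
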