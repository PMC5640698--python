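# roostkin

Population-genetic and behavioural statistics for a bat–pitcher-plant
mutualism study system: woolly bats (*Kerivoula hardwickii*) that roost
either inside *Nepenthes* pitchers or in furled leaves, genotyped at
microsatellite loci and tested for roost preference in a flight arena.

The package is for ecologists and population geneticists who need to ask,
from diploid microsatellite genotypes plus roost metadata and choice-trial
records:

* are roost-sharing bats closer kin than expected by chance?
* is genetic differentiation between sites explained by distance rather
  than by roost type?
* do bats prefer the roost type they were found in, and how often do they
  switch?

## What it computes

**Relatedness.** Pairwise relatedness r from codominant markers by two
estimators: the Queller–Goodnight moment estimator (multilocus
ratio-of-sums, symmetrised over the reference individual) and a dyadic
maximum-likelihood estimator of the non-inbred IBD-sharing coefficients
(k₀, k₁, k₂), maximising

  L(k) = Σ_loci log[ k₂·P₂(g_a, g_b) + k₁·P₁(g_a, g_b) + k₀·P₀(g_a, g_b) ]

over the simplex by multi-start EM, with r = k₁/2 + k₂. Kin networks keep
pairs with r > τ (default τ = 0.44, putative parent–offspring/full-sib
links).

**Population structure.** Pairwise Weir–Cockerham θ (variance components
a, b, c summed over alleles and loci; θ = Σa / Σ(a+b+c); negative values
retained), Mantel permutation tests for isolation by distance, and a
Guo–Thompson-style Monte Carlo exact test of Hardy–Weinberg proportions.

**Monte Carlo permutation tests.** The two bespoke tests of the study
design: (1) an approach test that shuffles each animal's approach counts
across the offered roost types and compares per-type mean approaches with
the permutation null; (2) a relatedness-by-roost test that compares mean
pairwise r within pitcher pairs, within leaf pairs and across mixed pairs
against a null built from balanced subsets with permuted roost labels.
All p-values use the add-one convention p = (1 + hits) / (n_perm + 1).

**Choice statistics.** Final-choice contingency tables, Fisher's exact
test (2×2 exact; r×c by margin-conditioned Monte Carlo), Holm step-down
("sequential Bonferroni") correction, and roost-switching summaries.

**Synthetic data.** A Wright–Fisher stepping-stone simulator (pedigree
recorded, k-allele mutation), planted parent–offspring/full-sib dyads with
known r, maternal transmission of a binary roost preference with fidelity
φ, and flight-arena trial generation — all pure functions of (config, seed).

## Worked example

```python
import roostkin as rk

# behavioural worked example: the roost-type experiment counts
trials = rk.roost_type_reference_trials()
s = rk.switching_summary(trials)["furled_leaf"]
print(s["n_switched"], "of", s["n_choosing"], "=", s["switch_percent"], "%")
# -> 8 of 38 = 21 %   (leaf-origin bats that switched to pitchers)

print(rk.fisher_exact_2x2([[18, 0], [8, 30]]))
# -> 7.357838227845548e-09  (origin x chose-pitcher association)

# genetic example: simulate ten demes on a transect, test isolation by distance
config = rk.SimulationConfig(seed=42)
table, sites, pedigree = rk.simulate_stepping_stone(config)
fst, summary = rk.pairwise_fst_matrix(table)
print(round(summary["mean"], 3), round(summary["min"], 3), round(summary["max"], 3))
# -> 0.048 0.007 0.151   (pairwise theta: mean, min, max)

res = rk.mantel_test(fst, sites.distance_matrix(fst.labels),
                     n_perm=99_999, seed=43)
print(round(res.r_observed, 2), res.p)
# -> 0.95 1e-05   (strong isolation by distance)
```

The first block reproduces the study's behavioural bookkeeping: of 68 bats
tested, 12 chose nothing within 30 minutes; every pitcher-origin chooser
stayed with pitchers while 21% of leaf-origin choosers switched. The
second block shows the simulator's default regime: weak differentiation
(mean θ ≈ 0.03–0.05) that increases with transect distance.

A full pipeline (simulate → F_ST/Mantel → relatedness → MC tests → choice
statistics → kin network, with a reproducibility manifest) runs via

```
roostkin demo --seed 7 --out demo_run
```

## Layout

```
src/roostkin/io.py         Genepop + CSV readers/writers, domain types
src/roostkin/simulate.py   WF stepping-stone simulator, planted kin, trials
src/roostkin/relatedness.py  QG + dyadic-ML estimators, kin networks
src/roostkin/popgen.py     Weir-Cockerham theta, Mantel, HWE exact MC
src/roostkin/permtest.py   the two bespoke Monte Carlo permutation tests
src/roostkin/choice.py     Fisher/Holm choice statistics, switching summary
src/roostkin/cli.py        `roostkin` CLI and the demo pipeline
docs/methods.md            models, assumptions, parameter choices
```
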