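"""Independent reference implementations used only as test oracles.

Each function recomputes a quantity by a different route from the package
code: exact integer enumeration for Fisher's test, an ANOVA mean-squares
route for the Weir-Cockerham variance components, a direct single-locus
formula for Queller-Goodnight, and brute-force enumeration over ordered
allele configurations for the IBD-state likelihoods (checked on a dense
simplex grid).
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np


# ---------------------------------------------------------------------------
# Fisher 2x2 by exact enumeration (integer arithmetic, point-probability rule)
# ---------------------------------------------------------------------------

def fisher_2x2_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration of margin-fixed tables."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    denom = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {x: Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
             for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


# ---------------------------------------------------------------------------
# Weir-Cockerham theta via the ANOVA mean-squares route
# ---------------------------------------------------------------------------

def wc_theta_anova(geno_by_pop: list[np.ndarray]):
    """theta from allele-indicator sums of squares (MSG/MSI/MSP).

    ``geno_by_pop``: per population an (n_i, 2) integer array of non-missing
    calls.  Returns (theta, a_sum, b_sum, c_sum) where a, b, c are the
    estimated variance components summed over alleles, or None if undefined.
    """
    r = len(geno_by_pop)
    n = np.array([g.shape[0] for g in geno_by_pop], dtype=float)
    n_sum = n.sum()
    if (n < 1).any() or n_sum <= r:
        return None
    n_c = (n_sum - (n ** 2).sum() / n_sum) / (r - 1)
    alleles = np.unique(np.concatenate([g.ravel() for g in geno_by_pop]))
    if alleles.size < 2:
        return None
    a_sum = b_sum = c_sum = 0.0
    for al in alleles:
        ssg = ssi = ssp = 0.0
        grand = sum(float((g == al).sum()) for g in geno_by_pop) / (2 * n_sum)
        for g in geno_by_pop:
            y = (g == al).astype(float)          # (n_i, 2) copy indicators
            ybar_ind = y.mean(axis=1)
            ybar_pop = y.mean()
            ssg += ((y - ybar_ind[:, None]) ** 2).sum()
            ssi += 2 * ((ybar_ind - ybar_pop) ** 2).sum()
            ssp += 2 * g.shape[0] * (ybar_pop - grand) ** 2
        msg = ssg / n_sum
        msi = ssi / (n_sum - r)
        msp = ssp / (r - 1)
        sigma_g = msg
        sigma_i = (msi - msg) / 2
        sigma_p = (msp - msi) / (2 * n_c)
        a_sum += sigma_p
        b_sum += sigma_i
        c_sum += sigma_g
    denom = a_sum + b_sum + c_sum
    if denom == 0:
        return None
    return a_sum / denom, a_sum, b_sum, c_sum


# ---------------------------------------------------------------------------
# Queller-Goodnight single-locus formula (direct transcription)
# ---------------------------------------------------------------------------

def qg_single_locus(ga, gb, p: dict[int, float]) -> float:
    """Symmetrised single-locus Queller-Goodnight relatedness."""
    a1, a2 = ga
    b1, b2 = gb

    def one_direction(x1, x2, y1, y2):
        sim = 0.5 * ((x1 == y1) + (x1 == y2) + (x2 == y1) + (x2 == y2))
        px = p.get(x1, 0.0) + p.get(x2, 0.0)
        return (sim - px) / (1.0 + (x1 == x2) - px)

    return 0.5 * (one_direction(a1, a2, b1, b2) + one_direction(b1, b2, a1, a2))


# ---------------------------------------------------------------------------
# IBD-state likelihood by brute-force enumeration + simplex grid search
# ---------------------------------------------------------------------------

def state_probs_enumeration(ga, gb, p: dict[int, float]):
    """(P0, P1, P2) for an unordered genotype pair by full enumeration.

    s = 0: four independent draws; s = 1: one shared draw plus one free
    draw per individual; s = 2: one shared unordered genotype.  Sums the
    probability of every ordered configuration matching the observed
    unordered genotypes.
    """
    obs_a = tuple(sorted(ga))
    obs_b = tuple(sorted(gb))
    alleles = list(p)

    def match(x, y, obs):
        return tuple(sorted((x, y))) == obs

    p0 = sum(p[w] * p[x] * p[y] * p[z]
             for w in alleles for x in alleles
             for y in alleles for z in alleles
             if match(w, x, obs_a) and match(y, z, obs_b))
    p1 = sum(p[z] * p[x] * p[y]
             for z in alleles for x in alleles for y in alleles
             if match(z, x, obs_a) and match(z, y, obs_b))
    p2 = sum(p[x] * p[y]
             for x in alleles for y in alleles
             if match(x, y, obs_a) and match(x, y, obs_b))
    return p0, p1, p2


def grid_max_loglik(state_probs: np.ndarray, step: float = 0.02):
    """Max log-likelihood over the (k0, k1, k2) simplex on a regular grid.

    ``state_probs``: (n_loci, 3) array of (P0, P1, P2) per locus.
    Returns (best_loglik, best_k).
    """
    ticks = np.arange(0.0, 1.0 + step / 2, step)
    best = (-np.inf, None)
    P = np.asarray(state_probs)
    for k0 in ticks:
        for k1 in ticks:
            k2 = 1.0 - k0 - k1
            if k2 < -1e-12:
                continue
            k2 = max(k2, 0.0)
            mix = k0 * P[:, 0] + k1 * P[:, 1] + k2 * P[:, 2]
            if (mix <= 0).any():
                continue
            ll = float(np.log(mix).sum())
            if ll > best[0]:
                best = (ll, (k0, k1, k2))
    return best


def all_genotype_configs(n: int, n_alleles: int = 2):
    """All multisets of n diploid genotypes on ``n_alleles`` alleles.

    Yields (n, 2) arrays; used for the exhaustive small-instance F_ST sweep.
    """
    genotypes = [tuple(sorted(g)) for g in
                 itertools.combinations_with_replacement(
                     range(1, n_alleles + 1), 2)]
    for combo in itertools.combinations_with_replacement(genotypes, n):
        yield np.array(combo)
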