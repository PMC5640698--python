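"""Population differentiation, isolation by distance and HWE screening.

F_ST is the Weir & Cockerham (1984) theta: per-allele variance components
a (among populations), b (among individuals within populations) and c
(within individuals), summed over alleles and loci before taking the
ratio-of-sums theta = sum(a) / sum(a + b + c).  Negative estimates are
reported as-is (they are part of an unbiased summary), and loci that are
monomorphic everywhere contribute nothing.

Isolation by distance is assessed with a Mantel test: the Pearson
correlation of the off-diagonal entries of two distance matrices, with a
null built by jointly permuting rows and columns of one matrix.

Hardy-Weinberg screening uses a Monte Carlo exact test: genotype
configurations are sampled conditional on the observed allele counts (by
random re-pairing of gene copies) and the p-value is the proportion of
configurations no more probable than the observed one.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .io import (MISSING, DistanceMatrix, GenotypeTable, ValidationError)


class PopgenError(ValueError):
    pass


@dataclass
class FstResult:
    pops: tuple[str, str]
    a: np.ndarray            # per-locus component sums (over alleles)
    b: np.ndarray
    c: np.ndarray
    theta: float
    n_loci_used: int


@dataclass
class MantelResult:
    r_observed: float
    p: float
    n_perm: int
    seed: int | None
    alternative: str


@dataclass
class HweResult:
    site: str
    locus: str
    p: float | None
    n_tables: int
    seed: int | None
    status: str = "ok"       # ok | monomorphic | too_few


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

def _wc_components_locus(geno_by_pop: list[np.ndarray]):
    """Variance components (a, b, c) summed over alleles at one locus.

    ``geno_by_pop``: per population, an (n_i, 2) array of non-missing calls.
    Returns None if the locus is unusable (some pop empty, or n_bar <= 1).
    """
    r = len(geno_by_pop)
    n = np.array([g.shape[0] for g in geno_by_pop], dtype=float)
    if (n < 1).any():
        return None
    n_sum = n.sum()
    n_bar = n_sum / r
    if n_bar <= 1 or n_sum <= r:
        return None
    n_c = (n_sum - (n ** 2).sum() / n_sum) / (r - 1)
    if n_c <= 0:
        return None
    alleles = np.unique(np.concatenate([g.ravel() for g in geno_by_pop]))
    if alleles.size < 2:
        return 0.0, 0.0, 0.0, True  # monomorphic everywhere: zero components
    a_tot = b_tot = c_tot = 0.0
    for al in alleles:
        p_i = np.array([(g == al).sum() / (2 * g.shape[0])
                        for g in geno_by_pop])
        h_i = np.array([((g == al).sum(axis=1) == 1).mean()
                        for g in geno_by_pop])
        p_bar = (n * p_i).sum() / n_sum
        s2 = (n * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
        h_bar = (n * h_i).sum() / n_sum
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4)
            / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2
            - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
        c = h_bar / 2
        a_tot += a
        b_tot += b
        c_tot += c
    return a_tot, b_tot, c_tot, False


def weir_cockerham_fst(table: GenotypeTable, pop_a: str,
                       pop_b: str) -> FstResult:
    """Multi-locus pairwise Weir-Cockerham theta between two sites."""
    groups = []
    for pop in (pop_a, pop_b):
        ids = table.individuals_of_site(pop)
        if len(ids) < 2:
            raise PopgenError(f"population {pop!r} has < 2 individuals")
        groups.append(np.array([table.index_of(i) for i in ids]))
    a_list, b_list, c_list = [], [], []
    n_used = 0
    for l in range(table.n_loci):
        geno_by_pop = []
        for idx in groups:
            g = table.calls[idx, l, :]
            g = g[g[:, 0] != MISSING]
            geno_by_pop.append(g)
        comp = _wc_components_locus(geno_by_pop)
        if comp is None:
            continue
        a, b, c, monomorphic = comp
        a_list.append(a)
        b_list.append(b)
        c_list.append(c)
        if not monomorphic:
            n_used += 1
    denom = sum(a_list) + sum(b_list) + sum(c_list)
    if n_used == 0 or denom == 0:
        raise PopgenError(
            f"no usable polymorphic loci between {pop_a!r} and {pop_b!r}")
    return FstResult(
        pops=(pop_a, pop_b),
        a=np.array(a_list), b=np.array(b_list), c=np.array(c_list),
        theta=float(sum(a_list) / denom),
        n_loci_used=n_used)


def pairwise_fst_matrix(
    table: GenotypeTable,
    min_per_site: int = 6,
) -> tuple[DistanceMatrix, dict]:
    """Pairwise theta over all usable sites, plus summary statistics.

    Sites with fewer than ``min_per_site`` genotyped individuals (default 6,
    i.e. "more than five") are excluded; pass ``min_per_site=2`` to keep
    every testable site.  Negative theta values are retained as-is.
    """
    if min_per_site < 2:
        min_per_site = 2
    sites = [s for s in table.sites
             if len(table.individuals_of_site(s)) >= min_per_site]
    if len(sites) < 2:
        raise PopgenError("fewer than 2 sites with enough individuals")
    n = len(sites)
    values = np.zeros((n, n))
    offdiag = []
    for i, j in itertools.combinations(range(n), 2):
        theta = weir_cockerham_fst(table, sites[i], sites[j]).theta
        values[i, j] = values[j, i] = theta
        offdiag.append(theta)
    offdiag = np.array(offdiag)
    summary = {
        "mean": float(offdiag.mean()), "sd": float(offdiag.std(ddof=1))
        if offdiag.size > 1 else 0.0,
        "min": float(offdiag.min()), "max": float(offdiag.max()),
        "n_pairs": int(offdiag.size),
        "excluded_sites": [s for s in table.sites if s not in sites],
    }
    # theta can be slightly negative: not a metric, but symmetric with 0 diagonal
    return DistanceMatrix(labels=sites, values=values), summary


def linearize_fst(matrix: DistanceMatrix) -> DistanceMatrix:
    """Rousset's linearisation F_ST / (1 - F_ST), off-diagonal only."""
    values = matrix.values / (1.0 - matrix.values)
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(labels=list(matrix.labels), values=values)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def mantel_test(
    d_gen: DistanceMatrix,
    d_geo: DistanceMatrix,
    n_perm: int = 99_999,
    seed: int | None = None,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel permutation test between two labelled distance matrices.

    The observed statistic is the Pearson correlation of the vectorised
    upper triangles; the null jointly permutes rows and columns of the
    second matrix.  ``alternative='greater'`` (the isolation-by-distance
    hypothesis) counts permuted correlations >= the observed one with the
    add-one convention; ``'two-sided'`` compares absolute values.
    """
    if set(d_gen.labels) != set(d_geo.labels):
        raise ValidationError("matrices must carry the same labels")
    if d_gen.n < 3:
        raise ValidationError("Mantel test needs >= 3 sites")
    if alternative not in ("greater", "two-sided"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    if seed is None:
        raise ValidationError("seed is mandatory for permutation tests")
    d_geo = d_geo.reorder(d_gen.labels)
    x = d_gen.upper_triangle()
    y = d_geo.upper_triangle()
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("constant off-diagonal: correlation undefined")
    xs = (x - x.mean()) / x.std()
    ys = (y - y.mean()) / y.std()
    r_obs = float((xs * ys).mean())

    rng = np.random.default_rng(seed)
    n = d_gen.n
    iu = np.triu_indices(n, k=1)
    Y = d_geo.values
    hits = 0
    chunk = 2000
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = np.argsort(rng.random((m, n)), axis=1)
        Yp = Y[perms[:, :, None], perms[:, None, :]]   # (m, n, n)
        yp = Yp[:, iu[0], iu[1]]                        # (m, n_pairs)
        yp = (yp - yp.mean(axis=1, keepdims=True)) / yp.std(axis=1, keepdims=True)
        r_perm = (yp * xs[None, :]).mean(axis=1)
        if alternative == "greater":
            hits += int((r_perm >= r_obs - 1e-12).sum())
        else:
            hits += int((np.abs(r_perm) >= abs(r_obs) - 1e-12).sum())
        done += m
    return MantelResult(r_observed=r_obs, p=(1 + hits) / (n_perm + 1),
                        n_perm=n_perm, seed=seed, alternative=alternative)


# ---------------------------------------------------------------------------
# Hardy-Weinberg Monte Carlo exact test
# ---------------------------------------------------------------------------

def _log_hwe_config_prob(genos: np.ndarray) -> float:
    """log P(genotype configuration | allele counts) up to margin constants.

    Levene/Haldane: P = n! 2^h prod_a m_a! / ((2n)! prod_{i<=j} n_ij!);
    only 2^h / prod n_ij! varies across configurations with fixed margins.
    """
    g = np.sort(genos, axis=1)
    het = int((g[:, 0] != g[:, 1]).sum())
    _, counts = np.unique(g, axis=0, return_counts=True)
    return het * np.log(2.0) - gammaln(counts + 1.0).sum()


def hwe_exact_mc(
    table: GenotypeTable,
    site: str,
    locus: str,
    n_tables: int = 10_000,
    seed: int | None = None,
) -> HweResult:
    """Monte Carlo exact test of Hardy-Weinberg proportions at (site, locus).

    Gene copies are randomly re-paired into diploids (which samples genotype
    configurations conditional on allele counts under HWE); the p-value is
    the add-one proportion of samples with conditional probability <= that
    of the observed configuration.  Deterministic given seed.
    """
    if seed is None:
        raise ValidationError("seed is mandatory for Monte Carlo tests")
    l = table.locus_names.index(locus)
    idx = [table.index_of(i) for i in table.individuals_of_site(site)]
    genos = table.calls[np.array(idx), l, :]
    genos = genos[genos[:, 0] != MISSING]
    n = genos.shape[0]
    if n < 5:
        return HweResult(site, locus, None, 0, seed, status="too_few")
    copies = genos.ravel()
    if np.unique(copies).size < 2:
        return HweResult(site, locus, None, 0, seed, status="monomorphic")
    log_obs = _log_hwe_config_prob(genos)
    rng = np.random.default_rng(seed)
    hits = 0
    pool = copies.copy()
    for _ in range(n_tables):
        rng.shuffle(pool)
        sampled = pool.reshape(n, 2)
        if _log_hwe_config_prob(sampled) <= log_obs + 1e-9:
            hits += 1
    return HweResult(site, locus, (1 + hits) / (n_tables + 1),
                     n_tables, seed)


def hwe_screen(table: GenotypeTable, n_tables: int = 10_000,
               seed: int | None = None) -> list[HweResult]:
    """HWE exact test over the full (site, locus) grid.

    Raw p-values; combine with :func:`roostkin.choice.holm` for the
    family-wise correction across the grid.
    """
    if seed is None:
        raise ValidationError("seed is mandatory for Monte Carlo tests")
    results = []
    for k, site in enumerate(table.sites):
        for j, locus in enumerate(table.locus_names):
            sub_seed = (seed + 1009 * k + j) % (2 ** 31)
            results.append(hwe_exact_mc(table, site, locus,
                                        n_tables=n_tables, seed=sub_seed))
    return results
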