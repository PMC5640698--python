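"""Pairwise relatedness estimation and kin-network construction.

Two estimators over diploid codominant markers:

* the Queller-Goodnight (1989) moment estimator, multilocus (numerators and
  denominators summed across loci before dividing) and symmetrised over
  which pair member serves as reference;
* a dyadic maximum-likelihood estimator of the non-inbred IBD-sharing
  coefficients (k0, k1, k2): the likelihood of the unordered genotype pair
  at each locus is a mixture over the number of alleles shared identical by
  descent, maximised over the probability simplex by EM from multiple
  starts.  Relatedness is r = k1/2 + k2.

The ML estimator is the dyadic analogue of the triadic likelihood (TrioML)
family: the same IBD-likelihood machinery without a reference individual,
so estimates are bounded to [0, 1] but carry the usual upward truncation
bias near r = 0.  Kin networks keep only pairs whose estimate exceeds a
threshold (default 0.44, i.e. putative parent-offspring/full-sib links).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import (MISSING, AlleleFreqTable, GenotypeTable, ValidationError,
                 all_pairs)

logger = logging.getLogger(__name__)

GLOBAL_POOL = "all"


class EstimationError(ValueError):
    """A pair (or matrix) could not be estimated."""


@dataclass
class RelatednessEstimate:
    pair: tuple[str, str]
    method: str                   # queller_goodnight | dyadic_ml
    r: float
    k: tuple[float, float, float] | None  # (k0, k1, k2); ML only
    n_loci_used: int
    converged: bool = True


@dataclass
class RelatednessMatrix:
    """Symmetric pairwise relatedness values; diagonal is NaN (undefined)."""

    ids: list[str]
    values: np.ndarray
    method: str

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError("matrix shape does not match ids")
        off = ~np.eye(n, dtype=bool)
        vals = self.values[off]
        finite = np.isfinite(vals)
        if not np.allclose(self.values[off][finite],
                           self.values.T[off][finite], atol=1e-9):
            raise ValidationError("relatedness matrix not symmetric")

    def value(self, id_a: str, id_b: str) -> float:
        return float(self.values[self.ids.index(id_a), self.ids.index(id_b)])

    def to_csv(self, path) -> None:
        rows = []
        for a, b in all_pairs(self.ids):
            rows.append({"id_a": a, "id_b": b, "method": self.method,
                         "r": self.value(a, b)})
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RelatednessMatrix":
        df = pd.read_csv(path, dtype={"id_a": str, "id_b": str})
        ids = sorted(set(df["id_a"]) | set(df["id_b"]))
        n = len(ids)
        idx = {v: i for i, v in enumerate(ids)}
        values = np.full((n, n), np.nan)
        for _, r in df.iterrows():
            i, j = idx[r["id_a"]], idx[r["id_b"]]
            values[i, j] = values[j, i] = r["r"]
        method = df["method"].iloc[0] if len(df) else "unknown"
        return cls(ids=ids, values=values, method=method)


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

def estimate_allele_frequencies(
    table: GenotypeTable, pooling: str = "global",
) -> AlleleFreqTable:
    """Count-based allele frequencies, pooled globally or per site.

    Frequency = allele count / non-missing gene copies per (pool, locus);
    a (pool, locus) with no non-missing calls is simply left unavailable.
    """
    if table.n_individuals == 0:
        raise ValidationError("empty genotype table")
    if pooling not in ("global", "per_site"):
        raise ValidationError(f"unknown pooling {pooling!r}")
    if pooling == "global":
        groups = {GLOBAL_POOL: np.arange(table.n_individuals)}
    else:
        groups = {site: np.array([table.index_of(i)
                                  for i in table.individuals_of_site(site)])
                  for site in table.sites}
    freqs: dict[tuple[str, str], dict[int, float]] = {}
    sizes: dict[tuple[str, str], int] = {}
    for pool, idx in groups.items():
        for l, locus in enumerate(table.locus_names):
            copies = table.calls[idx, l, :].ravel()
            copies = copies[copies != MISSING]
            if copies.size == 0:
                continue
            vals, counts = np.unique(copies, return_counts=True)
            freqs[(pool, locus)] = {int(v): c / copies.size
                                    for v, c in zip(vals, counts)}
            sizes[(pool, locus)] = int(copies.size)
    return AlleleFreqTable(freqs=freqs, sample_size=sizes)


def _pair_indices(pair, table: GenotypeTable) -> tuple[int, int]:
    a, b = pair
    return table.index_of(a), table.index_of(b)


# ---------------------------------------------------------------------------
# Queller-Goodnight moment estimator
# ---------------------------------------------------------------------------

def queller_goodnight_r(
    pair: tuple[str, str],
    table: GenotypeTable,
    freqs: AlleleFreqTable,
    pool: str = GLOBAL_POOL,
) -> RelatednessEstimate:
    """Symmetrised multilocus Queller-Goodnight relatedness.

    Loci missing in either individual or monomorphic in the pool are
    excluded; per-direction numerators and denominators are summed across
    the remaining loci before division, then the two directions averaged.
    """
    ia, ib = _pair_indices(pair, table)
    num_a = den_a = num_b = den_b = 0.0
    n_used = 0
    for l, locus in enumerate(table.locus_names):
        ga, gb = table.calls[ia, l], table.calls[ib, l]
        if ga[0] == MISSING or gb[0] == MISSING:
            continue
        if not freqs.available(pool, locus):
            continue
        p = freqs.freq(pool, locus)
        if len(p) < 2:
            continue  # monomorphic: no information
        a1, a2 = int(ga[0]), int(ga[1])
        b1, b2 = int(gb[0]), int(gb[1])
        sim = 0.5 * ((a1 == b1) + (a1 == b2) + (a2 == b1) + (a2 == b2))
        pa = p.get(a1, 0.0) + p.get(a2, 0.0)
        pb = p.get(b1, 0.0) + p.get(b2, 0.0)
        num_a += sim - pa
        den_a += 1.0 + (a1 == a2) - pa
        num_b += sim - pb
        den_b += 1.0 + (b1 == b2) - pb
        n_used += 1
    if n_used == 0:
        raise EstimationError(f"no usable loci for pair {pair}")
    directions = [(num_a, den_a), (num_b, den_b)]
    ratios = [n / d for n, d in directions if abs(d) > 1e-12]
    if not ratios:
        raise EstimationError(
            f"zero denominator in both reference directions for pair {pair}")
    return RelatednessEstimate(pair=tuple(pair), method="queller_goodnight",
                               r=float(np.mean(ratios)), k=None,
                               n_loci_used=n_used)


# ---------------------------------------------------------------------------
# Dyadic maximum-likelihood estimator
# ---------------------------------------------------------------------------

def _pair_state_probs(ga, gb, p: dict[int, float]) -> tuple[float, float, float]:
    """P(unordered genotype pair | s alleles IBD), s = 0, 1, 2 (non-inbred)."""
    a1, a2 = int(ga[0]), int(ga[1])
    b1, b2 = int(gb[0]), int(gb[1])
    for al in (a1, a2, b1, b2):
        if al not in p:
            raise EstimationError(
                f"allele {al} absent from frequency table; use pooled "
                "frequencies covering both individuals")
    pa1, pa2 = p[a1], p[a2]

    def geno_prob(x, y):
        return p[x] ** 2 if x == y else 2 * p[x] * p[y]

    p0 = geno_prob(a1, a2) * geno_prob(b1, b2)

    # one allele IBD: shared allele z, then one free allele in each individual
    p1 = 0.0
    for z in {a1, a2} & {b1, b2}:
        xa = a2 if z == a1 else a1
        xb = b2 if z == b1 else b1
        p1 += p[z] * p[xa] * p[xb]

    # two alleles IBD: genotypes identical
    if {a1, a2} == {b1, b2}:
        p2 = geno_prob(a1, a2)
    else:
        p2 = 0.0
    return p0, p1, p2


def _locus_state_probs(pair, table, freqs, pool):
    """Per-locus (P0, P1, P2) array for the usable loci of a pair."""
    ia, ib = _pair_indices(pair, table)
    rows = []
    for l, locus in enumerate(table.locus_names):
        ga, gb = table.calls[ia, l], table.calls[ib, l]
        if ga[0] == MISSING or gb[0] == MISSING:
            continue
        if not freqs.available(pool, locus):
            continue
        p = freqs.freq(pool, locus)
        rows.append(_pair_state_probs(ga, gb, p))
    if not rows:
        raise EstimationError(f"no usable loci for pair {pair}")
    return np.array(rows)  # (n_loci_used, 3) columns P0, P1, P2


_EM_STARTS = (
    (0.98, 0.01, 0.01),
    (0.01, 0.98, 0.01),
    (0.01, 0.01, 0.98),
    (1 / 3, 1 / 3, 1 / 3),
)


def _em_mixture(P: np.ndarray, start, tol=1e-10, max_iter=2000):
    """Maximise sum_l log(k . P_l) over the simplex by EM."""
    k = np.array(start, dtype=float)
    converged = False
    for _ in range(max_iter):
        weighted = k[None, :] * P          # (L, 3)
        totals = weighted.sum(axis=1)      # (L,)
        if (totals <= 0).any():
            return k, -np.inf, False
        new = (weighted / totals[:, None]).mean(axis=0)
        if np.abs(new - k).max() < tol:
            k = new
            converged = True
            break
        k = new
    loglik = float(np.log((k[None, :] * P).sum(axis=1)).sum())
    return k, loglik, converged


def dyadic_ml_r(
    pair: tuple[str, str],
    table: GenotypeTable,
    freqs: AlleleFreqTable,
    pool: str = GLOBAL_POOL,
) -> RelatednessEstimate:
    """Dyadic ML estimate of (k0, k1, k2) and r = k1/2 + k2.

    EM from four starts (near each simplex vertex plus the barycentre);
    the best local optimum is returned, with a convergence flag.
    """
    P = np.ascontiguousarray(_locus_state_probs(pair, table, freqs, pool))
    best = None
    for start in _EM_STARTS:
        k, ll, conv = _em_mixture(P, start)
        if best is None or ll > best[1]:
            best = (k, ll, conv)
    k, _, conv = best
    k = np.clip(k, 0.0, 1.0)
    k = k / k.sum()
    return RelatednessEstimate(
        pair=tuple(pair), method="dyadic_ml",
        r=float(k[1] / 2 + k[2]), k=(float(k[0]), float(k[1]), float(k[2])),
        n_loci_used=P.shape[0], converged=conv)


# ---------------------------------------------------------------------------
# Pairwise matrices
# ---------------------------------------------------------------------------

_ESTIMATORS = {
    "queller_goodnight": queller_goodnight_r,
    "qg": queller_goodnight_r,
    "dyadic_ml": dyadic_ml_r,
    "ml": dyadic_ml_r,
}


def pairwise_matrix(
    table: GenotypeTable,
    method: str = "queller_goodnight",
    freqs: AlleleFreqTable | None = None,
    pool: str = GLOBAL_POOL,
) -> RelatednessMatrix:
    """Apply an estimator to all unordered pairs of the table.

    Per-pair estimation errors become NaN entries (counted in the log);
    the result is symmetric with an undefined (NaN) diagonal.
    """
    if method not in _ESTIMATORS:
        raise ValidationError(f"unknown estimator {method!r}")
    estimator = _ESTIMATORS[method]
    if freqs is None:
        freqs = estimate_allele_frequencies(table, pooling="global")
    n = table.n_individuals
    values = np.full((n, n), np.nan)
    n_failed = 0
    for i, j in itertools.combinations(range(n), 2):
        pair = (table.individual_ids[i], table.individual_ids[j])
        try:
            est = estimator(pair, table, freqs, pool=pool)
        except EstimationError:
            n_failed += 1
            continue
        values[i, j] = values[j, i] = est.r
    if n_failed:
        logger.warning("pairwise_matrix: %d of %d pairs failed estimation",
                       n_failed, n * (n - 1) // 2)
    canonical = "dyadic_ml" if method in ("ml", "dyadic_ml") else "queller_goodnight"
    return RelatednessMatrix(ids=list(table.individual_ids), values=values,
                             method=canonical)


def write_estimates_csv(estimates: list[RelatednessEstimate], path) -> None:
    """Full per-pair estimate table: id_a,id_b,method,r,k0,k1,k2,n_loci."""
    rows = []
    for e in estimates:
        k0, k1, k2 = e.k if e.k is not None else (np.nan, np.nan, np.nan)
        rows.append({"id_a": e.pair[0], "id_b": e.pair[1], "method": e.method,
                     "r": e.r, "k0": k0, "k1": k1, "k2": k2,
                     "n_loci": e.n_loci_used})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Kin network
# ---------------------------------------------------------------------------

def build_kin_network(
    matrix: RelatednessMatrix,
    tau: float = 0.44,
    roost_of: dict[str, str] | None = None,
    sex_of: dict[str, str] | None = None,
) -> nx.Graph:
    """Undirected network keeping only pairs with r strictly above ``tau``.

    The default threshold 0.44 retains putative first-degree relatives
    (parent-offspring and full sibs).  Nodes carry roost and sex attributes
    when provided.
    """
    if not (-1.0 <= tau <= 1.1):
        raise ValidationError("threshold tau outside sensible range")
    g = nx.Graph(threshold=tau, method=matrix.method)
    for ind in matrix.ids:
        g.add_node(ind,
                   roost=(roost_of or {}).get(ind),
                   sex=(sex_of or {}).get(ind))
    for a, b in all_pairs(matrix.ids):
        r = matrix.value(a, b)
        if np.isfinite(r) and r > tau:
            g.add_edge(a, b, r=float(r))
    return g


def write_network_csv(g: nx.Graph, edges_path, nodes_path) -> None:
    edges = pd.DataFrame(
        [{"id_a": a, "id_b": b, "r": d["r"]} for a, b, d in g.edges(data=True)])
    edges.to_csv(edges_path, index=False)
    nodes = pd.DataFrame(
        [{"id": n, "roost": d.get("roost") or "", "sex": d.get("sex") or ""}
         for n, d in g.nodes(data=True)])
    nodes.to_csv(nodes_path, index=False)
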