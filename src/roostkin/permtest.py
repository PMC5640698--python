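"""The study design's two bespoke Monte Carlo permutation tests.

Approach test: for each tested animal the assignment of its approach counts
to the offered roost types is shuffled (counts stay with the animal); the
statistic is the mean number of approaches per roost type across animals,
and each type's observed mean is compared with its permutation null.

Relatedness-by-roost test: the observed statistics are the mean pairwise
relatedness within pitcher-pitcher pairs, within leaf-leaf pairs, and
across mixed pairs, computed over *all* labelled individuals.  The null is
built from balanced subsets: each replicate draws all pitcher-roosting
individuals plus an equally sized random subsample of leaf-roosting ones,
permutes the roost labels within that subset, and records the three
category means.  One fresh subsample per permutation replicate marginalises
jointly over subsampling and label permutation; a nested scheme (fixed
panels, several permutations each) is available for comparison.

All p-values use the add-one convention p = (1 + hits) / (n_perm + 1), so
the minimum attainable p is 1/(n_perm + 1) and p is never 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .choice import ChoiceTrial
from .io import ValidationError
from .relatedness import RelatednessMatrix

PAIR_CATEGORIES = ("pitcher-pitcher", "leaf-leaf", "mixed")


@dataclass
class MCTestResult:
    """Observed statistics, permutation null and p-values of one MC test."""

    statistic: str
    categories: list[str]
    observed: dict[str, float]
    p_values: dict[str, float]
    null_samples: dict[str, np.ndarray]
    n_perm: int
    seed: int | None
    sidedness: str
    status: dict[str, str] = field(default_factory=dict)

    def null_summary(self, category: str) -> dict:
        ns = self.null_samples[category]
        qs = np.quantile(ns, [0.025, 0.5, 0.975])
        return {"mean": float(ns.mean()), "sd": float(ns.std(ddof=1)),
                "q025": float(qs[0]), "median": float(qs[1]),
                "q975": float(qs[2])}

    def to_dict(self, include_null: bool = False) -> dict:
        out = {
            "statistic": self.statistic,
            "categories": list(self.categories),
            "observed": {k: float(v) for k, v in self.observed.items()},
            "p_values": {k: float(v) for k, v in self.p_values.items()},
            "n_perm": self.n_perm,
            "seed": self.seed,
            "sidedness": self.sidedness,
            "status": dict(self.status),
            "null": {c: self.null_summary(c) for c in self.categories
                     if c in self.null_samples and
                     len(self.null_samples[c])},
        }
        if include_null:
            out["null_samples"] = {c: s.tolist()
                                   for c, s in self.null_samples.items()}
        return out


def _p_from_null(obs: float, null: np.ndarray, sidedness: str) -> float:
    n = null.size
    eps = 1e-12
    p_hi = (1 + int((null >= obs - eps).sum())) / (n + 1)
    p_lo = (1 + int((null <= obs + eps).sum())) / (n + 1)
    if sidedness == "greater":
        return p_hi
    if sidedness == "less":
        return p_lo
    if sidedness == "two_sided":
        return min(1.0, 2 * min(p_lo, p_hi))
    raise ValidationError(f"unknown sidedness {sidedness!r}")


# ---------------------------------------------------------------------------
# Approach permutation test
# ---------------------------------------------------------------------------

def approach_permutation_test(
    trials: list[ChoiceTrial],
    n_perm: int = 10_000,
    seed: int | None = None,
    sidedness: str = "greater",
) -> MCTestResult:
    """Permutation test of roost-type effect on approach counts.

    Every trial must offer the same roost-type set.  Each permutation
    independently shuffles, within each animal, which count belongs to
    which roost type; observed and null statistics are the across-animal
    mean approaches per roost type.
    """
    if not trials:
        raise ValidationError("need at least one trial")
    if seed is None:
        raise ValidationError("seed is mandatory for permutation tests")
    offered = trials[0].offered
    for t in trials:
        if t.offered != offered:
            raise ValidationError(
                f"inconsistent offered sets: {t.offered} vs {offered}")
    counts = np.array([t.approaches for t in trials], dtype=float)
    n_animals, n_types = counts.shape
    observed = counts.mean(axis=0)
    if counts.sum() == 0:
        warnings.warn("all approach counts are zero; p = 1 for every type")

    rng = np.random.default_rng(seed)
    # shuffle count-to-type assignment within each animal, independently
    # per permutation replicate
    tiled = np.broadcast_to(counts, (n_perm, n_animals, n_types)).copy()
    null = rng.permuted(tiled, axis=2).mean(axis=1)   # (n_perm, n_types)

    p_values = {}
    null_samples = {}
    for j, roost in enumerate(offered):
        null_samples[roost] = null[:, j]
        p_values[roost] = _p_from_null(float(observed[j]), null[:, j],
                                       sidedness)
    return MCTestResult(
        statistic="mean approaches per roost type",
        categories=list(offered),
        observed={r: float(observed[j]) for j, r in enumerate(offered)},
        p_values=p_values,
        null_samples=null_samples,
        n_perm=n_perm, seed=seed, sidedness=sidedness)


# ---------------------------------------------------------------------------
# Relatedness-by-roost-preference test
# ---------------------------------------------------------------------------

def _category_means(R: np.ndarray, is_pitcher: np.ndarray) -> np.ndarray:
    """Mean pairwise r for (pp, ll, mixed) given a boolean pitcher mask."""
    n = R.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = R[iu]
    cat_p = is_pitcher[iu[0]].astype(int) + is_pitcher[iu[1]].astype(int)
    out = np.full(3, np.nan)
    for k, sel in ((0, cat_p == 2), (1, cat_p == 0), (2, cat_p == 1)):
        v = vals[sel]
        v = v[np.isfinite(v)]
        if v.size:
            out[k] = v.mean()
    return out


def relatedness_roost_test(
    matrix: RelatednessMatrix,
    roost_of: dict[str, str],
    n_subsample: int = 7,
    n_perm: int = 10_000,
    seed: int | None = None,
    sidedness: str = "two_sided",
    scheme: str = "joint",
    n_panels: int = 1_000,
) -> MCTestResult:
    """Monte Carlo test of roost-assortative relatedness within a site.

    ``scheme='joint'`` (default) draws one fresh leaf subsample per
    permutation replicate; ``'nested'`` draws ``n_panels`` subsample panels
    and permutes labels ``n_perm // n_panels`` times within each.
    """
    if seed is None:
        raise ValidationError("seed is mandatory for permutation tests")
    if scheme not in ("joint", "nested"):
        raise ValidationError(f"unknown scheme {scheme!r}")
    matrix_ids = set(matrix.ids)
    missing = [i for i in roost_of if i not in matrix_ids]
    if missing:
        raise ValidationError(
            f"matrix does not cover labelled individuals: {missing[:5]}")
    ids = [i for i in matrix.ids if i in roost_of]
    is_pitcher = np.array([roost_of[i] == "pitcher" for i in ids])
    if is_pitcher.all() or not is_pitcher.any():
        raise ValidationError("both roost categories must be non-empty")
    idx = np.array([matrix.ids.index(i) for i in ids])
    R = matrix.values[np.ix_(idx, idx)]
    n_dropped = int(np.isnan(R[np.triu_indices(len(ids), k=1)]).sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} pairs without relatedness estimate dropped")

    pitcher_idx = np.nonzero(is_pitcher)[0]
    leaf_idx = np.nonzero(~is_pitcher)[0]
    if n_subsample > leaf_idx.size:
        raise ValidationError(
            f"n_subsample={n_subsample} exceeds {leaf_idx.size} leaf-roosting "
            "individuals")

    observed = _category_means(R, is_pitcher)

    rng = np.random.default_rng(seed)
    n_p = pitcher_idx.size
    m = n_p + n_subsample
    if scheme == "joint":
        panel_draws = n_perm
        perms_per_panel = 1
    else:
        perms_per_panel = max(1, n_perm // n_panels)
        panel_draws = int(np.ceil(n_perm / perms_per_panel))

    chunk = 2000
    rows = []
    drawn = 0
    while drawn < n_perm:
        want = min(chunk, n_perm - drawn)
        panels = int(np.ceil(want / perms_per_panel))
        # leaf subsample per panel
        sub = np.array([rng.choice(leaf_idx, size=n_subsample, replace=False)
                        for _ in range(panels)])
        members = np.concatenate(
            [np.broadcast_to(pitcher_idx, (panels, n_p)), sub], axis=1)
        members = np.repeat(members, perms_per_panel, axis=0)[:want]
        # permute roost labels within each subset
        order = np.argsort(rng.random((want, m)), axis=1)
        perm_members = np.take_along_axis(members, order, axis=1)
        sub_R = R[perm_members[:, :, None], perm_members[:, None, :]]
        lab = np.zeros((want, m), dtype=bool)
        lab[:, :n_p] = True                      # first n_p slots = "pitcher"
        iu = np.triu_indices(m, k=1)
        vals = sub_R[:, iu[0], iu[1]]
        cat = lab[:, iu[0]].astype(int) + lab[:, iu[1]].astype(int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            pp = np.nanmean(np.where(cat == 2, vals, np.nan), axis=1)
            ll = np.nanmean(np.where(cat == 0, vals, np.nan), axis=1)
            mixed = np.nanmean(np.where(cat == 1, vals, np.nan), axis=1)
        rows.append(np.stack([pp, ll, mixed], axis=1))
        drawn += want
    null = np.concatenate(rows, axis=0)

    result_obs, result_p, null_samples, status = {}, {}, {}, {}
    for k, cat_name in enumerate(PAIR_CATEGORIES):
        if not np.isfinite(observed[k]):
            status[cat_name] = "untestable"
            result_obs[cat_name] = float("nan")
            result_p[cat_name] = float("nan")
            null_samples[cat_name] = np.empty(0)
            continue
        ns = null[:, k]
        ns = ns[np.isfinite(ns)]
        null_samples[cat_name] = ns
        result_obs[cat_name] = float(observed[k])
        result_p[cat_name] = _p_from_null(float(observed[k]), ns, sidedness)
        status[cat_name] = "ok"
    return MCTestResult(
        statistic="mean pairwise relatedness by roost-pair category",
        categories=list(PAIR_CATEGORIES),
        observed=result_obs, p_values=result_p, null_samples=null_samples,
        n_perm=n_perm, seed=seed, sidedness=sidedness, status=status)
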