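import itertools
import time

import numpy as np
import pytest

import roostkin as rk
from roostkin.io import DistanceMatrix, ValidationError
from roostkin.popgen import PopgenError, _wc_components_locus
from conftest import make_table
from oracles import all_genotype_configs, wc_theta_anova


def two_pop_table(genos_a, genos_b):
    n_a, n_b = len(genos_a), len(genos_b)
    ids = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    sites = {i: ("A" if i.startswith("a") else "B") for i in ids}
    calls = np.array(list(genos_a) + list(genos_b)).reshape(n_a + n_b, 1, 2)
    return make_table(calls, sites=sites, ids=ids)


# -- Weir-Cockerham theta ----------------------------------------------------

def test_fixed_difference_theta_one():
    table = two_pop_table([[1, 1]] * 20, [[2, 2]] * 20)
    res = rk.weir_cockerham_fst(table, "A", "B")
    assert res.theta == pytest.approx(1.0, abs=1e-12)


def test_identical_frequency_samples_near_zero():
    """Two samples from one pool: theta is a small-magnitude estimate."""
    rng = np.random.default_rng(99)
    thetas = []
    for _ in range(20):
        calls = rng.integers(1, 9, size=(100, 16, 2))
        ids = [f"i{j}" for j in range(100)]
        sites = {f"i{j}": ("A" if j < 50 else "B") for j in range(100)}
        table = make_table(calls, sites=sites, ids=ids)
        thetas.append(rk.weir_cockerham_fst(table, "A", "B").theta)
    assert max(abs(t) for t in thetas) <= 0.02


def test_toy_table_matches_anova_oracle():
    genos_a = [[1, 1], [1, 2], [1, 2], [2, 2], [1, 1]]
    genos_b = [[2, 2], [1, 2], [2, 2], [2, 2]]
    table = two_pop_table(genos_a, genos_b)
    res = rk.weir_cockerham_fst(table, "A", "B")
    oracle = wc_theta_anova([np.array(genos_a), np.array(genos_b)])
    assert res.theta == pytest.approx(oracle[0], abs=1e-12)
    assert res.a.sum() == pytest.approx(oracle[1], abs=1e-12)
    assert res.b.sum() == pytest.approx(oracle[2], abs=1e-12)
    assert res.c.sum() == pytest.approx(oracle[3], abs=1e-12)


def test_exhaustive_small_instance_oracle_sweep():
    """All 2-pop, 1-locus, 2-allele tables with n_i <= 6 match the oracle."""
    configs = {n: list(all_genotype_configs(n)) for n in (2, 3, 6)}
    checked = 0
    for n_a, n_b in [(2, 2), (2, 3), (3, 3), (2, 6), (6, 6)]:
        for ga in configs[n_a]:
            for gb in configs[n_b]:
                oracle = wc_theta_anova([ga, gb])
                comp = _wc_components_locus([ga, gb])
                if oracle is None:
                    # monomorphic or degenerate: implementation must agree
                    assert comp is None or comp[3] or \
                        (comp[0] + comp[1] + comp[2]) == 0
                    continue
                a, b, c, mono = comp
                assert not mono
                assert a / (a + b + c) == pytest.approx(oracle[0], abs=1e-12)
                checked += 1
    assert checked > 1000


def test_monomorphic_locus_excluded():
    table = two_pop_table([[1, 1]] * 3, [[1, 1]] * 3)
    with pytest.raises(PopgenError):
        rk.weir_cockerham_fst(table, "A", "B")


# -- pairwise matrix ---------------------------------------------------------

def test_duplicated_population_near_zero_offdiagonal():
    rng = np.random.default_rng(5)
    base = rng.integers(1, 6, size=(100, 10, 2))
    ids = [f"i{j}" for j in range(200)]
    sites = {f"i{j}": ("A" if j < 100 else "B") for j in range(200)}
    table = make_table(np.concatenate([base, base]), sites=sites, ids=ids)
    matrix, summary = rk.pairwise_fst_matrix(table, min_per_site=2)
    # duplicating one sample pins s^2 = 0, leaving theta slightly below 0
    assert -0.02 < summary["mean"] <= 0.0


def test_default_simulation_theta_range(default_sim):
    _, table, _, _ = default_sim
    matrix, summary = rk.pairwise_fst_matrix(table)
    assert 0.005 <= summary["mean"] <= 0.15
    np.testing.assert_allclose(matrix.values, matrix.values.T)
    assert np.diag(matrix.values).sum() == 0
    assert summary["n_pairs"] == 45


def test_small_sites_excluded(default_sim):
    _, table, _, _ = default_sim
    # drop most of deme_0 so it falls under the > 5 individuals rule
    keep = [i for i in table.individual_ids
            if table.site_of[i] != "deme_0"] + \
           table.individuals_of_site("deme_0")[:3]
    sub = table.subset(keep)
    matrix, summary = rk.pairwise_fst_matrix(sub)
    assert "deme_0" in summary["excluded_sites"]
    assert "deme_0" not in matrix.labels
    # disabling the filter keeps it
    matrix2, _ = rk.pairwise_fst_matrix(sub, min_per_site=2)
    assert "deme_0" in matrix2.labels


# -- Mantel ------------------------------------------------------------------

def random_dm(rng, n=8):
    a = rng.random((n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0)
    return DistanceMatrix([f"s{i}" for i in range(n)], a)


def test_mantel_identity_matrices():
    rng = np.random.default_rng(1)
    d = random_dm(rng)
    res = rk.mantel_test(d, d, n_perm=999, seed=2)
    assert res.r_observed == pytest.approx(1.0)
    assert res.p == pytest.approx(1 / 1000)


def test_mantel_constant_matrix_rejected():
    labels = ["a", "b", "c"]
    const = DistanceMatrix(labels, np.ones((3, 3)) - np.eye(3))
    with pytest.raises(ValidationError):
        rk.mantel_test(const, const, n_perm=99, seed=1)


def test_mantel_matches_skbio_oracle():
    skbio_stats = pytest.importorskip("skbio.stats.distance")
    rng = np.random.default_rng(7)
    x, y = random_dm(rng), random_dm(rng)
    res = rk.mantel_test(x, y, n_perm=999, seed=3)
    r_skbio, p_skbio, _ = skbio_stats.mantel(
        skbio_stats.DistanceMatrix(x.values, x.labels),
        skbio_stats.DistanceMatrix(y.values, y.labels),
        method="pearson", permutations=999, alternative="greater")
    assert res.r_observed == pytest.approx(float(r_skbio), abs=1e-12)
    assert abs(res.p - float(p_skbio)) < 0.1


def test_mantel_label_alignment():
    rng = np.random.default_rng(11)
    x = random_dm(rng)
    shuffled = x.reorder(list(reversed(x.labels)))
    res = rk.mantel_test(x, shuffled, n_perm=99, seed=4)
    assert res.r_observed == pytest.approx(1.0)


def test_mantel_speed_at_study_scale():
    """8 sites, 99,999 permutations: well under a second."""
    rng = np.random.default_rng(13)
    x, y = random_dm(rng), random_dm(rng)
    t0 = time.time()
    rk.mantel_test(x, y, n_perm=99_999, seed=5)
    assert time.time() - t0 < 2.0


def test_linearize_fst():
    dm = DistanceMatrix(["a", "b"], np.array([[0.0, 0.2], [0.2, 0.0]]))
    lin = rk.linearize_fst(dm)
    assert lin.values[0, 1] == pytest.approx(0.25)


# -- HWE ---------------------------------------------------------------------

def test_hwe_under_hw_proportions_not_rejected():
    rng = np.random.default_rng(17)
    calls = rng.integers(1, 5, size=(100, 1, 2))  # HW by construction
    table = make_table(calls)
    res = rk.hwe_exact_mc(table, "s1", "L0", n_tables=2000, seed=19)
    assert res.status == "ok"
    assert res.p > 0.01


def test_hwe_extreme_heterozygote_excess_rejected():
    table = make_table([[[1, 2]]] * 50)
    res = rk.hwe_exact_mc(table, "s1", "L0", n_tables=2000, seed=23)
    assert res.p < 0.01


def test_hwe_determinism_and_statuses():
    table = make_table([[[1, 2]]] * 20)
    a = rk.hwe_exact_mc(table, "s1", "L0", n_tables=500, seed=29)
    b = rk.hwe_exact_mc(table, "s1", "L0", n_tables=500, seed=29)
    assert a.p == b.p
    mono = make_table([[[1, 1]]] * 20)
    assert rk.hwe_exact_mc(mono, "s1", "L0", seed=1).status == "monomorphic"
    tiny = make_table([[[1, 2]]] * 3)
    assert rk.hwe_exact_mc(tiny, "s1", "L0", seed=1).status == "too_few"


def test_hwe_screen_covers_grid(default_sim):
    _, table, _, _ = default_sim
    sub = table.subset(table.individuals_of_site("deme_0")
                       + table.individuals_of_site("deme_1"))
    results = rk.hwe_screen(sub, n_tables=200, seed=31)
    assert len(results) == 2 * sub.n_loci
    ps = [r.p for r in results if r.status == "ok"]
    battery = rk.holm(ps)
    assert (battery.frame["p_adjusted"] >= battery.frame["p_raw"] - 1e-12).all()
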