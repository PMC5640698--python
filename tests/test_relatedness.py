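import itertools

import numpy as np
import pytest

import roostkin as rk
from roostkin.io import AlleleFreqTable, ValidationError
from roostkin.relatedness import (EstimationError, GLOBAL_POOL,
                                  _locus_state_probs, dyadic_ml_r,
                                  pairwise_matrix, queller_goodnight_r)
from conftest import make_table
from oracles import grid_max_loglik, qg_single_locus, state_probs_enumeration


def freq_table(per_locus: list[dict[int, float]]) -> AlleleFreqTable:
    return AlleleFreqTable(
        freqs={(GLOBAL_POOL, f"L{j}"): p for j, p in enumerate(per_locus)},
        sample_size={(GLOBAL_POOL, f"L{j}"): 20
                     for j in range(len(per_locus))})


# -- allele frequencies ------------------------------------------------------

def test_frequency_counting_trivial():
    t1 = make_table([[[2, 2]]])
    f1 = rk.estimate_allele_frequencies(t1)
    assert f1.freq(GLOBAL_POOL, "L0") == {2: 1.0}
    t2 = make_table([[[1, 1]], [[2, 2]]])
    f2 = rk.estimate_allele_frequencies(t2)
    assert f2.freq(GLOBAL_POOL, "L0") == {1: 0.5, 2: 0.5}


def test_frequency_counting_hand_tally():
    rng = np.random.default_rng(3)
    calls = rng.integers(1, 5, size=(10, 2, 2))
    table = make_table(calls)
    freqs = rk.estimate_allele_frequencies(table)
    for j, locus in enumerate(table.locus_names):
        copies = list(calls[:, j, :].ravel())
        for allele, freq in freqs.freq(GLOBAL_POOL, locus).items():
            assert freq == pytest.approx(copies.count(allele) / 20)


def test_missing_pool_locus_unavailable():
    table = make_table([[[0, 0]], [[0, 0]]])
    freqs = rk.estimate_allele_frequencies(table)
    assert not freqs.available(GLOBAL_POOL, "L0")


# -- Queller-Goodnight -------------------------------------------------------

def test_qg_matches_single_locus_oracle():
    """Non-degenerate single-locus cases agree with the direct formula."""
    p = {1: 0.3, 2: 0.2, 3: 0.4, 4: 0.1}
    cases = [((1, 2), (1, 2)), ((1, 1), (1, 2)), ((1, 2), (3, 4)),
             ((1, 1), (1, 1)), ((2, 3), (2, 4)), ((1, 1), (2, 2))]
    for ga, gb in cases:
        table = make_table([[list(ga)], [list(gb)]], ids=["x", "y"])
        est = queller_goodnight_r(("x", "y"), table, freq_table([p]))
        assert est.r == pytest.approx(qg_single_locus(ga, gb, p), abs=1e-12)
        # symmetric in pair order
        est_rev = queller_goodnight_r(("y", "x"), table, freq_table([p]))
        assert est.r == pytest.approx(est_rev.r, abs=1e-12)


def test_qg_excludes_monomorphic_and_missing():
    table = make_table([[[1, 2], [5, 5], [0, 0]],
                        [[1, 1], [5, 5], [3, 4]]], ids=["x", "y"])
    freqs = rk.estimate_allele_frequencies(table)
    est = queller_goodnight_r(("x", "y"), table, freqs)
    assert est.n_loci_used == 1  # L1 monomorphic, L2 missing in x
    only_mono = make_table([[[5, 5]], [[5, 5]]], ids=["x", "y"])
    with pytest.raises(EstimationError):
        queller_goodnight_r(("x", "y"), only_mono,
                            rk.estimate_allele_frequencies(only_mono))


# -- dyadic ML ---------------------------------------------------------------

def test_state_probs_match_enumeration_oracle():
    """Closed-form IBD-state likelihoods equal brute-force enumeration."""
    p = {1: 0.4, 2: 0.3, 3: 0.2, 4: 0.1}
    genotype_pairs = [((1, 1), (1, 1)), ((1, 1), (2, 2)), ((1, 1), (1, 2)),
                      ((1, 1), (2, 3)), ((1, 2), (1, 2)), ((1, 2), (1, 3)),
                      ((1, 2), (3, 4))]
    from roostkin.relatedness import _pair_state_probs
    for ga, gb in genotype_pairs:
        got = _pair_state_probs(np.array(ga), np.array(gb), p)
        expected = state_probs_enumeration(ga, gb, p)
        assert got == pytest.approx(expected, abs=1e-12)


def test_ml_identical_genotypes_rare_alleles():
    """50 loci of identical genotypes with rare alleles: r near 1."""
    rng = np.random.default_rng(8)
    geno = rng.integers(1, 9, size=(50, 2))
    table = make_table([geno, geno.copy()], ids=["x", "y"])
    p = {a: 1 / 8 for a in range(1, 9)}
    est = dyadic_ml_r(("x", "y"), table, freq_table([p] * 50))
    assert est.r >= 0.9
    assert sum(est.k) == pytest.approx(1.0, abs=1e-6)


def test_ml_simplex_constraint_and_grid_oracle(iid_table_100):
    """EM optimum on the simplex and >= the 0.02-step grid maximum."""
    rng = np.random.default_rng(12)
    freqs = rk.estimate_allele_frequencies(iid_table_100)
    ids = iid_table_100.individual_ids
    for _ in range(10):
        a, b = rng.choice(len(ids), size=2, replace=False)
        pair = (ids[a], ids[b])
        est = dyadic_ml_r(pair, iid_table_100, freqs)
        k = np.array(est.k)
        assert k.sum() == pytest.approx(1.0, abs=1e-6)
        assert (k >= -1e-9).all()
        assert est.r == pytest.approx(k[1] / 2 + k[2], abs=1e-9)
        P = _locus_state_probs(pair, iid_table_100, freqs, GLOBAL_POOL)
        grid_best, _ = grid_max_loglik(P)
        ll = float(np.log((k[None, :] * P).sum(axis=1)).sum())
        assert ll >= grid_best - 1e-6


def test_ml_unseen_allele_errors():
    table = make_table([[[1, 2]], [[1, 3]]], ids=["x", "y"])
    with pytest.raises(EstimationError, match="absent"):
        dyadic_ml_r(("x", "y"), table, freq_table([{1: 0.5, 2: 0.5}]))


def test_estimators_invariant_to_allele_relabeling(iid_table_100):
    """Allele labels are categorical: permuting them changes nothing."""
    sub = iid_table_100.subset(iid_table_100.individual_ids[:6])
    relabeled = make_table(11 * sub.calls - 3, ids=sub.individual_ids,
                           loci=sub.locus_names)
    f1 = rk.estimate_allele_frequencies(sub)
    f2 = rk.estimate_allele_frequencies(relabeled)
    pair = tuple(sub.individual_ids[:2])
    assert queller_goodnight_r(pair, sub, f1).r == pytest.approx(
        queller_goodnight_r(pair, relabeled, f2).r, abs=1e-12)
    assert dyadic_ml_r(pair, sub, f1).r == pytest.approx(
        dyadic_ml_r(pair, relabeled, f2).r, abs=1e-6)


# -- pairwise matrix and kin network -----------------------------------------

def test_pairwise_matrix_shape_and_symmetry(airport):
    table, _ = airport
    matrix = pairwise_matrix(table, "queller_goodnight")
    n = table.n_individuals
    off = ~np.eye(n, dtype=bool)
    assert np.isfinite(matrix.values[off]).sum() == n * (n - 1)
    np.testing.assert_allclose(matrix.values[off], matrix.values.T[off])
    assert np.isnan(np.diag(matrix.values)).all()


def test_planted_fs_exceed_unrelated(airport):
    table, truth = airport
    matrix = pairwise_matrix(table, "queller_goodnight")
    fs_vals = [matrix.value(r.id_a, r.id_b) for r in truth.itertuples()]
    bg_ids = [i for i in table.individual_ids if i.startswith("bg_")]
    bg_vals = [matrix.value(a, b)
               for a, b in itertools.combinations(bg_ids[:20], 2)]
    assert np.mean(fs_vals) > np.mean(bg_vals) + 0.3


def test_kin_network_threshold_behaviour(iid_table_100):
    """Fixture built so exactly one pair's estimate exceeds tau = 0.44."""
    base = iid_table_100.subset(iid_table_100.individual_ids[:10])
    twin = base.individual_ids[0]
    table = make_table(
        np.concatenate([base.calls, base.calls[:1]]),
        ids=base.individual_ids + ["twin_copy"],
        loci=base.locus_names)
    matrix = pairwise_matrix(table, "queller_goodnight",
                             rk.estimate_allele_frequencies(table))
    r_top = matrix.value(twin, "twin_copy")
    assert r_top > 0.9  # identical multilocus genotypes
    g = rk.build_kin_network(matrix, tau=0.44,
                             roost_of={twin: "pitcher"})
    assert g.number_of_edges() == 1 and g.has_edge(twin, "twin_copy")
    assert g.nodes[twin]["roost"] == "pitcher"
    assert rk.build_kin_network(matrix, tau=1.1).number_of_edges() == 0
    edge_counts = [rk.build_kin_network(matrix, tau=t).number_of_edges()
                   for t in (-1.0, 0.0, 0.44, 1.0)]
    assert edge_counts == sorted(edge_counts, reverse=True)
    # strict inequality at the threshold
    assert not rk.build_kin_network(matrix, tau=r_top).has_edge(
        twin, "twin_copy")


def test_matrix_csv_roundtrip(tmp_path, airport):
    table, _ = airport
    matrix = pairwise_matrix(table.subset(table.individual_ids[:8]),
                             "queller_goodnight")
    path = tmp_path / "m.csv"
    matrix.to_csv(path)
    back = rk.RelatednessMatrix.from_csv(path)
    for a, b in itertools.combinations(matrix.ids, 2):
        assert back.value(a, b) == pytest.approx(matrix.value(a, b))
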