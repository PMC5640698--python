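import numpy as np
import pytest

import roostkin as rk
from roostkin.io import GenotypeTable


def make_table(calls, sites=None, **kwargs):
    """Small helper: build a GenotypeTable from a nested call list."""
    calls = np.asarray(calls)
    n, L = calls.shape[0], calls.shape[1]
    ids = kwargs.pop("ids", [f"b{i}" for i in range(n)])
    loci = kwargs.pop("loci", [f"L{j}" for j in range(L)])
    if sites is None:
        sites = {i: "s1" for i in ids}
    return GenotypeTable(ids, loci, calls, sites, **kwargs)


@pytest.fixture(scope="session")
def iid_table_100():
    """200 unrelated individuals, 100 loci, 8 alleles, HW proportions."""
    table, _ = rk.simulate_airport_site(
        n_kin_cluster=0, n_unrelated=200, n_loci=100, n_alleles=8, seed=424)
    return table


@pytest.fixture(scope="session")
def airport():
    """Kin-clustered pitcher bats among unrelated leaf bats (one site)."""
    table, truth = rk.simulate_airport_site(seed=11)
    return table, truth


@pytest.fixture(scope="session")
def default_sim():
    """One default stepping-stone run shared across tests."""
    config = rk.SimulationConfig(seed=20_240_601)
    table, sites, pedigree = rk.simulate_stepping_stone(config)
    return config, table, sites, pedigree


@pytest.fixture()
def reference_trials():
    return rk.roost_type_reference_trials()
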