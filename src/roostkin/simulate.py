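"""Synthetic microsatellite populations and behavioural choice trials.

This module stands in for the study's raw data, which are not available in
machine-readable form.  It provides

* a discrete-generation Wright-Fisher simulator on a 1-D transect of demes
  with symmetric nearest-neighbour (stepping-stone) or island migration and
  k-allele mutation, recording the full pedigree so that kin truth and
  maternal transmission fall out naturally;
* planting of parent-offspring and full-sib dyads with known expected
  relatedness, for estimator validation;
* maternal transmission of a binary roost preference (pitcher vs. furled
  leaf) with configurable fidelity;
* flight-arena choice trials with per-roost approach counts and a
  possibly-missing final choice.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeTable, SiteTable, ValidationError
from .choice import ChoiceTrial, roost_category

DEME_SPACING_KM = 5.0

PITCHER = "pitcher"
LEAF = "furled_leaf"


@dataclass
class SimulationConfig:
    """Knobs of the population simulator.

    Defaults emulate the study system: ~10 demes along a transect, 16
    microsatellite loci of moderate polymorphism, weak differentiation with
    isolation by distance, and a mostly-faithful maternal roost tradition.
    """

    n_demes: int = 10
    deme_size: int = 100          # diploid N per deme
    generations: int = 200
    migration_rate: float = 0.2   # symmetric nearest-neighbour m
    n_loci: int = 16
    n_alleles: int = 8            # k of the k-allele mutation model
    mutation_rate: float = 1e-3
    n_family_dyads: int = 0       # planted PO and FS dyads, each
    transmission_fidelity: float = 0.9   # phi: P(offspring copies mother)
    pitcher_baseline: float = 0.3        # pi: founder/base pitcher probability
    sample_per_deme: int = 20
    migration_model: str = "stepping_stone"  # or "island"
    seed: int | None = None
    max_work: int = 500_000_000   # bound on N * n_demes * G * n_loci

    def validate(self) -> None:
        if not (0 <= self.migration_rate <= 0.5):
            raise ValidationError("migration rate must be in [0, 0.5]")
        if not (0.5 <= self.transmission_fidelity <= 1.0):
            raise ValidationError("transmission fidelity must be in [0.5, 1]")
        if not (0.0 <= self.pitcher_baseline <= 1.0):
            raise ValidationError("pitcher baseline must be in [0, 1]")
        if not (0.0 <= self.mutation_rate < 1.0):
            raise ValidationError("mutation rate must be in [0, 1)")
        if self.migration_model not in ("stepping_stone", "island"):
            raise ValidationError(f"unknown migration model {self.migration_model!r}")
        if self.n_alleles < 2 or self.n_loci < 1 or self.n_demes < 1:
            raise ValidationError("need >= 2 alleles, >= 1 locus, >= 1 deme")
        if self.sample_per_deme > self.deme_size:
            raise ValidationError("cannot sample more individuals than deme size")
        work = self.deme_size * self.n_demes * self.generations * self.n_loci
        if work > self.max_work:
            raise ValidationError(
                f"simulation work {work:.2g} exceeds bound {self.max_work:.2g}; "
                "reduce deme_size, n_demes, generations or n_loci, or raise "
                "max_work explicitly")
        if self.seed is None:
            raise ValidationError("seed is mandatory for generating operations")


@dataclass
class PedigreeRecord:
    individual_id: str
    mother_id: str | None
    father_id: str | None
    deme: int
    roost: str | None = None


@dataclass
class Pedigree:
    """Compact pedigree over all generations; parents precede offspring."""

    ids: list[str]
    mother: np.ndarray      # index into ids, -1 for founders
    father: np.ndarray
    deme: np.ndarray
    generation: np.ndarray

    def __len__(self) -> int:
        return len(self.ids)

    def records(self, roost_of: dict[str, str] | None = None):
        for i, ind in enumerate(self.ids):
            yield PedigreeRecord(
                individual_id=ind,
                mother_id=self.ids[self.mother[i]] if self.mother[i] >= 0 else None,
                father_id=self.ids[self.father[i]] if self.father[i] >= 0 else None,
                deme=int(self.deme[i]),
                roost=(roost_of or {}).get(ind),
            )

    def is_acyclic(self) -> bool:
        idx = np.arange(len(self.ids))
        ok = (self.mother < idx) & (self.father < idx)
        return bool(ok.all())


def _parent_demes(rng: np.random.Generator, n: int, deme: np.ndarray,
                  config: SimulationConfig) -> np.ndarray:
    """Deme of origin for each of n gamete-contributing parents."""
    d = deme.copy()
    if config.n_demes == 1 or config.migration_rate == 0:
        return d
    u = rng.random(n)
    if config.migration_model == "stepping_stone":
        step = np.zeros(n, dtype=int)
        step[u < config.migration_rate / 2] = -1
        step[(u >= config.migration_rate / 2) & (u < config.migration_rate)] = 1
        d = d + step
        # reflect at transect ends (migrant stays home)
        d = np.clip(d, 0, config.n_demes - 1)
    else:  # island: migrate to a uniformly chosen *other* deme
        mig = u < config.migration_rate
        other = rng.integers(0, config.n_demes - 1, size=n)
        other = np.where(other >= d, other + 1, other)
        d = np.where(mig, other, d)
    return d


def simulate_stepping_stone(
    config: SimulationConfig,
) -> tuple[GenotypeTable, SiteTable, Pedigree]:
    """Run the Wright-Fisher transect simulation.

    Returns a final-generation sample (``sample_per_deme`` individuals per
    deme, with sites ``deme_0 .. deme_{D-1}`` at 5-km spacing), the site
    table, and the full multi-generation pedigree of the simulated
    population.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    D, N, L, k = (config.n_demes, config.deme_size,
                  config.n_loci, config.n_alleles)
    n_tot = D * N
    deme_of = np.repeat(np.arange(D), N)

    # generation 0 founders: alleles uniform on 1..k (shared pool, F_ST = 0)
    pop = rng.integers(1, k + 1, size=(n_tot, L, 2), dtype=np.int16)

    ids: list[str] = [f"g0_d{d}_{i}" for d, i in zip(deme_of, np.tile(np.arange(N), D))]
    mothers = [np.full(n_tot, -1, dtype=np.int64)]
    fathers = [np.full(n_tot, -1, dtype=np.int64)]
    demes = [deme_of.copy()]
    gens = [np.zeros(n_tot, dtype=np.int64)]

    deme_offsets = np.arange(D) * N  # index of first individual of each deme
    for g in range(1, config.generations + 1):
        prev_offset = (g - 1) * n_tot
        md = _parent_demes(rng, n_tot, deme_of, config)
        fd = _parent_demes(rng, n_tot, deme_of, config)
        mi = deme_offsets[md] + rng.integers(0, N, size=n_tot)
        fi = deme_offsets[fd] + rng.integers(0, N, size=n_tot)

        mg = pop[mi[:, None], np.arange(L)[None, :],
                 rng.integers(0, 2, size=(n_tot, L))]
        fg = pop[fi[:, None], np.arange(L)[None, :],
                 rng.integers(0, 2, size=(n_tot, L))]
        new = np.stack([mg, fg], axis=2)
        if config.mutation_rate > 0:
            mut = rng.random(new.shape) < config.mutation_rate
            n_mut = int(mut.sum())
            if n_mut:
                new[mut] = rng.integers(1, k + 1, size=n_mut, dtype=np.int16)
        pop = new

        ids.extend(f"g{g}_d{d}_{i}"
                   for d, i in zip(deme_of, np.tile(np.arange(N), D)))
        mothers.append(prev_offset + mi)
        fathers.append(prev_offset + fi)
        demes.append(deme_of.copy())
        gens.append(np.full(n_tot, g, dtype=np.int64))

    pedigree = Pedigree(
        ids=ids,
        mother=np.concatenate(mothers),
        father=np.concatenate(fathers),
        deme=np.concatenate(demes),
        generation=np.concatenate(gens),
    )

    # sample the final generation
    sample_idx = np.concatenate([
        deme_offsets[d] + rng.choice(N, size=config.sample_per_deme,
                                     replace=False)
        for d in range(D)
    ])
    final_ids = [ids[config.generations * n_tot + i] for i in sample_idx]
    table = GenotypeTable(
        individual_ids=final_ids,
        locus_names=[f"L{j + 1:02d}" for j in range(L)],
        calls=pop[sample_idx].astype(np.int64),
        site_of={ind: f"deme_{deme_of[i]}"
                 for ind, i in zip(final_ids, sample_idx)},
    )
    sites = SiteTable(pd.DataFrame({
        "site_id": [f"deme_{d}" for d in range(D)],
        "x": np.arange(D) * DEME_SPACING_KM,
        "y": np.zeros(D),
    }))
    return table, sites, pedigree


# ---------------------------------------------------------------------------
# Planted families
# ---------------------------------------------------------------------------

def _draw_genotype(rng, alleles, probs, n_loci_range):
    return np.array([[rng.choice(alleles[l], p=probs[l]),
                      rng.choice(alleles[l], p=probs[l])]
                     for l in n_loci_range])


def plant_families(
    table: GenotypeTable,
    pedigree: Pedigree | None = None,
    n_po: int = 0,
    n_fs: int = 0,
    seed: int | None = None,
    site: str | None = None,
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Append planted parent-offspring and full-sib dyads with truth labels.

    Offspring receive one allele from each (simulated) parent; parents are
    drawn from the table's pooled allele frequencies, so planted pairs sit in
    the same frequency background as the rest of the sample.  Returns a new
    table plus a truth frame (pair_id, id_a, id_b, relationship, true_r).
    """
    if seed is None:
        raise ValidationError("seed is mandatory for generating operations")
    if n_po < 0 or n_fs < 0:
        raise ValidationError("dyad counts must be non-negative")
    if table.n_individuals == 0:
        raise ValidationError("cannot plant families into an empty table")
    max_new = 2 * (n_po + n_fs)
    if max_new > 50 * max(table.n_individuals, 1):
        raise ValidationError("requested dyads vastly exceed table size")
    if n_po == 0 and n_fs == 0:
        return table, pd.DataFrame(
            columns=["pair_id", "id_a", "id_b", "relationship", "true_r"])

    rng = np.random.default_rng(seed)
    site = site or table.sites[0]
    L = table.n_loci
    loci_range = range(L)

    # pooled allele frequencies from the observed table
    alleles, probs = [], []
    for l in loci_range:
        col = table.calls[:, l, :].ravel()
        col = col[col != 0]
        if col.size == 0:
            raise ValidationError(
                f"locus {table.locus_names[l]} has no non-missing calls")
        vals, counts = np.unique(col, return_counts=True)
        alleles.append(vals)
        probs.append(counts / counts.sum())

    new_ids: list[str] = []
    new_calls: list[np.ndarray] = []
    truth_rows = []

    def mendel_offspring(par_a: np.ndarray, par_b: np.ndarray) -> np.ndarray:
        ga = par_a[np.arange(L), rng.integers(0, 2, size=L)]
        gb = par_b[np.arange(L), rng.integers(0, 2, size=L)]
        return np.stack([ga, gb], axis=1)

    for j in range(n_po):
        parent = _draw_genotype(rng, alleles, probs, loci_range)
        mate = _draw_genotype(rng, alleles, probs, loci_range)
        child = mendel_offspring(parent, mate)
        pa, ch = f"po{j}_parent", f"po{j}_child"
        new_ids += [pa, ch]
        new_calls += [parent, child]
        truth_rows.append({"pair_id": f"PO{j}", "id_a": pa, "id_b": ch,
                           "relationship": "PO", "true_r": 0.5})

    for j in range(n_fs):
        mother = _draw_genotype(rng, alleles, probs, loci_range)
        father = _draw_genotype(rng, alleles, probs, loci_range)
        sib1 = mendel_offspring(mother, father)
        sib2 = mendel_offspring(mother, father)
        s1, s2 = f"fs{j}_sib1", f"fs{j}_sib2"
        new_ids += [s1, s2]
        new_calls += [sib1, sib2]
        truth_rows.append({"pair_id": f"FS{j}", "id_a": s1, "id_b": s2,
                           "relationship": "FS", "true_r": 0.5})

    out = GenotypeTable(
        individual_ids=table.individual_ids + new_ids,
        locus_names=list(table.locus_names),
        calls=np.concatenate(
            [table.calls, np.stack(new_calls).astype(np.int64)]),
        site_of={**table.site_of, **{i: site for i in new_ids}},
        roost_of=dict(table.roost_of),
        sex_of=dict(table.sex_of),
    )
    return out, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Maternal roost-preference transmission
# ---------------------------------------------------------------------------

def assign_roost_preferences(
    pedigree: Pedigree,
    fidelity: float,
    baseline: float,
    seed: int | None = None,
) -> dict[str, str]:
    """Propagate a binary roost preference down the maternal lines.

    Founders are pitcher-roosting with probability ``baseline``; every other
    individual copies its mother's category with probability ``fidelity``
    and otherwise draws afresh from the baseline.  Deterministic given seed.
    """
    if seed is None:
        raise ValidationError("seed is mandatory for generating operations")
    if not (0.5 <= fidelity <= 1.0):
        raise ValidationError("fidelity must be in [0.5, 1]")
    if not (0.0 <= baseline <= 1.0):
        raise ValidationError("baseline must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(pedigree)
    labels = np.empty(n, dtype=bool)  # True = pitcher
    copy_mum = rng.random(n) < fidelity
    fresh = rng.random(n) < baseline
    mother = pedigree.mother
    founders = mother < 0
    labels[founders] = fresh[founders]
    # pedigree order guarantees mothers precede offspring
    for i in np.nonzero(~founders)[0]:
        labels[i] = labels[mother[i]] if copy_mum[i] else fresh[i]
    return {ind: (PITCHER if lab else LEAF)
            for ind, lab in zip(pedigree.ids, labels)}


# ---------------------------------------------------------------------------
# Airport-like fixture: kin-clustered pitcher bats among unrelated leaf bats
# ---------------------------------------------------------------------------

def simulate_airport_site(
    n_kin_cluster: int = 7,
    n_unrelated: int = 36,
    n_loci: int = 16,
    n_alleles: int = 8,
    transmission_fidelity: float = 0.95,
    pitcher_baseline: float = 0.0,
    seed: int | None = None,
) -> tuple[GenotypeTable, pd.DataFrame]:
    """One site where a kin cluster carries the pitcher tradition.

    ``n_kin_cluster`` full sibs (offspring of one simulated pair, so pairwise
    expected r = 0.5) inherit their mother's pitcher preference with the
    given fidelity; ``n_unrelated`` independent individuals follow the
    baseline (default: all leaf-roosting).  Allele frequencies are moderate
    (symmetric Dirichlet over ``n_alleles`` alleles per locus).  Returns the
    genotype table (roost labels attached) and a truth frame of planted
    full-sib pairs.
    """
    if seed is None:
        raise ValidationError("seed is mandatory for generating operations")
    rng = np.random.default_rng(seed)
    alleles = [np.arange(1, n_alleles + 1) for _ in range(n_loci)]
    probs = [rng.dirichlet(np.full(n_alleles, 2.0)) for _ in range(n_loci)]
    loci_range = range(n_loci)

    mother = _draw_genotype(rng, alleles, probs, loci_range)
    father = _draw_genotype(rng, alleles, probs, loci_range)
    ids, calls, roost = [], [], {}
    truth_rows = []
    for j in range(n_kin_cluster):
        ga = mother[np.arange(n_loci), rng.integers(0, 2, size=n_loci)]
        gb = father[np.arange(n_loci), rng.integers(0, 2, size=n_loci)]
        ind = f"kin_{j}"
        ids.append(ind)
        calls.append(np.stack([ga, gb], axis=1))
        faithful = rng.random() < transmission_fidelity
        roost[ind] = PITCHER if faithful else LEAF
    for a in range(n_kin_cluster):
        for b in range(a + 1, n_kin_cluster):
            truth_rows.append({"pair_id": f"FS{a}_{b}", "id_a": f"kin_{a}",
                               "id_b": f"kin_{b}", "relationship": "FS",
                               "true_r": 0.5})
    for j in range(n_unrelated):
        ind = f"bg_{j}"
        ids.append(ind)
        calls.append(_draw_genotype(rng, alleles, probs, loci_range))
        roost[ind] = PITCHER if rng.random() < pitcher_baseline else LEAF

    table = GenotypeTable(
        individual_ids=ids,
        locus_names=[f"L{j + 1:02d}" for j in range(n_loci)],
        calls=np.stack(calls).astype(np.int64),
        site_of={i: "airport" for i in ids},
        roost_of=roost,
    )
    return table, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Flight-arena choice trials
# ---------------------------------------------------------------------------

@dataclass
class ChoiceExperimentConfig:
    """Generator knobs for synthetic flight-arena trials.

    ``weights[origin][roost]`` >= 0 expresses the preference of bats of a
    given origin for each offered roost; approach counts are Poisson with
    mean ``mean_approaches * w / sum(w)`` and the final choice is multinomial
    proportional to the weights, replaced by "no choice" with probability
    ``no_choice_prob``.
    """

    offered: tuple[str, ...] = ("Nh", "Nb", "Na", "Fl", "Pt")
    weights: dict[str, dict[str, float]] = field(default_factory=dict)
    mean_approaches: float = 10.0
    no_choice_prob: float = 0.1
    n_bats: dict[str, int] = field(default_factory=dict)
    experiment: str = "roost_type"
    seed: int | None = None

    def validate(self) -> None:
        if not (0.0 <= self.no_choice_prob <= 1.0):
            raise ValidationError("no-choice probability must be in [0, 1]")
        if not self.n_bats:
            raise ValidationError("n_bats must name at least one origin")
        for origin in self.n_bats:
            w = self.weights.get(origin)
            if not w:
                raise ValidationError(f"no weights for origin {origin!r}")
            vec = np.array([w.get(r, 0.0) for r in self.offered], dtype=float)
            if (vec < 0).any() or vec.sum() <= 0:
                raise ValidationError(
                    f"origin {origin!r} needs >= 1 positive weight")
        if self.seed is None:
            raise ValidationError("seed is mandatory for generating operations")


def simulate_choice_trials(config: ChoiceExperimentConfig) -> list[ChoiceTrial]:
    """Draw synthetic choice trials; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    trials: list[ChoiceTrial] = []
    counter = 0
    for origin in sorted(config.n_bats):
        w = np.array([config.weights[origin].get(r, 0.0)
                      for r in config.offered], dtype=float)
        p = w / w.sum()
        for _ in range(config.n_bats[origin]):
            approaches = rng.poisson(config.mean_approaches * p)
            if rng.random() < config.no_choice_prob:
                choice = None
            else:
                choice = config.offered[rng.choice(len(config.offered), p=p)]
            cat = roost_category(origin)
            trials.append(ChoiceTrial(
                bat_id=f"bat_{counter}",
                experiment=config.experiment,
                origin_category=cat if cat in (PITCHER, LEAF) else PITCHER,
                origin_species=origin,
                offered=tuple(config.offered),
                approaches=tuple(int(a) for a in approaches),
                final_choice=choice,
            ))
            counter += 1
    return trials
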