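"""Contingency statistics for the flight-arena roost-choice experiments.

A trial records one bat's experiment: where it was found in the wild
(pitcher vs. furled leaf, and the plant species), which roosts were offered,
how often it approached each (hovering flight within 10 cm), and which roost
it finally entered — or none within the 30-minute limit, in which case it is
excluded from final-choice analyses (with the exclusion counted).

Provides Fisher's exact test (2x2 exact, r x c by margin-conditioned Monte
Carlo), the Holm step-down ("sequential Bonferroni") correction, and the
descriptive roost-switching summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .io import ValidationError

#: roost label -> category; species codes follow the study system
#: (Nepenthes pitchers, furled leaves of Alpinia/Boesenbergia/Musa, plastic tube)
ROOST_CATEGORY = {
    "Nh": "pitcher", "Nb": "pitcher", "Na": "pitcher", "Nr": "pitcher",
    "Fl": "furled_leaf", "Al": "furled_leaf", "Bg": "furled_leaf",
    "Mm": "furled_leaf",
    "Pt": "plastic",
    "pitcher": "pitcher", "furled_leaf": "furled_leaf", "plastic": "plastic",
}


def roost_category(label: str) -> str:
    """Category (pitcher / furled_leaf / plastic) of a roost label."""
    try:
        return ROOST_CATEGORY[label]
    except KeyError:
        raise ValidationError(f"unknown roost label {label!r}") from None


@dataclass
class ChoiceTrial:
    """One bat's flight-arena record."""

    bat_id: str
    experiment: str            # pitcher_species | leaf_species | roost_type
    origin_category: str       # pitcher | furled_leaf
    origin_species: str
    offered: tuple[str, ...]
    approaches: tuple[int, ...]
    final_choice: str | None   # None = did not choose within 30 min

    def __post_init__(self) -> None:
        if self.origin_category not in ("pitcher", "furled_leaf"):
            raise ValidationError(
                f"origin category {self.origin_category!r} invalid")
        if len(self.offered) != len(self.approaches):
            raise ValidationError("approaches must cover every offered roost")
        if any(a < 0 for a in self.approaches):
            raise ValidationError("approach counts must be non-negative")
        if self.final_choice is not None and self.final_choice not in self.offered:
            raise ValidationError(
                f"final choice {self.final_choice!r} not among offered roosts")


@dataclass
class CountTable:
    """Origin-by-choice count table plus the number of dropped trials."""

    counts: pd.DataFrame   # rows: origin groups, columns: chosen roosts
    n_dropped: int

    @property
    def testable(self) -> bool:
        return self.counts.shape[0] >= 2 and self.counts.shape[1] >= 2


def tabulate_choices(
    trials: list[ChoiceTrial],
    row_by: str = "origin_category",
    col_by: str = "final_choice",
    drop_no_choice: bool = True,
) -> CountTable:
    """Cross-classify final choices of one experiment's trials.

    No-choice trials are dropped (and counted in ``n_dropped``) unless
    ``drop_no_choice`` is cleared, in which case they appear in a
    ``no_choice`` column.
    """
    if not trials:
        raise ValidationError("no trials to tabulate")
    experiments = {t.experiment for t in trials}
    if len(experiments) > 1:
        raise ValidationError(f"trials mix experiments: {sorted(experiments)}")
    rows = []
    n_dropped = 0
    for t in trials:
        if t.final_choice is None:
            if drop_no_choice:
                n_dropped += 1
                continue
            choice = "no_choice"
        else:
            choice = t.final_choice
        rows.append((getattr(t, row_by), choice))
    if not rows:
        raise ValidationError("no trials left after dropping no-choice records")
    df = pd.DataFrame(rows, columns=["row", "col"])
    counts = pd.crosstab(df["row"], df["col"])
    counts.index.name, counts.columns.name = row_by, col_by
    return CountTable(counts=counts, n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# Fisher's exact tests
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table.

    Two-sidedness by the point-probability rule: sum the hypergeometric
    probabilities of all tables with the same margins that are no more
    probable than the observed one.
    """
    arr = np.asarray(getattr(table, "counts", table), dtype=float)
    if arr.shape != (2, 2) or (arr < 0).any() or (arr != np.round(arr)).any():
        raise ValidationError("need a 2x2 table of non-negative integers")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return 1.0  # zero margin: only one table possible
    return float(stats.fisher_exact(arr.astype(int), alternative="two-sided")[1])


def _log_table_prob(arr: np.ndarray) -> np.ndarray:
    """log P(table | margins) up to the margin constant: -sum log(n_ij!)."""
    return -(gammaln(arr + 1.0)).sum(axis=(-2, -1))


def fisher_exact_rxc_mc(table, n_mc: int = 100_000,
                        seed: int | None = None) -> float:
    """Monte Carlo Fisher's exact p for an r x c table.

    Samples margin-conditioned tables (Patefield algorithm via
    ``scipy.stats.random_table``) and reports the add-one proportion whose
    conditional probability is <= the observed table's.
    """
    arr = np.asarray(getattr(table, "counts", table), dtype=int)
    if arr.ndim != 2 or min(arr.shape) < 2 or (arr < 0).any():
        raise ValidationError("need an r x c table (r, c >= 2) of counts")
    row = arr.sum(axis=1)
    col = arr.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        return 1.0  # degenerate margins
    if seed is None:
        raise ValidationError("seed is mandatory for Monte Carlo tests")
    rng = np.random.default_rng(seed)
    dist = stats.random_table(row, col)
    samples = dist.rvs(n_mc, random_state=rng)
    log_obs = _log_table_prob(arr.astype(float))
    log_samp = _log_table_prob(samples)
    hits = int((log_samp <= log_obs + 1e-9).sum())
    return (1 + hits) / (n_mc + 1)


# ---------------------------------------------------------------------------
# Multiple-testing correction
# ---------------------------------------------------------------------------

@dataclass
class TestBattery:
    """Raw and Holm-adjusted p-values for a family of comparisons."""

    frame: pd.DataFrame  # columns: comparison, p_raw, p_adjusted, significant

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def holm(p_values, labels=None, alpha: float = 0.05,
         method: str = "holm") -> TestBattery:
    """Step-down Holm adjustment (the standard 'sequential Bonferroni').

    ``method='bonferroni'`` switches to the plain single-step correction.
    Output preserves the input order.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value list")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    if method not in ("holm", "bonferroni"):
        raise ValidationError(f"unknown correction {method!r}")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method=method)
    if labels is None:
        labels = [f"test_{i}" for i in range(p.size)]
    return TestBattery(frame=pd.DataFrame({
        "comparison": list(labels),
        "p_raw": p,
        "p_adjusted": p_adj,
        "significant": reject,
    }))


# ---------------------------------------------------------------------------
# Switching summary
# ---------------------------------------------------------------------------

def switching_summary(trials: list[ChoiceTrial]) -> dict:
    """Roost-fidelity summary of the roost-type experiment.

    Per origin category: bats tested, bats that chose, and the number and
    percentage (rounded to the nearest integer) whose final choice fell in
    the *other* roost category.  Also breaks switchers down by the species
    they switched to.  Percentages are omitted when no bat chose.
    """
    out: dict[str, dict] = {}
    for origin in ("pitcher", "furled_leaf"):
        sub = [t for t in trials if t.origin_category == origin]
        choosers = [t for t in sub if t.final_choice is not None]
        switchers = [t for t in choosers
                     if roost_category(t.final_choice) != origin
                     and roost_category(t.final_choice) in
                     ("pitcher", "furled_leaf")]
        entry: dict = {
            "n_tested": len(sub),
            "n_choosing": len(choosers),
            "n_no_choice": len(sub) - len(choosers),
            "n_switched": len(switchers),
            "switched_to": {},
        }
        for t in switchers:
            entry["switched_to"][t.final_choice] = (
                entry["switched_to"].get(t.final_choice, 0) + 1)
        if choosers:
            frac = len(switchers) / len(choosers)
            entry["switch_fraction"] = frac
            entry["switch_percent"] = int(round(100 * frac))
        out[origin] = entry
    return out


# ---------------------------------------------------------------------------
# Trial CSV I/O (offered and approaches as semicolon lists, same order)
# ---------------------------------------------------------------------------

def write_trials_csv(trials: list[ChoiceTrial], path) -> None:
    rows = [{
        "bat_id": t.bat_id,
        "experiment": t.experiment,
        "origin_category": t.origin_category,
        "origin_species": t.origin_species,
        "offered": ";".join(t.offered),
        "approaches": ";".join(str(a) for a in t.approaches),
        "final_choice": t.final_choice or "",
    } for t in trials]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_trials_csv(path) -> list[ChoiceTrial]:
    df = pd.read_csv(path, dtype=str).fillna("")
    trials = []
    for _, r in df.iterrows():
        trials.append(ChoiceTrial(
            bat_id=r["bat_id"],
            experiment=r["experiment"],
            origin_category=r["origin_category"],
            origin_species=r["origin_species"],
            offered=tuple(r["offered"].split(";")),
            approaches=tuple(int(a) for a in r["approaches"].split(";")),
            final_choice=r["final_choice"] or None,
        ))
    return trials


# ---------------------------------------------------------------------------
# Worked example from the published counts
# ---------------------------------------------------------------------------

def roost_type_reference_trials() -> list[ChoiceTrial]:
    """The roost-type experiment reconstructed from the published counts.

    68 bats tested (21 found in pitchers, 47 in furled leaves); 3 + 9 = 12
    did not choose within 30 min.  All 18 pitcher-origin choosers stayed
    with pitchers, while 8 of the 38 leaf-origin choosers (21%) switched to
    pitchers: 5 chose N. hemsleyana, 1 N. bicalcarata and 2 N. ampullaria.
    Approach counts are not part of the published record and are set to
    zero; only the final choices matter here.
    """
    offered = ("Nh", "Nb", "Na", "Fl", "Pt")
    zeros = (0, 0, 0, 0, 0)
    trials: list[ChoiceTrial] = []

    def add(n, origin, species, choice):
        for _ in range(n):
            trials.append(ChoiceTrial(
                bat_id=f"ref_{len(trials)}", experiment="roost_type",
                origin_category=origin, origin_species=species,
                offered=offered, approaches=zeros, final_choice=choice))

    # pitcher-origin: 21 tested, 3 no-choice, 18 chose pitchers (no switch)
    add(18, "pitcher", "Np", "Nh")
    add(3, "pitcher", "Np", None)
    # leaf-origin: 47 tested, 9 no-choice, 38 choosers of which 8 switched
    add(5, "furled_leaf", "Fl", "Nh")
    add(1, "furled_leaf", "Fl", "Nb")
    add(2, "furled_leaf", "Fl", "Na")
    add(30, "furled_leaf", "Fl", "Fl")
    add(9, "furled_leaf", "Fl", None)
    return trials
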