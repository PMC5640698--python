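"""Domain types and file I/O for diploid microsatellite data.

Genotypes are integer allele labels (microsatellite fragment sizes or
arbitrary codes); ``0`` marks a missing call.  A call is missing only when
*both* slots are 0 — half-missing calls are rejected on construction so that
every downstream estimator can assume complete diploid genotypes.

The on-disk genotype format is Genepop text (2- or 3-digit allele coding);
per-individual metadata (site, roost category, sex) and site coordinates
travel in plain CSV.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = 0

ROOST_CATEGORIES = ("pitcher", "furled_leaf")


class GenepopError(ValueError):
    """Malformed Genepop file (parse or format problem)."""


class ValidationError(ValueError):
    """Data violate a domain invariant (e.g. half-missing call)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GenotypeTable:
    """Individuals x loci diploid microsatellite calls.

    Parameters
    ----------
    individual_ids
        Ordered, globally unique identifiers (one per row of ``calls``).
    locus_names
        Ordered, unique locus names.
    calls
        Integer array of shape ``(n_individuals, n_loci, 2)``; unordered
        allele pairs, ``0`` in both slots for a missing call.
    site_of
        Map from individual id to site id.
    roost_of, sex_of
        Optional per-individual annotations; roost categories are restricted
        to ``pitcher`` / ``furled_leaf``.
    """

    individual_ids: list[str]
    locus_names: list[str]
    calls: np.ndarray
    site_of: dict[str, str]
    roost_of: dict[str, str] = field(default_factory=dict)
    sex_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.individual_ids = list(self.individual_ids)
        self.locus_names = list(self.locus_names)
        self.calls = np.asarray(self.calls, dtype=np.int64)
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValidationError("individual ids must be unique")
        if len(set(self.locus_names)) != len(self.locus_names):
            raise ValidationError("locus names must be unique")
        expected = (len(self.individual_ids), len(self.locus_names), 2)
        if self.calls.shape != expected:
            raise ValidationError(
                f"calls shape {self.calls.shape} != expected {expected}")
        if (self.calls < 0).any():
            raise ValidationError("allele labels must be >= 0")
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            i, l = np.argwhere(half)[0]
            raise ValidationError(
                "half-missing call (one slot 0) for individual "
                f"{self.individual_ids[i]!r} at locus {self.locus_names[l]!r}")
        missing_sites = [i for i in self.individual_ids if i not in self.site_of]
        if missing_sites:
            raise ValidationError(f"individuals without site: {missing_sites[:5]}")
        for ind, cat in self.roost_of.items():
            if cat not in ROOST_CATEGORIES:
                raise ValidationError(
                    f"roost category {cat!r} for {ind!r} not in {ROOST_CATEGORIES}")

    # -- basic queries ------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def sites(self) -> list[str]:
        """Site ids in first-appearance order of individuals."""
        seen: dict[str, None] = {}
        for ind in self.individual_ids:
            seen.setdefault(self.site_of[ind], None)
        return list(seen)

    def index_of(self, individual_id: str) -> int:
        return self.individual_ids.index(individual_id)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci) mask of missing calls."""
        return (self.calls == MISSING).all(axis=2)

    def n_missing(self) -> int:
        return int(self.missing_mask().sum())

    def individuals_of_site(self, site: str) -> list[str]:
        return [i for i in self.individual_ids if self.site_of[i] == site]

    def subset(self, individual_ids: list[str]) -> "GenotypeTable":
        idx = [self.index_of(i) for i in individual_ids]
        return GenotypeTable(
            individual_ids=list(individual_ids),
            locus_names=list(self.locus_names),
            calls=self.calls[idx].copy(),
            site_of={i: self.site_of[i] for i in individual_ids},
            roost_of={i: self.roost_of[i] for i in individual_ids
                      if i in self.roost_of},
            sex_of={i: self.sex_of[i] for i in individual_ids
                    if i in self.sex_of},
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        sorted_calls = np.sort(self.calls, axis=2)
        other_sorted = np.sort(other.calls, axis=2)
        return (self.individual_ids == other.individual_ids
                and self.locus_names == other.locus_names
                and np.array_equal(sorted_calls, other_sorted)
                and self.site_of == other.site_of)


@dataclass
class AlleleFreqTable:
    """Per (pool, locus) allele frequencies and gene-copy sample sizes.

    ``freqs[(pool, locus)]`` maps allele label -> frequency in [0, 1];
    frequencies per cell sum to 1 and never include the missing code 0.
    ``sample_size`` counts non-missing gene copies (always even).
    A (pool, locus) with zero non-missing calls is simply absent.
    """

    freqs: dict[tuple[str, str], dict[int, float]]
    sample_size: dict[tuple[str, str], int]

    def __post_init__(self) -> None:
        for key, fr in self.freqs.items():
            if MISSING in fr:
                raise ValidationError(f"missing code 0 in frequency table {key}")
            total = sum(fr.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(f"frequencies at {key} sum to {total}")
            n = self.sample_size[key]
            if n < 2 or n % 2:
                raise ValidationError(f"sample size at {key} is {n}")

    @property
    def pools(self) -> list[str]:
        return sorted({p for p, _ in self.freqs})

    def available(self, pool: str, locus: str) -> bool:
        return (pool, locus) in self.freqs

    def freq(self, pool: str, locus: str) -> dict[int, float]:
        return self.freqs[(pool, locus)]


@dataclass
class SiteTable:
    """Study sites with planar coordinates (km) and optional habitat label."""

    frame: pd.DataFrame  # columns: site_id, x, y[, habitat]

    def __post_init__(self) -> None:
        required = {"site_id", "x", "y"}
        if not required.issubset(self.frame.columns):
            raise ValidationError(f"site table needs columns {sorted(required)}")
        if self.frame["site_id"].duplicated().any():
            raise ValidationError("duplicate site ids")
        coords = self.frame[["x", "y"]].to_numpy(dtype=float)
        if not np.isfinite(coords).all():
            raise ValidationError("non-finite site coordinates")
        self.frame = self.frame.reset_index(drop=True)

    @property
    def site_ids(self) -> list[str]:
        return self.frame["site_id"].tolist()

    def coords(self, site_id: str) -> tuple[float, float]:
        row = self.frame.loc[self.frame["site_id"] == site_id].iloc[0]
        return float(row["x"]), float(row["y"])

    def distance_matrix(self, site_ids: list[str] | None = None) -> "DistanceMatrix":
        """Euclidean inter-site distances (km)."""
        ids = site_ids if site_ids is not None else self.site_ids
        pts = np.array([self.coords(s) for s in ids])
        diff = pts[:, None, :] - pts[None, :, :]
        return DistanceMatrix(labels=list(ids),
                              values=np.sqrt((diff ** 2).sum(axis=2)))


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with labelled axes."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("matrix dimension does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValidationError("matrix diagonal not zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels=list(labels),
                              values=self.values[np.ix_(idx, idx)])

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels,
                     columns=self.labels).to_csv(path, index_label="label")

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col="label")
        values = df.to_numpy(dtype=float)
        # symmetrize away round-tripped decimal noise
        return cls(labels=[str(c) for c in df.columns],
                   values=0.5 * (values + values.T))


@dataclass
class Metadata:
    """Per-individual annotations plus the site table they reference."""

    sites: SiteTable
    site_of: dict[str, str]
    roost_of: dict[str, str]
    sex_of: dict[str, str]

    def apply(self, table: GenotypeTable) -> list[str]:
        """Attach roost/sex annotations to ``table`` in place.

        Returns the ids present in the metadata but absent from the table
        (never silently dropped).
        """
        known = set(table.individual_ids)
        for ind, cat in self.roost_of.items():
            if ind in known:
                table.roost_of[ind] = cat
        for ind, sex in self.sex_of.items():
            if ind in known:
                table.sex_of[ind] = sex
        return [i for i in self.site_of if i not in known]


# ---------------------------------------------------------------------------
# Genepop reader / writer
# ---------------------------------------------------------------------------

def _split_id_site(token: str, pop_index: int) -> tuple[str, str]:
    # "site:id" carries an explicit site; otherwise POP blocks become pop1, ...
    if ":" in token:
        site, _, rest = token.partition(":")
        return rest, site
    return token, f"pop{pop_index}"


def read_genepop(path) -> GenotypeTable:
    """Parse a Genepop text file into a :class:`GenotypeTable`.

    Accepts both the one-locus-per-line and the single comma-separated locus
    header; 2- vs 3-digit allele coding is auto-detected from token length
    (4 vs 6 characters).  POP blocks map to sites ``pop1, pop2, ...`` unless
    individual ids carry an explicit ``site:`` prefix.
    """
    with open(path, encoding="utf-8") as fh:
        raw = fh.read().splitlines()
    lines = [(i + 1, ln.strip()) for i, ln in enumerate(raw) if ln.strip()]
    if len(lines) < 2:
        raise GenepopError("file too short: need title and locus names")

    header = lines[1:]
    loci: list[str] = []
    body_start = None
    for k, (lineno, ln) in enumerate(header):
        if ln.upper() == "POP":
            body_start = k + 1
            break
        if "," in ln:
            loci.extend(t.strip() for t in ln.split(",") if t.strip())
        else:
            loci.append(ln)
    if not loci:
        raise GenepopError("no locus names before first POP")
    if body_start is None:
        # no POP blocks at all: an empty (but valid) table
        return GenotypeTable([], loci, np.zeros((0, len(loci), 2), dtype=int), {})

    ids: list[str] = []
    site_of: dict[str, str] = {}
    rows: list[list[tuple[int, int]]] = []
    pop_index = 0
    digits: int | None = None
    pending_pop = True
    for lineno, ln in header[body_start - 1:]:
        if ln.upper() == "POP":
            pop_index += 1
            pending_pop = False
            continue
        if pending_pop:
            continue
        if "," not in ln:
            raise GenepopError(f"line {lineno}: expected 'id , genotypes ...'")
        ind_token, _, geno_part = ln.partition(",")
        ind_token = ind_token.strip()
        tokens = geno_part.split()
        if len(tokens) != len(loci):
            raise GenepopError(
                f"line {lineno}: {len(tokens)} genotype tokens for "
                f"{len(loci)} loci")
        row: list[tuple[int, int]] = []
        for tok in tokens:
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise GenepopError(
                    f"line {lineno}: bad genotype token {tok!r}")
            tok_digits = len(tok) // 2
            if digits is None:
                digits = tok_digits
            elif tok_digits != digits:
                raise GenepopError(
                    f"line {lineno}: mixed {2 * digits}- and {len(tok)}-character "
                    "genotype tokens in one file")
            a1, a2 = int(tok[:digits]), int(tok[digits:])
            if (a1 == MISSING) != (a2 == MISSING):
                raise ValidationError(
                    f"line {lineno}: one-sided missing call {tok!r}")
            row.append((a1, a2))
        ind_id, site = _split_id_site(ind_token, pop_index)
        ids.append(ind_id)
        site_of[ind_id] = site
        rows.append(row)

    calls = np.array(rows, dtype=np.int64).reshape(len(ids), len(loci), 2)
    return GenotypeTable(ids, loci, calls, site_of)


def write_genepop(table: GenotypeTable, path, title: str = "roostkin export") -> None:
    """Write a :class:`GenotypeTable` as a Genepop file (3-digit coding).

    One POP block per site, sites in first-appearance order; individual ids
    are emitted as ``site:id`` so the site mapping round-trips exactly.
    """
    if table.calls.max(initial=0) > 999:
        bad = int(table.calls.max())
        raise GenepopError(f"allele label {bad} cannot be 3-digit encoded (> 999)")
    out = [title]
    out.extend(table.locus_names)
    for site in table.sites:
        out.append("POP")
        for ind in table.individuals_of_site(site):
            i = table.index_of(ind)
            tokens = [f"{a1:03d}{a2:03d}" for a1, a2 in table.calls[i]]
            label = ind if ind.startswith(f"{site}:") else f"{site}:{ind}"
            out.append(f"{label} , " + " ".join(tokens))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# CSV metadata
# ---------------------------------------------------------------------------

def read_metadata(path) -> Metadata:
    """Read per-individual metadata CSV (id, site, roost_type[, sex, x, y]).

    Rows sharing a site must agree on its coordinates; sites without
    coordinate columns get none (SiteTable then only lists ids with NaN
    coordinates rejected, so x/y are required when any row carries them).
    """
    df = pd.read_csv(path, dtype={"id": str, "site": str})
    required = {"id", "site", "roost_type"}
    if not required.issubset(df.columns):
        raise ValidationError(f"metadata needs columns {sorted(required)}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ValidationError(f"duplicate individual id {dup!r} in metadata")
    known_roost = df["roost_type"].notna() & (df["roost_type"] != "")
    bad = known_roost & ~df["roost_type"].isin(ROOST_CATEGORIES)
    if bad.any():
        raise ValidationError(
            f"roost_type {df.loc[bad, 'roost_type'].iloc[0]!r} not in "
            f"{ROOST_CATEGORIES}")

    if {"x", "y"}.issubset(df.columns):
        site_rows = (df.groupby("site", sort=False)[["x", "y"]]
                       .first().reset_index())
        site_rows.columns = ["site_id", "x", "y"]
    else:
        uniq = df["site"].drop_duplicates()
        site_rows = pd.DataFrame(
            {"site_id": uniq, "x": np.zeros(len(uniq)), "y": np.zeros(len(uniq))})
    sites = SiteTable(site_rows)

    sex_of = {}
    if "sex" in df.columns:
        sex_of = {r["id"]: r["sex"] for _, r in df.iterrows()
                  if isinstance(r["sex"], str)}
    return Metadata(
        sites=sites,
        site_of=dict(zip(df["id"], df["site"])),
        roost_of={i: r for i, r, ok in
                  zip(df["id"], df["roost_type"], known_roost) if ok},
        sex_of=sex_of,
    )


def write_metadata(table: GenotypeTable, sites: SiteTable, path) -> None:
    rows = []
    for ind in table.individual_ids:
        site = table.site_of[ind]
        x, y = sites.coords(site)
        rows.append({
            "id": ind, "site": site,
            "roost_type": table.roost_of.get(ind, ""),
            "sex": table.sex_of.get(ind, ""),
            "x": x, "y": y,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def all_pairs(ids: list[str]) -> list[tuple[str, str]]:
    """All unordered pairs of ids, in deterministic order."""
    return list(itertools.combinations(ids, 2))
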