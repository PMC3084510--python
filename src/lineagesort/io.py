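"""Microsatellite genotype I/O and allele-count tables.

The central containers are :class:`GenotypeDataset` — a diploid
individuals x loci allele-size matrix with population labels — and
:class:`AlleleCountTable`, the per-group, per-locus allele counts that
are the sufficient statistic for the Dirichlet-multinomial clustering
model.

Two on-disk formats are supported:

* GenePop 4.x text (2- or 3-digit allele coding; ``pop`` blocks define
  population membership; allele code 0 is missing).
* A long-form CSV dialect with columns
  ``individual,population,locus,allele1,allele2`` where ``0`` is the
  missing allele code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Internal sentinel for a missing allele slot (GenePop convention).
MISSING = 0


class ParseError(ValueError):
    """A genotype file could not be parsed; the message names the line."""


@dataclass
class GenotypeDataset:
    """Diploid genotypes for a set of individuals at a set of loci.

    Parameters
    ----------
    individuals
        Sample identifiers, one per row of ``genotypes``.
    populations
        Per-individual population label (parallel to ``individuals``).
    loci
        Locus identifiers (unique), one per column of ``genotypes``.
    genotypes
        Integer array of shape ``(n_individuals, n_loci, 2)`` holding
        allele codes (allele size in repeat units, or any integer
        label); ``0`` marks a missing slot.
    locus_meta
        Optional per-locus annotation indexed by locus id with columns
        such as ``chromosome``, ``region``, ``position`` (1-based bp).
    """

    individuals: list[str]
    populations: list[str]
    loci: list[str]
    genotypes: np.ndarray
    locus_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int64)
        n, L = len(self.individuals), len(self.loci)
        if self.genotypes.shape != (n, L, 2):
            raise ValueError(
                f"genotypes shape {self.genotypes.shape} != ({n}, {L}, 2)"
            )
        if len(self.populations) != n:
            raise ValueError("populations must parallel individuals")
        if len(set(self.loci)) != L:
            raise ValueError("locus identifiers must be unique")
        if n == 0:
            raise ValueError("dataset must contain at least one individual")
        if self.locus_meta is not None:
            unknown = set(self.locus_meta.index) - set(self.loci)
            if unknown:
                raise ValueError(f"locus_meta rows for unknown loci: {sorted(unknown)}")

    # -- basic views ---------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def pop_labels(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p, None)
        return list(seen)

    @property
    def n_populations(self) -> int:
        return len(self.pop_labels)

    def pop_indices(self, label: str) -> np.ndarray:
        pops = np.asarray(self.populations)
        idx = np.flatnonzero(pops == label)
        if idx.size == 0:
            raise KeyError(f"unknown population label {label!r}")
        return idx

    def __eq__(self, other: object) -> bool:  # value equality, metadata aside
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.populations == other.populations
            and self.loci == other.loci
            and np.array_equal(self.genotypes, other.genotypes)
        )

    # -- subsetting ----------------------------------------------------

    def subset_loci(self, locus_ids: Sequence[str]) -> "GenotypeDataset":
        """Return a dataset restricted to ``locus_ids`` in the given order."""
        if len(set(locus_ids)) != len(locus_ids):
            raise KeyError("locus_ids must be distinct")
        pos = {l: i for i, l in enumerate(self.loci)}
        try:
            cols = [pos[l] for l in locus_ids]
        except KeyError as e:
            raise KeyError(f"unknown locus id {e.args[0]!r}") from None
        meta = None
        if self.locus_meta is not None:
            meta = self.locus_meta.loc[
                [l for l in locus_ids if l in self.locus_meta.index]
            ]
        return GenotypeDataset(
            individuals=list(self.individuals),
            populations=list(self.populations),
            loci=list(locus_ids),
            genotypes=self.genotypes[:, cols, :].copy(),
            locus_meta=meta,
        )

    def subset_populations(self, labels: Sequence[str]) -> "GenotypeDataset":
        keep = set(labels)
        rows = [i for i, p in enumerate(self.populations) if p in keep]
        if not rows:
            raise KeyError("no individuals in the requested populations")
        return GenotypeDataset(
            individuals=[self.individuals[i] for i in rows],
            populations=[self.populations[i] for i in rows],
            loci=list(self.loci),
            genotypes=self.genotypes[rows],
            locus_meta=self.locus_meta,
        )


@dataclass
class AlleleCountTable:
    """Per-group, per-locus allele counts in a flat column layout.

    Alleles observed at each locus (across all groups) form an ordered
    registry, ascending by allele code; alleles never observed are
    absent. Counts are stored as a dense ``(n_groups, n_columns)``
    matrix where columns are the concatenated per-locus registries and
    ``offsets`` delimits loci, which makes merging groups and summing
    within loci cheap for the clustering search.
    """

    groups: list[str]
    loci: list[str]
    allele_codes: np.ndarray       # (n_columns,) allele code per column
    offsets: np.ndarray            # (n_loci + 1,) locus column boundaries
    counts: np.ndarray             # (n_groups, n_columns) non-negative ints

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_alleles(self) -> np.ndarray:
        """Number of registry alleles per locus."""
        return np.diff(self.offsets)

    def totals(self) -> np.ndarray:
        """N_{g,l}: observed allele slots per group and locus."""
        out = np.zeros((self.n_groups, self.n_loci), dtype=np.int64)
        nz = np.flatnonzero(self.n_alleles > 0)
        if nz.size:
            # empty loci occupy zero columns, so starts of non-empty loci
            # are exact reduceat segment boundaries
            out[:, nz] = np.add.reduceat(self.counts, self.offsets[:-1][nz], axis=1)
        return out

    def locus_alleles(self, locus: str) -> np.ndarray:
        i = self.loci.index(locus)
        return self.allele_codes[self.offsets[i] : self.offsets[i + 1]]

    def locus_counts(self, locus: str) -> np.ndarray:
        i = self.loci.index(locus)
        return self.counts[:, self.offsets[i] : self.offsets[i + 1]]

    def select_loci(self, locus_ids: Sequence[str]) -> "AlleleCountTable":
        """Column-select a subset of loci (order as given)."""
        pos = {l: i for i, l in enumerate(self.loci)}
        cols: list[np.ndarray] = []
        codes: list[np.ndarray] = []
        offs = [0]
        for lid in locus_ids:
            try:
                i = pos[lid]
            except KeyError:
                raise KeyError(f"unknown locus id {lid!r}") from None
            sl = slice(self.offsets[i], self.offsets[i + 1])
            cols.append(self.counts[:, sl])
            codes.append(self.allele_codes[sl])
            offs.append(offs[-1] + (sl.stop - sl.start))
        return AlleleCountTable(
            groups=list(self.groups),
            loci=list(locus_ids),
            allele_codes=np.concatenate(codes) if codes else np.empty(0, int),
            offsets=np.asarray(offs, dtype=np.int64),
            counts=np.hstack(cols) if cols else np.empty((self.n_groups, 0), int),
        )

    def merge_groups(self, grouping: Mapping[str, str]) -> "AlleleCountTable":
        """Sum rows that map to the same group label."""
        missing = set(self.groups) - set(grouping)
        if missing:
            raise KeyError(f"grouping does not cover groups: {sorted(missing)}")
        new_labels: dict[str, None] = {}
        for g in self.groups:
            new_labels.setdefault(grouping[g], None)
        labels = list(new_labels)
        counts = np.zeros((len(labels), self.counts.shape[1]), dtype=np.int64)
        row = {lab: i for i, lab in enumerate(labels)}
        for i, g in enumerate(self.groups):
            counts[row[grouping[g]]] += self.counts[i]
        return AlleleCountTable(
            groups=labels,
            loci=list(self.loci),
            allele_codes=self.allele_codes.copy(),
            offsets=self.offsets.copy(),
            counts=counts,
        )


@dataclass
class RegionAnnotation:
    """A named genomic region grouping a set of loci (e.g. ``Xr2``)."""

    region: str
    chromosome: str
    band: str
    start_bp: int
    end_bp: int
    loci: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, format: str = "csv") -> GenotypeDataset:
    """Read a genotype file in GenePop or long-form CSV format."""
    path = Path(path)
    if format == "genepop":
        return _read_genepop(path)
    if format == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown format {format!r} (expected 'genepop' or 'csv')")


def write_genotypes(
    dataset: GenotypeDataset, path: str | Path, format: str = "csv"
) -> None:
    """Write a dataset in GenePop or long-form CSV format."""
    path = Path(path)
    if format == "genepop":
        _write_genepop(dataset, path)
    elif format == "csv":
        _write_csv(dataset, path)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'genepop' or 'csv')")


def _read_genepop(path: Path) -> GenotypeDataset:
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    # line 1: title; then locus names until the first 'pop'
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = lines[i].strip()
        if chunk:
            loci.extend(x.strip() for x in chunk.split(",") if x.strip())
        i += 1
    if i == len(lines):
        raise ParseError(f"{path}: no 'pop' line found")
    if not loci:
        raise ParseError(f"{path}: no locus names before first 'pop'")

    individuals: list[str] = []
    populations: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    pop_counter = 0
    while i < len(lines):
        if lines[i].strip().lower() == "pop":
            pop_counter += 1
            i += 1
            continue
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if "," not in line:
            raise ParseError(f"{path}:{i + 1}: expected 'name , genotypes'")
        name, geno_part = line.split(",", 1)
        fields = geno_part.split()
        if len(fields) != len(loci):
            raise ParseError(
                f"{path}:{i + 1}: {len(fields)} genotype fields, expected {len(loci)}"
            )
        row = []
        for f in fields:
            if not f.isdigit() or len(f) not in (4, 6):
                raise ParseError(f"{path}:{i + 1}: bad genotype field {f!r}")
            w = len(f) // 2
            row.append((int(f[:w]), int(f[w:])))
        individuals.append(name.strip())
        populations.append(f"pop{pop_counter}")
        rows.append(row)
        i += 1
    if not rows:
        raise ParseError(f"{path}: no individuals")
    geno = np.array(rows, dtype=np.int64)
    return GenotypeDataset(individuals, populations, loci, geno)


def _write_genepop(dataset: GenotypeDataset, path: Path) -> None:
    width = 3 if int(dataset.genotypes.max(initial=0)) <= 999 else None
    if width is None:
        raise ValueError("GenePop supports allele codes up to 999")
    out = ["lineagesort export"]
    out.extend(dataset.loci)
    last_pop: str | None = None
    for i, (ind, pop) in enumerate(zip(dataset.individuals, dataset.populations)):
        if pop != last_pop:
            out.append("pop")
            last_pop = pop
        gfields = [
            f"{a:0{width}d}{b:0{width}d}" for a, b in dataset.genotypes[i]
        ]
        out.append(f"{ind} , " + " ".join(gfields))
    path.write_text("\n".join(out) + "\n")


_CSV_COLUMNS = ["individual", "population", "locus", "allele1", "allele2"]


def _read_csv(path: Path) -> GenotypeDataset:
    try:
        df = pd.read_csv(path, dtype={"individual": str, "population": str, "locus": str})
    except Exception as e:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {e}") from e
    missing_cols = set(_CSV_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ParseError(f"{path}: missing columns {sorted(missing_cols)}")
    individuals: list[str] = list(dict.fromkeys(df["individual"]))
    loci: list[str] = list(dict.fromkeys(df["locus"]))
    ind_pos = {x: i for i, x in enumerate(individuals)}
    loc_pos = {x: i for i, x in enumerate(loci)}
    geno = np.zeros((len(individuals), len(loci), 2), dtype=np.int64)
    seen = np.zeros((len(individuals), len(loci)), dtype=bool)
    pops: dict[str, str] = {}
    for rec in df.itertuples(index=False):
        i, j = ind_pos[rec.individual], loc_pos[rec.locus]
        if seen[i, j]:
            raise ParseError(
                f"{path}: duplicate record for {rec.individual}/{rec.locus}"
            )
        seen[i, j] = True
        geno[i, j, 0] = int(rec.allele1)
        geno[i, j, 1] = int(rec.allele2)
        prev = pops.setdefault(rec.individual, rec.population)
        if prev != rec.population:
            raise ParseError(
                f"{path}: individual {rec.individual} listed in two populations"
            )
    if not seen.all():
        i, j = np.argwhere(~seen)[0]
        raise ParseError(
            f"{path}: no record for individual {individuals[i]!r} at locus {loci[j]!r}"
        )
    populations = [pops[x] for x in individuals]
    return GenotypeDataset(individuals, populations, loci, geno)


def _write_csv(dataset: GenotypeDataset, path: Path) -> None:
    recs = []
    for i, (ind, pop) in enumerate(zip(dataset.individuals, dataset.populations)):
        for j, locus in enumerate(dataset.loci):
            a, b = dataset.genotypes[i, j]
            recs.append((ind, pop, locus, int(a), int(b)))
    pd.DataFrame(recs, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_regions(path: str | Path) -> list[RegionAnnotation]:
    """Read region annotations: CSV ``region,chromosome,band,start_bp,end_bp,locus``."""
    df = pd.read_csv(path, dtype=str)
    need = {"region", "chromosome", "band", "start_bp", "end_bp", "locus"}
    if not need <= set(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(need - set(df.columns))}")
    regions: dict[str, RegionAnnotation] = {}
    for rec in df.itertuples(index=False):
        r = regions.get(rec.region)
        if r is None:
            r = RegionAnnotation(
                region=rec.region,
                chromosome=rec.chromosome,
                band=rec.band,
                start_bp=int(rec.start_bp),
                end_bp=int(rec.end_bp),
                loci=[],
            )
            regions[rec.region] = r
        r.loci.append(rec.locus)
    return list(regions.values())


# ---------------------------------------------------------------------------
# Allele counts
# ---------------------------------------------------------------------------

def allele_counts(
    dataset: GenotypeDataset, grouping: Mapping[str, str] | None = None
) -> AlleleCountTable:
    """Tabulate non-missing allele counts per group and locus.

    ``grouping`` maps every population label to a group label; by
    default each population is its own group. Half-missing genotypes
    contribute their known slot only.
    """
    pop_labels = dataset.pop_labels
    if grouping is None:
        grouping = {p: p for p in pop_labels}
    else:
        missing = set(pop_labels) - set(grouping)
        if missing:
            raise KeyError(f"grouping does not cover populations: {sorted(missing)}")
    group_order: dict[str, None] = {}
    for p in pop_labels:
        group_order.setdefault(grouping[p], None)
    groups = list(group_order)
    grow = {g: i for i, g in enumerate(groups)}
    ind_group = np.array([grow[grouping[p]] for p in dataset.populations])

    codes_per_locus: list[np.ndarray] = []
    counts_per_locus: list[np.ndarray] = []
    for j in range(dataset.n_loci):
        sl = dataset.genotypes[:, j, :]           # (n, 2)
        mask = sl != MISSING
        codes = np.unique(sl[mask])
        codes_per_locus.append(codes)
        cnt = np.zeros((len(groups), codes.size), dtype=np.int64)
        if codes.size:
            code_pos = {c: k for k, c in enumerate(codes)}
            for g in range(len(groups)):
                vals = sl[ind_group == g]
                vals = vals[vals != MISSING]
                for v, c in zip(*np.unique(vals, return_counts=True)):
                    cnt[g, code_pos[v]] = c
        counts_per_locus.append(cnt)
    offsets = np.concatenate(
        [[0], np.cumsum([c.size for c in codes_per_locus])]
    ).astype(np.int64)
    allele_codes = (
        np.concatenate(codes_per_locus)
        if codes_per_locus
        else np.empty(0, dtype=np.int64)
    )
    counts = (
        np.hstack(counts_per_locus)
        if counts_per_locus
        else np.empty((len(groups), 0), dtype=np.int64)
    )
    return AlleleCountTable(
        groups=groups,
        loci=list(dataset.loci),
        allele_codes=allele_codes,
        offsets=offsets,
        counts=counts,
    )


def subset_loci(dataset: GenotypeDataset, locus_ids: Sequence[str]) -> GenotypeDataset:
    """Functional alias for :meth:`GenotypeDataset.subset_loci`."""
    return dataset.subset_loci(locus_ids)
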