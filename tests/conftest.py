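"""Shared fixtures: small random genotype datasets and count tables."""

from __future__ import annotations

import numpy as np
import pytest

from lineagesort.io import AlleleCountTable, GenotypeDataset


def make_dataset(
    rng: np.random.Generator,
    n_pops: int = 3,
    n_per_pop: int = 5,
    n_loci: int = 4,
    alleles=(98, 100, 102, 104),
    missing_rate: float = 0.0,
) -> GenotypeDataset:
    """A random diploid dataset with optional missing slots."""
    n = n_pops * n_per_pop
    geno = rng.choice(alleles, size=(n, n_loci, 2))
    if missing_rate > 0:
        geno[rng.random(geno.shape) < missing_rate] = 0
    individuals = [f"ind{i}" for i in range(n)]
    populations = [f"pop{i // n_per_pop + 1}" for i in range(n)]
    loci = [f"m{j + 1}" for j in range(n_loci)]
    return GenotypeDataset(individuals, populations, loci, geno)


def make_count_table(
    rng: np.random.Generator,
    n_groups: int = 3,
    n_loci: int = 4,
    max_alleles: int = 4,
    max_count: int = 10,
) -> AlleleCountTable:
    """A random allele-count table (registry sorted, no zero-total alleles)."""
    codes, offs, cols = [], [0], []
    for _ in range(n_loci):
        A = int(rng.integers(1, max_alleles + 1))
        codes.append(100 + 2 * np.arange(A))
        cnt = rng.integers(0, max_count + 1, size=(n_groups, A))
        # ensure no allele has zero total count
        zero = cnt.sum(axis=0) == 0
        cnt[0, zero] = 1
        cols.append(cnt)
        offs.append(offs[-1] + A)
    return AlleleCountTable(
        groups=[f"pop{i + 1}" for i in range(n_groups)],
        loci=[f"m{j + 1}" for j in range(n_loci)],
        allele_codes=np.concatenate(codes),
        offsets=np.asarray(offs),
        counts=np.hstack(cols),
    )


def make_structured_table(
    rng: np.random.Generator,
    true_partition: list[list[int]],
    n_loci: int = 20,
    n_alleles: int = 3,
    n_per_group: int = 30,
    concentration: float = 3.0,
) -> AlleleCountTable:
    """Counts drawn from cluster-specific allele frequencies.

    Populations in the same block of ``true_partition`` share a
    Dirichlet-drawn frequency vector per locus, so the block structure
    is recoverable by the clustering model at these sample sizes.
    """
    n_pops = sum(len(b) for b in true_partition)
    codes, offs, cols = [], [0], []
    for _ in range(n_loci):
        freqs = {}
        for b, block in enumerate(true_partition):
            freqs[b] = rng.dirichlet(np.full(n_alleles, concentration))
        cnt = np.zeros((n_pops, n_alleles), dtype=np.int64)
        for b, block in enumerate(true_partition):
            for p in block:
                cnt[p] = rng.multinomial(n_per_group, freqs[b])
        keep = cnt.sum(axis=0) > 0
        cnt = cnt[:, keep]
        codes.append(100 + 2 * np.arange(int(keep.sum())))
        cols.append(cnt)
        offs.append(offs[-1] + int(keep.sum()))
    return AlleleCountTable(
        groups=[f"pop{i + 1}" for i in range(n_pops)],
        loci=[f"m{j + 1}" for j in range(n_loci)],
        allele_codes=np.concatenate(codes),
        offsets=np.asarray(offs),
        counts=np.hstack(cols),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
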