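"""Locus-subsampling stability of clustering solutions.

For each subset size n, many random n-locus subsets are drawn from the
full dataset and clustered; the curve tracks how often the reference
partition is recovered, how many distinct solutions appear, the modal
cluster count, and the posterior support carried by wrong solutions.
With few loci, different random locus sets frequently support
different, yet individually well-supported, partitions — the signature
of genealogical lineage sorting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .clustering import Partition, PriorSpec, search_best_partition
from .io import GenotypeDataset, allele_counts

__all__ = ["StabilityCurve", "stability_curve", "wrong_solution_support"]


@dataclass
class StabilityCurve:
    """Per-draw clustering outcomes over a grid of subset sizes.

    ``records`` has one row per draw with columns ``n``, ``draw``,
    ``is_reference`` (set-of-sets equality with the reference
    partition), ``pp`` (posterior probability of the draw's best
    partition), ``k`` (its cluster count) and ``partition`` (canonical
    string form, for distinct-solution counting).
    """

    reference: Partition
    n_values: tuple[int, ...]
    draws: int
    seed: int | None
    records: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        """Aggregate per n: recovery frequency, distinct solutions, support."""
        rows = []
        for n, grp in self.records.groupby("n"):
            wrong = grp[~grp["is_reference"]]
            frac_wrong_hi = (
                float((wrong["pp"] > 0.95).mean()) if len(wrong) else np.nan
            )
            rows.append(
                {
                    "n": int(n),
                    "freq_reference": float(grp["is_reference"].mean()),
                    "n_distinct": int(grp["partition"].nunique()),
                    "frac_wrong_pp_gt_0.95": frac_wrong_hi,
                    "modal_k": int(grp["k"].mode().iloc[0]),
                }
            )
        return pd.DataFrame(rows).set_index("n")


def stability_curve(
    dataset: GenotypeDataset,
    reference: Partition,
    n_values: Sequence[int],
    draws: int = 1000,
    seed: int | None = None,
    prior: PriorSpec | None = None,
    n_runs: int = 1,
) -> StabilityCurve:
    """Cluster ``draws`` random n-locus subsets for each n in ``n_values``.

    Each draw samples n loci without replacement (draws are
    independent, so loci recur across draws), runs the partition
    search, and records whether the best partition equals the
    reference (label-free), its posterior probability, and its cluster
    count. Deterministic given ``seed``.
    """
    L = dataset.n_loci
    n_values = [int(n) for n in n_values]
    if any(n < 1 or n > L for n in n_values):
        raise ValueError(f"every n must be in [1, {L}]")
    if draws < 1:
        raise ValueError("draws must be >= 1")
    if reference.labels != frozenset(dataset.pop_labels):
        raise ValueError("reference partition must cover all populations")
    prior = prior or PriorSpec()
    rng = np.random.default_rng(seed)
    loci = np.asarray(dataset.loci, dtype=object)
    # tabulate once; per-draw tables are column selections (counts
    # commute with locus subsetting)
    full_counts = allele_counts(dataset)
    ref_key = reference.key()
    recs = []
    for n in n_values:
        for d in range(draws):
            pick = rng.choice(L, size=n, replace=False)
            counts = full_counts.select_loci(list(loci[pick]))
            res = search_best_partition(
                counts, prior, n_runs=n_runs, seed=int(rng.integers(2**31))
            )
            key = res.best.key()
            recs.append(
                {
                    "n": n,
                    "draw": d,
                    "is_reference": key == ref_key,
                    "pp": res.posterior_prob,
                    "k": res.best.k,
                    "partition": repr(res.best),
                }
            )
    return StabilityCurve(
        reference=reference,
        n_values=tuple(n_values),
        draws=draws,
        seed=seed,
        records=pd.DataFrame.from_records(recs),
    )


def wrong_solution_support(curve: StabilityCurve) -> pd.Series:
    """Per n: fraction of non-reference best solutions with pp > 0.95.

    NaN where every draw recovered the reference (no wrong solutions
    to assess).
    """
    out = {}
    for n, grp in curve.records.groupby("n"):
        wrong = grp[~grp["is_reference"]]
        out[int(n)] = float((wrong["pp"] > 0.95).mean()) if len(wrong) else np.nan
    return pd.Series(out, name="frac_wrong_pp_gt_0.95").rename_axis("n")
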