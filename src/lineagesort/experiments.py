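"""Reproductions of the study-scale simulation experiments.

These functions wire the simulation, clustering and subsampling
modules together into the two headline computer experiments:

* the divergence-recovery experiment — a five-population polytomy
  calibrated to a target mean pairwise F_ST, repeatedly subsampled at
  a fixed locus count and clustered, tracking how often the true
  five-cluster structure is recovered and how strongly wrong
  solutions are supported;
* the 13-population recovery-crossing experiment — a D. melanogaster
  -like hierarchy of 137 SMM loci, whose full-data best partition is
  taken as the reference for a locus-subsampling stability curve; the
  result is the smallest locus count at which the reference is
  recovered in at least 95% of draws.

Replicate counts default to a desk-scale 200 draws per point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .clustering import Partition, search_best_partition
from .io import allele_counts
from .popstats import mean_pairwise_fst
from .simulate import (
    calibrate_divergence,
    dmel_like_scenario,
    polytomy_scenario,
    simulate_dataset,
)
from .subsample import StabilityCurve, stability_curve

__all__ = [
    "DivergenceRecoveryResult",
    "RecoveryCrossingResult",
    "divergence_recovery_experiment",
    "dmel_recovery_crossing",
]


@dataclass
class DivergenceRecoveryResult:
    target_fst: float
    achieved_fst: float            # realized on the full simulated dataset
    divergence_time: float
    n_loci_per_draw: int
    draws: int
    freq_true: float               # frequency of the true 5-cluster solution
    modal_k: int                   # modal inferred cluster count
    n_wrong: int                   # draws recovering a different partition
    median_wrong_pp: float         # median pp among wrong-solution draws (NaN if none)
    frac_wrong_pp_gt_095: float    # fraction of wrong draws with pp > 0.95
    curve: StabilityCurve


def divergence_recovery_experiment(
    target_fst: float,
    seed: int,
    draws: int = 200,
    n_loci_per_draw: int = 30,
    n_pops: int = 5,
    n_per_pop: int = 50,
    pool_loci: int = 1000,
    theta: float = 1.0,
) -> DivergenceRecoveryResult:
    """Polytomy divergence scenario: calibrate, simulate, subsample, cluster.

    The scenario follows the study design: ``n_pops`` populations
    diverging simultaneously, 50 diploid individuals and 1000
    independent SMM loci per population, divergence time solved so the
    mean pairwise F_ST matches ``target_fst``. ``draws`` random
    ``n_loci_per_draw``-locus subsets are clustered against the true
    all-singletons partition.
    """
    rng = np.random.default_rng(seed)
    spec = polytomy_scenario(
        n_pops=n_pops,
        n_per_pop=n_per_pop,
        n_loci=pool_loci,
        theta=theta,
        divergence_time=1.0,
        target_fst=target_fst,
    )
    solved, _ = calibrate_divergence(spec, seed=int(rng.integers(2**31)))
    ds = simulate_dataset(solved, seed=int(rng.integers(2**31)))
    achieved = mean_pairwise_fst(ds)
    truth = Partition([[p] for p in ds.pop_labels])
    curve = stability_curve(
        ds, truth, [n_loci_per_draw], draws=draws, seed=int(rng.integers(2**31))
    )
    rec = curve.records
    wrong = rec[~rec["is_reference"]]
    return DivergenceRecoveryResult(
        target_fst=target_fst,
        achieved_fst=achieved,
        divergence_time=solved.splits[0][0],
        n_loci_per_draw=n_loci_per_draw,
        draws=draws,
        freq_true=float(rec["is_reference"].mean()),
        modal_k=int(rec["k"].mode().iloc[0]),
        n_wrong=int(len(wrong)),
        median_wrong_pp=float(wrong["pp"].median()) if len(wrong) else float("nan"),
        frac_wrong_pp_gt_095=(
            float((wrong["pp"] > 0.95).mean()) if len(wrong) else float("nan")
        ),
        curve=curve,
    )


@dataclass
class RecoveryCrossingResult:
    references: list[Partition]    # full-data best partition per realization
    threshold: float
    crossings: list[int]           # per-realization 95%-recovery crossing
    crossing_n: float              # mean of the per-realization crossings
    draws: int
    summary: pd.DataFrame          # mean stability summary over the grid
    per_realization: list[pd.DataFrame]


#: Panel-size grid: coarse below the region of interest, 5-locus
#: resolution where the 95% crossing falls.
_DEFAULT_GRID = [20, 40, 60] + list(range(80, 136, 5)) + [137]


def dmel_recovery_crossing(
    seed: int,
    draws: int = 200,
    grid: Sequence[int] | None = None,
    threshold: float = 0.95,
    realizations: int = 5,
    n_runs_reference: int = 3,
) -> RecoveryCrossingResult:
    """Loci needed for reliable recovery in the 13-population scenario.

    Simulates ``realizations`` independent 137-locus datasets under the
    D. melanogaster-like hierarchy; for each, clusters the full dataset
    (that realization's reference solution), computes the recovery
    frequency of ``draws`` random n-locus subsets over ``grid``, and
    takes the smallest n whose recovery reaches ``threshold`` (censored
    at the full panel if never reached below it). The reported value is
    the mean of the per-realization crossings — the expected panel size
    the study design needs, rather than the property of one
    genealogical realization.
    """
    if grid is None:
        grid = list(_DEFAULT_GRID)
    rng = np.random.default_rng(seed)
    refs: list[Partition] = []
    summaries: list[pd.DataFrame] = []
    crossings: list[int] = []
    for _ in range(max(1, realizations)):
        ds = simulate_dataset(dmel_like_scenario(), seed=int(rng.integers(2**31)))
        counts = allele_counts(ds)
        ref = search_best_partition(
            counts, n_runs=n_runs_reference, seed=int(rng.integers(2**31))
        ).best
        curve = stability_curve(
            ds, ref, list(grid), draws=draws, seed=int(rng.integers(2**31))
        )
        s = curve.summary()
        ok = s[s["freq_reference"] >= threshold]
        crossings.append(int(ok.index.min()) if len(ok) else int(max(grid)))
        refs.append(ref)
        summaries.append(s)
    mean_summary = pd.concat(summaries).groupby(level=0).mean()
    mean_summary["modal_k"] = (
        pd.concat(s["modal_k"] for s in summaries).groupby(level=0).median()
    )
    return RecoveryCrossingResult(
        references=refs,
        threshold=threshold,
        crossings=crossings,
        crossing_n=float(np.mean(crossings)),
        draws=draws,
        summary=mean_summary,
        per_realization=summaries,
    )
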