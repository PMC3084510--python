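"""Resampling comparison of clustering solutions from different locus sets.

Two locus sets cannot be compared by their marginal likelihoods
directly (those scale with the number and information content of the
loci), so each test set is instead characterized by a distribution of
marginal-likelihood differences against a common reference pool:

1. find the best partition S_test of the test loci;
2. per replicate, sample as many loci as the test set holds, without
   replacement, from a pool excluding the test loci;
3. find the best partition of that random set and record its log
   marginal likelihood (ml_random);
4. evaluate S_test on the same random set (ml_test);
5. the replicate value is d = ml_test - ml_random (<= 0 up to search
   error; concentrated at 0 when the two sets agree).

Distributions from different test sets are then compared pairwise
with two-sample Kolmogorov-Smirnov tests under a Bonferroni
correction. The module also provides the conditioned marginal
likelihood used to rank locus sets by how well their partition
explains the full data, and single-feature least-squares regressions
of region features on that conditioned likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import (
    LikelihoodEngine,
    Partition,
    PriorSpec,
    search_best_partition,
)
from .io import GenotypeDataset, allele_counts

__all__ = [
    "MlDifferenceDistribution",
    "ComparisonReport",
    "ml_difference_distribution",
    "ks_two_sample",
    "compare_test_sets",
    "conditioned_ml",
    "feature_regression",
]

POOL_RULES = ("same-chromosome-remainder", "other-chromosome", "all-remainder")


@dataclass
class MlDifferenceDistribution:
    """Replicated ml_test - ml_random values for one test locus set."""

    test_set: str
    pool: str
    values: np.ndarray          # (R,) log-likelihood differences, nats
    test_partition: Partition
    seed: int | None

    @property
    def R(self) -> int:
        return len(self.values)


@dataclass
class ComparisonReport:
    """Pairwise KS comparison of ml-difference distributions."""

    distributions: dict[str, MlDifferenceDistribution]
    D: pd.DataFrame             # KS statistic matrix
    p: pd.DataFrame             # asymptotic p-value matrix
    bonferroni_threshold: float # 0.05 / number of pairs
    significant: pd.DataFrame   # p < threshold


def ml_difference_distribution(
    dataset: GenotypeDataset,
    test_loci: Sequence[str],
    pool_loci: Sequence[str],
    R: int = 10000,
    seed: int | None = None,
    prior: PriorSpec | None = None,
    n_runs_test: int = 3,
    n_runs_random: int = 1,
    test_set_name: str = "test",
    pool_name: str = "pool",
) -> MlDifferenceDistribution:
    """Build the ml-difference distribution of one test locus set.

    ``pool_loci`` must be disjoint from ``test_loci`` and at least as
    large. ml_random is the maximum log marginal likelihood over the
    partitions visited by the replicate's search, so every value is
    <= 0 up to search error. Deterministic given ``seed``.
    """
    test_loci = list(test_loci)
    pool_loci = list(pool_loci)
    if set(test_loci) & set(pool_loci):
        raise ValueError("test_loci and pool_loci must be disjoint")
    if len(pool_loci) < len(test_loci):
        raise ValueError("pool must hold at least as many loci as the test set")
    prior = prior or PriorSpec()
    rng = np.random.default_rng(seed)

    full_counts = allele_counts(dataset)
    test_counts = full_counts.select_loci(test_loci)
    s_test = search_best_partition(
        test_counts, prior, n_runs=n_runs_test, seed=int(rng.integers(2**31))
    )
    n = len(test_loci)
    pool_arr = np.asarray(pool_loci, dtype=object)
    values = np.empty(R)
    for r in range(R):
        pick = rng.choice(len(pool_arr), size=n, replace=False)
        rand_counts = full_counts.select_loci(list(pool_arr[pick]))
        eng = LikelihoodEngine(rand_counts, prior)
        res = search_best_partition(
            rand_counts,
            prior,
            n_runs=n_runs_random,
            seed=int(rng.integers(2**31)),
            engine=eng,
        )
        ml_random = res.max_ledger_log_ml
        ml_test = eng.log_ml(s_test.best)
        values[r] = ml_test - ml_random
    return MlDifferenceDistribution(
        test_set=test_set_name,
        pool=pool_name,
        values=values,
        test_partition=s_test.best,
        seed=seed,
    )


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p-value).

    D = sup_t |F_x(t) - F_y(t)|; the p-value comes from the asymptotic
    Kolmogorov distribution at effective size |x||y|/(|x|+|y|).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def _pools_by_rule(
    dataset: GenotypeDataset,
    test_sets: Mapping[str, Sequence[str]],
    pool_rule: str,
) -> dict[str, list[str]]:
    if pool_rule not in POOL_RULES:
        raise ValueError(f"pool_rule must be one of {POOL_RULES}")
    all_loci = list(dataset.loci)
    chrom: dict[str, str] | None = None
    if pool_rule != "all-remainder":
        if dataset.locus_meta is None or "chromosome" not in dataset.locus_meta:
            raise ValueError(f"pool_rule {pool_rule!r} needs locus_meta.chromosome")
        chrom = dataset.locus_meta["chromosome"].to_dict()
    pools: dict[str, list[str]] = {}
    for name, loci in test_sets.items():
        test = set(loci)
        if pool_rule == "all-remainder":
            pool = [l for l in all_loci if l not in test]
        else:
            test_chroms = {chrom.get(l) for l in loci}
            if pool_rule == "same-chromosome-remainder":
                pool = [
                    l for l in all_loci
                    if l not in test and chrom.get(l) in test_chroms
                ]
            else:  # other-chromosome
                pool = [
                    l for l in all_loci
                    if l not in test and chrom.get(l) not in test_chroms
                ]
        if len(pool) < len(loci):
            raise ValueError(
                f"test set {name!r}: pool of {len(pool)} loci is smaller "
                f"than the test set ({len(loci)})"
            )
        pools[name] = pool
    return pools


def compare_test_sets(
    dataset: GenotypeDataset,
    test_sets: Mapping[str, Sequence[str]],
    pool_rule: str = "all-remainder",
    R: int = 10000,
    seed: int | None = None,
    prior: PriorSpec | None = None,
    alpha: float = 0.05,
    n_runs_test: int = 3,
    n_runs_random: int = 1,
) -> ComparisonReport:
    """Pairwise KS comparison of every test set's ml-difference distribution."""
    if len(test_sets) < 2:
        raise ValueError("need at least two test sets")
    pools = _pools_by_rule(dataset, test_sets, pool_rule)
    rng = np.random.default_rng(seed)
    dists: dict[str, MlDifferenceDistribution] = {}
    for name in test_sets:
        dists[name] = ml_difference_distribution(
            dataset,
            test_sets[name],
            pools[name],
            R=R,
            seed=int(rng.integers(2**31)),
            prior=prior,
            n_runs_test=n_runs_test,
            n_runs_random=n_runs_random,
            test_set_name=name,
            pool_name=pool_rule,
        )
    names = list(test_sets)
    D = pd.DataFrame(0.0, index=names, columns=names)
    p = pd.DataFrame(1.0, index=names, columns=names)
    pairs = list(combinations(names, 2))
    for a, b in pairs:
        d, pv = ks_two_sample(dists[a].values, dists[b].values)
        D.loc[a, b] = D.loc[b, a] = d
        p.loc[a, b] = p.loc[b, a] = pv
    threshold = alpha / len(pairs)
    sig = (p < threshold) & ~np.eye(len(names), dtype=bool)
    return ComparisonReport(
        distributions=dists,
        D=D,
        p=p,
        bonferroni_threshold=threshold,
        significant=pd.DataFrame(sig, index=names, columns=names),
    )


def conditioned_ml(
    dataset: GenotypeDataset,
    partition: Partition,
    prior: PriorSpec | None = None,
) -> float:
    """Log marginal likelihood of the FULL dataset under a fixed partition.

    Used to rank locus sets: a set whose best partition explains the
    complete data well scores high.
    """
    counts = allele_counts(dataset)
    return LikelihoodEngine(counts, prior).log_ml(partition)


def feature_regression(
    region_features: pd.DataFrame,
    conditioned_mls: pd.Series | Sequence[float],
) -> pd.DataFrame:
    """Single-feature ordinary least squares against conditioned log ml.

    One fit per feature column: slope, R-squared and the F-test
    p-value (equal to the two-sided t-test in simple regression).
    Constant features are flagged and not fitted.
    """
    y = np.asarray(conditioned_mls, dtype=float)
    if len(region_features) != len(y):
        raise ValueError("features and response must have equal length")
    if len(y) < 3:
        raise ValueError("need at least 3 regions")
    rows = []
    for col in region_features.columns:
        x = np.asarray(region_features[col], dtype=float)
        if np.allclose(x, x[0]):
            rows.append((col, np.nan, np.nan, np.nan, True))
            continue
        fit = stats.linregress(x, y)
        rows.append((col, fit.slope, fit.rvalue**2, fit.pvalue, False))
    return pd.DataFrame(
        rows, columns=["feature", "slope", "r_squared", "p_value", "constant"]
    ).set_index("feature")
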