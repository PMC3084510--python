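"""Coalescent microsatellite simulation and the lineage-sorting toy model.

Genealogies are simulated with msprime under divergence trees (no
migration, constant sizes); stepwise-mutation-model (SMM) mutations
are then dropped on each genealogy as a Poisson process with rate
theta/2 per unit branch length (time measured in coalescent units of
2N generations), each mutation stepping the allele size by +-1 repeat
unit with probability 1/2, from an arbitrary ancestral size.

Divergence scenarios can be calibrated so that the realized mean
pairwise Weir-Cockerham F_ST matches a target, by bisection on the
split-time scale using pilot simulations.

The five-marker-class toy model captures genealogical lineage sorting
for three populations A, B, C: class 1 supports the true topology
A(BC); classes 2 and 3 the two wrong pairings; class 4 a single
cluster (ABC); class 5 full separation (A)(B)(C). Locus sets are drawn
multinomially and the supported structure is decided by strict
majority; an exact dynamic-programming oracle gives the same
probabilities analytically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import msprime
import numpy as np
import tskit

from .io import GenotypeDataset

__all__ = [
    "ScenarioSpec",
    "MarkerClassDistribution",
    "polytomy_scenario",
    "dmel_like_scenario",
    "simulate_dataset",
    "calibrate_divergence",
    "lineage_sorting_draw",
    "analytic_majority_probability",
    "read_ms_output",
]

# Coalescent time unit: 2N generations. msprime populations are given
# diploid size 0.5 so that one generation equals one coalescent unit
# (pairwise coalescence rate 1) and theta = 4*N*mu maps to mutation
# rate theta/2 per lineage per unit time.
_UNIT_SIZE = 0.5


@dataclass(frozen=True)
class ScenarioSpec:
    """A divergence-tree simulation scenario.

    ``splits`` is a sequence of ``(time, children, parent)`` events,
    times in coalescent units of 2N generations, children naming
    sampled populations or previously created ancestors. A polytomy is
    a single event merging all populations. ``target_fst`` marks the
    scenario for calibration (see :func:`calibrate_divergence`).
    """

    pop_names: tuple[str, ...]
    sample_sizes: tuple[int, ...]            # diploid individuals per population
    n_loci: int
    theta: float
    splits: tuple[tuple[float, tuple[str, ...], str], ...]
    target_fst: float | None = None
    ancestral_size: int = 20
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.pop_names) != len(self.sample_sizes):
            raise ValueError("pop_names and sample_sizes must be parallel")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if any(n < 1 for n in self.sample_sizes):
            raise ValueError("sample sizes must be >= 1")
        if any(t < 0 for t, _, _ in self.splits):
            raise ValueError("split times must be >= 0")
        if self.target_fst is not None and not 0 < self.target_fst < 1:
            raise ValueError("target_fst must be in (0, 1)")

    def scaled_times(self, factor: float) -> "ScenarioSpec":
        """A copy with all split times multiplied by ``factor``."""
        splits = tuple((t * factor, c, p) for t, c, p in self.splits)
        return replace(self, splits=splits)


def polytomy_scenario(
    n_pops: int = 5,
    n_per_pop: int = 50,
    n_loci: int = 1000,
    theta: float = 1.0,
    divergence_time: float = 0.1,
    target_fst: float | None = None,
    seed: int | None = None,
) -> ScenarioSpec:
    """K populations diverging simultaneously from one ancestor."""
    names = tuple(f"pop{i + 1}" for i in range(n_pops))
    return ScenarioSpec(
        pop_names=names,
        sample_sizes=(n_per_pop,) * n_pops,
        n_loci=n_loci,
        theta=theta,
        splits=((divergence_time, names, "anc"),),
        target_fst=target_fst,
        seed=seed,
    )


# Default split times of the 13-population D. melanogaster-like
# scenario (coalescent units of 2N generations), chosen by calibrating
# pilot simulations (theta = 1.5, 30 diploids per population) against
# the pairwise F_ST structure observed between natural populations:
# within Europe ~0.03; the two North-American samples nearly
# undifferentiated from each other (~0.004) but slightly more diverged
# from Europe (~0.036) than Europe is internally; two of the Asian
# populations at ~0.05 with the third more distant (~0.09); Asia vs
# Europe intermediate (~0.12); Africa vs everything else strongly
# differentiated (~0.21) with the two African samples close (~0.02).
_DMEL_TIMES = {
    "europe": 0.031,         # star over the 6 European pops
    "na_pair": 0.004,        # split of the 2 North-American pops
    "eur_na": 0.040,         # Europe ancestor joins the N. American pair
    "asia_pair": 0.058,      # split of the 2 closer Asian pops
    "asia": 0.10,            # third Asian pop joins the pair
    "africa_within": 0.017,  # split of the 2 African pops
    "out_of_africa": 0.17,   # European + N. American ancestor joins Asia
    "root": 0.38,            # Africa vs all non-African
}


def dmel_like_scenario(
    n_loci: int = 137,
    theta: float = 1.5,
    n_per_pop: int = 30,
    times: dict[str, float] | None = None,
    seed: int | None = None,
) -> ScenarioSpec:
    """13-population hierarchy emulating worldwide D. melanogaster samples.

    Two African, six European, two North-American and three Asian
    populations: Africa splits deepest; Europe is a shallow star and
    the North-American pair, barely differentiated from each other,
    joins it only slightly deeper; the Asian populations are
    intermediately divergent both among themselves and from Europe.
    ``times`` may override the calibrated defaults.
    """
    t = dict(_DMEL_TIMES)
    if times:
        t.update(times)
    af = ("Af1", "Af2")
    eu = tuple(f"Eu{i + 1}" for i in range(6))
    na = ("NA1", "NA2")
    asi = ("As1", "As2", "As3")
    names = af + eu + na + asi
    splits = (
        (t["na_pair"], na, "NAm"),
        (t["europe"], eu, "Europe"),
        (t["eur_na"], ("Europe", "NAm"), "EurNA"),
        (t["asia_pair"], ("As1", "As2"), "AsiaPair"),
        (t["asia"], ("AsiaPair", "As3"), "Asia"),
        (t["africa_within"], af, "Africa"),
        (t["out_of_africa"], ("EurNA", "Asia"), "OOA"),
        (t["root"], ("Africa", "OOA"), "root"),
    )
    return ScenarioSpec(
        pop_names=names,
        sample_sizes=(n_per_pop,) * 13,
        n_loci=n_loci,
        theta=theta,
        splits=splits,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _demography(spec: ScenarioSpec) -> msprime.Demography:
    dem = msprime.Demography()
    for name in spec.pop_names:
        dem.add_population(name=name, initial_size=_UNIT_SIZE)
    for t, children, parent in sorted(spec.splits, key=lambda e: e[0]):
        dem.add_population(name=parent, initial_size=_UNIT_SIZE)
        dem.add_population_split(time=t, derived=list(children), ancestral=parent)
    return dem


def simulate_dataset(spec: ScenarioSpec, seed: int | None = None) -> GenotypeDataset:
    """Simulate a diploid SMM microsatellite dataset under the scenario.

    Loci are independent (one genealogy each); mutations are Poisson
    with mean theta/2 times branch length and step allele size by +-1;
    the two chromosomes of an individual are paired within its
    population. Deterministic given ``seed`` (falls back to
    ``spec.seed``).
    """
    seed = seed if seed is not None else spec.seed
    rng = np.random.default_rng(seed)
    ms_seed = int(rng.integers(1, 2**31 - 1))
    try:
        dem = _demography(spec)
    except Exception as e:
        raise ValueError(f"invalid population tree: {e}") from e
    samples = [
        msprime.SampleSet(n, population=name, ploidy=2)
        for name, n in zip(spec.pop_names, spec.sample_sizes)
    ]
    reps = msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        ploidy=2,
        sequence_length=1,
        num_replicates=spec.n_loci,
        random_seed=ms_seed,
    )
    n_ind = sum(spec.sample_sizes)
    geno = np.zeros((n_ind, spec.n_loci, 2), dtype=np.int64)
    individuals: list[str] | None = None
    populations: list[str] | None = None
    for j, ts in enumerate(reps):
        sizes = _drop_smm_mutations(ts, spec.theta, rng)
        if individuals is None:
            individuals, populations, ind_nodes = _individual_layout(ts)
        geno[:, j, 0] = spec.ancestral_size + sizes[ind_nodes[:, 0]]
        geno[:, j, 1] = spec.ancestral_size + sizes[ind_nodes[:, 1]]
    assert individuals is not None and populations is not None
    loci = [f"L{j + 1:04d}" for j in range(spec.n_loci)]
    return GenotypeDataset(individuals, populations, loci, geno)


def _drop_smm_mutations(
    ts: tskit.TreeSequence, theta: float, rng: np.random.Generator
) -> np.ndarray:
    """Net +-1 step displacement of every node from the root allele."""
    tree = ts.first()
    disp = np.zeros(ts.num_nodes, dtype=np.int64)
    rate = theta / 2.0
    for u in tree.nodes(order="preorder"):
        p = tree.parent(u)
        if p == tskit.NULL:
            continue
        m = rng.poisson(rate * tree.branch_length(u))
        step = 2 * rng.binomial(m, 0.5) - m if m else 0
        disp[u] = disp[p] + step
    return disp


def _individual_layout(
    ts: tskit.TreeSequence,
) -> tuple[list[str], list[str], np.ndarray]:
    pop_names = {p.id: p.metadata.get("name", f"pop{p.id}") for p in ts.populations()}
    individuals: list[str] = []
    populations: list[str] = []
    nodes = np.zeros((ts.num_individuals, 2), dtype=np.int64)
    counters: dict[str, int] = {}
    for ind in ts.individuals():
        nn = ind.nodes
        if len(nn) != 2:  # pragma: no cover - ploidy fixed to 2 above
            raise AssertionError("expected diploid individuals")
        pop = pop_names[ts.node(nn[0]).population]
        counters[pop] = counters.get(pop, 0) + 1
        individuals.append(f"{pop}_{counters[pop]:03d}")
        populations.append(pop)
        nodes[ind.id] = nn
    return individuals, populations, nodes


def calibrate_divergence(
    spec: ScenarioSpec,
    pilot_loci: int = 200,
    pilot_reps: int = 3,
    tol: float = 0.005,
    seed: int | None = None,
    scale_bounds: tuple[float, float] = (0.002, 50.0),
    max_iter: int = 30,
) -> tuple[ScenarioSpec, float]:
    """Solve the split-time scale so realized mean pairwise F_ST hits target.

    Bisection on a multiplier of all split times; each evaluation
    simulates ``pilot_reps`` pilot datasets of ``pilot_loci`` loci with
    common random seeds (so the realized F_ST is monotone in the
    scale) and measures the mean pairwise Weir-Cockerham theta.
    Returns the solved spec (target_fst cleared) and the achieved
    value. Raises if the search range does not bracket the target.
    """
    from .popstats import mean_pairwise_fst

    if spec.target_fst is None:
        raise ValueError("spec.target_fst must be set for calibration")
    if not 0.001 < spec.target_fst < 0.5:
        raise ValueError("target_fst must be in (0.001, 0.5)")
    target = spec.target_fst
    rng = np.random.default_rng(seed)
    pilot_seeds = [int(s) for s in rng.integers(1, 2**31 - 1, size=pilot_reps)]

    def realized(scale: float) -> float:
        s = replace(spec.scaled_times(scale), n_loci=pilot_loci, target_fst=None)
        vals = [mean_pairwise_fst(simulate_dataset(s, seed=ps)) for ps in pilot_seeds]
        return float(np.mean(vals))

    lo, hi = scale_bounds
    f_lo, f_hi = realized(lo), realized(hi)
    if not (f_lo < target < f_hi):
        raise RuntimeError(
            f"calibration range does not bracket target {target}: "
            f"F_ST({lo})={f_lo:.4f}, F_ST({hi})={f_hi:.4f}"
        )
    achieved = math.nan
    mid = (lo + hi) / 2
    for _ in range(max_iter):
        mid = math.sqrt(lo * hi)        # bisect in log scale
        f_mid = realized(mid)
        achieved = f_mid
        if abs(f_mid - target) <= tol:
            break
        if f_mid < target:
            lo = mid
        else:
            hi = mid
    solved = replace(spec.scaled_times(mid), target_fst=None)
    return solved, achieved


# ---------------------------------------------------------------------------
# Five-marker-class lineage-sorting toy model
# ---------------------------------------------------------------------------

#: Human-readable topology supported by each marker class.
CLASS_TOPOLOGIES = ("A(BC)", "(AB)C", "(AC)B", "(ABC)", "(A)(B)(C)")


@dataclass(frozen=True)
class MarkerClassDistribution:
    """Relative frequencies of the five marker classes (sum to 1)."""

    freqs: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.freqs) != 5:
            raise ValueError("exactly five class frequencies required")
        if any(f < 0 for f in self.freqs):
            raise ValueError("frequencies must be non-negative")
        if abs(sum(self.freqs) - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")

    @classmethod
    def from_truth_fraction(cls, f1: float) -> "MarkerClassDistribution":
        """Class 1 at frequency f1, classes 2-5 sharing the rest equally."""
        if not 0 <= f1 <= 1:
            raise ValueError("f1 must be in [0, 1]")
        rest = (1.0 - f1) / 4.0
        return cls((f1, rest, rest, rest, rest))


def lineage_sorting_draw(
    dist: MarkerClassDistribution,
    n_loci: int,
    reps: int = 1000,
    seed: int | None = None,
    break_ties: bool = False,
) -> dict[str, float]:
    """Monte-Carlo majority-rule frequencies of the five topologies.

    Each replicate draws class counts ~ Multinomial(n_loci, f); the
    supported topology is the class with the strictly largest count.
    Ties are reported as ``"unresolved"`` unless ``break_ties``, in
    which case a uniformly random tied class wins. Deterministic given
    ``seed``.
    """
    if n_loci < 1 or reps < 1:
        raise ValueError("n_loci and reps must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n_loci, dist.freqs, size=reps)     # (reps, 5)
    top = draws.max(axis=1)
    is_top = draws == top[:, None]
    n_top = is_top.sum(axis=1)
    winner = draws.argmax(axis=1)
    out = {name: 0 for name in CLASS_TOPOLOGIES}
    unresolved = 0
    for r in range(reps):
        if n_top[r] == 1:
            out[CLASS_TOPOLOGIES[winner[r]]] += 1
        elif break_ties:
            tied = np.flatnonzero(is_top[r])
            out[CLASS_TOPOLOGIES[tied[int(rng.integers(len(tied)))]]] += 1
        else:
            unresolved += 1
    freqs = {k: v / reps for k, v in out.items()}
    freqs["unresolved"] = unresolved / reps
    return freqs


def analytic_majority_probability(
    dist: MarkerClassDistribution, n_loci: int
) -> dict[str, float]:
    """Exact probability of each strict-majority outcome plus tie mass.

    Dynamic programming over multinomial count vectors: for each focal
    class c, P(c strictly max) = sum_k P(X_c = k) * P(all other counts
    <= k-1 and sum to n-k), the inner factor from convolving the other
    classes' truncated f^a/a! polynomials. Guarded at n_loci <= 150.
    """
    n = n_loci
    if n < 1:
        raise ValueError("n_loci must be >= 1")
    if n > 150:
        raise ValueError("exact enumeration guarded at n_loci <= 150")
    f = np.asarray(dist.freqs, dtype=float)
    fact_n = float(math.factorial(n))
    probs = np.zeros(5)
    for c in range(5):
        others = [f[j] for j in range(5) if j != c]
        total = 0.0
        for k in range(1, n + 1):
            # coefficient extraction: [x^{n-k}] prod_j sum_{a<k} (f_j x)^a / a!
            limit = min(k - 1, n - k)
            poly = np.zeros(n - k + 1)
            poly[0] = 1.0
            for fj in others:
                pj = np.array(
                    [fj**a / math.factorial(a) for a in range(limit + 1)]
                )
                poly = np.convolve(poly, pj)[: n - k + 1]
            coeff = poly[n - k]
            total += (f[c] ** k / math.factorial(k)) * coeff
        probs[c] = fact_n * total
    out = {name: float(p) for name, p in zip(CLASS_TOPOLOGIES, probs)}
    out["unresolved"] = float(max(0.0, 1.0 - probs.sum()))
    return out


# ---------------------------------------------------------------------------
# ms text adapter
# ---------------------------------------------------------------------------

def read_ms_output(
    text: str,
    sample_sizes: Sequence[int],
    pop_names: Sequence[str] | None = None,
    ancestral_size: int = 20,
    seed: int | None = None,
) -> GenotypeDataset:
    """Convert ms-style text output to an SMM microsatellite dataset.

    Each segregating site is assigned a +1 or -1 repeat-unit step with
    probability 1/2 (the ms2ms convention); a haplotype's allele size
    is the ancestral size plus the sum of steps of its derived sites.
    ``sample_sizes`` gives haploid counts per population; consecutive
    haplotype pairs form diploid individuals, so counts must be even.
    """
    if pop_names is None:
        pop_names = [f"pop{i + 1}" for i in range(len(sample_sizes))]
    if any(s % 2 for s in sample_sizes):
        raise ValueError("haploid sample sizes must be even to pair diploids")
    rng = np.random.default_rng(seed)
    blocks: list[tuple[int | None, list[str]]] = []
    cur: list[str] | None = None
    segsites: int | None = None
    for line in text.splitlines():
        line = line.strip()
        if line == "//":
            cur = []
            segsites = None
            blocks.append((None, cur))
        elif cur is not None and line.startswith("segsites:"):
            segsites = int(line.split(":")[1])
            blocks[-1] = (segsites, cur)
        elif cur is not None and line and set(line) <= {"0", "1"}:
            cur.append(line)
    n_hap = sum(sample_sizes)
    n_loci = len(blocks)
    if n_loci == 0:
        raise ValueError("no '//' replicate blocks found in ms output")
    hap_sizes = np.zeros((n_hap, n_loci), dtype=np.int64)
    for j, (S_decl, haps) in enumerate(blocks):
        if S_decl == 0 and not haps:     # ms prints no haplotypes then
            hap_sizes[:, j] = ancestral_size
            continue
        if len(haps) != n_hap:
            raise ValueError(
                f"replicate {j + 1}: {len(haps)} haplotypes, expected {n_hap}"
            )
        S = len(haps[0])
        steps = rng.choice([-1, 1], size=S) if S else np.empty(0, dtype=int)
        mat = np.array([[int(ch) for ch in h] for h in haps], dtype=np.int64)
        hap_sizes[:, j] = ancestral_size + mat @ steps if S else ancestral_size
    individuals: list[str] = []
    populations: list[str] = []
    geno = np.zeros((n_hap // 2, n_loci, 2), dtype=np.int64)
    row = 0
    offset = 0
    for name, s in zip(pop_names, sample_sizes):
        for i in range(s // 2):
            geno[row, :, 0] = hap_sizes[offset + 2 * i]
            geno[row, :, 1] = hap_sizes[offset + 2 * i + 1]
            individuals.append(f"{name}_{i + 1:03d}")
            populations.append(name)
            row += 1
        offset += s
    loci = [f"L{j + 1:04d}" for j in range(n_loci)]
    return GenotypeDataset(individuals, populations, loci, geno)
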