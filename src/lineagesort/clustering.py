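"""Bayesian clustering of predefined population groups.

The model is the BAPS-style group-level genetic mixture: populations
are assigned to clusters, allele frequencies within each cluster and
locus follow a symmetric Dirichlet prior, and the allele counts are
multinomial. Integrating the frequencies out gives an exact
Dirichlet-multinomial marginal likelihood for any partition of the
populations:

    log ml(S) = sum_c sum_l [ lnG(A_l a_l) - lnG(A_l a_l + M_cl)
                              + sum_a ( lnG(a_l + m_cla) - lnG(a_l) ) ]

with ``A_l`` observed alleles at locus ``l``, ``a_l`` the Dirichlet
hyperparameter (default 1/A_l), ``m_cla`` the pooled allele counts of
cluster ``c`` and ``M_cl`` their locus total. The multinomial ordering
constant is omitted consistently (it cancels in all comparisons).

The partition prior is uniform on the number of clusters k in
1..K_max and uniform over set partitions within each k, so
log prior(S) = -ln K_max - ln Stirling2(P, k).

Search is a greedy agglomeration from singletons followed by
hill-climbing (single-population relocations and binary cluster
splits), repeated over ``n_runs`` randomized restarts; every partition
evaluated on the way is recorded in a ledger used for posterior
probabilities. For small P the ledger is replaced by the full
enumeration of set partitions, making posterior probabilities exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .io import AlleleCountTable

__all__ = [
    "Partition",
    "PriorSpec",
    "ClusteringResult",
    "log_marginal_likelihood",
    "posterior_probabilities",
    "search_best_partition",
    "enumerate_partitions",
    "stirling2",
]

_TIE_TOL = 1e-9


class Partition:
    """A label-free assignment of population labels to clusters.

    Two partitions are equal iff they induce the same set of sets,
    regardless of cluster numbering or construction order.
    """

    __slots__ = ("clusters", "_key")

    def __init__(self, clusters: Iterable[Iterable[str]]):
        cl = [frozenset(c) for c in clusters]
        if any(len(c) == 0 for c in cl):
            raise ValueError("clusters must be non-empty")
        all_members: list[str] = [m for c in cl for m in c]
        if len(all_members) != len(set(all_members)):
            raise ValueError("clusters must be disjoint")
        self.clusters: tuple[frozenset[str], ...] = tuple(
            sorted(cl, key=lambda c: sorted(c))
        )
        self._key = frozenset(self.clusters)

    @classmethod
    def from_assignment(cls, assignment: Mapping[str, int]) -> "Partition":
        groups: dict[int, set[str]] = {}
        for label, k in assignment.items():
            groups.setdefault(k, set()).add(label)
        return cls(groups.values())

    def to_assignment(self) -> dict[str, int]:
        return {m: i for i, c in enumerate(self.clusters) for m in c}

    @property
    def k(self) -> int:
        return len(self.clusters)

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(m for c in self.clusters for m in c)

    def key(self) -> frozenset[frozenset[str]]:
        return self._key

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self._key == other._key

    def __hash__(self) -> int:
        return hash(self._key)

    def __repr__(self) -> str:
        inner = " | ".join("{" + ",".join(sorted(c)) + "}" for c in self.clusters)
        return f"Partition({inner})"


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the clustering model.

    ``alpha=None`` uses the per-locus symmetric Dirichlet 1/A_l (one
    pseudo-observation spread over the observed alleles); a float fixes
    the same alpha at every locus. ``kmax`` defaults to the number of
    populations. ``exact_pp_limit`` is the largest P for which
    posterior probabilities are normalized over the full partition
    enumeration instead of the search ledger.
    """

    alpha: float | None = None
    kmax: int | None = None
    exact_pp_limit: int = 10

    def __post_init__(self) -> None:
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be positive")


@dataclass
class ClusteringResult:
    """Outcome of a partition search."""

    best: Partition
    log_ml: float                       # natural-log marginal likelihood of best
    posterior_prob: float               # pp of best over the normalization set
    ledger: dict[frozenset[frozenset[str]], float]  # partition key -> log ml
    n_runs: int
    seed: int | None
    pp_mode: str = "ledger"             # "exact" (full enumeration) or "ledger"

    @property
    def max_ledger_log_ml(self) -> float:
        return max(self.ledger.values())


# ---------------------------------------------------------------------------
# Set-partition combinatorics
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def stirling2(n: int, k: int) -> int:
    """Stirling number of the second kind S(n, k) (exact integer)."""
    if k < 0 or k > n:
        return 0
    if n == 0:
        return 1 if k == 0 else 0
    if k == 0:
        return 0
    return k * stirling2(n - 1, k) + stirling2(n - 1, k - 1)


def enumerate_partitions(labels: Sequence[str] | int) -> Iterator[Partition]:
    """Yield every set partition of the labels exactly once (Bell(P) total).

    Accepts either a list of labels or an integer P (labels become
    ``"p1".."pP"``). Guarded at P <= 12.
    """
    if isinstance(labels, int):
        labels = [f"p{i + 1}" for i in range(labels)]
    P = len(labels)
    if P > 12:
        raise ValueError(f"enumeration guarded at P <= 12 (got {P})")
    if P == 0:
        return
    for groups in _rgs_partitions(P):
        yield Partition([[labels[i] for i in g] for g in groups])


def _rgs_partitions(P: int) -> Iterator[list[list[int]]]:
    """Restricted-growth-string enumeration of set partitions of range(P)."""
    a = [0] * P
    b = [0] * P  # b[i] = max(a[:i+1])

    def rec(i: int) -> Iterator[list[list[int]]]:
        if i == P:
            k = b[P - 1] + 1
            groups: list[list[int]] = [[] for _ in range(k)]
            for j, g in enumerate(a):
                groups[g].append(j)
            yield groups
            return
        for v in range(b[i - 1] + 2 if i > 0 else 1):
            a[i] = v
            b[i] = max(b[i - 1], v) if i > 0 else 0
            yield from rec(i + 1)

    yield from rec(0)


def log_partition_prior(P: int, k: int, kmax: int) -> float:
    """log prior of a k-cluster partition under uniform-on-k, uniform within k."""
    if not 1 <= k <= kmax:
        return -math.inf
    return -math.log(kmax) - math.log(stirling2(P, k))


# ---------------------------------------------------------------------------
# Likelihood engine
# ---------------------------------------------------------------------------

class LikelihoodEngine:
    """Caches per-cluster marginal-likelihood terms for one count table.

    The log marginal likelihood of a partition is a sum over clusters
    of a term that depends only on the cluster's member set, so terms
    are cached by member frozenset across the whole search.
    """

    def __init__(self, counts: AlleleCountTable, prior: PriorSpec | None = None):
        prior = prior or PriorSpec()
        self.table = counts
        self.prior = prior
        self.groups = list(counts.groups)
        self.P = len(self.groups)
        self.kmax = prior.kmax if prior.kmax is not None else self.P
        if not 1 <= self.kmax <= self.P:
            raise ValueError("kmax must be in [1, P]")
        self._index = {g: i for i, g in enumerate(self.groups)}

        n_alleles = counts.n_alleles
        keep = n_alleles > 0            # loci with zero observed alleles contribute 0
        self._X = counts.counts.astype(np.float64)
        self._starts = counts.offsets[:-1][keep]
        A = n_alleles[keep].astype(np.float64)
        if prior.alpha is None:
            alpha_locus = 1.0 / A
        else:
            alpha_locus = np.full(A.shape, float(prior.alpha))
        self._a0 = A * alpha_locus                       # A_l * alpha_l
        self._gln_a0 = gammaln(self._a0)
        # per-column alpha; empty loci occupy no registry columns, so this
        # covers every column of the count matrix
        self._alpha_col = np.repeat(alpha_locus, n_alleles[keep].astype(int))
        if self._alpha_col.size != counts.counts.shape[1]:  # pragma: no cover
            raise AssertionError("registry columns inconsistent with allele counts")
        self._gln_alpha_col_sum = float(gammaln(self._alpha_col).sum()) if self._alpha_col.size else 0.0
        self._term_cache: dict[frozenset[int], float] = {}

    # -- terms ---------------------------------------------------------

    def term(self, members: frozenset[int]) -> float:
        """Marginal-likelihood contribution of one cluster (log, nats)."""
        t = self._term_cache.get(members)
        if t is None:
            rows = self._X[list(members)].sum(axis=0) if len(members) > 1 else self._X[next(iter(members))]
            t = self._term_from_counts(rows)
            self._term_cache[members] = t
        return t

    def _term_from_counts(self, m: np.ndarray) -> float:
        if m.size == 0:
            return 0.0
        M = np.add.reduceat(m, self._starts) if self._starts.size else np.empty(0)
        t = float(
            gammaln(self._alpha_col + m).sum()
            - self._gln_alpha_col_sum
            + (self._gln_a0 - gammaln(self._a0 + M)).sum()
        )
        return t

    def members(self, cluster: Iterable[str]) -> frozenset[int]:
        try:
            return frozenset(self._index[g] for g in cluster)
        except KeyError as e:
            raise KeyError(f"population {e.args[0]!r} not in count table") from None

    def log_ml(self, partition: Partition) -> float:
        if partition.labels != frozenset(self.groups):
            raise ValueError("partition must cover exactly the table's groups")
        return sum(self.term(self.members(c)) for c in partition.clusters)

    def log_prior(self, k: int) -> float:
        return log_partition_prior(self.P, k, self.kmax)

    def score(self, partition: Partition) -> float:
        return self.log_ml(partition) + self.log_prior(partition.k)

    # -- exact enumeration ----------------------------------------------

    def enumerate_log_ml(self) -> dict[frozenset[frozenset[str]], float]:
        """log ml of every set partition of the groups (P <= 12 guard)."""
        out: dict[frozenset[frozenset[str]], float] = {}
        labels = self.groups
        for groups in _rgs_partitions(self.P):
            lm = sum(self.term(frozenset(g)) for g in groups)
            key = frozenset(frozenset(labels[i] for i in g) for g in groups)
            out[key] = lm
        return out


def log_marginal_likelihood(
    counts: AlleleCountTable,
    partition: Partition,
    prior: PriorSpec | None = None,
) -> float:
    """Exact Dirichlet-multinomial log marginal likelihood (nats)."""
    return LikelihoodEngine(counts, prior).log_ml(partition)


def posterior_probabilities(
    ledger: Mapping[frozenset[frozenset[str]], float],
    prior: PriorSpec | None = None,
    P: int | None = None,
    kmax: int | None = None,
) -> dict[frozenset[frozenset[str]], float]:
    """Normalized posterior weight of each partition in the ledger.

    pp(S) = exp(logml(S) + logprior(S)) / sum over the ledger, computed
    with log-sum-exp. ``P`` defaults to the label count of the first
    entry, ``kmax`` to P.
    """
    if not ledger:
        raise ValueError("ledger is empty")
    keys = list(ledger)
    if P is None:
        P = sum(len(c) for c in keys[0])
    if kmax is None:
        kmax = (prior.kmax if prior and prior.kmax is not None else None) or P
    logpost = np.array(
        [ledger[k] + log_partition_prior(P, len(k), kmax) for k in keys]
    )
    lse = logsumexp(logpost)
    pps = np.exp(logpost - lse)
    return dict(zip(keys, pps.tolist()))


# ---------------------------------------------------------------------------
# Search
# ---------------------------------------------------------------------------

def search_best_partition(
    counts: AlleleCountTable,
    prior: PriorSpec | None = None,
    n_runs: int = 3,
    seed: int | None = None,
    engine: LikelihoodEngine | None = None,
) -> ClusteringResult:
    """Stochastic search for the maximum-posterior partition.

    Each run starts from singletons, greedily merges the pair of
    clusters giving the largest improvement of log ml + log prior
    (random tie-breaking within 1e-9), then hill-climbs with
    single-population relocations and binary cluster splits until a
    local optimum. All runs' visited partitions are pooled into the
    ledger. Posterior probabilities are exact (full enumeration) when
    P <= prior.exact_pp_limit, otherwise normalized over the ledger.
    Deterministic given ``seed``.
    """
    prior = prior or PriorSpec()
    eng = engine if engine is not None else LikelihoodEngine(counts, prior)
    P = eng.P
    rng = np.random.default_rng(seed)
    ledger: dict[frozenset[frozenset[str]], float] = {}

    best_key: frozenset[frozenset[str]] | None = None
    best_score = -math.inf
    for _ in range(max(1, n_runs)):
        key, score = _single_run(eng, rng, ledger)
        if score > best_score:
            best_score, best_key = score, key

    pp_mode = "ledger"
    if P <= prior.exact_pp_limit:
        ledger = eng.enumerate_log_ml()
        pp_mode = "exact"
        # the enumerated optimum supersedes the search optimum
        best_key = max(
            ledger, key=lambda k: ledger[k] + eng.log_prior(len(k))
        )
        best_score = ledger[best_key] + eng.log_prior(len(best_key))

    assert best_key is not None
    pps = posterior_probabilities(ledger, prior, P=P, kmax=eng.kmax)
    best = Partition(best_key)
    return ClusteringResult(
        best=best,
        log_ml=ledger[best_key],
        posterior_prob=pps[best_key],
        ledger=ledger,
        n_runs=n_runs,
        seed=seed,
        pp_mode=pp_mode,
    )


def _partition_key(
    state: list[frozenset[int]], labels: list[str]
) -> frozenset[frozenset[str]]:
    return frozenset(frozenset(labels[i] for i in c) for c in state)


def _single_run(
    eng: LikelihoodEngine,
    rng: np.random.Generator,
    ledger: dict[frozenset[frozenset[str]], float],
) -> tuple[frozenset[frozenset[str]], float]:
    labels = eng.groups
    P = eng.P
    order = rng.permutation(P)
    state: list[frozenset[int]] = [frozenset([int(i)]) for i in order]
    log_ml = sum(eng.term(c) for c in state)
    ledger.setdefault(_partition_key(state, labels), log_ml)

    def record(candidate_ml: float, st: list[frozenset[int]]) -> None:
        ledger.setdefault(_partition_key(st, labels), candidate_ml)

    # -- greedy agglomeration ------------------------------------------
    while len(state) > 1:
        k = len(state)
        dprior = eng.log_prior(k - 1) - eng.log_prior(k)
        cands: list[tuple[float, int, int, float]] = []
        for i in range(k):
            for j in range(i + 1, k):
                merged = state[i] | state[j]
                dml = eng.term(merged) - eng.term(state[i]) - eng.term(state[j])
                cands.append((dml + dprior, i, j, dml))
                new_state = [c for t, c in enumerate(state) if t not in (i, j)]
                new_state.append(merged)
                record(log_ml + dml, new_state)
        top = max(c[0] for c in cands)
        if top <= 0:
            break
        ties = [c for c in cands if c[0] >= top - _TIE_TOL]
        _, i, j, dml = ties[int(rng.integers(len(ties)))]
        merged = state[i] | state[j]
        state = [c for t, c in enumerate(state) if t not in (i, j)]
        state.append(merged)
        log_ml += dml

    # -- hill climbing: relocations and binary splits -------------------
    improved = True
    while improved:
        improved = False
        best_move: tuple[float, float, list[frozenset[int]]] | None = None

        k = len(state)
        # relocate one population to another cluster or to a new singleton
        for i, src in enumerate(state):
            for p in src:
                rest = src - {p}
                targets: list[int | None] = [j for j in range(k) if j != i]
                if rest:
                    targets.append(None)  # new singleton cluster
                for j in targets:
                    new_state = []
                    dml = -eng.term(src)
                    if rest:
                        dml += eng.term(rest)
                    dk = 0 if rest else -1
                    for t, c in enumerate(state):
                        if t == i:
                            if rest:
                                new_state.append(rest)
                            continue
                        if t == j:
                            dml += eng.term(c | {p}) - eng.term(c)
                            new_state.append(c | {p})
                        else:
                            new_state.append(c)
                    if j is None:
                        new_state.append(frozenset([p]))
                        dml += eng.term(frozenset([p]))
                        dk += 1
                    new_k = k + dk
                    if not 1 <= new_k <= eng.kmax:
                        continue
                    dscore = dml + eng.log_prior(new_k) - eng.log_prior(k)
                    record(log_ml + dml, new_state)
                    if dscore > _TIE_TOL and (
                        best_move is None or dscore > best_move[0]
                    ):
                        best_move = (dscore, dml, new_state)

        # split a cluster by a locally-refined binary reassignment
        if k < eng.kmax:
            dprior = eng.log_prior(k + 1) - eng.log_prior(k)
            for i, src in enumerate(state):
                if len(src) < 2:
                    continue
                half1, half2 = _refine_split(eng, src, rng)
                dml = eng.term(half1) + eng.term(half2) - eng.term(src)
                new_state = [c for t, c in enumerate(state) if t != i]
                new_state.extend([half1, half2])
                record(log_ml + dml, new_state)
                dscore = dml + dprior
                if dscore > _TIE_TOL and (best_move is None or dscore > best_move[0]):
                    best_move = (dscore, dml, new_state)

        if best_move is not None:
            _, dml, state = best_move
            log_ml += dml
            improved = True

    key = _partition_key(state, labels)
    ledger.setdefault(key, log_ml)
    return key, log_ml + eng.log_prior(len(state))


def _refine_split(
    eng: LikelihoodEngine, cluster: frozenset[int], rng: np.random.Generator
) -> tuple[frozenset[int], frozenset[int]]:
    """Best binary split of a cluster by seeded local moves."""
    members = sorted(cluster)
    sides = rng.integers(0, 2, size=len(members))
    if sides.min() == sides.max():
        sides[int(rng.integers(len(members)))] ^= 1
    g1 = {m for m, s in zip(members, sides) if s == 0}
    g2 = set(cluster) - g1

    def val() -> float:
        return eng.term(frozenset(g1)) + eng.term(frozenset(g2))

    current = val()
    moved = True
    while moved:
        moved = False
        for m in members:
            src, dst = (g1, g2) if m in g1 else (g2, g1)
            if len(src) == 1:
                continue
            src.remove(m)
            dst.add(m)
            v = val()
            if v > current + _TIE_TOL:
                current = v
                moved = True
            else:
                dst.remove(m)
                src.add(m)
    return frozenset(g1), frozenset(g2)
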