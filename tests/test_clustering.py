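"""Clustering-engine oracles: exact marginal likelihood, enumeration,
posterior normalization, and search behavior."""

import math

import numpy as np
import pytest

from lineagesort.clustering import (
    LikelihoodEngine,
    Partition,
    PriorSpec,
    enumerate_partitions,
    log_marginal_likelihood,
    log_partition_prior,
    posterior_probabilities,
    search_best_partition,
    stirling2,
)
from lineagesort.io import AlleleCountTable

from conftest import make_count_table, make_structured_table


def chain_rule_log_ml(table: AlleleCountTable, partition: Partition, alpha=None):
    """Independent sequential-predictive oracle for the marginal likelihood.

    Observations arrive one allele at a time; the predictive of the
    next allele a is (alpha + seen_a) / (A*alpha + seen_total). The
    product over any order equals the Dirichlet-multinomial marginal.
    """
    assignment = {}
    for idx, cl in enumerate(partition.clusters):
        for g in cl:
            assignment[g] = idx
    total = 0.0
    for l_idx, locus in enumerate(table.loci):
        codes = table.allele_codes[table.offsets[l_idx]: table.offsets[l_idx + 1]]
        A = len(codes)
        if A == 0:
            continue
        a = (1.0 / A) if alpha is None else alpha
        cnt = table.locus_counts(locus)
        merged: dict[int, np.ndarray] = {}
        for g_idx, g in enumerate(table.groups):
            c = assignment[g]
            merged[c] = merged.get(c, np.zeros(A, dtype=int)) + cnt[g_idx]
        for m in merged.values():
            seen = np.zeros(A)
            tot = 0
            for k in range(A):
                for _ in range(int(m[k])):
                    total += math.log((a + seen[k]) / (A * a + tot))
                    seen[k] += 1
                    tot += 1
    return total


class TestLogMarginalLikelihood:
    def test_hand_gamma_evaluation(self):
        # 1 cluster, 1 locus, 2 alleles, alpha=0.5, counts (1,1):
        # Gamma(1)/Gamma(3) * (Gamma(1.5)/Gamma(0.5))^2 = 1/8
        t = AlleleCountTable(
            groups=["p1"], loci=["m1"],
            allele_codes=np.array([100, 102]),
            offsets=np.array([0, 2]),
            counts=np.array([[1, 1]]),
        )
        v = log_marginal_likelihood(t, Partition([["p1"]]), PriorSpec(alpha=0.5))
        assert v == pytest.approx(math.log(0.125), abs=1e-12)

    def test_empty_table_is_zero(self):
        t = AlleleCountTable(
            groups=["p1", "p2"], loci=["m1"],
            allele_codes=np.empty(0, dtype=int),
            offsets=np.array([0, 0]),
            counts=np.zeros((2, 0), dtype=int),
        )
        assert log_marginal_likelihood(t, Partition([["p1", "p2"]])) == 0.0

    @pytest.mark.parametrize("alpha", [None, 0.5, 1.0])
    def test_matches_chain_rule_oracle(self, rng, alpha):
        for _ in range(10):
            t = make_count_table(rng, n_groups=3, n_loci=3, max_alleles=3, max_count=5)
            for part in enumerate_partitions(t.groups):
                got = log_marginal_likelihood(t, part, PriorSpec(alpha=alpha))
                want = chain_rule_log_ml(t, part, alpha)
                assert got == pytest.approx(want, abs=1e-10)

    def test_invariant_to_relabeling_and_allele_permutation(self, rng):
        t = make_count_table(rng, n_groups=4, n_loci=4, max_alleles=4)
        p1 = Partition([["pop1", "pop3"], ["pop2"], ["pop4"]])
        p2 = Partition([["pop4"], ["pop2"], ["pop3", "pop1"]])
        assert log_marginal_likelihood(t, p1) == log_marginal_likelihood(t, p2)
        # permute allele columns within the first locus
        A = int(t.n_alleles[0])
        perm = np.random.default_rng(1).permutation(A)
        counts2 = t.counts.copy()
        counts2[:, :A] = counts2[:, perm]
        t2 = AlleleCountTable(t.groups, t.loci, t.allele_codes, t.offsets, counts2)
        assert log_marginal_likelihood(t2, p1) == pytest.approx(
            log_marginal_likelihood(t, p1), abs=1e-12
        )


class TestPartitionCombinatorics:
    @pytest.mark.parametrize("P,bell", [(1, 1), (3, 5), (4, 15), (8, 4140)])
    def test_enumeration_count_and_uniqueness(self, P, bell):
        parts = list(enumerate_partitions(P))
        assert len(parts) == bell
        assert len({p.key() for p in parts}) == bell

    def test_guard(self):
        with pytest.raises(ValueError):
            next(enumerate_partitions(13))

    def test_stirling_recurrence_values(self):
        assert stirling2(8, 1) == 1
        assert stirling2(8, 8) == 1
        assert sum(stirling2(8, k) for k in range(1, 9)) == 4140
        assert stirling2(5, 2) == 15

    def test_partition_equality_is_label_free(self):
        a = Partition([["x", "y"], ["z"]])
        b = Partition([["z"], ["y", "x"]])
        assert a == b and hash(a) == hash(b)
        assert a != Partition([["x"], ["y", "z"]])


class TestPosteriorProbabilities:
    def test_degenerate_ledgers(self):
        k1 = frozenset([frozenset(["a", "b"])])
        assert posterior_probabilities({k1: -5.0}) == {k1: 1.0}
        k2 = frozenset([frozenset(["a"]), frozenset(["b"])])
        # equal logml+logprior -> 0.5 each (priors equal: S(2,1)=S(2,2)=1)
        pps = posterior_probabilities({k1: -5.0, k2: -5.0})
        assert pps[k1] == pytest.approx(0.5)
        assert pps[k2] == pytest.approx(0.5)

    def test_full_enumeration_matches_direct_normalization(self, rng):
        t = make_count_table(rng, n_groups=4, n_loci=3, max_alleles=3)
        eng = LikelihoodEngine(t)
        ledger = eng.enumerate_log_ml()
        assert len(ledger) == 15
        pps = posterior_probabilities(ledger, P=4)
        assert sum(pps.values()) == pytest.approx(1.0, abs=1e-12)
        # direct normalization with raw exponentials
        raw = {
            k: math.exp(v + log_partition_prior(4, len(k), 4))
            for k, v in ledger.items()
        }
        Z = sum(raw.values())
        for k in ledger:
            assert pps[k] == pytest.approx(raw[k] / Z, rel=1e-9)


class TestSearch:
    def test_identical_populations_pool_into_one_cluster(self):
        counts = np.tile(np.array([[6, 4, 2]]), (5, 1))
        t = AlleleCountTable(
            groups=[f"p{i}" for i in range(5)], loci=["m1"],
            allele_codes=np.array([100, 102, 104]),
            offsets=np.array([0, 3]),
            counts=counts,
        )
        res = search_best_partition(t, n_runs=3, seed=0)
        assert res.best.k == 1

    def test_deterministic_given_seed(self, rng):
        t = make_structured_table(rng, [[0, 1], [2, 3], [4]])
        a = search_best_partition(t, n_runs=3, seed=9)
        b = search_best_partition(t, n_runs=3, seed=9)
        assert a.best == b.best
        assert a.log_ml == b.log_ml
        assert a.posterior_prob == b.posterior_prob

    def test_recovers_planted_structure(self, rng):
        truth = [[0, 1, 2], [3, 4], [5]]
        t = make_structured_table(rng, truth, n_loci=40, n_per_group=40)
        res = search_best_partition(t, n_runs=3, seed=1)
        want = Partition([["pop1", "pop2", "pop3"], ["pop4", "pop5"], ["pop6"]])
        assert res.best == want
        assert 0 < res.posterior_prob <= 1

    def test_search_matches_enumeration_on_small_fixtures(self, rng):
        # genuine search (ledger mode), enumeration as the independent oracle
        prior = PriorSpec(exact_pp_limit=0)
        hits = 0
        for i in range(20):
            t = make_structured_table(
                rng, [[0, 1], [2], [3, 4, 5]], n_loci=15, n_per_group=25
            )
            eng = LikelihoodEngine(t, prior)
            res = search_best_partition(t, prior, n_runs=3, seed=i, engine=eng)
            best_enum = max(
                enumerate_partitions(t.groups), key=lambda p: eng.score(p)
            )
            hits += res.best == best_enum
        assert hits >= 19

    def test_search_beats_user_partition(self, rng):
        t = make_structured_table(rng, [[0, 1, 2], [3, 4]], n_loci=20)
        prior = PriorSpec(exact_pp_limit=0)
        eng = LikelihoodEngine(t, prior)
        res = search_best_partition(t, prior, n_runs=3, seed=4, engine=eng)
        for cand in (
            Partition([["pop1", "pop2", "pop3", "pop4", "pop5"]]),
            Partition([[p] for p in t.groups]),
            Partition([["pop1"], ["pop2", "pop3"], ["pop4", "pop5"]]),
        ):
            assert eng.score(res.best) >= eng.score(cand) - 1e-9

    def test_exact_mode_below_limit(self, rng):
        t = make_count_table(rng, n_groups=4, n_loci=4)
        res = search_best_partition(t, n_runs=1, seed=0)
        assert res.pp_mode == "exact"
        assert len(res.ledger) == 15
        assert sum(
            posterior_probabilities(res.ledger, P=4).values()
        ) == pytest.approx(1.0)
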