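"""Summary-statistic oracles: gene diversity, F_ST, theta, rarefaction."""

import itertools
import math

import numpy as np
import pytest

from lineagesort.io import GenotypeDataset, allele_counts
from lineagesort.popstats import (
    allele_drop_heterozygosity,
    allelic_richness,
    expected_heterozygosity,
    pairwise_fst,
    theta_estimators,
)

from conftest import make_count_table, make_dataset


class TestExpectedHeterozygosity:
    def test_hand_value_and_monomorphic(self):
        geno = np.array([[[100, 102]], [[100, 102]]])
        ds = GenotypeDataset(["a", "b"], ["p1", "p1"], ["m1"], geno)
        he = expected_heterozygosity(allele_counts(ds))
        assert he.loc["p1", "m1"] == pytest.approx(4 / 3 * 0.5)
        mono = GenotypeDataset(["a", "b"], ["p1", "p1"], ["m1"],
                               np.full((2, 1, 2), 100))
        assert expected_heterozygosity(allele_counts(mono)).loc["p1", "m1"] == 0.0

    def test_undefined_below_two_slots(self):
        geno = np.array([[[100, 0]]])
        ds = GenotypeDataset(["a"], ["p1"], ["m1"], geno)
        assert np.isnan(expected_heterozygosity(allele_counts(ds)).loc["p1", "m1"])

    def test_matches_naive_sum_of_squares(self, rng):
        t = make_count_table(rng, n_groups=3, n_loci=6, max_alleles=5)
        he = expected_heterozygosity(t)
        for g_idx, g in enumerate(t.groups):
            for l in t.loci:
                n = t.locus_counts(l)[g_idx]
                N = n.sum()
                if N < 2:
                    assert np.isnan(he.loc[g, l])
                    continue
                naive = N / (N - 1) * (1 - sum((x / N) ** 2 for x in n))
                assert he.loc[g, l] == pytest.approx(naive, abs=1e-12)


class TestAlleleDrop:
    def test_homozygous_dataset_unchanged(self, rng):
        geno = rng.choice([100, 104], size=(12, 3, 1))
        geno = np.repeat(geno, 2, axis=2)  # every genotype homozygous
        ds = GenotypeDataset(
            [f"i{k}" for k in range(12)], ["p1"] * 12, ["m1", "m2", "m3"], geno
        )
        plain = expected_heterozygosity(allele_counts(ds))
        dropped = allele_drop_heterozygosity(ds, reps=5, seed=1)
        # dropping changes nothing in the allele composition; the two
        # estimators differ only by Nei's N/(N-1) factor at their
        # respective slot counts (N=12 haploidized vs N=24 diploid)
        np.testing.assert_allclose(
            dropped.values * (11 / 12), plain.values * (23 / 24), atol=1e-12
        )

    def test_deterministic_given_seed(self, rng):
        ds = make_dataset(rng, n_pops=2, n_per_pop=6, n_loci=3)
        a = allele_drop_heterozygosity(ds, reps=1, seed=42)
        b = allele_drop_heterozygosity(ds, reps=1, seed=42)
        np.testing.assert_array_equal(a.values, b.values)

    def test_all_heterozygous_matches_binomial_expectation(self):
        # 10 individuals all 100/102: kept copies of allele 100 ~ Bin(10, 1/2);
        # E[He] = E[2X(10-X)]/90 = 0.5 exactly
        geno = np.tile(np.array([100, 102]), (10, 1, 1))
        ds = GenotypeDataset([f"i{k}" for k in range(10)], ["p1"] * 10, ["m1"], geno)
        est = allele_drop_heterozygosity(ds, reps=4000, seed=3).loc["p1", "m1"]
        assert est == pytest.approx(0.5, abs=0.01)


class TestPairwiseFst:
    def test_fixed_difference_gives_one(self):
        geno = np.concatenate([np.full((5, 4, 2), 100), np.full((5, 4, 2), 104)])
        ds = GenotypeDataset(
            [f"i{k}" for k in range(10)], ["p1"] * 5 + ["p2"] * 5,
            [f"m{j}" for j in range(4)], geno,
        )
        fst, _ = pairwise_fst(ds, n_perm=0)
        assert fst.loc["p1", "p2"] == pytest.approx(1.0)

    def test_duplicated_population_near_zero(self, rng):
        half = make_dataset(rng, n_pops=1, n_per_pop=12, n_loci=8)
        geno = np.concatenate([half.genotypes, half.genotypes])
        ds = GenotypeDataset(
            [f"i{k}" for k in range(24)], ["p1"] * 12 + ["p2"] * 12,
            half.loci, geno,
        )
        fst, _ = pairwise_fst(ds, n_perm=0)
        assert fst.loc["p1", "p2"] <= 1e-9  # identical samples: theta <= 0

    def test_matches_scalar_transcription(self, rng):
        # independent per-allele transcription of the 1984 two-sample
        # variance components, scalar arithmetic throughout
        ds = make_dataset(rng, n_pops=2, n_per_pop=8, n_loci=5)
        fst, _ = pairwise_fst(ds, n_perm=0)
        num = den = 0.0
        g = ds.genotypes
        rows = {p: ds.pop_indices(p) for p in ds.pop_labels}
        for j in range(ds.n_loci):
            g1 = g[rows["pop1"], j]
            g2 = g[rows["pop2"], j]
            n1, n2 = len(g1), len(g2)
            nbar = (n1 + n2) / 2
            nc = 2 * nbar - (n1 * n1 + n2 * n2) / (2 * nbar)
            for a in set(g[:, j].ravel()):
                p1 = sum(x == a for row in g1 for x in row) / (2 * n1)
                p2 = sum(x == a for row in g2 for x in row) / (2 * n2)
                h1 = sum(r[0] != r[1] and a in r for r in g1.tolist()) / n1
                h2 = sum(r[0] != r[1] and a in r for r in g2.tolist()) / n2
                pbar = (n1 * p1 + n2 * p2) / (2 * nbar)
                s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
                hbar = (n1 * h1 + n2 * h2) / (2 * nbar)
                inner = pbar * (1 - pbar) - s2 / 2
                A = (nbar / nc) * (s2 - (inner - hbar / 4) / (nbar - 1))
                B = (nbar / (nbar - 1)) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
                num += A
                den += A + B + hbar / 2
        assert fst.loc["pop1", "pop2"] == pytest.approx(num / den, abs=1e-12)

    def test_symmetry_and_pvalues(self, rng):
        ds = make_dataset(rng, n_pops=3, n_per_pop=6, n_loci=4)
        fst, p = pairwise_fst(ds, n_perm=50, seed=5)
        np.testing.assert_allclose(fst.values, fst.values.T)
        assert np.allclose(np.diag(fst.values), 0)
        off = p.values[np.triu_indices(3, k=1)]
        assert ((off > 0) & (off <= 1)).all()

    def test_tiny_population_flagged(self):
        geno = np.full((3, 2, 2), 100)
        ds = GenotypeDataset(["a", "b", "c"], ["p1", "p1", "p2"],
                             ["m1", "m2"], geno)
        fst, _ = pairwise_fst(ds, n_perm=0)
        assert np.isnan(fst.loc["p1", "p2"])


class TestTheta:
    def test_closed_forms(self):
        assert theta_estimators(0.0) == (0.0, 0.0)
        iam, smm = theta_estimators(0.5)
        assert iam == pytest.approx(1.0)
        assert smm == pytest.approx(1.5)
        _, smm1 = theta_estimators(1 - 1 / math.sqrt(3))
        assert smm1 == pytest.approx(1.0, abs=1e-12)

    def test_smm_inversion_round_trips(self):
        he = np.linspace(0.0, 0.95, 30)
        _, smm = theta_estimators(he)
        back = 1 - 1 / np.sqrt(1 + 2 * smm)
        np.testing.assert_allclose(back, he, atol=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            theta_estimators(1.0)

    def test_smm_dominates_iam(self):
        he = np.linspace(0.05, 0.9, 10)
        iam, smm = theta_estimators(he)
        assert (smm > iam).all()
        assert (np.diff(iam) > 0).all() and (np.diff(smm) > 0).all()


class TestAllelicRichness:
    def test_depth_one_and_full_depth(self, rng):
        t = make_count_table(rng, n_groups=2, n_loci=5, max_alleles=4)
        r1 = allelic_richness(t, 1)
        for g_idx, g in enumerate(t.groups):
            for l_idx, l in enumerate(t.loci):
                n = t.locus_counts(l)[g_idx]
                if n.sum() >= 1 and (n > 0).sum() >= 2:
                    assert r1.loc[g, l] == pytest.approx(1.0)

    def test_full_depth_equals_observed_count(self):
        rng = np.random.default_rng(3)
        t = make_count_table(rng, n_groups=1, n_loci=4, max_alleles=4)
        N = t.totals()
        depth = int(N.min())
        r = allelic_richness(t, depth)
        for l_idx, l in enumerate(t.loci):
            if N[0, l_idx] == depth:
                n = t.locus_counts(l)[0]
                assert r.loc[t.groups[0], l] == pytest.approx((n > 0).sum())

    def test_matches_exhaustive_subset_enumeration(self):
        counts = {100: 3, 102: 2, 104: 1}
        pool = [a for a, c in counts.items() for _ in range(c)]
        g = 3
        expect = np.mean(
            [len(set(s)) for s in itertools.combinations(pool, g)]
        )
        geno = np.array([[pool[:2]], [pool[2:4]], [pool[4:]]])
        ds = GenotypeDataset(["a", "b", "c"], ["p1"] * 3, ["m1"], geno)
        r = allelic_richness(allele_counts(ds), g)
        assert r.loc["p1", "m1"] == pytest.approx(expect, abs=1e-12)

    def test_overdeep_flagged(self, rng):
        t = make_count_table(rng, n_groups=1, n_loci=3, max_alleles=2)
        r = allelic_richness(t, int(t.totals().max()) + 1)
        assert r.isna().all().all()
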