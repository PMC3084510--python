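"""Summary statistics for microsatellite data.

Gene diversity (Nei's unbiased expected heterozygosity), the
allele-dropping correction for inbred-line data, pairwise Weir &
Cockerham (1984) F_ST with permutation significance, moment estimators
of theta = 4*N*mu under the infinite-alleles and stepwise mutation
models, and hypergeometric rarefaction of allelic richness.
"""

from __future__ import annotations


import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import MISSING, AlleleCountTable, GenotypeDataset, allele_counts

__all__ = [
    "expected_heterozygosity",
    "allele_drop_heterozygosity",
    "pairwise_fst",
    "mean_pairwise_fst",
    "theta_estimators",
    "allelic_richness",
]


def expected_heterozygosity(counts: AlleleCountTable) -> pd.DataFrame:
    """Nei's unbiased gene diversity per group and locus.

    He = N/(N-1) * (1 - sum_a p_a^2), with p_a = n_a/N. Loci with
    N < 2 in a group are undefined and returned as NaN.
    """
    G, L = counts.n_groups, counts.n_loci
    he = np.full((G, L), np.nan)
    N = counts.totals().astype(float)
    for j in range(L):
        sl = slice(counts.offsets[j], counts.offsets[j + 1])
        n = counts.counts[:, sl].astype(float)
        Nl = N[:, j]
        ok = Nl >= 2
        if ok.any():
            p2 = np.zeros(G)
            p2[ok] = (n[ok] ** 2).sum(axis=1) / Nl[ok] ** 2
            he[ok, j] = Nl[ok] / (Nl[ok] - 1.0) * (1.0 - p2[ok])
    return pd.DataFrame(he, index=counts.groups, columns=counts.loci)


def allele_drop_heterozygosity(
    dataset: GenotypeDataset,
    reps: int = 200,
    seed: int | None = None,
) -> pd.DataFrame:
    """Gene diversity averaged over random haploidized replicates.

    In every replicate one of the two allele slots of each individual
    at each locus is discarded uniformly at random (independently per
    locus), He is computed on the surviving counts, and the mean over
    ``reps`` replicates is returned per population and locus. This
    corrects the upward bias that inbred-line homozygosity imposes on
    diploid allele counts. Deterministic given ``seed``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    n, L = dataset.n_individuals, dataset.n_loci
    pops = dataset.pop_labels
    rows = {p: dataset.pop_indices(p) for p in pops}
    acc = np.zeros((len(pops), L))
    cnt = np.zeros((len(pops), L))
    for _ in range(reps):
        keep = rng.integers(0, 2, size=(n, L))
        kept = np.take_along_axis(dataset.genotypes, keep[:, :, None], axis=2)[:, :, 0]
        for gi, p in enumerate(pops):
            sub = kept[rows[p]]                       # (n_p, L)
            for j in range(L):
                vals = sub[:, j]
                vals = vals[vals != MISSING]
                N = vals.size
                if N >= 2:
                    _, c = np.unique(vals, return_counts=True)
                    he = N / (N - 1.0) * (1.0 - ((c / N) ** 2).sum())
                    acc[gi, j] += he
                    cnt[gi, j] += 1
    with np.errstate(invalid="ignore"):
        out = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return pd.DataFrame(out, index=pops, columns=dataset.loci)


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST
# ---------------------------------------------------------------------------

def _wc_components(
    g1: np.ndarray, g2: np.ndarray
) -> tuple[float, float] | None:
    """Sum of a and of a+b+c over alleles for one locus, two samples.

    ``g1``/``g2`` are (n_i, 2) genotype arrays with complete (non
    missing) genotypes only. Returns None when either sample has
    fewer than 2 complete genotypes.
    """
    n1, n2 = len(g1), len(g2)
    if n1 < 2 or n2 < 2:
        return None
    alleles = np.unique(np.concatenate([g1.ravel(), g2.ravel()]))
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1.0)
    num = 0.0
    den = 0.0
    het1 = g1[:, 0] != g1[:, 1]
    het2 = g2[:, 0] != g2[:, 1]
    for a in alleles:
        p1 = (g1 == a).sum() / (2.0 * n1)
        p2 = (g2 == a).sum() / (2.0 * n2)
        h1 = (het1 & ((g1 == a).any(axis=1))).sum() / n1
        h2 = (het2 & ((g2 == a).any(axis=1))).sum() / n2
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        inner = pbar * (1 - pbar) - (r - 1.0) / r * s2
        a_comp = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b_comp = (nbar / (nbar - 1.0)) * (
            inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c_comp = hbar / 2.0
        num += a_comp
        den += a_comp + b_comp + c_comp
    return num, den


def _pair_theta(
    geno: np.ndarray, rows1: np.ndarray, rows2: np.ndarray
) -> float:
    """Multilocus Weir-Cockerham theta (ratio of sums over loci/alleles)."""
    num = 0.0
    den = 0.0
    L = geno.shape[1]
    for j in range(L):
        g1 = geno[rows1, j, :]
        g2 = geno[rows2, j, :]
        g1 = g1[(g1 != MISSING).all(axis=1)]
        g2 = g2[(g2 != MISSING).all(axis=1)]
        comp = _wc_components(g1, g2)
        if comp is not None:
            num += comp[0]
            den += comp[1]
    if den == 0.0:
        return np.nan
    return num / den


def pairwise_fst(
    dataset: GenotypeDataset,
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Pairwise multilocus Weir & Cockerham theta with permutation tests.

    Returns the symmetric F_ST matrix (diagonal 0; estimates may be
    slightly negative) and, when ``n_perm > 0``, Bonferroni-corrected
    permutation p-values: individuals are shuffled between the two
    populations, p = (b + 1)/(n_perm + 1) with b the count of permuted
    theta >= observed, multiplied by the number of pairs and capped at
    1. Pairs involving a population with fewer than 2 individuals are
    NaN.
    """
    pops = dataset.pop_labels
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    rng = np.random.default_rng(seed)
    P = len(pops)
    fst = np.zeros((P, P))
    pvals = np.full((P, P), np.nan) if n_perm > 0 else None
    n_pairs = P * (P - 1) // 2
    rows = {p: dataset.pop_indices(p) for p in pops}
    for i in range(P):
        for j in range(i + 1, P):
            r1, r2 = rows[pops[i]], rows[pops[j]]
            if len(r1) < 2 or len(r2) < 2:
                fst[i, j] = fst[j, i] = np.nan
                continue
            obs = _pair_theta(dataset.genotypes, r1, r2)
            fst[i, j] = fst[j, i] = obs
            if n_perm > 0 and np.isfinite(obs):
                pool = np.concatenate([r1, r2])
                b = 0
                for _ in range(n_perm):
                    perm = rng.permutation(pool)
                    t = _pair_theta(dataset.genotypes, perm[: len(r1)], perm[len(r1):])
                    if np.isfinite(t) and t >= obs:
                        b += 1
                p = (b + 1) / (n_perm + 1) * n_pairs
                pvals[i, j] = pvals[j, i] = min(p, 1.0)
    fst_df = pd.DataFrame(fst, index=pops, columns=pops)
    p_df = pd.DataFrame(pvals, index=pops, columns=pops) if n_perm > 0 else None
    return fst_df, p_df


def mean_pairwise_fst(dataset: GenotypeDataset) -> float:
    """Mean of the off-diagonal pairwise theta values (no p-values)."""
    fst, _ = pairwise_fst(dataset, n_perm=0)
    vals = fst.values[np.triu_indices(len(fst), k=1)]
    return float(np.nanmean(vals))


# ---------------------------------------------------------------------------
# theta estimators and allelic richness
# ---------------------------------------------------------------------------

def theta_estimators(he: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Moment estimators of theta = 4*N*mu from gene diversity.

    Under the infinite-alleles model theta_IAM = He/(1 - He); under the
    stepwise mutation model theta_SMM = 0.5*[(1/(1 - He))^2 - 1]
    (inverting the SMM equilibrium He = 1 - 1/sqrt(1 + 2*theta)).
    """
    he_arr = np.asarray(he, dtype=float)
    if np.any(he_arr >= 1.0) or np.any(he_arr < 0.0):
        raise ValueError("He must lie in [0, 1)")
    theta_iam = he_arr / (1.0 - he_arr)
    theta_smm = 0.5 * ((1.0 / (1.0 - he_arr)) ** 2 - 1.0)
    if np.isscalar(he):
        return float(theta_iam), float(theta_smm)
    return theta_iam, theta_smm


def allelic_richness(counts: AlleleCountTable, depth: int) -> pd.DataFrame:
    """Rarefied allelic richness per group and locus at sample depth g.

    Hypergeometric rarefaction: sum_a [1 - C(N - n_a, g)/C(N, g)],
    the expected number of distinct alleles in g draws without
    replacement. NaN where g exceeds the observed allele slots N.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    G, L = counts.n_groups, counts.n_loci
    out = np.full((G, L), np.nan)
    N = counts.totals()
    for j in range(L):
        sl = slice(counts.offsets[j], counts.offsets[j + 1])
        n = counts.counts[:, sl]
        for g in range(G):
            Ngl = N[g, j]
            if Ngl < depth or n.shape[1] == 0:
                continue
            na = n[g]
            na = na[na > 0]
            out[g, j] = float(
                np.sum(1.0 - np.exp(_log_comb(Ngl - na, depth) - _log_comb(Ngl, depth)))
            )
    return pd.DataFrame(out, index=counts.groups, columns=counts.loci)


def _log_comb(n: np.ndarray | int, k: int) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    out = np.full(n.shape, -np.inf)
    ok = n >= k
    out[ok] = gammaln(n[ok] + 1) - gammaln(np.asarray(k, float) + 1) - gammaln(n[ok] - k + 1)
    return out
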