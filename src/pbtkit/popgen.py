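"""Population-genetic summaries for biallelic SNP genotype tables.

Implements observed/expected heterozygosity, the Levene-Haldane exact test
for Hardy-Weinberg equilibrium with the heterozygote-excess statistic D,
the Weir-Cockerham (1984) F_ST estimator, and a deterministic genotype PCA.

The exact HWE test conditions on the observed allele counts: given ``n``
diploids carrying ``n_minor`` copies of the minor allele, the heterozygote
count ``h`` has the conditional distribution

    P(h) = n! * n_A! * n_B! * 2^h / [(2n)! * n_AA! * h! * n_BB!]

over counts ``h`` with the parity of ``n_minor``.  The two-sided p-value
sums P(h') over all h' with P(h') <= P(h_obs) (the "selome" convention:
probability of a sample as likely or less likely than the one observed).
"""

from __future__ import annotations

import dataclasses
from math import lgamma, log

import numpy as np

from .data import MISSING

_LOG2 = log(2.0)


def genotype_counts(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus counts of (hom-ref, het, hom-alt) from a code matrix."""
    codes = np.asarray(codes)
    n0 = (codes == 0).sum(axis=0)
    n1 = (codes == 1).sum(axis=0)
    n2 = (codes == 2).sum(axis=0)
    return n0, n1, n2


def allele_frequencies(codes: np.ndarray) -> np.ndarray:
    """Per-locus frequency of the B allele; NaN where no calls."""
    n0, n1, n2 = genotype_counts(codes)
    n = n0 + n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, (n1 + 2 * n2) / (2.0 * n), np.nan)


# ---------------------------------------------------------------------------
# heterozygosity


def heterozygosity(codes: np.ndarray) -> tuple[float, float]:
    """Mean observed and unbiased expected heterozygosity over loci.

    He per locus is Nei's unbiased estimator 2*p*q * 2N/(2N-1); loci with
    fewer than two called genotypes are skipped.
    """
    n0, n1, n2 = genotype_counts(codes)
    n = n0 + n1 + n2
    keep = n >= 2
    if not keep.any():
        raise ValueError("no locus with >=2 called genotypes")
    n = n[keep].astype(float)
    n1 = n1[keep].astype(float)
    p = (n1 + 2 * n2[keep]) / (2 * n)
    ho = n1 / n
    he = 2 * p * (1 - p) * (2 * n) / (2 * n - 1)
    return float(ho.mean()), float(he.mean())


# ---------------------------------------------------------------------------
# exact Hardy-Weinberg test


@dataclasses.dataclass
class HWEResult:
    """Exact HWE test result for one biallelic locus."""

    n_AA: int
    n_AB: int
    n_BB: int
    D: float
    p_value: float

    @property
    def n(self) -> int:
        return self.n_AA + self.n_AB + self.n_BB


def _levene_haldane_pmf(n_minor: int, n_major: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional pmf of the heterozygote count given allele counts.

    Returns (support, probabilities); the support runs over heterozygote
    counts with the parity of ``n_minor``.
    """
    hs = np.arange(n_minor % 2, n_minor + 1, 2)
    n = (n_minor + n_major) // 2
    base = lgamma(n + 1) + lgamma(n_minor + 1) + lgamma(n_major + 1) - lgamma(2 * n + 1)
    logp = np.array(
        [
            base
            + h * _LOG2
            - lgamma((n_major - h) // 2 + 1)
            - lgamma(h + 1)
            - lgamma((n_minor - h) // 2 + 1)
            for h in hs
        ]
    )
    logp -= logp.max()
    p = np.exp(logp)
    return hs, p / p.sum()


def hwe_exact(n_AA: int, n_AB: int, n_BB: int) -> HWEResult:
    """Exact two-sided Hardy-Weinberg test with heterozygote-excess D.

    D is half the deviation of the observed heterozygote count from its
    Hardy-Weinberg expectation at the sample allele frequencies:
    D = (n_AB - 2*p*q*N) / 2.  Positive D is heterozygote excess.
    """
    if min(n_AA, n_AB, n_BB) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_AB + n_BB
    if n < 1:
        raise ValueError("empty sample")
    n_a = 2 * n_AA + n_AB
    n_b = 2 * n_BB + n_AB
    # D from exact fractions of allele counts
    d = (n_AB - n_a * n_b / (2.0 * n)) / 2.0
    if n_a == 0 or n_b == 0:  # monomorphic
        return HWEResult(n_AA, n_AB, n_BB, 0.0, 1.0)
    hs, pmf = _levene_haldane_pmf(min(n_a, n_b), max(n_a, n_b))
    p_obs = pmf[np.searchsorted(hs, n_AB)]
    p_value = float(pmf[pmf <= p_obs * (1 + 1e-12)].sum())
    return HWEResult(n_AA, n_AB, n_BB, float(d), min(p_value, 1.0))


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST


@dataclasses.dataclass
class FstResult:
    """Weir-Cockerham theta-hat between populations.

    ``theta`` is the multilocus ratio-of-sums estimate; per-locus variance
    components a (among populations), b (among individuals within
    populations) and c (within individuals) are retained.
    """

    loci: list[str]
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray

    @property
    def theta(self) -> float:
        den = (self.a + self.b + self.c).sum()
        if den == 0:
            raise ValueError("no variance: theta undefined")
        return float(self.a.sum() / den)

    def per_locus_theta(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.a / (self.a + self.b + self.c)


def pairwise_fst(codes_by_pop: list[np.ndarray], loci: list[str] | None = None) -> FstResult:
    """Weir-Cockerham (1984) theta-hat over two or more populations.

    Parameters
    ----------
    codes_by_pop : list of genotype code matrices (one per population)
        on a shared locus panel.

    Loci monomorphic across all populations (or with no calls somewhere
    needed) contribute no variance components and are excluded.
    """
    r = len(codes_by_pop)
    if r < 2:
        raise ValueError("need >=2 populations")
    n_loci = codes_by_pop[0].shape[1]
    if loci is None:
        loci = [f"L{j}" for j in range(n_loci)]

    # per population x locus: sample size, allele freq, observed het
    n_i = np.zeros((r, n_loci))
    p_i = np.zeros((r, n_loci))
    h_i = np.zeros((r, n_loci))
    for i, codes in enumerate(codes_by_pop):
        n0, n1, n2 = genotype_counts(codes)
        n = (n0 + n1 + n2).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, (n1 + 2 * n2) / (2 * n), np.nan)
            h = np.where(n > 0, n1 / n, np.nan)
        n_i[i], p_i[i], h_i[i] = n, p, h

    valid = (n_i > 0).all(axis=0)
    nbar = n_i.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
        hbar = (n_i * h_i).sum(axis=0) / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        nc = (n_i.sum(axis=0) - (n_i**2).sum(axis=0) / n_i.sum(axis=0)) / (r - 1)

        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2

    poly = valid & ~np.isclose(pbar * (1 - pbar) + s2, 0.0)
    if not poly.any():
        raise ValueError("no polymorphic shared loci")
    keep = np.flatnonzero(poly)
    return FstResult([loci[j] for j in keep], a[keep], b[keep], c[keep])


# ---------------------------------------------------------------------------
# PCA


def pca_genotypes(codes: np.ndarray, n_components: int | None = None) -> np.ndarray:
    """Principal-component scores of a genotype matrix.

    Genotypes are coded 0/1/2 by counted allele; missing values are
    replaced by the locus mean; columns are mean-centred; scores come from
    the SVD.  Component signs are fixed by making each component's
    largest-magnitude loading positive, so the output is deterministic.
    """
    codes = np.asarray(codes)
    if codes.shape[0] < 2:
        raise ValueError("need >=2 samples")
    x = codes.astype(float)
    x[codes == MISSING] = np.nan
    col_mean = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    inds = np.where(np.isnan(x))
    x[inds] = col_mean[inds[1]]
    x -= x.mean(axis=0)
    if np.allclose(x, 0.0):
        k = n_components or min(x.shape)
        return np.zeros((x.shape[0], k))
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    flip = np.sign(vt[np.arange(vt.shape[0]), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    scores = u * s * flip
    if n_components is not None:
        scores = scores[:, :n_components]
    return scores


def subsample_per_group(
    groups: np.ndarray, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Indices of a seeded random subset of up to ``size`` per group.

    Utility for interannual / interprogram F_ST replication on equal-sized
    random subsets (e.g. 300 broodstock per program).
    """
    idx: list[np.ndarray] = []
    for g in np.unique(groups):
        members = np.flatnonzero(groups == g)
        take = min(size, members.size)
        idx.append(rng.choice(members, size=take, replace=False))
    return np.sort(np.concatenate(idx))
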