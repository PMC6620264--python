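"""Population-genetic estimators on genotype matrices.

All functions consume the int8 genotype coding of :mod:`cohortqc.store`
(0/1/2 alt-allele counts, -1 missing). Estimators that need allele
frequencies take them from an explicit reference subset of samples, which
for the QC checks is the study cohort plus the benchmark samples of the
matched population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .store import MISSING

__all__ = [
    "allele_frequencies", "allele_frequency", "sample_missing_rate",
    "sample_missing_rates", "hwe_exact_test", "ld_prune",
    "inbreeding_coefficient", "inbreeding_coefficients", "x_inbreeding",
    "pairwise_ibd", "ibd_mom", "pca", "PairRelatedness", "PCAResult",
    "SampleMetrics",
]


@dataclass
class SampleMetrics:
    sample_id: str
    missing_rate: float = np.nan
    f_autosomal: float = np.nan
    f_x: float = np.nan


@dataclass
class PairRelatedness:
    """Method-of-moments IBD summary for one sample pair.

    kinship = k1/4 + k2/2; pi_hat = k1/2 + k2 (PLINK's proportion IBD,
    kept for comparability with its PI_HAT >= 0.125 convention).
    """

    id_a: str
    id_b: str
    k0: float
    k1: float
    k2: float
    kinship: float
    pi_hat: float
    known_relation: str = "unknown"
    predicted_related: bool = False


@dataclass
class PCAResult:
    eigenvectors: np.ndarray       # n_samples x K, orthonormal columns
    eigenvalues: np.ndarray        # length K, non-increasing, >= 0
    variant_set: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# frequencies and missing rates
# ---------------------------------------------------------------------------

def allele_frequencies(values: np.ndarray,
                       sample_rows=None) -> np.ndarray:
    """Alt-allele frequency per variant over ``sample_rows``.

    Returns NaN for variants with no called genotype in the subset.
    """
    g = values if sample_rows is None else values[sample_rows]
    called = g != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
    return p


def allele_frequency(values: np.ndarray, variant_col: int,
                     sample_rows=None) -> float:
    """Alt-allele frequency of a single variant; raises on all-missing."""
    p = allele_frequencies(values[:, [variant_col]], sample_rows)[0]
    if np.isnan(p):
        raise ValueError(
            f"variant column {variant_col}: all genotypes missing")
    return float(p)


def minor_allele_frequency(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    return np.minimum(p, 1.0 - p)


def sample_missing_rates(values: np.ndarray) -> np.ndarray:
    if values.shape[1] == 0:
        raise ValueError("no variants")
    return (values == MISSING).mean(axis=1)


def sample_missing_rate(values: np.ndarray, sample_row: int) -> float:
    return float(sample_missing_rates(values[[sample_row]])[0])


# ---------------------------------------------------------------------------
# exact Hardy-Weinberg test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test.

    Conditional on the observed allele counts, sums the probabilities of
    every heterozygote count whose probability does not exceed that of
    the observed table. Uses the standard ratio recurrence between
    adjacent heterozygote counts, so no factorials are formed. Returns a
    p-value in (0, 1].
    """
    for c in (n_AA, n_Aa, n_aa):
        if int(c) != c or c < 0:
            raise ValueError("genotype counts must be non-negative integers")
    n_AA, n_Aa, n_aa = int(n_AA), int(n_Aa), int(n_aa)
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotype required")

    n_rare = 2 * min(n_AA, n_aa) + n_Aa          # minor allele copies
    het_max = min(n_rare, 2 * n - n_rare)
    # heterozygote count must share parity with the rare-allele count
    hets = np.arange(n_rare % 2, het_max + 1, 2)
    if len(hets) == 0:                            # monomorphic
        return 1.0

    # unnormalized probabilities via the recurrence
    #   P(h+2)/P(h) = [ (rare-h)(2n-rare-h) ] / [ (h+2)(h+1) ]
    probs = np.empty(len(hets), dtype=float)
    probs[0] = 1.0
    for i in range(1, len(hets)):
        h = hets[i - 1]
        probs[i] = probs[i - 1] * ((n_rare - h) * (2 * n - n_rare - h)
                                   / ((h + 2.0) * (h + 1.0)))
        # rescale on the fly to avoid overflow on large tables
        if probs[i] > 1e250:
            probs /= probs[i]
    probs /= probs.sum()

    obs = np.searchsorted(hets, n_Aa)
    p_obs = probs[obs]
    p = probs[probs <= p_obs * (1.0 + 1e-10)].sum()
    return float(min(1.0, p))


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _pairwise_complete_r2(x, mx, block, mblock) -> np.ndarray:
    """r^2 of one genotype column against a block, each pair computed on
    its jointly-called samples. Degenerate pairs (n<2 or zero variance)
    return 0."""
    xm = np.where(mx, x, 0.0)
    x2m = xm * xm
    bm = np.where(mblock, block, 0.0)
    b2m = bm * bm
    n = mx.astype(float) @ mblock
    sx = xm @ mblock
    sy = mx.astype(float) @ bm
    sxx = x2m @ mblock
    syy = mx.astype(float) @ b2m
    sxy = xm @ bm
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx * sx
        vary = n * syy - sy * sy
        r2 = np.where((n > 1) & (varx > 0) & (vary > 0),
                      (cov * cov) / (varx * vary), 0.0)
    return r2


def ld_prune(values: np.ndarray, chroms, positions, sample_rows=None,
             r2_threshold: float = 0.2, window_bp: int = 500_000,
             seed=None) -> np.ndarray:
    """Greedy positional LD pruning; returns a keep-mask over variants.

    Variants are scanned left to right within each chromosome; a variant
    is removed when its squared genotype correlation (pairwise-complete)
    with any already-kept variant within ``window_bp`` exceeds
    ``r2_threshold``. Fully deterministic given the variant ordering;
    ``seed`` is accepted for interface stability but unused.
    """
    if not (0 < r2_threshold <= 1):
        raise ValueError("r2_threshold must be in (0, 1]")
    g = values if sample_rows is None else values[sample_rows]
    g = g.astype(float)
    mask = np.asarray(values if sample_rows is None
                      else values[sample_rows]) != MISSING
    chroms = np.asarray(chroms)
    positions = np.asarray(positions, dtype=np.int64)
    m = g.shape[1]
    keep = np.zeros(m, dtype=bool)

    for chrom in pd_unique(chroms):
        idx = np.nonzero(chroms == chrom)[0]
        idx = idx[np.argsort(positions[idx], kind="stable")]
        kept: list = []
        for j in idx:
            lo = positions[j] - window_bp
            while kept and positions[kept[0]] < lo:
                kept.pop(0)
            if kept:
                r2 = _pairwise_complete_r2(
                    g[:, j], mask[:, j], g[:, kept], mask[:, kept])
                if (r2 > r2_threshold).any():
                    continue
            kept.append(j)
            keep[j] = True
    return keep


def pd_unique(arr):
    """Unique values in order of first appearance."""
    seen, out = set(), []
    for x in arr:
        if x not in seen:
            seen.add(x)
            out.append(x)
    return out


# ---------------------------------------------------------------------------
# inbreeding coefficient
# ---------------------------------------------------------------------------

def inbreeding_coefficients(values: np.ndarray, sample_rows,
                            variant_cols, p: np.ndarray) -> np.ndarray:
    """Excess-homozygosity inbreeding coefficient per sample.

    F = (O_hom - E_hom) / (m - E_hom) over each sample's non-missing
    variants, with E_hom = sum_i (1 - 2 p_i (1 - p_i)). Variants whose
    reference frequency is 0, 1 or NaN carry no information and are
    excluded. No small-sample frequency correction is applied.
    """
    p = np.asarray(p, dtype=float)
    usable = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    cols = np.asarray(variant_cols)[usable]
    p = p[usable]
    g = values[np.asarray(sample_rows)][:, cols]
    called = g != MISSING
    het_exp = 2.0 * p * (1.0 - p)
    o_hom = (called & (g != 1)).sum(axis=1).astype(float)
    m = called.sum(axis=1).astype(float)
    e_hom = called @ (1.0 - het_exp)
    denom = m - e_hom              # = sum of 2pq over called sites
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(denom > 0, (o_hom - e_hom) / denom, np.nan)
    return f


def inbreeding_coefficient(values: np.ndarray, sample_row: int,
                           variant_cols, p: np.ndarray) -> float:
    f = inbreeding_coefficients(values, [sample_row], variant_cols, p)[0]
    if not np.isfinite(f):
        raise ValueError(
            "inbreeding coefficient undefined: no informative variants "
            "(all frequencies in {0,1} or all genotypes missing)")
    return float(f)


def x_inbreeding(values: np.ndarray, sample_row: int, x_cols,
                 positions, par_intervals, p: np.ndarray,
                 min_variants: int = 50):
    """X-chromosome inbreeding coefficient with PAR sites excluded.

    ``par_intervals`` is a sequence of (start, end) 1-based inclusive
    intervals on X. Returns ``(F, n_usable)``; a warning is emitted when
    fewer than ``min_variants`` usable X variants remain.
    """
    x_cols = np.asarray(x_cols)
    positions = np.asarray(positions, dtype=np.int64)
    non_par = np.ones(len(x_cols), dtype=bool)
    for start, end in par_intervals:
        non_par &= ~((positions >= start) & (positions <= end))
    cols = x_cols[non_par]
    p_sub = np.asarray(p, dtype=float)[non_par]
    usable = int((np.isfinite(p_sub) & (p_sub > 0) & (p_sub < 1)).sum())
    if usable < min_variants:
        warnings.warn(
            f"only {usable} usable non-PAR X variants (<{min_variants}); "
            "sex inference may be unstable", stacklevel=2)
    f = inbreeding_coefficient(values, sample_row, cols, p_sub)
    return f, usable


# ---------------------------------------------------------------------------
# method-of-moments IBD
# ---------------------------------------------------------------------------

def pairwise_ibd(values: np.ndarray, p: np.ndarray,
                 sample_rows=None):
    """PLINK-style method-of-moments IBD for all sample pairs.

    Observed genome-wide identity-by-state class counts are equated with
    their expectations under Hardy-Weinberg given allele frequencies:

        k0 = N(IBS0) / E[IBS0 | IBD0]
        k1 = (N(IBS1) - k0 E[IBS1|IBD0]) / E[IBS1|IBD1]
        k2 = (N(IBS2) - k0 E[IBS2|IBD0] - k1 E[IBS2|IBD1]) / N(called)

    with expectations summed over each pair's jointly-called variants.
    Estimates are truncated to [0,1] and renormalized to the simplex.
    Returns (K0, K1, K2, KIN, VALID) as n x n symmetric matrices,
    where KIN = k1/4 + k2/2 and VALID counts jointly-called variants.
    """
    g = values if sample_rows is None else values[np.asarray(sample_rows)]
    p = np.asarray(p, dtype=float)
    usable = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    g = g[:, usable]
    p = p[usable]
    q = 1.0 - p

    M = (g != MISSING)
    A0 = (g == 0) & M
    A1 = (g == 1) & M
    A2 = (g == 2) & M
    A0f = A0.astype(np.float64)
    A1f = A1.astype(np.float64)
    A2f = A2.astype(np.float64)
    Mf = M.astype(np.float64)

    ibs0 = A0f @ A2f.T
    ibs0 = ibs0 + ibs0.T
    ibs2 = A0f @ A0f.T + A1f @ A1f.T + A2f @ A2f.T
    valid = Mf @ Mf.T
    ibs1 = valid - ibs0 - ibs2

    # per-variant IBS-class expectations conditional on IBD state
    e00 = 2.0 * p**2 * q**2                       # P(IBS0 | IBD0)
    e10 = 4.0 * p**3 * q + 4.0 * p * q**3         # P(IBS1 | IBD0)
    e20 = p**4 + q**4 + 4.0 * p**2 * q**2         # P(IBS2 | IBD0)
    e11 = 2.0 * p**2 * q + 2.0 * p * q**2         # P(IBS1 | IBD1)
    e21 = p**3 + q**3 + p * q                     # P(IBS2 | IBD1)

    E00 = (Mf * e00) @ Mf.T
    E10 = (Mf * e10) @ Mf.T
    E20 = (Mf * e20) @ Mf.T
    E11 = (Mf * e11) @ Mf.T
    E21 = (Mf * e21) @ Mf.T
    # expectation matrices are symmetric only up to missingness pattern;
    # symmetrize to keep pair order irrelevant
    for M_ in (E00, E10, E20, E11, E21):
        M_ += M_.T
        M_ *= 0.5

    with np.errstate(invalid="ignore", divide="ignore"):
        k0 = ibs0 / E00
        k1 = (ibs1 - k0 * E10) / E11
        k2 = (ibs2 - k0 * E20 - k1 * E21) / valid

    k0 = np.clip(k0, 0.0, 1.0)
    k1 = np.clip(k1, 0.0, 1.0)
    k2 = np.clip(k2, 0.0, 1.0)
    total = k0 + k1 + k2
    with np.errstate(invalid="ignore", divide="ignore"):
        k0, k1, k2 = k0 / total, k1 / total, k2 / total
    kin = k1 / 4.0 + k2 / 2.0
    return k0, k1, k2, kin, valid


def ibd_mom(values: np.ndarray, row_a: int, row_b: int,
            variant_cols, p: np.ndarray, id_a: str = "a",
            id_b: str = "b", min_variants: int = 100) -> PairRelatedness:
    """IBD coefficients for a single pair over ``variant_cols``."""
    cols = np.asarray(variant_cols)
    sub = values[np.asarray([row_a, row_b])][:, cols]
    p = np.asarray(p, dtype=float)
    usable = (np.isfinite(p) & (p > 0) & (p < 1)
              & (sub != MISSING).all(axis=0))
    if usable.sum() < min_variants:
        raise ValueError(
            f"only {int(usable.sum())} usable variants for IBD "
            f"(need >= {min_variants}); estimator unstable")
    k0, k1, k2, kin, _ = pairwise_ibd(sub, p)
    k0, k1, k2, kin = (float(k0[0, 1]), float(k1[0, 1]),
                       float(k2[0, 1]), float(kin[0, 1]))
    return PairRelatedness(id_a, id_b, k0, k1, k2, kin,
                           pi_hat=k1 / 2.0 + k2)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(values: np.ndarray, variant_cols, sample_rows=None,
        n_components: int = 4) -> PCAResult:
    """Price-style PCA of the genotype matrix.

    Each variant column is centered by 2p and scaled by sqrt(2p(1-p)),
    with p estimated from the given samples; missing entries are set to
    zero after centering. Eigenvectors of the sample-sample covariance
    are returned with a deterministic sign convention (largest-magnitude
    loading positive).
    """
    rows = (np.arange(values.shape[0]) if sample_rows is None
            else np.asarray(sample_rows))
    cols = np.asarray(variant_cols)
    g = values[rows][:, cols].astype(float)
    called = g != MISSING
    p = allele_frequencies(values[rows][:, cols])
    informative = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    g = g[:, informative]
    called = called[:, informative]
    p = p[informative]

    n, m = g.shape
    if m == 0:
        raise ValueError("no informative variants for PCA")
    k = min(n_components, n, m)
    if k < n_components:
        warnings.warn(
            f"requested {n_components} components, only {k} available",
            stacklevel=2)

    scale = np.sqrt(2.0 * p * (1.0 - p))
    x = np.where(called, (g - 2.0 * p) / scale, 0.0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    evec = u[:, :k]
    eval_ = (s[:k] ** 2) / m
    # deterministic sign: largest |loading| entry positive
    for j in range(k):
        i = int(np.argmax(np.abs(evec[:, j])))
        if evec[i, j] < 0:
            evec[:, j] = -evec[:, j]
    return PCAResult(evec, eval_, list(cols[informative]))
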