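"""Diversity statistics, LD, pruning, PCA and Weir-Cockerham Fst.

Per-SNP observed/expected heterozygosity, per-sample multi-locus
heterozygosity (MLH), pairwise dosage r-squared with distance-binned LD
decay, greedy window LD pruning, dosage-standardised PCA, and the
two-population Weir-Cockerham (1984) Fst variance-component estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genodata import MISSING, GenotypeMatrix

__all__ = [
    "allele_stats",
    "heterozygosity",
    "mlh",
    "diversity_summary",
    "ld_r2",
    "ld_decay",
    "ld_prune",
    "pca",
    "fst_weir_cockerham",
    "FstResult",
    "LDDecayCurve",
]


# ---------------------------------------------------------------------------
# Per-SNP and per-sample statistics
# ---------------------------------------------------------------------------

def allele_stats(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP ALT frequency, MAF and call count.

    Returns a frame with columns ``p`` (ALT frequency), ``maf``,
    ``n_called`` and ``no_calls`` (flag for SNPs with zero calls, whose
    frequencies are NaN rather than an error).
    """
    if gm.n_snps == 0:
        raise ValueError("empty genotype matrix")
    called = gm.calls != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, gm.calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
    return pd.DataFrame({
        "p": p,
        "maf": np.fmin(p, 1.0 - p),
        "n_called": n_called,
        "no_calls": n_called == 0,
    })


def heterozygosity(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP observed (Ho) and expected (He = 2p(1-p)) heterozygosity.

    Zero-call SNPs get NaN and are excluded from downstream summaries.
    With ``unbiased=True`` semantics see :func:`diversity_summary`.
    """
    st = allele_stats(gm)
    called = gm.calls != MISSING
    n_het = (gm.calls == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(st.n_called > 0, n_het / st.n_called, np.nan)
    he = 2.0 * st.p * (1.0 - st.p)
    return pd.DataFrame({"Ho": ho, "He": he, "p": st.p, "maf": st.maf,
                         "n_called": st.n_called})


def mlh(gm: GenotypeMatrix) -> np.ndarray:
    """Per-sample multi-locus heterozygosity (N - O) / N.

    O is the sample's observed homozygote count and N its non-missing SNP
    count; equivalently the heterozygous fraction of non-missing calls.
    """
    called = gm.calls != MISSING
    N = called.sum(axis=1)
    if np.any(N == 0):
        bad = [gm.samples[i] for i in np.flatnonzero(N == 0)]
        raise ValueError(f"samples with no called genotypes: {bad}")
    O = (called & (gm.calls != 1)).sum(axis=1)
    return (N - O) / N


def diversity_summary(
    gm: GenotypeMatrix,
    strata: tuple[float, ...] = (0.0, 0.01, 0.05),
) -> pd.DataFrame:
    """Mean +/- sd of Ho, He, MAF (across SNPs) and MLH (across samples)
    within MAF strata (each cutoff keeps SNPs with MAF >= cutoff).

    Empty strata are reported as absent (dropped rows).
    """
    het = heterozygosity(gm)
    rows = []
    for cutoff in strata:
        keep = (het.maf >= cutoff) & het.Ho.notna()
        if not keep.any():
            continue
        sub = het[keep]
        gm_s = gm.take_snps(np.flatnonzero(keep.values))
        mlh_v = mlh(gm_s)
        rows.append({
            "stratum": f"maf>={cutoff:g}" if cutoff > 0 else "all",
            "n_snps": int(keep.sum()),
            "Ho_mean": sub.Ho.mean(), "Ho_sd": sub.Ho.std(ddof=1) if len(sub) > 1 else 0.0,
            "He_mean": sub.He.mean(), "He_sd": sub.He.std(ddof=1) if len(sub) > 1 else 0.0,
            "MAF_mean": sub.maf.mean(), "MAF_sd": sub.maf.std(ddof=1) if len(sub) > 1 else 0.0,
            "MLH_mean": mlh_v.mean(), "MLH_sd": mlh_v.std(ddof=1) if len(mlh_v) > 1 else 0.0,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_r2(gm: GenotypeMatrix, i: int, j: int) -> float:
    """Squared Pearson correlation of ALT dosages at SNPs i and j over
    samples called at both (composite LD). NaN if either is monomorphic
    in the joint set."""
    a, b = gm.calls[:, i], gm.calls[:, j]
    ok = (a != MISSING) & (b != MISSING)
    return _r2_vec(a[ok].astype(float), b[ok].astype(float))


def _r2_vec(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return np.nan
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class LDDecayCurve:
    """Mean r^2 per physical-distance bin with pair counts."""

    bin_edges: np.ndarray  # bp, length k+1
    mean_r2: np.ndarray    # length k, NaN where no pairs
    n_pairs: np.ndarray    # length k

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "dist_low": self.bin_edges[:-1],
            "dist_high": self.bin_edges[1:],
            "mean_r2": self.mean_r2,
            "n_pairs": self.n_pairs,
        })


def ld_decay(
    gm: GenotypeMatrix,
    max_dist: int = 500_000,
    bin_width: int = 1_000,
    maf_min: float = 0.01,
    max_pairs_per_snp: int | None = None,
) -> LDDecayCurve:
    """Distance-binned mean r^2 over all intra-chromosome SNP pairs
    with separation <= ``max_dist``, using SNPs with MAF >= ``maf_min``.
    """
    from .genodata import MISSING as MISS
    st = allele_stats(gm)
    keep = np.flatnonzero((st.maf >= maf_min) & (st.n_called > 1))
    edges = np.arange(0, max_dist + bin_width, bin_width)
    k = len(edges) - 1
    sums = np.zeros(k)
    counts = np.zeros(k, dtype=np.int64)
    pos = gm.variants.pos
    chrom = gm.variants.chrom
    calls = gm.calls
    for a_idx, i in enumerate(keep):
        upper = np.searchsorted(pos, pos[i] + max_dist, side="right")
        js = keep[(keep > i) & (keep < upper)]
        js = js[chrom[js] == chrom[i]]
        if max_pairs_per_snp is not None:
            js = js[:max_pairs_per_snp]
        for j in js:
            a, b = calls[:, i], calls[:, j]
            ok = (a != MISS) & (b != MISS)
            r2 = _r2_vec(a[ok].astype(float), b[ok].astype(float))
            if np.isnan(r2):
                continue
            bi = min(int((pos[j] - pos[i]) // bin_width), k - 1)
            sums[bi] += r2
            counts[bi] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LDDecayCurve(bin_edges=edges, mean_r2=mean, n_pairs=counts)


def ld_prune(
    gm: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 10,
    r2_max: float = 0.2,
) -> np.ndarray:
    """Greedy sliding-window LD pruning (indep-pairwise style).

    Within each window of ``window_snps`` retained SNPs, while any retained
    pair has r^2 > ``r2_max``, the member with the lower MAF is removed
    (ties: the later position).  Windows advance by ``step_snps``.
    Deterministic; returns the retained SNP indices in order.
    """
    m = gm.n_snps
    st = allele_stats(gm)
    maf = st.maf.values
    keep = np.ones(m, dtype=bool)
    calls = gm.calls
    chrom = gm.variants.chrom

    start = 0
    while start < m:
        win = np.flatnonzero(keep[start:start + window_snps]) + start
        if len(win) > 1:
            win = win[chrom[win] == chrom[win[0]]]
        if len(win) > 1:
            r2m = _pairwise_r2(calls, win)
            alive = np.ones(len(win), dtype=bool)
            while True:
                # first offending pair in deterministic (ai, bi) scan order
                hit = None
                for ai in range(len(win)):
                    if not alive[ai]:
                        continue
                    for bi in range(ai + 1, len(win)):
                        if alive[bi] and r2m[ai, bi] > r2_max:
                            hit = (ai, bi)
                            break
                    if hit:
                        break
                if hit is None:
                    break
                ai, bi = hit
                i, j = win[ai], win[bi]
                # drop the lower-MAF member; ties drop the later position
                drop_local = bi if maf[i] >= maf[j] else ai
                alive[drop_local] = False
                keep[win[drop_local]] = False
        start += step_snps
    return np.flatnonzero(keep)


def _pairwise_r2(calls: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """r^2 matrix for the given SNP columns, pairwise-complete on missing."""
    sub = calls[:, idx].astype(float)
    k = len(idx)
    if not (sub == MISSING).any():
        sd = sub.std(axis=0)
        ok = sd > 0
        r2m = np.full((k, k), np.nan)
        if ok.sum() > 1:
            r = np.corrcoef(sub[:, ok], rowvar=False)
            r2m[np.ix_(ok, ok)] = r * r
        np.fill_diagonal(r2m, np.nan)
        return np.where(np.isnan(r2m), -1.0, r2m)
    r2m = np.full((k, k), -1.0)
    for ai in range(k):
        for bi in range(ai + 1, k):
            a, b = sub[:, ai], sub[:, bi]
            m_ok = (a != MISSING) & (b != MISSING)
            v = _r2_vec(a[m_ok], b[m_ok])
            if not np.isnan(v):
                r2m[ai, bi] = r2m[bi, ai] = v
    return r2m


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(gm: GenotypeMatrix, k: int = 2) -> np.ndarray:
    """Sample coordinates on the leading k genotype principal components.

    Dosages are centered by 2p and scaled by sqrt(2p(1-p)) per SNP
    (zero-variance SNPs dropped, missing imputed at the mean); coordinates
    are the leading eigenvectors of the sample covariance scaled by
    root-eigenvalues.  Per component, the largest-magnitude coordinate is
    made positive.
    """
    if k >= gm.n_samples:
        raise ValueError("k must be smaller than the number of samples")
    st = allele_stats(gm)
    p = st.p.values
    poly = (p > 0) & (p < 1) & ~np.isnan(p)
    X = gm.calls[:, poly].astype(float)
    p = p[poly]
    X[X == MISSING] = np.nan
    mean = 2.0 * p
    sd = np.sqrt(2.0 * p * (1.0 - p))
    X = (X - mean) / sd
    X = np.where(np.isnan(X), 0.0, X)

    u, s, _ = np.linalg.svd(X, full_matrices=False)
    coords = u[:, :k] * s[:k]
    for c in range(k):
        imax = np.argmax(np.abs(coords[:, c]))
        if coords[imax, c] < 0:
            coords[:, c] = -coords[:, c]
    return coords


# ---------------------------------------------------------------------------
# Weir-Cockerham Fst
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    """Per-SNP Weir-Cockerham variance components and genome-wide estimates.

    ``weighted`` is the ratio of sums sum(a)/sum(a+b+c); ``mean_of_ratios``
    averages the per-SNP ratios a/(a+b+c) over informative SNPs.  Negative
    per-SNP components are retained, not clamped.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    informative: np.ndarray  # bool mask of SNPs entering the sums
    weighted: float
    mean_of_ratios: float


def fst_weir_cockerham(gm_a: GenotypeMatrix, gm_b: GenotypeMatrix) -> FstResult:
    """Two-population Weir-Cockerham (1984) theta from genotype matrices
    sharing a variant table.

    Uses per-population sample sizes, allele frequencies and observed
    heterozygote fractions; SNPs monomorphic across both populations (or
    with fewer than 2 calls in either) are excluded from the sums.
    """
    if not np.array_equal(gm_a.variants.pos, gm_b.variants.pos):
        raise ValueError("populations must share a variant table")
    comp = []
    for gm in (gm_a, gm_b):
        called = gm.calls != MISSING
        n = called.sum(axis=0).astype(float)           # diploid individuals called
        alt = np.where(called, gm.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / (2.0 * n), np.nan)
            h = np.where(n > 0, (gm.calls == 1).sum(axis=0) / n, np.nan)
        comp.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = comp

    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)

        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0)
                           / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                     - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0

    poly = np.isfinite(pbar) & (pbar > 0) & (pbar < 1) & (n1 > 1) & (n2 > 1)
    denom = a + b + c
    informative = poly & np.isfinite(denom) & (denom != 0)
    weighted = float(a[informative].sum() / denom[informative].sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = a[informative] / denom[informative]
    mor = float(np.nanmean(ratios)) if informative.any() else np.nan
    return FstResult(a=a, b=b, c=c, informative=informative,
                     weighted=weighted, mean_of_ratios=mor)
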