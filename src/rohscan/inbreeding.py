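"""Genomic inbreeding coefficients: F_ROH, F_HOM, F_GRM, F_UNI.

F_ROH is the fraction of the SNP-covered autosomal genome inside an
individual's ROH segments.  F_HOM is the excess-homozygosity estimate
(O - E)/(L - E).  F_GRM comes from the diagonal of the genomic
relationship matrix and F_UNI from the correlation between uniting
gametes; both follow the standard SNP-by-SNP estimators

    F_GRM = (1/m) * sum_j (x_j - 2 p_j)^2 / (2 p_j (1 - p_j)) - 1
    F_UNI = (1/m) * sum_j (x_j^2 - (1 + 2 p_j) x_j + 2 p_j^2) / (2 p_j (1 - p_j))

with x the ALT dosage and p the cohort ALT frequency.  Allele frequencies
are computed within the analysed cohort; apply per population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genodata import MISSING, GenotypeMatrix
from .roh import ROHSegment

__all__ = [
    "GenomeExtent",
    "genome_extent",
    "f_roh",
    "f_hom",
    "f_grm",
    "f_uni",
    "inbreeding_table",
    "inbreeding_correlations",
]


@dataclass(frozen=True)
class GenomeExtent:
    """Autosomal length covered by SNPs: per chromosome last - first
    position, summed."""

    L_aut: int

    def __post_init__(self) -> None:
        if self.L_aut <= 0:
            raise ValueError("L_aut must be positive")


def genome_extent(gm: GenotypeMatrix) -> GenomeExtent:
    total = 0
    for c in pd.unique(gm.variants.chrom):
        p = gm.variants.pos[gm.variants.chrom == c]
        total += int(p.max() - p.min())
    return GenomeExtent(L_aut=total)


def f_roh(segments_for_sample: list[ROHSegment], extent: GenomeExtent) -> float:
    """Sum of the sample's ROH segment lengths divided by L_aut."""
    return sum(s.length_bp for s in segments_for_sample) / extent.L_aut


def _cohort_freqs(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP cohort ALT frequency p_j and non-missing allele count T_j."""
    called = gm.calls != MISSING
    T = 2.0 * called.sum(axis=0)
    alt = np.where(called, gm.calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(T > 0, alt / T, np.nan)
    return p, T


def f_hom(gm: GenotypeMatrix, sample: str, small_sample_correction: bool = True) -> float:
    """Excess-homozygosity inbreeding coefficient (O - E)/(L - E).

    O: the sample's observed homozygote count; L: its non-missing SNP
    count; E: homozygotes expected by chance, sum over those SNPs of
    1 - 2 p (1 - p) * T/(T - 1) at cohort frequencies (the T/(T-1)
    small-sample correction can be disabled).
    """
    si = gm.samples.index(sample)
    p, T = _cohort_freqs(gm)
    called = gm.calls[si] != MISSING
    usable = called & (T > 1) & np.isfinite(p)
    if usable.sum() < 2:
        raise ValueError(f"sample {sample}: too few usable SNPs")
    x = gm.calls[si, usable]
    pj, Tj = p[usable], T[usable]
    O = int((x != 1).sum())
    L = int(usable.sum())
    corr = Tj / (Tj - 1.0) if small_sample_correction else 1.0
    E = float(np.sum(1.0 - 2.0 * pj * (1.0 - pj) * corr))
    if np.isclose(L, E):
        raise ValueError("degenerate cohort: expected homozygosity equals L")
    return (O - E) / (L - E)


def _poly_mask(gm: GenotypeMatrix, si: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    p, T = _cohort_freqs(gm)
    called = gm.calls[si] != MISSING
    usable = called & np.isfinite(p) & (p > 0) & (p < 1)
    if usable.sum() == 0:
        raise ValueError("no usable polymorphic SNPs for this sample")
    return gm.calls[si, usable].astype(float), p[usable], T[usable]


def f_grm(gm: GenotypeMatrix, sample: str) -> float:
    """Diagonal-GRM inbreeding estimate over the sample's non-missing
    polymorphic SNPs."""
    x, p, _ = _poly_mask(gm, gm.samples.index(sample))
    num = (x - 2.0 * p) ** 2
    den = 2.0 * p * (1.0 - p)
    return float(np.mean(num / den) - 1.0)


def f_uni(gm: GenotypeMatrix, sample: str) -> float:
    """Uniting-gametes correlation inbreeding estimate."""
    x, p, _ = _poly_mask(gm, gm.samples.index(sample))
    num = x ** 2 - (1.0 + 2.0 * p) * x + 2.0 * p ** 2
    den = 2.0 * p * (1.0 - p)
    return float(np.mean(num / den))


def inbreeding_table(
    gm: GenotypeMatrix,
    segments: list[ROHSegment],
    extent: GenomeExtent | None = None,
) -> pd.DataFrame:
    """All four coefficients per sample of one cohort."""
    extent = extent or genome_extent(gm)
    by_sample: dict[str, list[ROHSegment]] = {s: [] for s in gm.samples}
    for seg in segments:
        if seg.sample in by_sample:
            by_sample[seg.sample].append(seg)
    rows = []
    for s in gm.samples:
        rows.append({
            "sample": s,
            "F_ROH": f_roh(by_sample[s], extent),
            "F_HOM": f_hom(gm, s),
            "F_GRM": f_grm(gm, s),
            "F_UNI": f_uni(gm, s),
        })
    return pd.DataFrame(rows)


def inbreeding_correlations(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and two-sided p-values between coefficient pairs.

    Requires >= 3 samples.  Pairs involving a zero-variance coefficient are
    reported as NaN (flagged, not an error).
    """
    coefs = [c for c in ("F_ROH", "F_HOM", "F_GRM", "F_UNI") if c in table.columns]
    if len(table) < 3:
        raise ValueError("need at least 3 samples for correlations")
    k = len(coefs)
    r = pd.DataFrame(np.eye(k), index=coefs, columns=coefs)
    pv = pd.DataFrame(np.zeros((k, k)), index=coefs, columns=coefs)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = table[coefs[i]].values, table[coefs[j]].values
            if np.std(a) == 0 or np.std(b) == 0:
                rij, pij = np.nan, np.nan
            else:
                rij, pij = sps.pearsonr(a, b)
            r.iloc[i, j] = r.iloc[j, i] = rij
            pv.iloc[i, j] = pv.iloc[j, i] = pij
    return r, pv
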