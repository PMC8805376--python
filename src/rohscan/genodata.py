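"""Genotype/haplotype data model, VCF and BED I/O, and marker QC.

Coordinate conventions
----------------------
Variant positions are stored 1-based (as in VCF).  Interval sets are stored
0-based half-open (as in BED).  Conversions happen only at the I/O boundary.

Missing genotypes are encoded as ``MISSING`` (-1), never as dosage 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("rohscan")

MISSING = -1  # sentinel for a missing diploid call

__all__ = [
    "MISSING",
    "VariantTable",
    "GenotypeMatrix",
    "IntervalSet",
    "SampleHetStats",
    "FilterReport",
    "read_vcf",
    "write_vcf",
    "read_intervals",
    "write_intervals",
    "qc_filter",
    "hwe_exact_test",
]


class EmptyInputError(ValueError):
    """Raised when an input yields no usable variants or samples."""


class FormatError(ValueError):
    """Raised on malformed input records."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantTable:
    """Biallelic SNP loci: chromosome, 1-based position, REF/ALT alleles.

    Positions must be strictly increasing within each chromosome.
    """

    chrom: np.ndarray  # str array, shape (m,)
    pos: np.ndarray    # int64, 1-based bp
    ref: np.ndarray    # single-character alleles
    alt: np.ndarray
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = len(self.pos)
        for arr in (self.chrom, self.ref, self.alt):
            if len(arr) != m:
                raise ValueError("variant table columns have unequal lengths")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    def __len__(self) -> int:
        return len(self.pos)

    def take(self, idx: np.ndarray) -> "VariantTable":
        return VariantTable(
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            ids=None if self.ids is None else self.ids[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "pos": self.pos, "ref": self.ref, "alt": self.alt}
        )


@dataclass
class GenotypeMatrix:
    """Samples x variants diploid genotype matrix (ALT-allele dosage).

    ``calls`` holds {0, 1, 2, MISSING}; ``haplotypes`` (n, 2, m) binary is
    present iff every non-missing call in the source data was phased, in
    which case hap sums equal the dosage at every non-missing call.
    """

    variants: VariantTable
    samples: list[str]
    calls: np.ndarray  # int8 (n, m)
    haplotypes: np.ndarray | None = None  # uint8 (n, 2, m)
    population: np.ndarray | None = None  # str per sample

    def __post_init__(self) -> None:
        n, m = self.calls.shape
        if len(self.samples) != n:
            raise ValueError("sample list does not match call matrix")
        if len(self.variants) != m:
            raise ValueError("variant table does not match call matrix")
        if self.haplotypes is not None:
            if self.haplotypes.shape != (n, 2, m):
                raise ValueError("haplotype array has wrong shape")
            hsum = self.haplotypes.sum(axis=1).astype(np.int8)
            ok = (self.calls == MISSING) | (hsum == self.calls)
            if not np.all(ok):
                raise ValueError("haplotype sums disagree with dosages")
        if self.population is not None and len(self.population) != n:
            raise ValueError("population labels do not match samples")

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    @property
    def phased(self) -> bool:
        return self.haplotypes is not None

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            variants=self.variants,
            samples=[self.samples[i] for i in idx],
            calls=self.calls[idx],
            haplotypes=None if self.haplotypes is None else self.haplotypes[idx],
            population=None if self.population is None else self.population[idx],
        )

    def take_snps(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            variants=self.variants.take(idx),
            samples=list(self.samples),
            calls=self.calls[:, idx],
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, :, idx],
            population=self.population,
        )


@dataclass(frozen=True)
class SampleHetStats:
    """Per-sample homozygosity bookkeeping.

    O: observed homozygote count; N: non-missing autosomal SNP count;
    E: homozygotes expected by chance under HWE at cohort frequencies.
    L is the symbol some estimators use for N.
    """

    O: int
    N: int
    E: float

    @property
    def L(self) -> int:
        return self.N


def sample_het_stats(gm: "GenotypeMatrix") -> list[SampleHetStats]:
    """Per-sample O (observed homozygotes), N (non-missing SNPs) and E
    (homozygotes expected by chance at cohort frequencies, with the
    T/(T-1) small-sample correction), for --het style reporting."""
    called = gm.calls != MISSING
    T = 2.0 * called.sum(axis=0)
    alt = np.where(called, gm.calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(T > 0, alt / T, np.nan)
        e_het = 2.0 * p * (1.0 - p) * np.where(T > 1, T / (T - 1.0), np.nan)
    out = []
    for i in range(gm.n_samples):
        usable = called[i] & (T > 1)
        O = int((usable & (gm.calls[i] != 1)).sum())
        N = int(usable.sum())
        E = float(np.sum(1.0 - e_het[usable]))
        out.append(SampleHetStats(O=O, N=N, E=E))
    return out


@dataclass
class IntervalSet:
    """Genomic intervals, 0-based half-open, with an optional name per record."""

    records: pd.DataFrame  # columns: chrom, start, end, name

    COLUMNS = ("chrom", "start", "end", "name")

    @classmethod
    def from_records(cls, recs: Iterable[tuple]) -> "IntervalSet":
        rows = []
        for r in recs:
            chrom, start, end = r[0], int(r[1]), int(r[2])
            name = r[3] if len(r) > 3 else "."
            if start >= end:
                raise FormatError(f"interval start >= end: {chrom}:{start}-{end}")
            rows.append((str(chrom), start, end, str(name)))
        df = pd.DataFrame(rows, columns=list(cls.COLUMNS))
        return cls(df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True))

    @classmethod
    def empty(cls) -> "IntervalSet":
        return cls(pd.DataFrame(columns=list(cls.COLUMNS)))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return self.records.itertuples(index=False)

    def total_length(self) -> int:
        if len(self) == 0:
            return 0
        return int((self.records.end - self.records.start).sum())


@dataclass
class FilterReport:
    """Counts of samples/SNPs removed by each QC criterion."""

    samples_in: int = 0
    samples_removed_call_rate: int = 0
    snps_in: int = 0
    snps_removed_call_rate: int = 0
    snps_removed_hwe: int = 0
    snps_removed_maf: int = 0

    def to_tsv(self) -> str:
        rows = [
            ("samples_in", self.samples_in),
            ("samples_removed_call_rate", self.samples_removed_call_rate),
            ("snps_in", self.snps_in),
            ("snps_removed_call_rate", self.snps_removed_call_rate),
            ("snps_removed_hwe", self.snps_removed_hwe),
            ("snps_removed_maf", self.snps_removed_maf),
        ]
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

_NUCS = frozenset("ACGT")


def read_vcf(path: str | Path, autosomes_only: bool = False) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multi-allelic and non-SNP records are skipped (counted in the log).
    Haplotypes are populated only when every non-missing call in the file
    is phased; a single unphased call disables phase for the whole matrix.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read VCF: {path}")
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    n = len(samples)

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    vids: list[str] = []
    dosages: list[np.ndarray] = []
    haps: list[np.ndarray] = []
    all_phased = True
    n_skipped = 0

    for v in vcf:
        if len(v.ALT) != 1 or v.REF not in _NUCS or v.ALT[0] not in _NUCS:
            n_skipped += 1
            continue
        if autosomes_only and _is_non_autosome(v.CHROM):
            n_skipped += 1
            continue
        g = np.array(v.genotypes, dtype=np.int16)  # (n, 3): a0, a1, phased
        a0, a1, ph = g[:, 0], g[:, 1], g[:, 2]
        miss = (a0 < 0) | (a1 < 0)
        dos = np.where(miss, MISSING, a0 + a1).astype(np.int8)
        if all_phased and n > 0 and not np.all(ph[~miss] == 1):
            all_phased = False
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        vids.append(v.ID or ".")
        dosages.append(dos)
        haps.append(np.where(miss[:, None], 0, np.stack([a0, a1], axis=1)).astype(np.uint8))
    vcf.close()

    if n_skipped:
        logger.info("read_vcf: skipped %d multi-allelic/non-SNP records", n_skipped)
    if not dosages:
        raise EmptyInputError(f"no eligible biallelic SNPs in {path}")

    calls = np.stack(dosages, axis=1)  # (n, m)
    variants = VariantTable(
        chrom=np.array(chroms),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs),
        alt=np.array(alts),
        ids=np.array(vids),
    )
    haplotypes = None
    if all_phased and n > 0:
        haplotypes = np.stack(haps, axis=2)  # (n, 2, m)
    return GenotypeMatrix(variants=variants, samples=samples, calls=calls, haplotypes=haplotypes)


def _is_non_autosome(chrom: str) -> bool:
    c = chrom.removeprefix("chr").upper()
    return c in {"X", "Y", "Z", "W", "M", "MT"}


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as a minimal GT-only VCF 4.2 text file.

    Round-trip safe: ``read_vcf(write_vcf(gm))`` reproduces calls,
    positions and sample order. Phased matrices use the ``|`` separator.
    """
    if gm.n_samples == 0 or gm.n_snps == 0:
        raise EmptyInputError("refusing to write an empty VCF")
    path = Path(path)
    sep = "|" if gm.phased else "/"
    v = gm.variants
    ids = v.ids if v.ids is not None else np.full(len(v), ".")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(v.chrom):
            ln = int(v.pos[v.chrom == c].max()) + 1
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for j in range(gm.n_snps):
            if gm.phased:
                h = gm.haplotypes[:, :, j]
                gts = [f"{h[i, 0]}{sep}{h[i, 1]}" for i in range(gm.n_samples)]
            else:
                lut = {0: f"0{sep}0", 1: f"0{sep}1", 2: f"1{sep}1", MISSING: f".{sep}."}
                gts = [lut[int(x)] for x in gm.calls[:, j]]
            # missing calls always written unphased-style "./."
            col = gm.calls[:, j]
            gts = ["./." if col[i] == MISSING else gts[i] for i in range(gm.n_samples)]
            fh.write(f"{v.chrom[j]}\t{v.pos[j]}\t{ids[j]}\t{v.ref[j]}\t{v.alt[j]}"
                     f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def read_intervals(path: str | Path) -> IntervalSet:
    """Read a BED3/BED4 file (0-based half-open) into an IntervalSet."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read BED: {path}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            rows.append((parts[0], start, end, parts[3] if len(parts) > 3 else "."))
    if not rows:
        return IntervalSet.empty()
    return IntervalSet.from_records(rows)


def write_intervals(iv: IntervalSet, path: str | Path) -> None:
    """Write an IntervalSet as BED4."""
    with open(path, "w") as fh:
        for r in iv:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\n")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one
    (no mid-p correction).  Returns a value in (0, 1].
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no individuals")
    if n == 1:
        return 1.0
    n_rare = 2 * min(n_AA, n_aa) + n_Aa  # rare-allele copies
    # heterozygote counts share parity with the rare-allele total
    het_max = min(n_rare, 2 * n - n_rare)
    hets = list(range(n_rare % 2, het_max + 1, 2))
    # unnormalized probabilities by the standard recurrence, from the mode
    probs = np.zeros(len(hets))
    mid_idx = len(hets) // 2
    probs[mid_idx] = 1.0
    for k in range(mid_idx, len(hets) - 1):
        h = hets[k]
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        # P(h+2)/P(h) = 4*hom_r*hom_c / ((h+2)(h+1))
        probs[k + 1] = probs[k] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
    for k in range(mid_idx, 0, -1):
        h = hets[k]
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        # P(h-2)/P(h) = h(h-1) / (4*(hom_r+1)*(hom_c+1))
        probs[k - 1] = probs[k] * h * (h - 1.0) / (4.0 * (hom_r + 1.0) * (hom_c + 1.0))
    probs /= probs.sum()
    p_obs = probs[hets.index(n_Aa)]
    p = float(probs[probs <= p_obs * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def qc_filter(
    gm: GenotypeMatrix,
    sample_call_rate: float = 0.90,
    snp_call_rate: float = 0.95,
    hwe_p: float = 1e-5,
    maf_min: float = 0.0,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Marker and sample QC in the conventional order.

    Samples with call rate <= ``sample_call_rate`` are removed first; then
    SNPs failing call rate (<= ``snp_call_rate``), the HWE exact test
    (p < ``hwe_p``) or the MAF floor (< ``maf_min``) are removed.  Retained
    row/column order is preserved. Idempotent.
    """
    for t in (sample_call_rate, snp_call_rate, maf_min):
        if not 0.0 <= t <= 1.0:
            raise ValueError("thresholds must lie in [0, 1]")
    report = FilterReport(samples_in=gm.n_samples, snps_in=gm.n_snps)

    called = gm.calls != MISSING
    s_rate = called.mean(axis=1)
    keep_s = s_rate > sample_call_rate
    report.samples_removed_call_rate = int((~keep_s).sum())
    if not keep_s.any():
        raise EmptyInputError("all samples removed by call-rate filter")
    gm = gm.take_samples(np.flatnonzero(keep_s))

    called = gm.calls != MISSING
    v_rate = called.mean(axis=0)
    keep_cr = v_rate > snp_call_rate
    report.snps_removed_call_rate = int((~keep_cr).sum())

    keep_hwe = np.ones(gm.n_snps, dtype=bool)
    if hwe_p > 0:
        for j in np.flatnonzero(keep_cr):
            col = gm.calls[:, j]
            nAA = int((col == 0).sum())
            nAa = int((col == 1).sum())
            naa = int((col == 2).sum())
            if nAA + nAa + naa == 0:
                continue
            if hwe_exact_test(nAA, nAa, naa) < hwe_p:
                keep_hwe[j] = False
    report.snps_removed_hwe = int((keep_cr & ~keep_hwe).sum())

    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0,
                     np.where(gm.calls == MISSING, 0, gm.calls).sum(axis=0) / (2.0 * n_called),
                     np.nan)
    maf = np.fmin(p, 1.0 - p)
    keep_maf = ~(maf < maf_min)  # NaN-MAF SNPs are dropped by call-rate already
    report.snps_removed_maf = int((keep_cr & keep_hwe & ~keep_maf).sum())

    keep = keep_cr & keep_hwe & keep_maf
    if not keep.any():
        raise EmptyInputError("all SNPs removed by QC filters")
    return gm.take_snps(np.flatnonzero(keep)), report
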