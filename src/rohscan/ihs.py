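"""Extended haplotype homozygosity (EHH), integrated EHH (iHH) and the
standardized iHS selection statistic.

EHH at a flanking SNP x, for the carriers of one allele at a focal SNP, is
the probability that two randomly drawn carrier haplotypes are identical
over the whole interval between the focus and x:

    EHH(x) = sum_k C(n_k, 2) / C(n_allele, 2)

where n_k are the sizes of the identical-extended-haplotype groups.  iHH
is the trapezoidal integral of EHH against physical position, truncated
where EHH first falls below a cutoff (default 0.05).  The unstandardized
score ln(iHH_ancestral / iHH_derived) is standardized to mean 0 / sd 1
within derived-allele-frequency bins, and transformed to

    p_iHS = -log10(1 - 2 |Phi(iHS) - 0.5|)

a -log10-scaled two-sided tail quantity; the top fraction of p_iHS
(default 0.1%) is flagged as candidate selection signatures.

The partition-refinement inner loop is JIT-compiled with numba; the
public :func:`ehh` wraps the same kernel, so oracle tests exercise the
one implementation path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import erfc, ndtr

from .genodata import GenotypeMatrix

logger = logging.getLogger("rohscan")

__all__ = ["EHHCurve", "ehh", "ihh", "ihs_scan", "region_ihs_summary", "p_ihs"]


# ---------------------------------------------------------------------------
# EHH kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _ehh_side(haps, focal, carrier_idx, step, cutoff):  # pragma: no cover
    """EHH values at successive flanking SNPs (one side).

    Returns (values, hit_cutoff): values[t] is EHH at the (t+1)-th flanking
    SNP; the walk stops at the first value below ``cutoff``, at EHH == 0,
    or at the chromosome end.
    """
    n = carrier_idx.shape[0]
    m = haps.shape[1]
    denom = 0.5 * n * (n - 1)
    ids = np.zeros(n, dtype=np.int64)
    key = np.empty(n, dtype=np.int64)
    max_steps = focal if step < 0 else m - 1 - focal
    out = np.empty(max_steps, dtype=np.float64)
    cnt = 0
    hit_cutoff = False
    j = focal + step
    while 0 <= j < m:
        for t in range(n):
            key[t] = ids[t] * 2 + haps[carrier_idx[t], j]
        order = np.argsort(key)
        cid = 0
        num = 0.0
        run = 1
        prev = key[order[0]]
        ids[order[0]] = 0
        for t in range(1, n):
            kk = key[order[t]]
            if kk == prev:
                run += 1
            else:
                num += 0.5 * run * (run - 1)
                cid += 1
                run = 1
                prev = kk
            ids[order[t]] = cid
        num += 0.5 * run * (run - 1)
        e = num / denom
        out[cnt] = e
        cnt += 1
        if e < cutoff:
            hit_cutoff = True
            break
        if e == 0.0:
            break
        j += step
    return out[:cnt], hit_cutoff


@dataclass
class EHHCurve:
    """EHH values outward from a focal SNP for one allele and side.

    ``positions``/``values`` start at the focal SNP itself (EHH = 1);
    ``truncated`` is "cutoff" when the walk stopped because EHH fell below
    the cutoff (or reached 0), else "chrom_end".
    """

    focal_idx: int
    allele: int
    side: str
    positions: np.ndarray
    values: np.ndarray
    truncated: str


def ehh(
    haps: np.ndarray,
    positions: np.ndarray,
    focal: int,
    allele: int | str,
    side: str,
    cutoff: float = 0.0,
) -> EHHCurve:
    """EHH curve for the carriers of ``allele`` at ``focal``, one side.

    ``haps`` is (n_haplotypes, n_snps) binary and must be fully phased
    without missing calls; ``allele`` is 0/1 or "ancestral"/"derived";
    ``side`` is "left" or "right".  Requires >= 2 carrier haplotypes.
    """
    al = {"ancestral": 0, "derived": 1}.get(allele, allele)
    if al not in (0, 1):
        raise ValueError(f"allele must be 0/1 or ancestral/derived, got {allele!r}")
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    carriers = np.flatnonzero(haps[:, focal] == al).astype(np.int64)
    if len(carriers) < 2:
        raise ValueError(f"fewer than 2 haplotypes carry allele {al} at SNP {focal}")
    step = -1 if side == "left" else 1
    vals, hit = _ehh_side(np.ascontiguousarray(haps, dtype=np.uint8),
                          focal, carriers, step, cutoff)
    k = len(vals)
    if side == "left":
        flank_pos = positions[focal - k:focal][::-1]
    else:
        flank_pos = positions[focal + 1:focal + 1 + k]
    trunc = "cutoff" if (hit or (k and vals[-1] == 0.0)) else "chrom_end"
    return EHHCurve(
        focal_idx=focal,
        allele=al,
        side=side,
        positions=np.concatenate([[positions[focal]], flank_pos]).astype(np.int64),
        values=np.concatenate([[1.0], vals]),
        truncated=trunc,
    )


def ihh(curve: EHHCurve, cutoff: float = 0.05) -> tuple[float, bool]:
    """One-sided integrated EHH (bp-scaled trapezoid area) and reliability.

    Integration runs outward from the focal SNP and stops at the first
    flanking SNP where EHH < ``cutoff``, including the final interval by
    linear interpolation to the cutoff crossing.  The value is unreliable
    (False) when the curve hits the chromosome end while EHH >= cutoff.
    """
    pos = curve.positions.astype(float)
    e = curve.values
    area = 0.0
    for t in range(1, len(e)):
        gap = abs(pos[t] - pos[t - 1])
        if e[t] < cutoff:
            drop = e[t - 1] - e[t]
            frac = (e[t - 1] - cutoff) / drop if drop > 0 else 0.0
            area += 0.5 * (e[t - 1] + cutoff) * frac * gap
            return area, True
        area += 0.5 * (e[t - 1] + e[t]) * gap
    return area, False  # chromosome end reached with EHH >= cutoff


# ---------------------------------------------------------------------------
# iHS scan
# ---------------------------------------------------------------------------

def p_ihs(z: np.ndarray | float) -> np.ndarray | float:
    """-log10(1 - 2|Phi(z) - 0.5|), the -log10 two-sided Gaussian tail."""
    # 1 - 2|Phi(z) - 0.5| == erfc(|z|/sqrt(2)), computed tail-stably
    return -np.log10(erfc(np.abs(z) / np.sqrt(2.0)))


def ihs_scan(
    gm: GenotypeMatrix,
    region: tuple[str, int, int] | None = None,
    cutoff: float = 0.05,
    maf_min: float = 0.05,
    bin_width: float = 0.025,
    candidate_fraction: float = 0.001,
    min_bin_snps: int = 10,
    ancestral_is_ref: bool = True,
) -> pd.DataFrame:
    """Per-SNP iHS scan over a phased matrix.

    Focal SNPs are those with MAF >= ``maf_min`` (inside ``region`` =
    (chrom, start_bp, end_bp), inclusive, when given).  Per focal SNP the
    ancestral (REF by default) and derived iHH are integrated on both
    sides; SNPs with an unreliable iHH (chromosome-end truncation) are
    excluded and counted.  uniHS = ln(iHH_A/iHH_D) is standardized within
    derived-allele-frequency bins of width ``bin_width`` (bins with fewer
    than ``min_bin_snps`` SNPs are merged with their neighbour); candidates
    are the top ``candidate_fraction`` of p_iHS, ties included.
    """
    if not gm.phased:
        raise ValueError("ihs_scan requires phased haplotypes")
    n, m = gm.n_samples, gm.n_snps
    haps = np.ascontiguousarray(gm.haplotypes.reshape(2 * n, m), dtype=np.uint8)
    pos = gm.variants.pos
    chrom = gm.variants.chrom

    daf = haps.mean(axis=0)  # derived (ALT) allele frequency
    if not ancestral_is_ref:
        daf = 1.0 - daf
    maf = np.minimum(daf, 1.0 - daf)
    focal_ok = maf >= maf_min
    if region is not None:
        rc, rs, re_ = region
        focal_ok &= (chrom == rc) & (pos >= rs) & (pos <= re_)
    focal_idx = np.flatnonzero(focal_ok)

    anc_allele, der_allele = (0, 1) if ancestral_is_ref else (1, 0)
    rows = []
    n_unreliable = 0
    for j in focal_idx:
        rec = {"chrom": chrom[j], "pos": int(pos[j]), "daf": float(daf[j])}
        ok = True
        for name, al in (("A", anc_allele), ("D", der_allele)):
            carriers = np.flatnonzero(haps[:, j] == al).astype(np.int64)
            total = 0.0
            for step, side in ((-1, "left"), (1, "right")):
                vals, hit = _ehh_side(haps, int(j), carriers, step, cutoff)
                curve = _curve_from(vals, hit, int(j), al, side, pos)
                a, reliable = ihh(curve, cutoff)
                if not reliable:
                    ok = False
                total += a
            rec[f"iHH_{name}"] = total
        if not ok or rec["iHH_A"] <= 0 or rec["iHH_D"] <= 0:
            n_unreliable += 1
            continue
        rec["uniHS"] = np.log(rec["iHH_A"] / rec["iHH_D"])
        rows.append(rec)
    if n_unreliable:
        logger.info("ihs_scan: excluded %d SNPs with unreliable iHH", n_unreliable)
    df = pd.DataFrame(rows, columns=["chrom", "pos", "daf", "iHH_A", "iHH_D", "uniHS"])
    if df.empty:
        df["iHS"] = df["p_iHS"] = df["candidate"] = df["freq_bin"] = []
        return df

    df["freq_bin"] = _merged_bins(df.daf.values, bin_width, min_bin_snps)
    grp = df.groupby("freq_bin")["uniHS"]
    mu = grp.transform("mean")
    sd = grp.transform("std")
    df["iHS"] = (df.uniHS - mu) / sd
    df = df[np.isfinite(df.iHS)].reset_index(drop=True)
    df["p_iHS"] = p_ihs(df.iHS.values)

    k = int(np.ceil(candidate_fraction * len(df)))
    thr = np.sort(df.p_iHS.values)[::-1][k - 1]
    df["candidate"] = df.p_iHS >= thr
    return df


def _curve_from(vals: np.ndarray, hit: bool, focal: int, allele: int,
                side: str, positions: np.ndarray) -> EHHCurve:
    k = len(vals)
    if side == "left":
        flank = positions[focal - k:focal][::-1]
    else:
        flank = positions[focal + 1:focal + 1 + k]
    trunc = "cutoff" if (hit or (k and vals[-1] == 0.0)) else "chrom_end"
    return EHHCurve(focal_idx=focal, allele=allele, side=side,
                    positions=np.concatenate([[positions[focal]], flank]).astype(np.int64),
                    values=np.concatenate([[1.0], vals]), truncated=trunc)


def _merged_bins(daf: np.ndarray, bin_width: float, min_bin_snps: int) -> np.ndarray:
    """Assign derived-frequency bins, merging sparse bins with neighbours."""
    raw = np.minimum((daf / bin_width).astype(int), int(1.0 / bin_width) - 1)
    present = np.unique(raw)
    counts = {b: int((raw == b).sum()) for b in present}
    # left-to-right sweep: accumulate consecutive bins until large enough
    mapping: dict[int, int] = {}
    acc: list[int] = []
    acc_n = 0
    merged_id = 0
    for b in present:
        acc.append(b)
        acc_n += counts[b]
        if acc_n >= min_bin_snps:
            for bb in acc:
                mapping[bb] = merged_id
            merged_id += 1
            acc, acc_n = [], 0
    if acc:  # trailing sparse group joins the previous merged bin
        tgt = merged_id - 1 if merged_id > 0 else 0
        for bb in acc:
            mapping[bb] = tgt
        if merged_id == 0:
            merged_id = 1
    n_merged = len(present) - len(set(mapping.values()))
    if n_merged:
        logger.info("ihs_scan: merged %d sparse frequency bins", n_merged)
    return np.array([mapping[b] for b in raw])


def region_ihs_summary(
    records: pd.DataFrame,
    interval: tuple[str, int, int],
) -> dict:
    """Mean |iHS| inside an interval vs. chromosome-wide, plus the top SNP.

    ``interval`` is (chrom, start_bp, end_bp), 1-based inclusive.  Raises
    on an empty region.
    """
    rc, rs, re_ = interval
    on_chrom = records[records.chrom == rc]
    inside = on_chrom[(on_chrom.pos >= rs) & (on_chrom.pos <= re_)]
    if inside.empty:
        raise ValueError(f"no scanned SNPs in region {rc}:{rs}-{re_}")
    top = inside.loc[inside.iHS.abs().idxmax()]
    return {
        "region_mean_abs_ihs": float(inside.iHS.abs().mean()),
        "chrom_mean_abs_ihs": float(on_chrom.iHS.abs().mean()),
        "n_region_snps": int(len(inside)),
        "top_snp_pos": int(top.pos),
        "top_snp_abs_ihs": float(abs(top.iHS)),
        "top_snp_p_ihs": float(top.p_iHS),
    }
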