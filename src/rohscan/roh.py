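"""Scanning-window detection of runs of homozygosity (ROH).

The detector follows the PLINK-style sliding-window parameterization:
windows of ``window_snps`` SNPs are classified homozygous-eligible when
they contain at most ``window_max_het`` heterozygous and
``window_max_missing`` missing calls; a SNP is "in state" when the
fraction of windows covering it that are eligible reaches
``window_threshold``; maximal in-state runs become candidate segments,
which are split at large inter-SNP gaps, trimmed to homozygous
non-missing end calls, and filtered on SNP count, physical length and
mean SNP density.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .genodata import MISSING, GenotypeMatrix

__all__ = ["ROHParams", "ROHSegment", "detect_roh", "classify_roh",
           "segments_to_frame", "summarize_roh"]


@dataclass(frozen=True)
class ROHParams:
    """Sliding-window ROH detection parameters (PLINK-style defaults)."""

    min_snps_in_roh: int = 50
    window_snps: int = 50
    window_max_missing: int = 5
    window_max_het: int = 3
    min_length_kb: float = 300.0
    min_density_kb_per_snp: float = 50.0
    max_gap_kb: float = 1000.0
    window_threshold: float = 0.05

    def __post_init__(self) -> None:
        if min(self.min_snps_in_roh, self.window_snps) <= 0:
            raise ValueError("SNP counts must be positive")
        if not (0.0 < self.window_threshold <= 1.0):
            raise ValueError("window_threshold must lie in (0, 1]")
        if min(self.min_length_kb, self.min_density_kb_per_snp, self.max_gap_kb) <= 0:
            raise ValueError("lengths must be positive")


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous run in one sample.

    ``start_bp``/``end_bp`` are the 1-based positions of the first and last
    SNP of the run (inclusive); length is end - start + 1.
    """

    sample: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def size_class(self) -> str:
        return classify_roh(self)


def classify_roh(segment: ROHSegment) -> str:
    """Size class: short (< 1 Mb), medium (1-3 Mb inclusive), long (> 3 Mb)."""
    mb = segment.length_bp / 1e6
    if mb < 1.0:
        return "short"
    if mb <= 3.0:
        return "medium"
    return "long"


def detect_roh(gm: GenotypeMatrix, params: ROHParams = ROHParams()) -> list[ROHSegment]:
    """Detect ROH segments in every sample of ``gm``.

    Expects the matrix sorted by (chrom, pos) and already filtered to the
    population's eligible SNPs (e.g. MAF >= 0.01).  Chromosomes with fewer
    than ``window_snps`` SNPs are skipped.  Output is deterministic,
    sorted by (sample, chrom, start), and independent of sample order.
    """
    segments: list[ROHSegment] = []
    chrom_order = list(pd.unique(gm.variants.chrom))
    for si, sample in enumerate(gm.samples):
        for c in chrom_order:
            mask = gm.variants.chrom == c
            m = int(mask.sum())
            if m < params.window_snps:
                continue
            pos = gm.variants.pos[mask]
            calls = gm.calls[si, mask]
            segments.extend(
                _detect_one(sample, c, pos, calls, params)
            )
    segments.sort(key=lambda s: (s.sample, s.chrom, s.start_bp))
    return segments


def _detect_one(sample: str, chrom: str, pos: np.ndarray, calls: np.ndarray,
                params: ROHParams) -> list[ROHSegment]:
    m = len(pos)
    w = params.window_snps
    het = (calls == 1).astype(np.int64)
    mis = (calls == MISSING).astype(np.int64)
    csum_het = np.concatenate([[0], np.cumsum(het)])
    csum_mis = np.concatenate([[0], np.cumsum(mis)])
    n_win = m - w + 1
    win_het = csum_het[w:] - csum_het[:-w]
    win_mis = csum_mis[w:] - csum_mis[:-w]
    eligible = (win_het <= params.window_max_het) & (win_mis <= params.window_max_missing)
    csum_elig = np.concatenate([[0], np.cumsum(eligible)])

    # windows covering SNP j start in [max(0, j-w+1), min(j, n_win-1)]
    j = np.arange(m)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(j, n_win - 1)
    n_cover = hi - lo + 1
    n_elig = csum_elig[hi + 1] - csum_elig[lo]
    in_state = n_elig / n_cover >= params.window_threshold

    out: list[ROHSegment] = []
    max_gap_bp = params.max_gap_kb * 1000.0
    # maximal runs of in-state SNPs
    for a, b in _runs(in_state):
        # split at large inter-SNP gaps
        gaps = np.diff(pos[a:b + 1])
        cut = np.flatnonzero(gaps > max_gap_bp)
        starts = np.concatenate([[a], a + cut + 1])
        ends = np.concatenate([a + cut, [b]])
        for s, e in zip(starts, ends):
            seg = _trim_and_filter(sample, chrom, pos, calls, int(s), int(e), params)
            if seg is not None:
                out.append(seg)
    return out


def _runs(mask: np.ndarray):
    """Yield (first, last) index pairs of maximal True runs."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(idx) - 1]])
    for s, e in zip(starts, ends):
        yield int(idx[s]), int(idx[e])


def _trim_and_filter(sample: str, chrom: str, pos: np.ndarray, calls: np.ndarray,
                     s: int, e: int, params: ROHParams) -> ROHSegment | None:
    # trim to homozygous non-missing end calls
    hom = (calls == 0) | (calls == 2)
    while s <= e and not hom[s]:
        s += 1
    while e >= s and not hom[e]:
        e -= 1
    if s > e:
        return None
    n_snps = e - s + 1
    length_bp = int(pos[e] - pos[s] + 1)
    if n_snps < params.min_snps_in_roh:
        return None
    if length_bp < params.min_length_kb * 1000.0:
        return None
    if length_bp / n_snps > params.min_density_kb_per_snp * 1000.0:
        return None
    return ROHSegment(sample=sample, chrom=chrom, start_bp=int(pos[s]),
                      end_bp=int(pos[e]), n_snps=n_snps)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def segments_to_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    rows = [{**asdict(s), "length_bp": s.length_bp, "size_class": s.size_class}
            for s in segments]
    cols = ["sample", "chrom", "start_bp", "end_bp", "n_snps", "length_bp", "size_class"]
    return pd.DataFrame(rows, columns=cols)


def summarize_roh(
    segments: list[ROHSegment],
    samples: list[str],
    populations: dict[str, str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Descriptive ROH summaries.

    Returns per-population totals and per-bird means/sds, per-size-class
    percentages, per-chromosome counts and coverage, and the per-bird
    (count, total length) table with its Pearson correlation.  An empty
    segment list yields all-zero summaries.
    """
    df = segments_to_frame(segments)
    populations = populations or {s: "all" for s in samples}

    per_bird = pd.DataFrame({"sample": samples})
    if len(df):
        agg = df.groupby("sample").agg(n_roh=("length_bp", "size"),
                                       total_len_bp=("length_bp", "sum"))
        per_bird = per_bird.merge(agg, left_on="sample", right_index=True, how="left")
    else:
        per_bird["n_roh"] = 0
        per_bird["total_len_bp"] = 0
    per_bird = per_bird.fillna(0)
    per_bird["population"] = per_bird["sample"].map(populations)
    if len(per_bird) > 2 and per_bird.n_roh.std() > 0 and per_bird.total_len_bp.std() > 0:
        count_length_r = float(np.corrcoef(per_bird.n_roh, per_bird.total_len_bp)[0, 1])
    else:
        count_length_r = np.nan

    pop_rows = []
    for popname, grp in per_bird.groupby("population"):
        pop_rows.append({
            "population": popname,
            "n_birds": len(grp),
            "total_segments": int(grp.n_roh.sum()),
            "mean_count_per_bird": grp.n_roh.mean(),
            "sd_count_per_bird": grp.n_roh.std(ddof=1) if len(grp) > 1 else 0.0,
            "total_length_mb": grp.total_len_bp.sum() / 1e6,
            "mean_length_per_bird_mb": grp.total_len_bp.mean() / 1e6,
            "sd_length_per_bird_mb": (grp.total_len_bp.std(ddof=1) if len(grp) > 1 else 0.0) / 1e6,
            "min_snps": int(df.n_snps.min()) if len(df) else 0,
            "max_snps": int(df.n_snps.max()) if len(df) else 0,
        })

    if len(df):
        cls = df.size_class.value_counts()
        class_pct = pd.DataFrame({
            "size_class": ["short", "medium", "long"],
            "n": [int(cls.get(c, 0)) for c in ("short", "medium", "long")],
        })
        class_pct["pct"] = 100.0 * class_pct.n / class_pct.n.sum()
        per_chrom = df.groupby("chrom").agg(
            n=("length_bp", "size"), covered_bp=("length_bp", "sum")).reset_index()
    else:
        class_pct = pd.DataFrame({"size_class": ["short", "medium", "long"],
                                  "n": [0, 0, 0], "pct": [0.0, 0.0, 0.0]})
        per_chrom = pd.DataFrame(columns=["chrom", "n", "covered_bp"])

    return {
        "per_population": pd.DataFrame(pop_rows),
        "per_class": class_pct,
        "per_chrom": per_chrom,
        "per_bird": per_bird,
        "count_length_r": count_length_r,
    }
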