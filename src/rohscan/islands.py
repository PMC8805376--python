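"""ROH islands: SNP-in-ROH incidence, top-fraction consensus calling,
and interval annotation.

A SNP's incidence is the number of distinct samples with at least one ROH
covering it.  Islands are maximal runs of consecutive SNPs whose incidence
ranks in the top fraction (default 1%, ties at the threshold included);
they are annotated against feature intervals (QTL, genes) by 1-bp-minimum
overlap, and feature sharing across populations is summarised by set
intersection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genodata import GenotypeMatrix, IntervalSet, VariantTable
from .roh import ROHSegment

__all__ = [
    "IncidenceTrack",
    "ROHIsland",
    "snp_roh_incidence",
    "call_islands",
    "islands_to_intervals",
    "annotate_islands",
    "shared_features",
]


@dataclass
class IncidenceTrack:
    """Per-SNP count (and fraction) of samples whose ROH covers the SNP."""

    variants: VariantTable
    count: np.ndarray     # int, per SNP
    n_samples: int

    @property
    def fraction(self) -> np.ndarray:
        return self.count / self.n_samples


@dataclass
class ROHIsland:
    """A merged run of consecutive threshold-qualifying SNPs.

    Coordinates are the first/last member SNP positions, 1-based inclusive.
    """

    chrom: str
    start_bp: int
    end_bp: int
    snp_indices: np.ndarray
    min_incidence: float
    mean_incidence: float
    peak_incidence: float
    population: str = "."


def snp_roh_incidence(
    segments: list[ROHSegment],
    variants: VariantTable,
    n_samples: int,
) -> IncidenceTrack:
    """Count, per SNP, the distinct samples with >= 1 ROH covering it.

    Segment ends are inclusive; overlapping segments of the same sample
    count once.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    m = len(variants)
    count = np.zeros(m, dtype=np.int64)
    by_sample: dict[str, np.ndarray] = {}
    for seg in segments:
        cover = by_sample.setdefault(seg.sample, np.zeros(m, dtype=bool))
        on_chrom = variants.chrom == seg.chrom
        cover |= on_chrom & (variants.pos >= seg.start_bp) & (variants.pos <= seg.end_bp)
        by_sample[seg.sample] = cover
    for cover in by_sample.values():
        count += cover
    return IncidenceTrack(variants=variants, count=count, n_samples=n_samples)


def call_islands(
    track: IncidenceTrack,
    top_fraction: float = 0.01,
    population: str = ".",
) -> list[ROHIsland]:
    """Call consensus islands from the top-``top_fraction`` incidence SNPs.

    The qualifying threshold is the incidence of the ceil(top_fraction*m)-th
    ranked SNP (descending); every SNP at or above it qualifies (ties
    included), except that zero-incidence SNPs never qualify.  Maximal runs
    of consecutive qualifying SNPs on a chromosome become islands.
    """
    m = len(track.count)
    if m == 0:
        raise ValueError("empty incidence track")
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError("top_fraction must lie in (0, 1]")
    if not track.count.any():
        return []
    k = int(np.ceil(top_fraction * m))
    order = np.sort(track.count)[::-1]
    threshold = order[k - 1]
    qualify = (track.count >= threshold) & (track.count > 0)

    islands: list[ROHIsland] = []
    idx = np.flatnonzero(qualify)
    if len(idx) == 0:
        return []
    chrom = track.variants.chrom
    pos = track.variants.pos
    # break runs at non-consecutive indices or chromosome changes
    brk = np.flatnonzero((np.diff(idx) > 1) | (chrom[idx[1:]] != chrom[idx[:-1]]))
    starts = np.concatenate([[0], brk + 1])
    ends = np.concatenate([brk, [len(idx) - 1]])
    for s, e in zip(starts, ends):
        members = idx[s:e + 1]
        inc = track.fraction[members]
        islands.append(ROHIsland(
            chrom=str(chrom[members[0]]),
            start_bp=int(pos[members[0]]),
            end_bp=int(pos[members[-1]]),
            snp_indices=members,
            min_incidence=float(inc.min()),
            mean_incidence=float(inc.mean()),
            peak_incidence=float(inc.max()),
            population=population,
        ))
    islands.sort(key=lambda isl: (isl.chrom, isl.start_bp))
    return islands


def islands_to_intervals(islands: list[ROHIsland]) -> IntervalSet:
    """Islands as a 0-based half-open IntervalSet (BED convention)."""
    if not islands:
        return IntervalSet.empty()
    return IntervalSet.from_records(
        [(i.chrom, i.start_bp - 1, i.end_bp, f"island_{k}")
         for k, i in enumerate(islands)]
    )


def annotate_islands(
    islands: IntervalSet,
    features: IntervalSet,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Report every (island, feature) pair overlapping by >= 1 bp.

    Returns (overlaps, unannotated): the first frame has both records plus
    the overlap length; the second lists islands with no overlapping
    feature.  A chromosome present on only one side triggers a warning.
    """
    from intervaltree import IntervalTree
    import logging

    isl = islands.records
    feat = features.records
    chroms_i = set(isl.chrom.unique()) if len(isl) else set()
    chroms_f = set(feat.chrom.unique()) if len(feat) else set()
    only = chroms_i.symmetric_difference(chroms_f)
    if only:
        logging.getLogger("rohscan").warning(
            "annotate_islands: chromosomes on one side only: %s "
            "(islands per chrom: %s; features per chrom: %s)",
            sorted(only), isl.chrom.value_counts().to_dict() if len(isl) else {},
            feat.chrom.value_counts().to_dict() if len(feat) else {})

    trees: dict[str, IntervalTree] = {}
    for c, grp in (feat.groupby("chrom") if len(feat) else []):
        trees[c] = IntervalTree.from_tuples(
            (r.start, r.end, (r.name, r.start, r.end))
            for r in grp.itertuples(index=False))

    rows, missed = [], []
    for r in (isl.itertuples(index=False) if len(isl) else []):
        hits = trees.get(r.chrom, IntervalTree()).overlap(r.start, r.end)
        if not hits:
            missed.append({"chrom": r.chrom, "start": r.start, "end": r.end,
                           "name": r.name})
            continue
        for h in sorted(hits):
            fname, fs, fe = h.data
            ov = min(r.end, fe) - max(r.start, fs)
            rows.append({
                "island_chrom": r.chrom, "island_start": r.start,
                "island_end": r.end, "island_name": r.name,
                "feature_name": fname, "feature_start": fs, "feature_end": fe,
                "overlap_bp": int(ov),
            })
    overlap_cols = ["island_chrom", "island_start", "island_end", "island_name",
                    "feature_name", "feature_start", "feature_end", "overlap_bp"]
    return (pd.DataFrame(rows, columns=overlap_cols),
            pd.DataFrame(missed, columns=["chrom", "start", "end", "name"]))


def shared_features(per_population_overlaps: dict[str, pd.DataFrame]
                    ) -> tuple[set[str], pd.DataFrame]:
    """Features annotated to islands in every population.

    Returns the full intersection of feature names plus a pairwise sharing
    matrix (counts of features common to each population pair).
    """
    if len(per_population_overlaps) < 2:
        raise ValueError("need at least 2 populations")
    sets = {popname: set(df.feature_name.unique()) if len(df) else set()
            for popname, df in per_population_overlaps.items()}
    pops = list(sets)
    common = set.intersection(*sets.values())
    mat = pd.DataFrame(0, index=pops, columns=pops, dtype=int)
    for a in pops:
        for b in pops:
            mat.loc[a, b] = len(sets[a] & sets[b])
    return common, mat
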