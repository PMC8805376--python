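"""SNP-in-ROH incidence, island calling and interval annotation."""

import numpy as np
import pandas as pd
import pytest

import rohscan as rs
from rohscan.genodata import IntervalSet
from conftest import make_gm
from oracles import incidence_scan, island_merge, quadratic_intersect


def _variants(m, spacing=1000, chrom="1"):
    import rohscan as rs
    pos = np.arange(1, m + 1) * spacing
    return rs.VariantTable(chrom=np.full(m, chrom), pos=pos.astype(np.int64),
                           ref=np.full(m, "A"), alt=np.full(m, "G"))


def _seg(sample, start, end, chrom="1"):
    return rs.ROHSegment(sample=sample, chrom=chrom, start_bp=start, end_bp=end,
                         n_snps=10)


# ---------------------------------------------------------------------------
# incidence
# ---------------------------------------------------------------------------

def test_incidence_single_segment():
    vt = _variants(30)
    segs = [_seg("a", 10_000, 20_000)]
    track = rs.snp_roh_incidence(segs, vt, n_samples=1)
    inside = (vt.pos >= 10_000) & (vt.pos <= 20_000)
    assert (track.count[inside] == 1).all()
    assert (track.count[~inside] == 0).all()


def test_incidence_deduplicates_same_sample():
    vt = _variants(30)
    segs = [_seg("a", 5_000, 15_000), _seg("a", 10_000, 20_000)]
    track = rs.snp_roh_incidence(segs, vt, n_samples=1)
    assert track.count.max() == 1


def test_incidence_matches_brute_force():
    rng = np.random.default_rng(0)
    vt = _variants(300)
    segs = []
    for s in [f"s{i}" for i in range(8)]:
        for _ in range(rng.integers(0, 5)):
            a = int(rng.integers(1, 290_000))
            segs.append(_seg(s, a, a + int(rng.integers(5_000, 60_000))))
    track = rs.snp_roh_incidence(segs, vt, n_samples=8)
    want = incidence_scan([(s.sample, s.chrom, s.start_bp, s.end_bp) for s in segs],
                          list(vt.chrom), list(vt.pos), 8)
    assert list(track.count) == want


# ---------------------------------------------------------------------------
# call_islands
# ---------------------------------------------------------------------------

def _track(counts, chrom=None):
    m = len(counts)
    vt = _variants(m)
    if chrom is not None:
        vt = rs.VariantTable(chrom=np.asarray(chrom), pos=vt.pos,
                             ref=vt.ref, alt=vt.alt)
    from rohscan.islands import IncidenceTrack
    return IncidenceTrack(variants=vt, count=np.asarray(counts, dtype=np.int64),
                          n_samples=max(int(np.max(counts)), 1))


def test_distinct_incidences_top_one_percent():
    counts = np.arange(1, 1001)
    track = _track(counts)
    islands = rs.call_islands(track, top_fraction=0.01)
    n_members = sum(len(i.snp_indices) for i in islands)
    assert n_members == 10  # ceil(0.01 * 1000)
    assert all(counts[j] >= 991 for i in islands for j in i.snp_indices)


def test_uniform_incidence_one_island_per_chromosome():
    chrom = ["1"] * 50 + ["2"] * 50
    track = _track(np.full(100, 7), chrom=chrom)
    islands = rs.call_islands(track, top_fraction=0.01)
    assert len(islands) == 2
    assert {i.chrom for i in islands} == {"1", "2"}


def test_islands_match_threshold_and_merge_oracle():
    rng = np.random.default_rng(1)
    counts = rng.integers(0, 12, size=500)
    chrom = ["1"] * 250 + ["2"] * 250
    track = _track(counts, chrom=chrom)
    for tf in (0.01, 0.05, 0.001):
        islands = rs.call_islands(track, top_fraction=tf)
        thr, want_runs = island_merge(list(counts), chrom, tf)
        got_runs = [(int(i.snp_indices[0]), int(i.snp_indices[-1])) for i in islands]
        assert got_runs == want_runs
        # membership is exactly the qualifying set
        members = {j for i in islands for j in i.snp_indices}
        assert members == {j for j in range(500) if counts[j] >= thr and counts[j] > 0}


def test_lower_top_fraction_never_adds_snps():
    rng = np.random.default_rng(2)
    counts = rng.integers(0, 30, size=400)
    track = _track(counts)
    big = {j for i in rs.call_islands(track, 0.05) for j in i.snp_indices}
    small = {j for i in rs.call_islands(track, 0.01) for j in i.snp_indices}
    assert small <= big


def test_member_incidence_dominates_nonmembers():
    rng = np.random.default_rng(3)
    counts = rng.integers(0, 40, size=600)
    track = _track(counts)
    islands = rs.call_islands(track, 0.01)
    members = {j for i in islands for j in i.snp_indices}
    if members:
        min_member = min(counts[j] for j in members)
        max_nonmember = max((counts[j] for j in range(600) if j not in members), default=0)
        assert min_member >= max_nonmember or min_member == max_nonmember


def test_all_zero_track_empty():
    assert rs.call_islands(_track(np.zeros(50, dtype=int))) == []


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def test_overlap_arithmetic():
    islands = IntervalSet.from_records([("1", 100, 200, "isl")])
    feats = IntervalSet.from_records([("1", 150, 300, "gene")])
    overlaps, missed = rs.annotate_islands(islands, feats)
    assert len(overlaps) == 1 and overlaps.overlap_bp.iloc[0] == 50
    assert len(missed) == 0


def test_touching_half_open_intervals_do_not_overlap():
    islands = IntervalSet.from_records([("1", 100, 200, "isl")])
    feats = IntervalSet.from_records([("1", 200, 300, "gene")])
    overlaps, missed = rs.annotate_islands(islands, feats)
    assert len(overlaps) == 0 and len(missed) == 1


def test_annotation_matches_quadratic_oracle():
    rng = np.random.default_rng(4)

    def random_set(n, tag):
        recs = []
        for k in range(n):
            c = str(rng.integers(1, 4))
            s = int(rng.integers(0, 900_000))
            recs.append((c, s, s + int(rng.integers(1_000, 120_000)), f"{tag}{k}"))
        return IntervalSet.from_records(recs)

    islands, feats = random_set(40, "i"), random_set(60, "f")
    overlaps, missed = rs.annotate_islands(islands, feats)
    want = quadratic_intersect(
        [tuple(r) for r in islands.records.itertuples(index=False)],
        [tuple(r) for r in feats.records.itertuples(index=False)])
    got = set()
    irec = islands.records
    frec = feats.records
    for r in overlaps.itertuples(index=False):
        i = irec[(irec.chrom == r.island_chrom) & (irec.start == r.island_start)
                 & (irec.name == r.island_name)].index[0]
        j = frec[(frec.name == r.feature_name) & (frec.start == r.feature_start)].index[0]
        got.add((int(i), int(j), int(r.overlap_bp)))
    assert got == set(want)
    assert len(missed) == len(islands) - len({i for i, _, _ in want})


# ---------------------------------------------------------------------------
# shared features
# ---------------------------------------------------------------------------

def _ov(names):
    return pd.DataFrame({"feature_name": names})


def test_shared_features_intersection():
    per_pop = {
        "A": _ov(["g1", "g2", "g3"]),
        "B": _ov(["g2", "g3"]),
        "C": _ov(["g3", "g4"]),
    }
    common, mat = rs.shared_features(per_pop)
    assert common == {"g3"}
    assert mat.loc["A", "B"] == 2 and mat.loc["A", "C"] == 1
    assert mat.loc["A", "A"] == 3


def test_shared_features_engineered_common_locus():
    """Three populations with islands built around one shared locus."""
    feats = IntervalSet.from_records([
        ("5", 1_000_000, 1_050_000, "commonGene"),
        ("5", 9_000_000, 9_050_000, "privateA"),
        ("5", 5_000_000, 5_060_000, "privateB"),
    ])
    per_pop = {}
    windows = {"A": [(990_000, 1_060_000), (8_990_000, 9_010_000)],
               "B": [(1_020_000, 1_100_000), (5_010_000, 5_020_000)],
               "C": [(995_000, 1_005_000)]}
    for popname, spans in windows.items():
        isl = IntervalSet.from_records([("5", a, b, f"{popname}{k}")
                                        for k, (a, b) in enumerate(spans)])
        per_pop[popname], _ = rs.annotate_islands(isl, feats)
    common, _ = rs.shared_features(per_pop)
    assert common == {"commonGene"}


def test_shared_features_requires_two_populations():
    with pytest.raises(ValueError):
        rs.shared_features({"A": _ov(["g"])})
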