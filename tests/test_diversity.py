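"""Diversity statistics, LD, pruning, PCA and Fst."""

import numpy as np
import pytest

import rohscan as rs
from rohscan.genodata import MISSING
from rohscan.diversity import _pairwise_r2
from conftest import make_gm
from oracles import wc_components


# ---------------------------------------------------------------------------
# allele_stats / heterozygosity / mlh
# ---------------------------------------------------------------------------

def test_allele_stats_examples():
    gm = make_gm(np.array([[0], [0], [1], [2]]))
    st = rs.allele_stats(gm)
    assert st.p[0] == pytest.approx(0.375)
    assert st.maf[0] == pytest.approx(0.375)

    gm = make_gm(np.array([[0], [0], [0]]))
    assert rs.allele_stats(gm).maf[0] == 0.0

    gm = make_gm(np.array([[2], [2], [MISSING]]))
    st = rs.allele_stats(gm)
    assert st.p[0] == 1.0 and st.n_called[0] == 2


def test_heterozygosity_examples():
    gm = make_gm(np.array([[1], [1], [1], [1]]))
    het = rs.heterozygosity(gm)
    assert het.Ho[0] == 1.0 and het.He[0] == pytest.approx(0.5)

    gm = make_gm(np.array([[0], [2]]))
    het = rs.heterozygosity(gm)
    assert het.Ho[0] == 0.0 and het.He[0] == pytest.approx(0.5)


def test_mlh_formula():
    # 100 SNPs, 70 homozygous, 30 het -> MLH 0.30
    calls = np.concatenate([np.zeros(40), np.full(30, 2), np.ones(30)])
    gm = make_gm(calls[None, :].astype(np.int8))
    assert rs.mlh(gm)[0] == pytest.approx(0.30)
    assert rs.mlh(make_gm(np.zeros((1, 10), dtype=np.int8)))[0] == 0.0
    assert rs.mlh(make_gm(np.ones((1, 10), dtype=np.int8)))[0] == 1.0


def test_mlh_all_missing_errors():
    gm = make_gm(np.full((1, 5), MISSING, dtype=np.int8))
    with pytest.raises(ValueError):
        rs.mlh(gm)


def test_mean_mlh_equals_mean_ho_without_missingness(neutral_panel):
    het = rs.heterozygosity(neutral_panel)
    assert rs.mlh(neutral_panel).mean() == pytest.approx(het.Ho.mean(), abs=1e-12)


def test_diversity_summary_strata(neutral_panel):
    summ = rs.diversity_summary(neutral_panel)
    assert list(summ.stratum) == ["all", "maf>=0.01", "maf>=0.05"]
    # filter contract: the restricted stratum only sees common SNPs
    het = rs.heterozygosity(neutral_panel)
    assert het.maf[het.maf >= 0.05].mean() == pytest.approx(
        summ[summ.stratum == "maf>=0.05"].MAF_mean.iloc[0])
    # rare SNPs depress mean Ho: common-SNP stratum reads higher
    assert (summ[summ.stratum == "maf>=0.05"].Ho_mean.iloc[0]
            >= summ[summ.stratum == "all"].Ho_mean.iloc[0])


def test_single_snp_stratum_sd_zero():
    gm = make_gm(np.array([[1], [1], [0]]))
    summ = rs.diversity_summary(gm, strata=(0.0,))
    assert summ.Ho_sd.iloc[0] == 0.0


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def test_ld_r2_perfect_correlation():
    gm = make_gm(np.array([[0, 0, 2], [2, 2, 0], [0, 0, 2], [2, 2, 0]]))
    assert rs.ld_r2(gm, 0, 1) == pytest.approx(1.0)   # identical columns
    assert rs.ld_r2(gm, 0, 2) == pytest.approx(1.0)   # perfect negative


def test_ld_r2_independent_snps_near_zero():
    rng = np.random.default_rng(0)
    calls = rng.binomial(2, 0.4, size=(1000, 40)).astype(np.int8)
    gm = make_gm(calls)
    vals = [rs.ld_r2(gm, i, j) for i in range(20) for j in range(20, 40)]
    assert np.mean(vals) < 0.01  # null expectation ~ 1/n


def test_ld_decay_equals_brute_force(neutral_panel):
    gm = neutral_panel.take_snps(np.arange(300))
    curve = rs.ld_decay(gm, max_dist=200_000, bin_width=20_000, maf_min=0.01)
    st = rs.allele_stats(gm)
    keep = np.flatnonzero((st.maf >= 0.01).values)
    pos = gm.variants.pos
    sums = np.zeros(10)
    counts = np.zeros(10)
    for a in range(len(keep)):
        for b in range(a + 1, len(keep)):
            i, j = keep[a], keep[b]
            d = pos[j] - pos[i]
            if d > 200_000:
                continue
            r2 = rs.ld_r2(gm, i, j)
            if np.isnan(r2):
                continue
            bi = min(int(d // 20_000), 9)
            sums[bi] += r2
            counts[bi] += 1
    assert np.array_equal(counts, curve.n_pairs)
    want = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    np.testing.assert_allclose(curve.mean_r2, want, atol=1e-12)


def test_ld_decay_empty_when_no_pairs(neutral_panel):
    curve = rs.ld_decay(neutral_panel, max_dist=1, bin_width=1)
    assert curve.n_pairs.sum() == 0


def test_ld_prune_duplicate_column():
    rng = np.random.default_rng(1)
    col = rng.binomial(2, 0.5, size=50).astype(np.int8)
    other = rng.binomial(2, 0.5, size=(50, 3)).astype(np.int8)
    calls = np.column_stack([col, col, other])
    gm = make_gm(calls)
    kept = rs.ld_prune(gm, window_snps=5, step_snps=2, r2_max=0.2)
    assert int(np.isin([0, 1], kept).sum()) == 1


def test_ld_prune_identity_when_independent():
    rng = np.random.default_rng(2)
    calls = rng.binomial(2, 0.5, size=(500, 30)).astype(np.int8)
    gm = make_gm(calls)
    kept = rs.ld_prune(gm, window_snps=10, step_snps=5, r2_max=0.2)
    assert len(kept) == 30


def test_ld_prune_postcondition_oracle(neutral_panel):
    """After pruning, no surviving pair inside any sliding window exceeds
    the r^2 ceiling."""
    gm = neutral_panel.take_snps(np.arange(100))
    window, step, r2_max = 20, 5, 0.2
    kept = rs.ld_prune(gm, window_snps=window, step_snps=step, r2_max=r2_max)
    kept_set = set(kept.tolist())
    for start in range(0, gm.n_snps, step):
        win = [j for j in range(start, min(start + window, gm.n_snps)) if j in kept_set]
        for a in range(len(win)):
            for b in range(a + 1, len(win)):
                r2 = rs.ld_r2(gm, win[a], win[b])
                assert np.isnan(r2) or r2 <= r2_max


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_separates_diverged_populations():
    rng = np.random.default_rng(3)
    base = np.clip(rng.beta(0.5, 0.5, 3000), 0.05, 0.95)
    a, b = rs.split_populations(base, 0.10, (25, 25), rs.SimConfig(seed=13))
    merged = rs.GenotypeMatrix(
        variants=a.variants, samples=a.samples + b.samples,
        calls=np.vstack([a.calls, b.calls]))
    coords = rs.pca(merged, k=2)
    pc1 = coords[:, 0]
    from sklearn.metrics import silhouette_score
    labels = [0] * 25 + [1] * 25
    assert silhouette_score(pc1[:, None], labels) > 0.5


def test_pca_duplicated_sample_identical_coords(neutral_panel):
    gm = neutral_panel.take_samples(np.array([0, 0, 1, 2, 3]))
    coords = rs.pca(gm, k=2)
    np.testing.assert_allclose(coords[0], coords[1], atol=1e-8)


def test_pca_two_samples_symmetric():
    rng = np.random.default_rng(4)
    calls = rng.binomial(2, 0.5, size=(2, 200)).astype(np.int8)
    coords = rs.pca(make_gm(calls), k=1)
    assert coords[0, 0] == pytest.approx(-coords[1, 0], abs=1e-10)


def test_pca_k_too_large(neutral_panel):
    with pytest.raises(ValueError):
        rs.pca(neutral_panel, k=neutral_panel.n_samples)


# ---------------------------------------------------------------------------
# Fst
# ---------------------------------------------------------------------------

def test_fst_fixed_difference_is_one():
    a = make_gm(np.full((10, 5), 2, dtype=np.int8))
    b = make_gm(np.zeros((10, 5), dtype=np.int8))
    res = rs.fst_weir_cockerham(a, b)
    assert res.weighted == pytest.approx(1.0)


def test_fst_identical_populations_nonpositive(neutral_panel):
    res = rs.fst_weir_cockerham(neutral_panel, neutral_panel)
    assert res.weighted <= 1e-12


def test_fst_matches_scalar_component_oracle():
    rng = np.random.default_rng(5)
    calls_a = rng.binomial(2, rng.uniform(0.1, 0.9, 40), size=(12, 40)).astype(np.int8)
    calls_b = rng.binomial(2, rng.uniform(0.1, 0.9, 40), size=(15, 40)).astype(np.int8)
    calls_a[rng.random(calls_a.shape) < 0.05] = MISSING
    a, b = make_gm(calls_a), make_gm(calls_b)
    res = rs.fst_weir_cockerham(a, b)
    num = den = 0.0
    for j in range(40):
        comp = wc_components(calls_a, calls_b, j)
        if comp is None:
            assert not res.informative[j]
            continue
        aa, bb, cc = comp
        assert res.a[j] == pytest.approx(aa, abs=1e-10)
        assert res.b[j] == pytest.approx(bb, abs=1e-10)
        assert res.c[j] == pytest.approx(cc, abs=1e-10)
        num += aa
        den += aa + bb + cc
    assert res.weighted == pytest.approx(num / den, abs=1e-10)


def test_fst_weighted_identity():
    rng = np.random.default_rng(6)
    a = make_gm(rng.binomial(2, 0.3, size=(10, 30)).astype(np.int8))
    b = make_gm(rng.binomial(2, 0.6, size=(10, 30)).astype(np.int8))
    res = rs.fst_weir_cockerham(a, b)
    inf = res.informative
    assert res.weighted == pytest.approx(
        res.a[inf].sum() / (res.a + res.b + res.c)[inf].sum(), abs=1e-12)
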