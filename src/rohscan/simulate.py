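"""Synthetic phased genotype data with known truth.

The generator emulates the data regime of a dense re-sequencing study of
small village-flock populations: 10-50 diploid individuals per population,
~1 SNP per 1-10 kb, a U-shaped allele-frequency spectrum, and local LD
produced by a founder-mosaic copying model.  On top of the neutral panel,
truth can be planted: autozygous tracts (two identical haplotypes over an
interval), a partial selective sweep (one core haplotype shared by a
fraction of chromosomes around a focal SNP), and two-population divergence
under the Balding-Nichols model at a target Fst.

All generators are pure functions of (inputs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genodata import MISSING, GenotypeMatrix, IntervalSet, VariantTable

__all__ = [
    "SimConfig",
    "TruthSet",
    "simulate_neutral",
    "plant_autozygosity",
    "plant_sweep",
    "split_populations",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the neutral founder-mosaic simulation.

    ``switch_rate`` is the per-bp probability that a sample haplotype
    switches to a new random founder, so segments copied from one founder
    have exponentially distributed lengths with mean 1/switch_rate; this is
    what induces distance-decaying LD.  The allele-frequency spectrum is
    Beta(freq_alpha, freq_beta) truncated to [freq_min, 1-freq_min]; the
    default Beta(0.2, 0.2) gives a U-shaped spectrum with mean MAF near
    0.11-0.13, the regime of dense re-sequencing panels.
    """

    n_samples: int = 25
    n_snps: int = 20_000
    chrom_length_bp: int = 100_000_000
    chrom: str = "1"
    n_founder_haplotypes: int = 40
    freq_alpha: float = 0.2
    freq_beta: float = 0.2
    freq_min: float = 0.01
    switch_rate: float = 1e-5
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_snps, self.chrom_length_bp) <= 0:
            raise ValueError("counts must be positive")
        if self.n_founder_haplotypes < 2:
            raise ValueError("need at least 2 founder haplotypes")
        if not (0.0 <= self.missing_rate <= 1.0) or self.switch_rate < 0:
            raise ValueError("rates must lie in [0, 1]")


@dataclass
class TruthSet:
    """Planted truth accompanying a simulated matrix."""

    planted_tracts: dict[str, IntervalSet] = field(default_factory=dict)
    sweep_focal_bp: int | None = None
    sweep_carrier_freq: float | None = None
    sweep_decay_span_bp: float | None = None
    bn_F: float | None = None


def _sample_positions(rng: np.random.Generator, length_bp: int, m: int) -> np.ndarray:
    """m distinct sorted positions in [1, length_bp] without materialising
    the full range."""
    if m > length_bp:
        raise ValueError("more SNPs than base pairs")
    pos = np.unique(rng.integers(1, length_bp + 1, size=int(m * 1.05) + 16))
    while len(pos) < m:
        extra = rng.integers(1, length_bp + 1, size=m)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.permutation(pos)[:m])


def _draw_variants(cfg: SimConfig, rng: np.random.Generator) -> tuple[VariantTable, np.ndarray]:
    pos = _sample_positions(rng, cfg.chrom_length_bp, cfg.n_snps)
    freqs = rng.beta(cfg.freq_alpha, cfg.freq_beta, size=cfg.n_snps)
    freqs = np.clip(freqs, cfg.freq_min, 1.0 - cfg.freq_min)
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, size=cfg.n_snps)]
    alt = bases[(np.char.find("ACGT", ref) + rng.integers(1, 4, size=cfg.n_snps)) % 4]
    vt = VariantTable(chrom=np.full(cfg.n_snps, cfg.chrom), pos=pos.astype(np.int64),
                      ref=ref, alt=alt)
    return vt, freqs


def _mosaic_haplotypes(cfg: SimConfig, founders: np.ndarray, pos: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Copy 2*n_samples haplotypes as founder mosaics with exponential segments."""
    n_hap = 2 * cfg.n_samples
    m = len(pos)
    haps = np.empty((n_hap, m), dtype=np.uint8)
    # probability of >=1 switch between consecutive SNPs
    gaps = np.diff(pos).astype(float)
    p_switch = 1.0 - np.exp(-cfg.switch_rate * gaps) if cfg.switch_rate < np.inf else np.ones(m - 1)
    for h in range(n_hap):
        switches = rng.random(m - 1) < p_switch
        seg_ids = np.concatenate([[0], np.cumsum(switches)])
        founder_per_seg = rng.integers(0, cfg.n_founder_haplotypes, size=seg_ids[-1] + 1)
        src = founder_per_seg[seg_ids]
        haps[h] = founders[src, np.arange(m)]
    return haps


def simulate_neutral(cfg: SimConfig) -> tuple[GenotypeMatrix, TruthSet]:
    """Simulate a phased neutral panel with founder-mosaic LD.

    Founder haplotypes are drawn site-wise from the frequency spectrum;
    each sample haplotype is a mosaic copy of founders.  Reproducible given
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    vt, freqs = _draw_variants(cfg, rng)
    founders = (rng.random((cfg.n_founder_haplotypes, cfg.n_snps)) < freqs).astype(np.uint8)
    haps = _mosaic_haplotypes(cfg, founders, vt.pos, rng)
    return _assemble(cfg, vt, haps, rng), TruthSet()


def _assemble(cfg: SimConfig, vt: VariantTable, haps: np.ndarray,
              rng: np.random.Generator) -> GenotypeMatrix:
    n, m = cfg.n_samples, len(vt)
    hap3 = haps.reshape(n, 2, m)
    calls = hap3.sum(axis=1).astype(np.int8)
    if cfg.missing_rate > 0:
        miss = rng.random((n, m)) < cfg.missing_rate
        calls[miss] = MISSING
    samples = [f"S{i:03d}" for i in range(n)]
    return GenotypeMatrix(variants=vt, samples=samples, calls=calls, haplotypes=hap3)


def plant_autozygosity(
    gm: GenotypeMatrix,
    sample: str,
    tracts: IntervalSet,
    het_error: float = 0.0,
    seed: int = 0,
) -> tuple[GenotypeMatrix, TruthSet]:
    """Overwrite one sample's second haplotype with its first inside tracts.

    Inside each tract (0-based half-open bp intervals) the sample becomes
    autozygous; each in-tract site is then independently flipped to a
    heterozygous call with probability ``het_error`` to emulate genotyping
    error.  Missing calls in the tract are left missing.
    """
    if not gm.phased:
        raise ValueError("plant_autozygosity requires a phased matrix")
    rng = np.random.default_rng(seed)
    si = gm.samples.index(sample)
    pos0 = gm.variants.pos - 1  # tract coords are 0-based half-open
    recs = tracts.records.sort_values("start")
    if (recs.start.values[1:] < recs.end.values[:-1]).any():
        raise ValueError(f"overlapping tracts for sample {sample}")
    if len(recs) and int(recs.end.max()) > int(gm.variants.pos.max()):
        pass  # tracts may extend past the last SNP; only covered SNPs change

    haps = gm.haplotypes.copy()
    calls = gm.calls.copy()
    in_tract = np.zeros(gm.n_snps, dtype=bool)
    for r in recs.itertuples(index=False):
        in_tract |= (pos0 >= r.start) & (pos0 < r.end)
    idx = np.flatnonzero(in_tract)
    haps[si, 1, idx] = haps[si, 0, idx]
    flip = idx[rng.random(len(idx)) < het_error]
    haps[si, 1, flip] = 1 - haps[si, 0, flip]
    was_called = calls[si, idx] != MISSING
    calls[si, idx[was_called]] = haps[si, :, idx[was_called]].sum(axis=1).astype(np.int8)

    out = GenotypeMatrix(variants=gm.variants, samples=list(gm.samples),
                         calls=calls, haplotypes=haps, population=gm.population)
    truth = TruthSet(planted_tracts={sample: tracts})
    return out, truth


def plant_sweep(
    gm: GenotypeMatrix,
    focal_bp: int,
    carrier_freq: float,
    decay_span_bp: float,
    seed: int = 0,
) -> tuple[GenotypeMatrix, TruthSet]:
    """Plant a partial selective sweep around an existing focal SNP.

    A fraction ``carrier_freq`` of haplotypes carries the ALT allele at the
    focal SNP; each carrier is overwritten by one shared core haplotype over
    a contiguous extent around the focus whose per-side length is
    Exponential(``decay_span_bp``), so the per-site probability of carrying
    the core decays as exp(-distance/decay_span).  This creates the long
    shared haplotype homozygosity of an incomplete sweep.
    """
    if not gm.phased:
        raise ValueError("plant_sweep requires a phased matrix")
    if not (0.0 < carrier_freq < 1.0):
        raise ValueError("carrier_freq must lie in (0, 1)")
    pos = gm.variants.pos
    j_focal = int(np.searchsorted(pos, focal_bp))
    if j_focal >= len(pos) or pos[j_focal] != focal_bp:
        raise ValueError(f"no variant at position {focal_bp}")

    rng = np.random.default_rng(seed)
    n, m = gm.n_samples, gm.n_snps
    haps = gm.haplotypes.reshape(n * 2, m).copy()
    n_hap = n * 2
    n_carriers = int(round(carrier_freq * n_hap))
    n_carriers = min(max(n_carriers, 2), n_hap - 1)
    carriers = rng.choice(n_hap, size=n_carriers, replace=False)
    core = haps[carriers[0]].copy()
    core[j_focal] = 1

    dist = np.abs(pos.astype(float) - focal_bp)
    for h in carriers:
        if np.isinf(decay_span_bp):
            ext_l = ext_r = np.inf
        else:
            ext_l = rng.exponential(decay_span_bp)
            ext_r = rng.exponential(decay_span_bp)
        left = (pos < focal_bp) & (dist <= ext_l)
        right = (pos > focal_bp) & (dist <= ext_r)
        sel = left | right
        sel[j_focal] = True
        haps[h, sel] = core[sel]
    non_carriers = np.setdiff1d(np.arange(n_hap), carriers)
    haps[non_carriers, j_focal] = 0  # exact carrier frequency at the focus

    hap3 = haps.reshape(n, 2, m)
    calls = gm.calls.copy()
    miss = calls == MISSING
    calls = hap3.sum(axis=1).astype(np.int8)
    calls[miss] = MISSING
    out = GenotypeMatrix(variants=gm.variants, samples=list(gm.samples),
                         calls=calls, haplotypes=hap3, population=gm.population)
    truth = TruthSet(sweep_focal_bp=focal_bp, sweep_carrier_freq=carrier_freq,
                     sweep_decay_span_bp=decay_span_bp)
    return out, truth


def split_populations(
    base_freqs: np.ndarray,
    F: float,
    sizes: tuple[int, int],
    cfg: SimConfig,
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Draw two diverged populations under the Balding-Nichols model.

    Each population's per-SNP allele frequency is Beta-distributed with
    mean ``base_freq`` and variance ``F * base_freq * (1 - base_freq)``;
    genotypes are then binomial per sample.  Degenerate base frequencies
    (0 or 1) are skipped.
    """
    if not (0.0 < F < 1.0):
        raise ValueError("F must lie in (0, 1)")
    base_freqs = np.asarray(base_freqs, dtype=float)
    ok = (base_freqs > 0.0) & (base_freqs < 1.0)
    n_skip = int((~ok).sum())
    if n_skip:
        import logging
        logging.getLogger("rohscan").info(
            "split_populations: skipped %d degenerate sites", n_skip)
    p = base_freqs[ok]
    m = len(p)
    rng = np.random.default_rng(cfg.seed)
    cfg_m = replace(cfg, n_snps=m)
    vt, _ = _draw_variants(cfg_m, np.random.default_rng(cfg.seed + 1))

    scale = (1.0 - F) / F
    out = []
    for k, size in enumerate(sizes):
        pk = rng.beta(p * scale, (1.0 - p) * scale)
        hap = (rng.random((size, 2, m)) < pk).astype(np.uint8)
        calls = hap.sum(axis=1).astype(np.int8)
        samples = [f"P{k}_{i:03d}" for i in range(size)]
        out.append(GenotypeMatrix(
            variants=vt, samples=samples, calls=calls, haplotypes=hap,
            population=np.full(size, f"pop{k}")))
    return out[0], out[1]
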