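"""Independent brute-force oracles used to check the library.

Every function here restates its statistic directly from the definition in
plain loops, deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np

MISSING = -1


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test by full enumeration (exact rational arithmetic)
# ---------------------------------------------------------------------------

def hwe_enumeration(n_AA: int, n_Aa: int, n_aa: int) -> float:
    n = n_AA + n_Aa + n_aa
    nA = 2 * n_AA + n_Aa
    na = 2 * n - nA
    if n == 1:
        return 1.0

    def prob(h: int) -> Fraction:
        hom_A = (nA - h) // 2
        hom_a = (na - h) // 2
        if hom_A < 0 or hom_a < 0:
            return Fraction(0)
        # multinomial genotype arrangements * 2^h over allele arrangements
        num = Fraction(comb(n, hom_A) * comb(n - hom_A, h) * (2 ** h))
        return num / comb(2 * n, nA)

    hets = [h for h in range(nA % 2, min(nA, na) + 1, 2)]
    probs = {h: prob(h) for h in hets}
    p_obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= p_obs))


# ---------------------------------------------------------------------------
# ROH detection restated step by step
# ---------------------------------------------------------------------------

def roh_segments(pos, calls, *, window_snps=50, window_max_het=3,
                 window_max_missing=5, window_threshold=0.05,
                 min_snps=50, min_length_kb=300.0, min_density_kb=50.0,
                 max_gap_kb=1000.0):
    """Segments (start_bp, end_bp, n_snps) for one sample on one chromosome."""
    pos = [int(p) for p in pos]
    calls = [int(c) for c in calls]
    m = len(pos)
    w = window_snps
    if m < w:
        return []
    eligible = []
    for i in range(m - w + 1):
        win = calls[i:i + w]
        n_het = sum(1 for c in win if c == 1)
        n_mis = sum(1 for c in win if c == MISSING)
        eligible.append(n_het <= window_max_het and n_mis <= window_max_missing)
    in_state = []
    for j in range(m):
        lo = max(0, j - w + 1)
        hi = min(j, m - w)
        covering = list(range(lo, hi + 1))
        frac = sum(1 for i in covering if eligible[i]) / len(covering)
        in_state.append(frac >= window_threshold)

    candidates = []
    j = 0
    while j < m:
        if not in_state[j]:
            j += 1
            continue
        k = j
        while k + 1 < m and in_state[k + 1]:
            k += 1
        sub = j
        for t in range(j, k):
            if pos[t + 1] - pos[t] > max_gap_kb * 1000.0:
                candidates.append((sub, t))
                sub = t + 1
        candidates.append((sub, k))
        j = k + 1

    out = []
    for s, e in candidates:
        while s <= e and calls[s] not in (0, 2):
            s += 1
        while e >= s and calls[e] not in (0, 2):
            e -= 1
        if s > e:
            continue
        n_snps = e - s + 1
        length = pos[e] - pos[s] + 1
        if n_snps < min_snps:
            continue
        if length < min_length_kb * 1000.0:
            continue
        if length / n_snps > min_density_kb * 1000.0:
            continue
        out.append((pos[s], pos[e], n_snps))
    return out


# ---------------------------------------------------------------------------
# EHH by all-pairs identity checking
# ---------------------------------------------------------------------------

def ehh_all_pairs(haps, focal, allele, side):
    """EHH values at successive flanking SNPs (full curve to chromosome end)."""
    haps = np.asarray(haps)
    carriers = [h for h in range(haps.shape[0]) if haps[h, focal] == allele]
    n = len(carriers)
    pairs = n * (n - 1) // 2
    m = haps.shape[1]
    xs = range(focal - 1, -1, -1) if side == "left" else range(focal + 1, m)
    values = []
    for x in xs:
        lo, hi = (x, focal - 1) if side == "left" else (focal + 1, x)
        same = 0
        for a in range(n):
            for b in range(a + 1, n):
                if np.array_equal(haps[carriers[a], lo:hi + 1],
                                  haps[carriers[b], lo:hi + 1]):
                    same += 1
        values.append(same / pairs)
    return values


# ---------------------------------------------------------------------------
# Weir-Cockerham components, scalar per SNP
# ---------------------------------------------------------------------------

def wc_components(calls_a, calls_b, j):
    """(a, b, c) at SNP j from two call matrices, or None if uninformative."""
    stats = []
    for calls in (calls_a, calls_b):
        col = [int(c) for c in calls[:, j] if c != MISSING]
        ni = len(col)
        if ni < 2:
            return None
        pi = sum(col) / (2.0 * ni)
        hi = sum(1 for c in col if c == 1) / ni
        stats.append((ni, pi, hi))
    (n1, p1, h1), (n2, p2, h2) = stats
    r = 2.0
    nbar = (n1 + n2) / r
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    if pbar <= 0.0 or pbar >= 1.0:
        return None
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1.0)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2.0
    return a, b, c


# ---------------------------------------------------------------------------
# Inbreeding coefficients, scalar single pass
# ---------------------------------------------------------------------------

def _freqs(calls):
    m = calls.shape[1]
    out = []
    for j in range(m):
        col = [int(c) for c in calls[:, j] if c != MISSING]
        T = 2 * len(col)
        out.append((sum(col) / T if T else float("nan"), T))
    return out

def f_hom_direct(calls, si):
    pq = _freqs(calls)
    O = E = L = 0.0
    for j in range(calls.shape[1]):
        x = calls[si, j]
        p, T = pq[j]
        if x == MISSING or T <= 2:
            continue
        L += 1
        if x != 1:
            O += 1
        E += 1.0 - 2.0 * p * (1.0 - p) * (T / (T - 1.0))
    return (O - E) / (L - E)


def f_grm_direct(calls, si):
    pq = _freqs(calls)
    total, m = 0.0, 0
    for j in range(calls.shape[1]):
        x = calls[si, j]
        p, _ = pq[j]
        if x == MISSING or not (0.0 < p < 1.0):
            continue
        total += (x - 2 * p) ** 2 / (2 * p * (1 - p))
        m += 1
    return total / m - 1.0


def f_uni_direct(calls, si):
    pq = _freqs(calls)
    total, m = 0.0, 0
    for j in range(calls.shape[1]):
        x = calls[si, j]
        p, _ = pq[j]
        if x == MISSING or not (0.0 < p < 1.0):
            continue
        total += (x * x - (1 + 2 * p) * x + 2 * p * p) / (2 * p * (1 - p))
        m += 1
    return total / m


# ---------------------------------------------------------------------------
# Incidence / island / interval oracles
# ---------------------------------------------------------------------------

def incidence_scan(segments, chrom, pos, n_samples):
    """segments: (sample, chrom, start_bp, end_bp) tuples; per-SNP counts."""
    m = len(pos)
    counts = []
    for j in range(m):
        samples = set()
        for s, c, lo, hi in segments:
            if c == chrom[j] and lo <= pos[j] <= hi:
                samples.add(s)
        counts.append(len(samples))
    return counts


def island_merge(counts, chrom, top_fraction):
    """(threshold, list of (first_idx, last_idx)) by rank-and-merge."""
    m = len(counts)
    k = -(-int(top_fraction * m * 1e9) // int(1e9))  # ceil without float drift
    import math
    k = math.ceil(top_fraction * m)
    threshold = sorted(counts, reverse=True)[k - 1]
    qualify = [c >= threshold and c > 0 for c in counts]
    out = []
    j = 0
    while j < m:
        if not qualify[j]:
            j += 1
            continue
        e = j
        while e + 1 < m and qualify[e + 1] and chrom[e + 1] == chrom[e]:
            e += 1
        out.append((j, e))
        j = e + 1
    return threshold, out


def quadratic_intersect(islands, features):
    """All overlapping half-open pairs: (island_i, feature_j, overlap_bp)."""
    out = []
    for i, (ci, si, ei, *_ ) in enumerate(islands):
        for j, (cf, sf, ef, *_ ) in enumerate(features):
            if ci == cf and si < ef and sf < ei:
                out.append((i, j, min(ei, ef) - max(si, sf)))
    return out
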