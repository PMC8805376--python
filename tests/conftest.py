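import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import rohscan as rs


@pytest.fixture(scope="session")
def neutral_panel():
    """Seeded 10-sample phased panel with mosaic LD, MAF >= 0.01 filtered."""
    cfg = rs.SimConfig(n_samples=10, n_snps=4000, chrom_length_bp=20_000_000, seed=42)
    gm, _ = rs.simulate_neutral(cfg)
    st = rs.allele_stats(gm)
    return gm.take_snps(np.flatnonzero((st.maf >= 0.01).values))


def make_gm(calls, pos=None, chrom="1", haps=None, samples=None):
    """Hand-build a GenotypeMatrix from a dosage array."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    pos = np.arange(1, m + 1) * 1000 if pos is None else np.asarray(pos, dtype=np.int64)
    vt = rs.VariantTable(chrom=np.full(m, chrom), pos=pos,
                         ref=np.full(m, "A"), alt=np.full(m, "G"))
    return rs.GenotypeMatrix(
        variants=vt,
        samples=samples or [f"S{i}" for i in range(n)],
        calls=calls,
        haplotypes=None if haps is None else np.asarray(haps, dtype=np.uint8),
    )
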