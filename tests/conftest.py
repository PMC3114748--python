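import numpy as np
import pytest

from ffg import synthetic_cross as sc


@pytest.fixture(scope="session")
def small_genome():
    """1 chromosome x 200 kb, 1 SNP/kb, unmasked; session-wide reuse."""
    return sc.simulate_genome(1, [200_000], 1e-3, 0.0, seed=11, cm_per_mb=20.0)


@pytest.fixture(scope="session")
def small_cross(small_genome):
    genome, panel = small_genome
    mutations = sc.apply_ems(
        genome, rate=2e-5, causal_pos=("chr1", 100_001), seed=12, snp_panel=panel
    )
    f2 = sc.simulate_f2(genome, panel, mutations, 400, seed=13)
    mutant, wildtype = sc.build_pools(f2, pool_size=60, seed=14)
    return genome, panel, mutations, f2, mutant, wildtype


def make_column(
    bases, strands=None, starts=None, quals=None, chrom="chr1", pos=100
):
    """Build a PileupColumn from plain lists (test helper)."""
    n = len(bases)
    strands = strands or ["+", "-"] * (n // 2 + 1)
    starts = starts if starts is not None else list(range(n))
    quals = quals if quals is not None else [30] * n
    return sc.PileupColumn(
        chrom,
        pos,
        np.array(list(bases), dtype="U1"),
        np.array(strands[:n], dtype="U1"),
        np.array(starts[:n], dtype=np.int64),
        np.array(quals[:n], dtype=np.int64),
    )


def random_column(rng, max_obs=40, chrom="chr1", pos=100):
    """Random small pileup column for filter-oracle fuzzing."""
    n = int(rng.integers(0, max_obs + 1))
    bases = rng.choice(list("ACGT"), size=n, p=[0.45, 0.35, 0.1, 0.1])
    strands = rng.choice(["+", "-"], size=n)
    starts = rng.integers(80, 101, size=n)
    quals = rng.integers(5, 41, size=n)
    return sc.PileupColumn(
        chrom, pos, bases.astype("U1"), strands.astype("U1"),
        starts.astype(np.int64), quals.astype(np.int64),
    )
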