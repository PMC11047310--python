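import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from rohscan import GenotypeMatrix, SimulationConfig


def make_matrix(calls, positions=None, chrom="1", spacing=10_000):
    """GenotypeMatrix from a (samples x SNPs) code array on one chromosome."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_snps = calls.shape
    if positions is None:
        positions = np.arange(1, n_snps + 1) * spacing
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(positions, dtype=np.int64),
            "id": [f"snp{i}" for i in range(n_snps)],
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeMatrix(
        samples=[f"S{i:03d}" for i in range(n_samples)],
        variants=variants,
        calls=calls,
    )


@pytest.fixture
def small_config():
    return SimulationConfig(
        n_samples=8,
        chrom_lengths={"1": 20_000_000, "2": 10_000_000},
        seed=11,
        snp_density_per_kb=0.1,
    )


def random_instance(rng, max_samples=5, max_snps=300, n_chroms=(1, 3)):
    """A random small genotype matrix for oracle-equivalence checks.

    Genotype mix is skewed towards homozygosity so that segments actually
    occur; spacing is drawn widely enough to exercise the gap and density
    filters.
    """
    n_samples = int(rng.integers(1, max_samples + 1))
    n_chrom = int(rng.integers(n_chroms[0], n_chroms[1] + 1))
    chroms, positions = [], []
    remaining = int(rng.integers(60, max_snps + 1))
    for c in range(n_chrom):
        n = remaining if c == n_chrom - 1 else int(rng.integers(20, max(21, remaining // 2)))
        n = min(n, remaining)
        remaining -= n
        if n == 0:
            continue
        gaps = rng.choice(
            [2_000, 8_000, 25_000, 60_000, 700_000], size=n, p=[0.3, 0.3, 0.25, 0.1, 0.05]
        )
        pos = np.cumsum(gaps) + 1
        chroms.extend([str(c + 1)] * n)
        positions.append(pos)
    pos_all = np.concatenate(positions)
    n_snps = pos_all.size
    variants = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos_all.astype(np.int64),
            "id": [f"m{i}" for i in range(n_snps)],
            "ref": "A",
            "alt": "G",
        }
    )
    calls = rng.choice(
        [0, 1, 2, -1], size=(n_samples, n_snps), p=[0.55, 0.08, 0.32, 0.05]
    ).astype(np.int8)
    return GenotypeMatrix(
        samples=[f"S{i:03d}" for i in range(n_samples)], variants=variants, calls=calls
    )
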