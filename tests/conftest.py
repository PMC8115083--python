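import numpy as np
import pandas as pd
import pytest

from grainqtl import simulate
from grainqtl.genio import GenotypeMatrix


def make_genotypes(calls, chrom="1", start=1000, step=1000, samples=None,
                   **flags):
    """Small GenotypeMatrix from a raw call array (rows = accessions)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if samples is None:
        samples = [f"acc{i + 1:03d}" for i in range(n)]
    pos = [start + j * step for j in range(m)]
    markers = pd.DataFrame({
        "id": [f"S{chrom}_{p}" for p in pos],
        "chrom": chrom, "pos": pos, "ref": "A", "alt": "G",
    })
    for col, vals in flags.items():
        markers[col] = vals
    return GenotypeMatrix(samples=samples, markers=markers, calls=calls)


@pytest.fixture
def small_panel():
    """60 accessions x 300 markers, 4 subpopulations, deterministic."""
    cfg = simulate.SimConfig(n_accessions=60, n_subpops=4, n_snps=300,
                             divergence=0.15, rng_seed=7)
    G, labels = simulate.simulate_genotypes(cfg)
    return G, labels, cfg


@pytest.fixture
def default_panel():
    """Full-size default panel: 150 accessions, 8 subpopulations."""
    cfg = simulate.SimConfig(rng_seed=11)
    G, labels = simulate.simulate_genotypes(cfg)
    return G, labels, cfg
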