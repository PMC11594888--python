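import numpy as np
import pandas as pd
import pytest

from popsweep.variants import GenotypeMatrix


def make_gm(
    calls,
    chrom="chr1",
    positions=None,
    quals=None,
    depth=10.0,
    samples=None,
    ref="A",
    alt="C",
):
    """Build a GenotypeMatrix from a raw calls array (samples x variants)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 100
    if quals is None:
        quals = np.full(m, 50.0)
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    if np.isscalar(depth):
        depth_arr = np.full((n, m), float(depth))
    else:
        depth_arr = np.asarray(depth, dtype=float)
    variants = pd.DataFrame(
        dict(
            chrom=[chrom] * m,
            pos=list(positions),
            ref=[ref] * m,
            alt=[alt] * m,
            qual=list(quals),
        )
    )
    g = GenotypeMatrix(
        samples=list(samples), variants=variants, calls=calls, depth=depth_arr
    )
    g.validate()
    return g


@pytest.fixture(scope="session")
def small_sim():
    """Desk-scale simulation shared by read-only tests."""
    from popsweep.simdata import CausalSnp, SimConfig, SweepRegion, simulate_genotypes_and_phenotypes

    cfg = SimConfig(
        n_tall=10,
        n_short=10,
        chrom_lengths={"chr1": 600_000, "chr2": 600_000},
        n_variants=3_000,
        background_fst=0.05,
        sweep_regions=[SweepRegion("chr1", 200_001, 300_000, "SL", 0.95)],
        causal_snp=CausalSnp("chr2", 300_001, 3.0),
        missing_rate=0.02,
        seed=11,
    )
    return cfg, simulate_genotypes_and_phenotypes(cfg)
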