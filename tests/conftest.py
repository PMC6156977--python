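import numpy as np
import pandas as pd
import pytest

from twinmeth.containers import BetaMatrix
from twinmeth.simulate import SimConfig, generate_twin_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort exercised by several modules (20 pairs, replicates)."""
    config = SimConfig(
        n_pairs=20, n_cpgs=400, n_snps=300, n_mqtl_cpgs=20, seed=11
    )
    return generate_twin_cohort(config)


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Pure mixture cohort: no noise, no familial term, no mQTLs, no failures."""
    config = SimConfig(
        n_pairs=10,
        n_cpgs=200,
        n_snps=50,
        n_mqtl_cpgs=0,
        noise_sd=0.0,
        familial_corr=0.0,
        fail_rate=0.0,
        n_replicate_pairs=0,
        seed=5,
    )
    return generate_twin_cohort(config)


def make_beta(values, sample_ids=None, chrom="1", start=1000, step=100):
    """Small BetaMatrix from a 2-D array; coordinates are synthesized."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    cpgs = [f"cg{i:05d}" for i in range(n)]
    samples = sample_ids or [f"s{j}" for j in range(m)]
    frame = pd.DataFrame(values, index=pd.Index(cpgs, name="cpg_id"), columns=samples)
    coords = pd.DataFrame(
        {"chrom": chrom, "pos": start + step * np.arange(n)}, index=frame.index
    )
    return BetaMatrix(frame, coords)
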