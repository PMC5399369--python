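import numpy as np
import pandas as pd
import pytest

from pdig import synthetic
from pdig.genotypes import GenotypeMatrix


@pytest.fixture(scope="session")
def cohort():
    """One default 40+40 cohort with streamlines and scores."""
    return synthetic.simulate_cohort(seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 20+20 cohort without streamline records."""
    return synthetic.simulate_cohort(n_hc=20, n_pd=20, seed=7, with_streamlines=False)


def make_genotypes(calls: np.ndarray, subject_ids=None, snp_ids=None) -> GenotypeMatrix:
    """Wrap a raw call array into a GenotypeMatrix with stub metadata."""
    calls = np.asarray(calls, dtype=float)
    n, m = calls.shape
    subject_ids = subject_ids or [f"S{i:03d}" for i in range(n)]
    snp_ids = snp_ids or [f"snp{j}" for j in range(m)]
    snps = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "gene_label": ["stub"] * m,
            "base_pair_position": np.arange(m) + 1,
            "minor_allele": ["A"] * m,
        }
    ).set_index("snp_id")
    return GenotypeMatrix(
        calls=pd.DataFrame(calls, index=subject_ids, columns=snp_ids), snps=snps
    )
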