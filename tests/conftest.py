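import numpy as np
import pytest

from afckit.correction import normalize_log
from afckit.io_formats import HaplotypeDesign
from afckit.simulation import SimParams, simulate_cohort


@pytest.fixture(scope="session")
def cohort3():
    """One 3-eQTL gene, 500 individuals, moderate expression."""
    return simulate_cohort(
        SimParams(n_individuals=500, n_eqtls=3, n_genes=1, seed=7)
    )


@pytest.fixture(scope="session")
def cohort3_y(cohort3):
    y = normalize_log(cohort3.counts)
    d = cohort3.design_for("GENE0000")
    return d, y.loc["GENE0000", d.sample_ids].to_numpy(float)


def make_design(H1, H2, gene_id="g"):
    """Wrap raw haplotype matrices into a design for direct model tests."""
    H1 = np.atleast_2d(np.asarray(H1, float))
    H2 = np.atleast_2d(np.asarray(H2, float))
    n, N = H1.shape
    return HaplotypeDesign(
        gene_id=gene_id,
        variant_ids=[f"chr1_{1000 + k}_A_G" for k in range(N)],
        sample_ids=[f"S{i}" for i in range(n)],
        H1=H1,
        H2=H2,
    )
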