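import numpy as np
import pandas as pd
import pytest

from omicshub.containers import OmicsMatrix
from omicshub.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default planted cohort (30 pairs, log2 effect 2, noise 0.3)."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for fast structural tests."""
    return generate_cohort(
        CohortConfig(
            n_patients=20, n_paired=10, n_genes=300, n_mirnas=120,
            n_methylation_sites=400, frac_de_genes=0.2,
            planted_mirna_pairs=8, planted_meth_genes=8, planted_cna_genes=8,
            seed=5,
        )
    )


@pytest.fixture()
def paired_matrix():
    """Tiny hand-buildable paired matrix: 4 patients, tumor+normal each."""
    rng = np.random.default_rng(42)
    samples = [f"P{i}-T" for i in range(4)] + [f"P{i}-N" for i in range(4)]
    meta = pd.DataFrame(
        {"patient_id": [f"P{i}" for i in range(4)] * 2,
         "tissue": ["tumor"] * 4 + ["normal"] * 4},
        index=pd.Index(samples, name="sample_id"),
    )
    values = pd.DataFrame(
        rng.uniform(1, 100, size=(6, 8)),
        index=pd.Index([f"g{i}" for i in range(6)], name="feature_id"),
        columns=samples,
    )
    return OmicsMatrix(values, meta)
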