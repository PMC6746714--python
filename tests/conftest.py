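import numpy as np
import pandas as pd
import pytest

import embryomics as em
from embryomics.datatypes import StageDesign


@pytest.fixture
def toy_design() -> StageDesign:
    """Two stages x three replicates."""
    return StageDesign.from_sample_names(
        [f"{st}_rep{r}" for st in ("oocyte", "2cell") for r in (1, 2, 3)],
        reference="oocyte",
    )


@pytest.fixture
def toy_matrix(toy_design) -> pd.DataFrame:
    rng = np.random.default_rng(0)
    data = rng.normal(0, 1, (5, 6))
    return pd.DataFrame(
        data, index=[f"p{i}" for i in range(5)], columns=toy_design.samples
    )


@pytest.fixture(scope="session")
def small_dataset() -> em.SyntheticDataset:
    """A small default-structure dataset shared across tests."""
    return em.simulate_dataset(em.SimulationConfig(n_genes=400, seed=42))
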