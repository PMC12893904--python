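import numpy as np
import pandas as pd
import pytest

from immunokit.simulate import TissueSimConfig, gen_spatial_tissue


@pytest.fixture(scope="session")
def csr_map() -> pd.DataFrame:
    """One complete-spatial-randomness tissue (no cross-type attraction)."""
    cfg = TissueSimConfig(
        n_cells_per_type={"A": 300, "B": 300},
        attraction={("A", "B"): 0.0},
        seed=11,
    )
    return gen_spatial_tissue(cfg)


@pytest.fixture(scope="session")
def clustered_map() -> pd.DataFrame:
    """Tissue with strong cross-type attraction (B clusters around A)."""
    cfg = TissueSimConfig(
        n_cells_per_type={"A": 300, "B": 300},
        attraction={("A", "B"): 0.7},
        seed=12,
    )
    return gen_spatial_tissue(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
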