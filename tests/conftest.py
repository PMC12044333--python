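import numpy as np
import pandas as pd
import pytest

from freeil18 import default_idic_config, generate_cohort


@pytest.fixture(scope="session")
def idic_cohort() -> pd.DataFrame:
    """One default synthetic cohort (n=295), shared across tests."""
    return generate_cohort(default_idic_config(seed=42))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)
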