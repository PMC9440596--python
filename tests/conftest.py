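import numpy as np
import pandas as pd
import pytest

from rgbn.catalog import BOYS_OLDER, RESPONSE_NAMES
from rgbn.synthetic import default_study_specs, simulate_group


@pytest.fixture(scope="session")
def specs():
    return default_study_specs()


@pytest.fixture(scope="session")
def boys_older_table(specs):
    """One simulated boys-over-14 group at n = 2000 (shared, read-only)."""
    return simulate_group(BOYS_OLDER, 2000, 42, specs)


def make_chain(n: int, seed: int, beta: float = 0.9, noise: float = 0.4) -> pd.DataFrame:
    """X -> Y -> Z linear-Gaussian chain for d-separation oracles."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = beta * x + rng.normal(scale=noise, size=n)
    z = beta * y + rng.normal(scale=noise, size=n)
    return pd.DataFrame({"X": x, "Y": y, "Z": z})


def make_independent(n: int, seed: int, k: int = 4) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {f"V{i}": rng.normal(size=n) for i in range(k)}
    )
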