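import numpy as np
import pandas as pd
import pytest

from neurobn import GaussianBN, sample
from neurobn.graphs import DAGStructure


@pytest.fixture
def chain_xy() -> GaussianBN:
    """X -> Y with beta = 2 and unit residual variances: Sigma = [[1,2],[2,5]]."""
    s = DAGStructure(("X", "Y"), frozenset({("X", "Y")}))
    return GaussianBN(s, {"X": 0.0, "Y": 0.0}, {"X": {}, "Y": {"X": 2.0}}, {"X": 1.0, "Y": 1.0})


@pytest.fixture
def chain_xyz() -> GaussianBN:
    """X -> Y -> Z, strong coefficients."""
    s = DAGStructure(("X", "Y", "Z"), frozenset({("X", "Y"), ("Y", "Z")}))
    return GaussianBN(
        s,
        {"X": 0.0, "Y": 0.0, "Z": 0.0},
        {"X": {}, "Y": {"X": 1.2}, "Z": {"Y": -0.9}},
        {"X": 1.0, "Y": 0.8, "Z": 1.1},
    )


@pytest.fixture
def chain_data(chain_xy) -> pd.DataFrame:
    return sample(chain_xy, 2000, seed=42)


@pytest.fixture
def independent_data() -> pd.DataFrame:
    rng = np.random.default_rng(7)
    return pd.DataFrame(rng.standard_normal((2000, 4)), columns=list("ABCD"))
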