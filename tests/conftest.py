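import numpy as np
import pandas as pd
import pytest

from dietsurv import ExpressionMatrix, GeneSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_fpkm():
    """2-gene x 2-sample FPKM matrix with hand-checkable values."""
    df = pd.DataFrame(
        [[1.0, 3.0], [3.0, 1.0]], index=["g1", "g2"], columns=["s1", "s2"]
    )
    return ExpressionMatrix(df, scale="fpkm")


@pytest.fixture
def random_log2p1(rng):
    df = pd.DataFrame(
        rng.uniform(0.0, 10.0, size=(10, 5)),
        index=[f"g{i}" for i in range(10)],
        columns=[f"s{j}" for j in range(5)],
    )
    return ExpressionMatrix(df, scale="log2p1")


@pytest.fixture
def fao_panel():
    return GeneSet("FAO", ["g1", "g2"])
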