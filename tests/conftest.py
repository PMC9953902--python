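import numpy as np
import pandas as pd
import pytest

from layerscope.expression import ExpressionMatrix


@pytest.fixture
def toy_matrix():
    """3 genes x 4 samples, two batches."""
    data = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [5.0, 6.0, 7.0, 8.0],
         [2.0, 2.5, 3.0, 3.5]],
        index=["G1", "G2", "G3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    batch = pd.Series(["a", "a", "b", "b"], index=data.columns)
    return ExpressionMatrix(data, batch)


@pytest.fixture
def random_matrix():
    rng = np.random.default_rng(1)
    data = pd.DataFrame(
        rng.normal(size=(20, 12)),
        index=[f"G{i}" for i in range(20)],
        columns=[f"s{j}" for j in range(12)],
    )
    return ExpressionMatrix(data)
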