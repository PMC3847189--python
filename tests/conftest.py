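import numpy as np
import pandas as pd
import pytest

from mirdiverge.io_formats import CountTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_counts():
    df = pd.DataFrame({"s1": [6, 60, 10], "s2": [7, 55, 0], "s3": [8, 70, 200]},
                      index=["mirA", "mirB", "mirC"])
    return CountTable(df, {"s1": 1_000_000, "s2": 1_000_000, "s3": 1_000_000})
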