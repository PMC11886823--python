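import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def small_table() -> pd.DataFrame:
    """Three enhancers in two samples with hand-checkable counts."""
    return pd.DataFrame(
        {
            "enhancer_id": ["e1", "e1", "e2", "e2", "e3", "e3"],
            "sample_id": ["s1", "s2", "s1", "s2", "s1", "s2"],
            "forward": [3, 0, 10, 10, 0, 0],
            "reverse": [0, 4, 0, 0, 5, 5],
        }
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
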