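import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def intro_matrix() -> pd.DataFrame:
    """Three profiles whose d_a distances exhibit a triangle violation."""
    return pd.DataFrame(
        [[6.0, 4.0, 9.0], [6.0, 9.0, 5.0], [3.0, 10.0, 7.0]],
        index=["x", "y", "z"],
        columns=["c1", "c2", "c3"],
    )


def random_expression(seed: int, n_items=None, n_dims=None) -> pd.DataFrame:
    """A seeded random expression matrix (standard-normal entries)."""
    rng = np.random.default_rng(seed)
    n_items = n_items or int(rng.integers(5, 16))
    n_dims = n_dims or int(rng.integers(3, 41))
    return pd.DataFrame(
        rng.standard_normal((n_items, n_dims)),
        index=[f"g{i}" for i in range(n_items)],
    )
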