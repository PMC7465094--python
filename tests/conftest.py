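import numpy as np
import pandas as pd
import pytest

from idopnet.io import ExpressionDataset


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """2 genes x 2 samples with risk labels; EI = column sums = [4, 6]."""
    values = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0]], index=["gA", "gB"], columns=["s1", "s2"]
    )
    risk = pd.Series(["high", "low"], index=["s1", "s2"])
    return ExpressionDataset(values, risk)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def power_curve_data():
    """Clean power-law data y = 1.5 * E**0.7 on a positive EI grid."""
    e = np.linspace(600.0, 1400.0, 80)
    return e, 1.5 * e**0.7
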