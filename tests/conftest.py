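import numpy as np
import pandas as pd
import pytest

from mirtrend import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """3 features x 3 ages with unequal depths."""
    values = pd.DataFrame(
        {"3": [100.0, 10.0, 50.0], "12": [80.0, 10.0, 60.0], "24": [60.0, 10.0, 75.0]},
        index=pd.Index(["mir-a", "mir-b", "mir-c"], name="feature"),
    )
    return ExpressionMatrix(values=values, ages=[3, 12, 24],
                            totals=np.array([1e6, 2e6, 4e6]))


def synthetic_rpm_table() -> tuple[pd.DataFrame, list[float]]:
    """Synthetic stand-in for a published rpm-by-age table.

    A small miRNA x age table constructed (not downloaded) so that one
    high-abundance feature declines unidirectionally from 2207.22 rpm at 3
    months to 897.94 rpm at 30 months while a second candidate starts >3.3x
    lower. Used to exercise the load -> classify -> rank query path.
    """
    values = pd.DataFrame(
        {
            "3": [2207.22, 650.0, 480.0, 55.0],
            "6": [1950.0, 580.0, 500.0, 52.0],
            "12": [1700.0, 515.0, 470.0, 56.0],
            "18": [1400.0, 455.0, 490.0, 53.0],
            "24": [1100.0, 400.0, 465.0, 55.0],
            "30": [897.94, 350.0, 505.0, 54.0],
        },
        index=pd.Index(["Mir146b", "Mir22", "Mir146a", "Mir362"], name="feature"),
    )
    return values, [3.0, 6.0, 12.0, 18.0, 24.0, 30.0]
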