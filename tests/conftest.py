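import numpy as np
import pandas as pd
import pytest

from pbapflow.fluorescence import ThresholdSet
from pbapflow.synthetic_data import generate_campaign, get_preset


@pytest.fixture
def thresholds():
    """Exact threshold set matching the default generator FT statistics."""
    return ThresholdSet(ft_mean=np.array([50.0, 40.0, 30.0]), ft_sd=np.array([5.0, 4.0, 3.0]))


@pytest.fixture
def toy_particles():
    """Six handcrafted particles spanning the classification cases."""
    t0 = pd.Timestamp("2017-01-06T00:00:00")
    return pd.DataFrame(
        {
            "timestamp": [t0 + pd.Timedelta(minutes=i) for i in range(6)],
            "d_opt": [0.8, 1.0, 2.0, 5.0, 9.0, 14.0],
            "af": [5.0, 5.0, 6.0, 12.0, 15.0, 20.0],
            # thresholds: t3=(65,52,39), t9=(95,76,57)
            "fl_a": [10.0, 66.0, 10.0, 96.0, 66.0, 10.0],
            "fl_b": [10.0, 10.0, 53.0, 77.0, 53.0, 10.0],
            "fl_c": [10.0, 10.0, 10.0, 58.0, 10.0, 40.0],
            "quality_flags": [0, 0, 0, 0, 0, 1],
        }
    )


@pytest.fixture(scope="session")
def small_campaign():
    """Two-day pristine campaign, small enough for fast unit tests."""
    return generate_campaign(get_preset("pristine", duration_h=48.0, seed=1234))


@pytest.fixture(scope="session")
def small_mixed_campaign():
    """Ten-day coastal campaign with a terrestrial plume."""
    return generate_campaign(get_preset("mixed", duration_h=240.0, seed=99))
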