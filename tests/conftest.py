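import numpy as np
import pytest

from platesense import datasets
from platesense.synthetic import GeneratorConfig


@pytest.fixture(scope="session")
def plate_model():
    """The plate imager's published red-channel calibration."""
    return datasets.plate_calibration_model()


@pytest.fixture(scope="session")
def survey():
    """27-sample river-water survey measured by both instruments."""
    return datasets.load_river_survey()


@pytest.fixture
def quiet_config():
    """Noise-free generator: every stage should be exact."""
    return GeneratorConfig(seed=7, well_noise_sd=0.0, pixel_noise_sd=0.0)


def ols_oracle(x, y):
    """Independent normal-equations OLS: (slope, intercept, se_slope,
    se_intercept, r2) from the textbook closed forms."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    xbar, ybar = x.mean(), y.mean()
    sxx = np.sum((x - xbar) ** 2)
    sxy = np.sum((x - xbar) * (y - ybar))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - slope * x - intercept
    rss = np.sum(resid**2)
    tss = np.sum((y - ybar) ** 2)
    s2 = rss / (n - 2)
    se_slope = np.sqrt(s2 / sxx)
    se_intercept = np.sqrt(s2 * (1.0 / n + xbar**2 / sxx))
    r2 = 1.0 - rss / tss
    return slope, intercept, se_slope, se_intercept, r2
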