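"""Shared fixtures: small phantoms and a session-scoped trained cascade."""

import numpy as np
import pytest

from hotspotseg import PhantomSpec, generate_cohort
from hotspotseg.pipeline import TrainedModels, study_config, train_models


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def config():
    """Desk-scale pipeline configuration shared by end-to-end tests."""
    return study_config(seed=11)


@pytest.fixture(scope="session")
def trained(config) -> TrainedModels:
    """Cascade trained once on a default-condition cohort (reused widely)."""
    spec = PhantomSpec()
    train_cases = generate_cohort((20, 0, 14), spec, seed=9100)
    calib_cases = generate_cohort((5, 3, 4), spec, seed=9200)
    return train_models(train_cases, config, calibration_cases=calib_cases)


@pytest.fixture()
def disk_case():
    """A bright disk (0.9) on dark background (0.1) with sigma=0.05 noise,
    plus an oracle probability map (blurred ground truth)."""
    from scipy import ndimage

    rng = np.random.default_rng(77)
    h = w = 64
    yy, xx = np.mgrid[0:h, 0:w]
    mask = (yy - 32) ** 2 + (xx - 30) ** 2 <= 12**2
    image = np.where(mask, 0.9, 0.1) + rng.normal(0, 0.05, (h, w))
    image = np.clip(image, 0.0, 1.0)
    prob = ndimage.gaussian_filter(mask.astype(float), 2.0)
    prob = prob / prob.max()
    return image, mask, prob
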