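import dataclasses

import numpy as np
import pytest

from femsym import (AnatomySDs, PoseParams, PositioningParams, SyntheticConfig,
                    generate_dataset, make_template)


@pytest.fixture(scope="session")
def template():
    """Canonical left-femur template contour and its index map."""
    return make_template()


@pytest.fixture(scope="session")
def small_dataset():
    """Small artefact-laden synthetic cohort with its ground truth."""
    cfg = SyntheticConfig(n_subjects=12, seed=7)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def clean_config():
    """Config with no positioning artefacts and no left-right noise."""
    return SyntheticConfig(
        n_subjects=8, seed=3, lr_noise_sd=0.0,
        positioning=PositioningParams(0.0, 0.0, 0.0, 0.0),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def zeroed_anatomy():
    return AnatomySDs(0, 0, 0, 0, 0, 0, 0)


@pytest.fixture(scope="session")
def noise_only_config():
    """Sides exchangeable and independent: landmark noise is the only variation."""
    return SyntheticConfig(
        n_subjects=25, seed=11, lr_noise_sd=0.3,
        anatomy_sds=zeroed_anatomy(),
        positioning=PositioningParams(0.0, 0.0, 0.0, 0.0),
        pose=PoseParams(0.0, 0.0, 0.0),
    )
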