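import numpy as np
import pytest

from eegcam import (
    GeneratorConfig,
    bandpass,
    build_feature_matrix,
    extract_epochs,
    generate_session,
)


@pytest.fixture(scope="session")
def default_cfg() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def g1_session(default_cfg):
    """One group-1 subject at the default study conditions."""
    return generate_session(default_cfg, "s01", seed=1)


@pytest.fixture(scope="session")
def g1_feature_matrix(g1_session, default_cfg):
    """95-column absolute-power table for the group-1 subject."""
    filtered = bandpass(g1_session)
    return build_feature_matrix(
        extract_epochs(filtered, (0.0, default_cfg.epoch_length))
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
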