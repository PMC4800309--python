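import numpy as np
import pytest

from affectscr.synthetic import default_affective_config, generate_feature_table


@pytest.fixture(scope="session")
def default_table():
    """3 classes x 8 stimuli feature table at the default study conditions."""
    return generate_feature_table(default_affective_config(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
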