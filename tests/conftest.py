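import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_design():
    from eradimix import SurveyDesign

    return SurveyDesign.constant(n_surveys=4, n_points=3)
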