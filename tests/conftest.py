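import numpy as np
import pytest

from ki67window.evaluation import train_default_classifier
from ki67window.ihc.scoring import PipelineParams
from ki67window.simulate.slides import SlideSpec, generate_slide
from ki67window.simulate.trial import TrialSimSpec, generate_trial_table


@pytest.fixture(scope="session")
def classifier():
    """One trained patch classifier shared by all scoring tests."""
    return train_default_classifier(seed=6)


@pytest.fixture(scope="session")
def params():
    return PipelineParams()


@pytest.fixture(scope="session")
def reference_slide():
    """A 30%-positive slide with ground truth, reused across tests."""
    return generate_slide(SlideSpec(positive_fraction=0.3, seed=7))


@pytest.fixture(scope="session")
def default_trial():
    return generate_trial_table(TrialSimSpec(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
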