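import numpy as np
import pytest

import vocpanel as vp
from vocpanel.pipeline import class_labels, model_analysis_set, pooled_analysis_set


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study: 2 models x 2 conditions x 2 timepoints,
    25 animals per group, 47 peaks, 11 planted differential + 4 interaction."""
    design = vp.StudyDesign(seed=20260925)
    return vp.generate_peak_tables(design, vp.default_effects(design))


@pytest.fixture(scope="session")
def lkr_set(default_study):
    """Normalized subtracted analysis set of the first model."""
    return model_analysis_set(default_study, "LKR")


@pytest.fixture(scope="session")
def pooled_set(default_study):
    return pooled_analysis_set(default_study)


@pytest.fixture(scope="session")
def lkr_labels(lkr_set):
    return class_labels(lkr_set).to_numpy()


def make_study(seed, **effect_kwargs):
    design = vp.StudyDesign(seed=seed)
    return vp.generate_peak_tables(design, vp.default_effects(design, **effect_kwargs))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
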