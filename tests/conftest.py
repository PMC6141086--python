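import numpy as np
import pytest

from hipdyn.pipeline import AnalysisSettings, analyze_trial
from hipdyn.synthetic import (
    GaitGeneratorParams,
    generate_gait_trial,
    make_toy_model,
    perturb_model,
)


@pytest.fixture(scope="session")
def lowerlimb():
    return make_toy_model("lowerlimb-12m")


@pytest.fixture(scope="session")
def planar():
    return make_toy_model("planar-2seg")


@pytest.fixture(scope="session")
def abductor_rig():
    return make_toy_model("hip-abductor-rig")


@pytest.fixture(scope="session")
def clean_gait(lowerlimb):
    """One clean (noise-free) synthetic gait cycle with its pipeline reference."""
    trial, truth = generate_gait_trial(lowerlimb, GaitGeneratorParams(seed=11))
    return trial, truth


@pytest.fixture(scope="session")
def refined_results(clean_gait):
    """Full pipeline results on the uncorrupted model (the 'refined' state)."""
    _, truth = clean_gait
    return truth.reference_results


@pytest.fixture(scope="session")
def defective_results(lowerlimb, clean_gait):
    """Pipeline results with the condyle wraps removed from the knee flexors."""
    trial, _ = clean_gait
    bad, _ = perturb_model(lowerlimb, {"remove_wrap": ["ham_med", "ham_lat"]})
    return analyze_trial(bad, trial, AnalysisSettings())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
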