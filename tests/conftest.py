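import numpy as np
import pytest

from elbowstiff.dynamics import SegmentProperties
from elbowstiff.parameters import default_ground_truth_vector, split_vector
from elbowstiff.synthetic import GroundTruth, ScenarioSpec, synth_trial


@pytest.fixture(scope="session")
def ground_truth() -> GroundTruth:
    return GroundTruth()


@pytest.fixture(scope="session")
def gt_params(ground_truth):
    """(HillParams, PassiveJointParams) of the default ground truth."""
    return split_vector(ground_truth.vector)


@pytest.fixture(scope="session")
def segment() -> SegmentProperties:
    return SegmentProperties()


@pytest.fixture(scope="session")
def small_trial(ground_truth):
    """Two noisy cycles at 30 bpm / 0.5 kg, 100 Hz."""
    spec = ScenarioSpec(tempo=30.0, load=0.5, n_repetitions=2, fs=100.0, seed=101)
    return synth_trial(ground_truth, spec)


@pytest.fixture(scope="session")
def clean_trial(ground_truth):
    """Two noiseless cycles at 30 bpm / 0.5 kg, 100 Hz."""
    spec = ScenarioSpec(tempo=30.0, load=0.5, n_repetitions=2, fs=100.0, seed=102,
                        envelope_noise=0.0, goniometer_noise_deg=0.0)
    return synth_trial(ground_truth, spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
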