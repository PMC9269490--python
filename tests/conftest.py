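import numpy as np
import pytest

from spineposture.model import build_default_model
from spineposture.synthetic import SyntheticSubject, generate_truth


@pytest.fixture(scope="session")
def default_model():
    return build_default_model()


@pytest.fixture(scope="session")
def male_truth():
    """One deterministic pure-sagittal male subject with ground truth."""
    subj = SyntheticSubject(
        sex="male", axial_rotation_deg=0.0, lateral_bend_deg=0.0, seed=11
    )
    return generate_truth(subj)


@pytest.fixture(scope="session")
def female_truth():
    subj = SyntheticSubject(
        sex="female", lordosis_deg=50.0, kyphosis_deg=35.0,
        axial_rotation_deg=2.0, lateral_bend_deg=2.0, seed=12,
    )
    return generate_truth(subj)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
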