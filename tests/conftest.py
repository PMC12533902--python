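import numpy as np
import pytest

from cilad import synthetic_data as sd
from cilad.datatypes import FeatureTable


@pytest.fixture(scope="session")
def small_beats():
    return sd.gen_ecg_beats(20, 3, beat_len=187, noise_sd=0.05, seed=7)


@pytest.fixture(scope="session")
def small_images():
    return sd.gen_cardiac_images(4, size=48, seed=3, n_classes=3)


@pytest.fixture(scope="session")
def records():
    return sd.gen_patient_records(400, n_signal=5, n_noise=8, seed=3)


@pytest.fixture(scope="session")
def food_db():
    return sd.gen_food_db(20, seed=0)


@pytest.fixture(scope="session")
def hypertension_profile():
    return sd.gen_patient_profile("hypertension", seed=0)


@pytest.fixture()
def tiny_features():
    """A 40-sample, 4-feature table where feature 0 separates the classes,
    feature 1 is weakly informative, 2 is noise and 3 is constant."""
    rng = np.random.default_rng(5)
    y = np.repeat([0, 1], 20)
    x0 = y + rng.normal(0, 0.1, 40)
    x1 = y + rng.normal(0, 1.0, 40)
    x2 = rng.normal(0, 1.0, 40)
    x3 = np.zeros(40)
    return FeatureTable(["sep", "weak", "noise", "const"],
                        np.column_stack([x0, x1, x2, x3]), y)
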