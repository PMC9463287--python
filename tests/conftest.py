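import numpy as np
import pytest

from voxattr import fixtures as fx
from voxattr.targets import classification_target, segmentation_target


@pytest.fixture(scope="session")
def toy_models():
    return fx.make_toy_models(seed=0, clf_shape=(8, 8, 8, 2), seg_shape=(8, 8, 8, 2))


@pytest.fixture(scope="session")
def classifier(toy_models):
    return toy_models["classifier"]


@pytest.fixture(scope="session")
def segmenter(toy_models):
    return toy_models["segmenter"]


@pytest.fixture(scope="session")
def smooth_cnn():
    return fx.make_smooth_cnn(seed=0, input_shape=(8, 8, 8, 2))


@pytest.fixture(scope="session")
def linear_model():
    return fx.make_linear_model(np.array([1.0, 2.0, 3.0]))


@pytest.fixture(scope="session")
def blob_detector():
    return fx.make_blob_detector(kernel_radius=1, input_shape=(32, 32, 32, 4))


@pytest.fixture(scope="session")
def phantom():
    return fx.make_phantom((32, 32, 32), seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def class_target():
    return classification_target(1)


@pytest.fixture
def seg_target():
    return segmentation_target(1)
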