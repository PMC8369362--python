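import numpy as np
import pytest

from dbtdet.detector_core import DetectorConfig, build_detector
from dbtdet.io_formats import LesionClass, LesionType
from dbtdet.phantom_sim import LesionSpec, PhantomSpec, generate_volume
from dbtdet.preprocess import preprocess_volume

TINY_DETECTOR = DetectorConfig(growth_rate=4, blocks=(1, 1), seed=0)


@pytest.fixture(scope="session")
def tiny_detector():
    return build_detector(TINY_DETECTOR)


@pytest.fixture(scope="session")
def mass_phantom():
    """Small-preset phantom with one mass lesion; shared read-only."""
    spec = PhantomSpec(
        lesions=(LesionSpec(LesionType.MASS, (250, 380, 20), 64, 400.0,
                            LesionClass.CANCER),),
        seed=3,
    )
    return generate_volume(spec)


@pytest.fixture(scope="session")
def preprocessed_mass_phantom(mass_phantom):
    volume, annotations = mass_phantom
    pvol, masks = preprocess_volume(volume)
    return pvol, masks, annotations


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
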