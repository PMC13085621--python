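import numpy as np
import pytest

from dvoscope import features as feat
from dvoscope import synth_cohort as sc
from dvoscope.calibration import load_calibration
from dvoscope.optics import NoiseConfig, load_extinction_table
from dvoscope.protocol import default_protocol


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


@pytest.fixture(scope="session")
def calibration():
    return load_calibration()


@pytest.fixture(scope="session")
def extinction():
    return load_extinction_table()


@pytest.fixture(scope="session")
def mean_targets_nonpad():
    """Calibration-mean feature targets for the non-PAD group."""
    return feat.FeatureSet(
        at_60=feat.PressureFeatures(delta_hbo=6.81, hf=2.48, vo2=0.066, tp=23.44),
        at_100=feat.PressureFeatures(delta_hbo=9.44, hf=2.90, vo2=0.079, tp=20.86),
    )


@pytest.fixture(scope="session")
def mean_targets_pad():
    return feat.FeatureSet(
        at_60=feat.PressureFeatures(delta_hbo=2.01, hf=0.86, vo2=0.040, tp=20.70),
        at_100=feat.PressureFeatures(delta_hbo=3.90, hf=1.35, vo2=0.052, tp=17.12),
    )


@pytest.fixture(scope="session")
def mean_trace_nonpad(mean_targets_nonpad, protocol):
    return sc.construct_trace(mean_targets_nonpad, protocol)


@pytest.fixture(scope="session")
def small_noiseless_cohort(protocol):
    return sc.generate_cohort(2, 2, protocol, NoiseConfig.none(), seed=1)


@pytest.fixture(scope="session")
def small_noisy_cohort(protocol):
    return sc.generate_cohort(5, 5, protocol, None, seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
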