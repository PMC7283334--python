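import numpy as np
import pytest

from petref import phantom as ph
from petref.acquisition import default_schedule
from petref.experiment import RegionalForwardModel
from petref.input_function import InputFunctionModel, default_input_model


@pytest.fixture(scope="session")
def atlas_and_maps():
    """64^3 phantom shared across the suite (deterministic)."""
    return ph.build_phantom((64, 64, 64))


@pytest.fixture(scope="session")
def atlas(atlas_and_maps):
    return atlas_and_maps[0]


@pytest.fixture(scope="session")
def tissue_maps(atlas_and_maps):
    return atlas_and_maps[1]


@pytest.fixture(scope="session")
def forward_model(atlas, tissue_maps):
    return RegionalForwardModel.from_phantom(atlas, tissue_maps, psf_fwhm_mm=6.0)


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture(scope="session")
def input_model():
    return default_input_model()


@pytest.fixture(scope="session")
def planted_triexp():
    """Tri-exponential plasma model with the planted recovery-test parameters."""
    return InputFunctionModel(
        t_peak=0.5,
        amplitudes=np.array([800.0, 150.0, 50.0]),
        rates=np.array([0.5, 0.05, 0.005]),
    )
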