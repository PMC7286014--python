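import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import sfdose as sf

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def beam():
    """Default 6 MV beam with the collimator width asymmetry."""
    return sf.BeamModel()


@pytest.fixture(scope="session")
def symmetric_beam():
    """Beam with no per-axis width bias: FWHM equals the projected width."""
    return sf.BeamModel(width_bias_cross_mm=0.0, width_bias_in_mm=0.0)


@pytest.fixture(scope="session")
def noise_free_scenario(tmp_path_factory):
    """Complete synthetic dataset with zero reading noise (closure fixture)."""
    out = tmp_path_factory.mktemp("noise_free")
    config = sf.ScenarioConfig(noise_sd=0.0)
    return sf.generate_scenario(config, seed=1234, out_dir=out)


@pytest.fixture(scope="session")
def noisy_scenario(tmp_path_factory):
    """Synthetic dataset at the default 0.3% reading noise."""
    out = tmp_path_factory.mktemp("noisy")
    return sf.generate_scenario(sf.ScenarioConfig(), seed=99, out_dir=out)


def fof_table_from_values(detector_id, values_by_side, column="fof_uncorrected"):
    """Build a FOFTable directly from printed output-factor values."""
    sides = sorted(values_by_side)
    frame = pd.DataFrame(
        {
            "collimator_side_cm": sides,
            "sclin_cm": sides,
            "fof_uncorrected": [values_by_side[s] for s in sides],
            "k_applied": 1.0,
            "fof_corrected": [values_by_side[s] for s in sides],
            "method": "direct",
            "small_field": [s < 2.0 for s in sides],
        }
    )
    return sf.FOFTable(detector_id=detector_id, frame=frame)


@pytest.fixture
def erf_profile(symmetric_beam):
    """A 3 cm erf-edge profile at 10 cm depth, CAX-normalized."""
    profile = sf.true_profile(symmetric_beam, 3.0, 100.0)
    return sf.normalize_to_cax(profile)
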