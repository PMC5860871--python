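import numpy as np
import pytest

import boldadapt as ba
from boldadapt.pipeline import PipelineConfig


@pytest.fixture(scope="session")
def hrf():
    return ba.TwoGammaHRF()


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def tiny_design():
    """Small, fast cohort layout: 4^3 grid, 4 trials/block, short gaps."""
    return ba.CohortDesign(grid_shape=(4, 4, 4), n_trials=4, gap_s=10.0, tail_s=20.0)


@pytest.fixture(scope="session")
def noiseless():
    return ba.NoiseSpec(sigma=0.0, drift_amp=0.0, spatial_fwhm_mm=0.0)


@pytest.fixture(scope="session")
def homogeneous_truth():
    shape = (4, 4, 4)
    return ba.GroundTruth(
        a_map=np.full(shape, 0.5),
        b_map=np.full(shape, 1.0),
        tau_map=np.full(shape, 4.0),
    )


@pytest.fixture(scope="session")
def raw_config(tiny_design):
    """Pipeline config with preprocessing off (raw forward model)."""
    return PipelineConfig(
        design=tiny_design,
        do_detrend=False,
        do_zscore=False,
        do_smooth=False,
    )
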