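import numpy as np
import pytest

from actitrial.synth import TrialConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def noiseless_config():
    """Deterministic trial: no variance components, no dropout, no outliers."""
    return TrialConfig(
        n_per_arm=5,
        participant_sd=0.0,
        residual_sd=0.0,
        skew_outlier_rate=0.0,
        dropout_rate=0.0,
        sedentary_sd=0.0,
        steps_base_sd=0.0,
        steps_day_sd=0.0,
        baseline_mean_by_arm={"IG": 40.0, "DG": 60.0},
        true_secular_trend={0: 0.0, 13: 5.0, 26: 8.0, 39: 3.0},
        true_exposure_effects={0: 0.0, 12: 13.0, 25: 6.0, 38: 4.0},
        seed=1,
    )


@pytest.fixture
def paper_scale_config():
    """Stochastic trial at realistic scale (tens of min/day, skewed days)."""
    return TrialConfig(
        n_per_arm=25,
        participant_sd=35.0,
        residual_sd=25.0,
        true_secular_trend={0: 0.0, 13: 2.0, 26: 4.0, 39: 1.0},
        true_exposure_effects={0: 0.0, 12: 13.0, 25: 6.0, 38: 3.0},
        seed=7,
    )
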