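import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pmnet import synth

settings.register_profile(
    "suite", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def campaign():
    """Default full-scale campaign, minute resolution, hygroscopic growth on."""
    return synth.simulate_campaign(synth.GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def campaign_nogrowth():
    """Full-scale campaign with the humidity bias switched off: the affine
    sensor biases are then exact ground truth for calibration recovery."""
    return synth.simulate_campaign(synth.GeneratorConfig(seed=1, growth_enabled=False))


@pytest.fixture(scope="session")
def fast_campaign():
    """Hour-resolution campaign for tests that only need hourly structure."""
    return synth.simulate_campaign(synth.GeneratorConfig(seed=0, time_resolution="hour"))


def phase_wide(campaign, phase: str) -> pd.DataFrame:
    """Hour x sensor matrix of one study phase."""
    from pmnet import core

    start, end = getattr(campaign.config.periods, phase)
    h = campaign.hourly
    return core.to_wide(h[(h["hour_start"] >= start) & (h["hour_start"] < end)])


@pytest.fixture(scope="session")
def small_config():
    """Short three-phase campaign for fast minute-resolution tests."""
    periods = synth.StudyPeriods(
        pre=(pd.Timestamp("2016-11-10"), pd.Timestamp("2016-11-12")),
        deployment=(pd.Timestamp("2016-12-01"), pd.Timestamp("2016-12-06")),
        post=(pd.Timestamp("2016-12-10"), pd.Timestamp("2016-12-12")),
    )
    return synth.GeneratorConfig(seed=7, periods=periods)
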