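import datetime as dt

import pytest

from nesttorpor import SimConfig, sun_times


@pytest.fixture(scope="session")
def site_sun():
    """Sun times at the colony site for a mid-season date."""
    return sun_times(51.0411, 7.8267, dt.date(2017, 6, 20), 2.0)


@pytest.fixture()
def quiet_config():
    """Config with all noise sources off (deterministic physics only)."""
    return SimConfig(
        mr_noise_sd=0.0,
        sensor_noise_sd=0.0,
        ambient_noise_sd=0.0,
        day_jitter_sd=0.0,
        cold_day_prob=0.0,
    )


@pytest.fixture()
def default_config():
    return SimConfig()


@pytest.fixture(scope="session")
def tiny_season():
    """One small noisy season shared by read-only tests."""
    from nesttorpor import simulate_season

    config = SimConfig(
        n_nests=3,
        season_start=dt.date(2017, 6, 1),
        season_end=dt.date(2017, 6, 12),
        torpor_probability=0.35,
        seed=11,
    )
    return simulate_season(config)
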