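import datetime as dt

import numpy as np
import pytest

from dayspace.config import SyntheticConfig
from dayspace.gps import GpsTrack
from dayspace.synthetic import generate_environment, generate_participant_roster


def make_track(t, x, y, imputed=None, pid="P000", wave="T1", date=dt.date(2017, 1, 9)):
    n = len(t)
    if imputed is None:
        imputed = np.zeros(n, dtype=bool)
    day_type = "weekend" if date.weekday() >= 5 else "weekday"
    return GpsTrack(pid, wave, date, day_type, np.asarray(t), np.asarray(x, dtype=float),
                    np.asarray(y, dtype=float), imputed)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_participants=4, region_extent=2000.0, block_size=200.0,
                           tract_size=500.0, n_parks=2, seed=7)


@pytest.fixture(scope="session")
def small_env(small_config):
    return generate_environment(small_config)


@pytest.fixture(scope="session")
def small_roster(small_config):
    return generate_participant_roster(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
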