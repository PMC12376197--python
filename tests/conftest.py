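import warnings

import numpy as np
import pandas as pd
import pytest

from pmdecode import synthdata as sd

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_network():
    """15 stations / 5 counties, fixed seed."""
    return sd.generate_station_network(15, 5, seed=11)


@pytest.fixture(scope="session")
def two_year_dates():
    return pd.date_range("2013-01-01", "2014-12-31", freq="D")


@pytest.fixture(scope="session")
def small_world(small_network, two_year_dates):
    """Stations + meteorology + emission + PM with a smooth met response."""
    stations, counties = small_network
    met = sd.generate_meteorology(stations, two_year_dates, seed=12)
    emission = sd.generate_emission_signal(stations, two_year_dates, seed=13)
    response = sd.make_met_response(stations, "smooth", seed=14)
    truth = sd.SyntheticTruth(emission, response, noise_sd=6.0)
    pm = sd.synthesize_pm(truth, met, seed=15)
    return {
        "stations": stations,
        "counties": counties,
        "dates": two_year_dates,
        "met": met,
        "truth": truth,
        "pm": pm,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
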