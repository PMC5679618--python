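import datetime as dt

import numpy as np
import pytest

from pondpredict import synthetic
from pondpredict.timeseries import PondSeries
from pondpredict.water_detection import PondObservation


def make_obs(pond_id=1, date="2000-01-01", area=0.0, area_max=None, cloud=0.0):
    if area_max is None:
        area_max = area if cloud == 0.0 else area + 900.0
    return PondObservation(pond_id, dt.date.fromisoformat(date), area, area_max, cloud)


@pytest.fixture
def never_dry_series() -> PondSeries:
    """27-year, 16-day-cadence series that is wet in every observation."""
    truth = synthetic.SeriesTruth(
        pond_id=1,
        seasonal=synthetic.cosine_seasonal(amplitude=0.4),
        noise_sd=0.15,
        dry_threshold=0.0,
        cloud_prob=0.4,
        seed=11,
    )
    series = synthetic.generate_pond_series(truth)
    assert all(o.area > 0 for o in series.cloud_free())
    return series


@pytest.fixture
def seasonal_series() -> PondSeries:
    """Strongly seasonal series: wet winter, dry summer."""
    truth = synthetic.SeriesTruth(
        pond_id=2,
        seasonal=synthetic.cosine_seasonal(amplitude=1.0, peak_doy=15),
        noise_sd=0.05,
        dry_threshold=0.9,
        cloud_prob=0.3,
        seed=7,
    )
    return synthetic.generate_pond_series(truth)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240904)
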