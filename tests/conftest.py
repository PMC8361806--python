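import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ftcdlat.model import BilingualLateralityModel
from ftcdlat.preprocess import EpochSet
from ftcdlat.synthetic import SyntheticConfig

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def epochset_factory():
    """Build an EpochSet directly from a (trials, time, 2) array."""

    def make(data, rate=25.0, t0=-11.0, stage="epoched", included=None, reasons=None):
        data = np.asarray(data, dtype=float)
        n_trials, n_time, _ = data.shape
        return EpochSet(
            data=data,
            time_axis=t0 + np.arange(n_time) / rate,
            included=(
                np.ones(n_trials, dtype=bool) if included is None
                else np.asarray(included, dtype=bool)
            ),
            reasons=list(reasons) if reasons is not None else [None] * n_trials,
            stage=stage,
            sample_rate=rate,
        )

    return make


@pytest.fixture
def study1_epochs(epochset_factory):
    """Full-length study-1 epochs (-11..30 s at 25 Hz): left-right
    difference of 2.0 in the POI, zero elsewhere, plus distinct trials."""

    def make(diffs=(2.0, 2.0, 2.0), base=100.0):
        rate, t0 = 25.0, -11.0
        n_time = int(round(41 * rate))
        t = t0 + np.arange(n_time) / rate
        poi = (t >= 8.0) & (t < 20.0)
        data = np.full((len(diffs), n_time, 2), base)
        for i, d in enumerate(diffs):
            data[i, poi, 0] += d
        return epochset_factory(data, rate=rate, t0=t0)

    return make


@pytest.fixture(scope="session")
def small_cohort_fit():
    """A fitted 6-participant, two-language synthetic cohort."""
    model = BilingualLateralityModel.from_synthetic(
        SyntheticConfig(n_participants=6, seed=5)
    )
    return model, model.fit()
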