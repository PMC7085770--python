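import numpy as np
import pytest

from prefall.activities import ADL_ACTIVITIES, FALL_ACTIVITIES
from prefall.activity_scripts import make_script
from prefall.signals import ImuSeries
from prefall.synthetic import NoiseModel, SyntheticTrial, synthesize


def make_static_series(
    n: int = 200,
    rate_hz: float = 100.0,
    acc=(0.0, 0.0, 1.0),
    gyr=(0.0, 0.0, 0.0),
) -> ImuSeries:
    """A constant-input series (quiet posture, optionally with gyro bias)."""
    t = np.arange(n) / rate_hz
    return ImuSeries(t, np.tile(acc, (n, 1)), np.tile(gyr, (n, 1)), rate_hz)


def random_trial(seed: int, noise: NoiseModel | None = None) -> SyntheticTrial:
    """One jittered trial of a randomly chosen study activity."""
    rng = np.random.default_rng(seed)
    activity = (ADL_ACTIVITIES + FALL_ACTIVITIES)[rng.integers(0, 20)]
    script = make_script(activity, rng)
    nm = noise or NoiseModel(seed=seed, gyro_bias=tuple(rng.uniform(-1, 1, 3)))
    return synthesize(script, nm)


@pytest.fixture(scope="session")
def quiet_standing_series() -> ImuSeries:
    """Quiet standing with realistic sensor noise (sigma 0.02 g / 0.5 dps)."""
    rng = np.random.default_rng(42)
    n, rate = 1000, 100.0
    t = np.arange(n) / rate
    acc = np.tile((0.0, 0.0, 1.0), (n, 1)) + rng.normal(0, 0.02, (n, 3))
    gyr = rng.normal(0, 0.5, (n, 3))
    return ImuSeries(t, acc, gyr, rate)
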