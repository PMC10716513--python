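import numpy as np
import pytest

import popgaze as pg
from popgaze.simulate import draw_infants


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_schedule():
    return pg.generate_schedule(seed=1)


@pytest.fixture(scope="session")
def small_params():
    """Two-infant cohort with realistic noise/missingness."""
    return pg.SimulationParams(n_infants_per_age=1)


@pytest.fixture(scope="session")
def clean_params():
    """Noise- and missingness-free conditions (ground truth still random)."""
    return pg.SimulationParams(n_infants_per_age=1).noise_free()


@pytest.fixture
def one_infant(clean_params):
    return draw_infants(clean_params, np.random.default_rng(7))[0]


def make_series(t, sound_onset_s=0.75, visual_onset_s=1.0,
                visual_offset_s=4.0, **channels):
    """Hand-built series: unspecified channels default to zeros (gaze) /
    4 mm (pupil)."""
    n = len(t)
    defaults = {"lx": np.zeros(n), "ly": np.zeros(n),
                "rx": np.zeros(n), "ry": np.zeros(n),
                "lp": np.full(n, 4.0), "rp": np.full(n, 4.0)}
    defaults.update({k: np.asarray(v, float) for k, v in channels.items()})
    return pg.EyeSampleSeries(t=np.asarray(t, float), **defaults,
                              sound_onset_s=sound_onset_s,
                              visual_onset_s=visual_onset_s,
                              visual_offset_s=visual_offset_s,
                              infant_id="x", trial_index=1)


@pytest.fixture
def series_factory():
    return make_series
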