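import warnings

import numpy as np
import pandas as pd
import pytest

from denshab.grids import GridSpec
from denshab.synthetic_world import (DEFAULT_LAYER_SPECS, generate_landscape,
                                     simulate_recolonization, simulate_telemetry,
                                     simulate_track_survey)

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec(0.0, 0.0, 2.0, 60, 60)  # 120 x 120 km


@pytest.fixture(scope="session")
def landscape(small_grid):
    return generate_landscape(small_grid, DEFAULT_LAYER_SPECS, seed=11)


@pytest.fixture(scope="session")
def world(landscape):
    """A 15-year IPD recolonization (~15 packs) shared across tests."""
    return simulate_recolonization(
        landscape, years=15, growth={"N0": 8.0, "K": 64.0, "r": 0.4}, seed=5)


@pytest.fixture(scope="session")
def telemetry(world):
    return simulate_telemetry(world, fixes_per_pack_year=40,
                              collared_fraction=0.8, seed=7)


@pytest.fixture(scope="session")
def survey(world):
    return simulate_track_survey(world, detection_prob=1.0,
                                 panel_gap_years={9}, seed=13)


def locations_frame(xy, pack_id="p1", year=0):
    xy = np.asarray(xy, float)
    return pd.DataFrame({"pack_id": pack_id, "year": year,
                         "x_km": xy[:, 0], "y_km": xy[:, 1]})
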