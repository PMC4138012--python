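import numpy as np
import pytest

from batscape.calibration import classify_records, fit_rma
from batscape.config import SyntheticConfig
from batscape.raster import Isoscape
from batscape.synthetic import make_world


@pytest.fixture(scope="session")
def world():
    """Default synthetic study world, seed 0 (shared, read-only)."""
    return make_world(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def rma(world):
    return fit_rma(world.calib_precip, world.calib_fur)


@pytest.fixture(scope="session")
def classified(world, rma):
    return classify_records(world.records, world.sites, rma)


@pytest.fixture()
def toy_isoscape():
    """3x3 isoscape over 51-54N, 10-13E with one no-data cell."""
    vals = np.array(
        [[-80.0, -78.0, -76.0], [-70.0, -68.0, -66.0], [-60.0, np.nan, -56.0]]
    )
    return Isoscape(values=vals, lat_max=54.0, lon_min=10.0, cell_arcmin=60.0)
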