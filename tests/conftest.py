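import numpy as np
import pytest

from fretflux.kinetics import ConcentrationSeries, KineticParams
from fretflux.protocols import get_protocol
from fretflux.render import EllipseCell, NoiseModel, ScenePhantom, render_movie
from fretflux.sensors import LACONIC


@pytest.fixture
def params():
    return KineticParams()


@pytest.fixture
def mct_block():
    return get_protocol("mct_block")


@pytest.fixture
def single_cell_scene():
    """One bright elliptical cell centred in a small frame."""
    return ScenePhantom(
        shape=(64, 64),
        cells=(EllipseCell(32.0, 32.0, 6.0, 8.0, 100.0),),
        background=2.0,
    )


@pytest.fixture
def constant_series():
    """Flat 1 mM lactate / 2 mM glucose over 60 s."""
    t = np.arange(0.0, 61.0, 1.0)
    return ConcentrationSeries(t=t, lac_in=np.full_like(t, 1.0), glc_in=np.full_like(t, 2.0))


@pytest.fixture
def noiseless_movie(constant_series, single_cell_scene):
    return render_movie(constant_series, LACONIC, single_cell_scene, NoiseModel.none(), 2.0)
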