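import numpy as np
import pytest

from hasec import (
    ColumnGeometry,
    SimulationSpec,
    fit_concentration_curve,
    simulate_standard_sets,
)
from hasec.pipeline import fit_mw_curve_from_table


@pytest.fixture
def geom():
    """Ultrahydrogel-2000-like geometry with volume-consistent times."""
    return ColumnGeometry.ultrahydrogel_2000()


@pytest.fixture
def geom_printed_times():
    """Same column with the instrument-reported void time of 6.00 min."""
    return ColumnGeometry(
        v0_ml=6.87, vt_ml=13.75, vc_ml=14.34, flow_ml_min=0.8,
        t0_min=6.00, tt_min=17.1875,
    )


@pytest.fixture
def make_spec():
    def _make(**kwargs):
        return SimulationSpec(**kwargs)

    return _make


@pytest.fixture
def mw_fit(make_spec):
    """Noiseless MW calibration fit recovering the simulator's true Kav law."""
    spec = make_spec()
    tables = simulate_standard_sets(spec)
    return fit_mw_curve_from_table(tables["mw"], spec.geom)


@pytest.fixture
def conc_fit(make_spec):
    """Noiseless concentration calibration (area = response_factor * conc)."""
    spec = make_spec()
    tables = simulate_standard_sets(spec)
    grp = tables["concentration"].query("standard_mw_da == 1.125e6")
    return fit_concentration_curve(
        list(zip(grp["concentration_mg_L"], grp["peak_area"]))
    )


@pytest.fixture
def gaussian_chromatogram():
    """Unit-area Gaussian peak (apex 11.0 min, sigma 0.2) on a fine grid."""
    from hasec import Chromatogram

    t = np.linspace(8.0, 14.0, 6001)
    sig = np.exp(-0.5 * ((t - 11.0) / 0.2) ** 2) / (0.2 * np.sqrt(2 * np.pi))
    return Chromatogram(t, sig, {"label": "gaussian"})
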