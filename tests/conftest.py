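import numpy as np
import pytest

import ringanchor as ra


@pytest.fixture
def linear_curve():
    """Calibration curve falling 1 14C yr per calendar year, sigma 10."""
    grid = np.arange(900, 1101)
    return ra.CalCurve(grid, 2000.0 - grid, np.full(grid.shape, 10.0), name="linear")


@pytest.fixture
def spike_scenario():
    return ra.SpikeScenario()


@pytest.fixture
def spike_reference(spike_scenario):
    return ra.make_reference(spike_scenario)


@pytest.fixture
def toy_intcal_file(tmp_path):
    """Two-node curve: cal BP 950 -> 1000+-10, cal BP 900 -> 950+-10."""
    path = tmp_path / "toy_curve.14c"
    path.write_text(
        "# toy calibration curve\n"
        "# cal BP, 14C age, sigma\n"
        "950, 1000, 10\n"
        "900, 950, 10\n"
    )
    return path


def make_series(item_id, rings, ages, sigmas):
    return ra.RingSeries(
        item_id,
        np.asarray(rings, dtype=int),
        np.asarray(ages, dtype=float),
        np.asarray(sigmas, dtype=float),
    )


@pytest.fixture
def series_factory():
    return make_series
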