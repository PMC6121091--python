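import numpy as np
import pytest

from aquaphot.dataset import SpectraSet, WavelengthGrid, make_meta
from aquaphot.design import generate_measurement_plan
from aquaphot.synthetic import default_grid, default_model, simulate_dataset


def build_set(intensities, grid=None, groups=None, unit="absorbance", **meta_kw):
    """Small SpectraSet helper for hand-built matrices."""
    x = np.atleast_2d(np.asarray(intensities, dtype=float))
    n = x.shape[0]
    if grid is None:
        grid = WavelengthGrid(1300.0 + 10.0 * np.arange(x.shape[1]))
    records = []
    for i in range(n):
        rec = {
            "sample_id": f"s{i}",
            "replicate": 1,
            "consecutive": 1,
            "group": groups[i] if groups is not None else "g",
        }
        for k, v in meta_kw.items():
            rec[k] = v[i]
        records.append(rec)
    return SpectraSet(grid, x, make_meta(records), unit)


@pytest.fixture(scope="session")
def kcl_design():
    """The worked-example measurement plan: 10 levels × 2 replicates ×
    3 consecutives with a water control every 5 samples."""
    return generate_measurement_plan(
        n_levels=10, n_replicates=2, n_consecutives=3, control_interval=5,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def kcl_lownoise(kcl_design):
    """Low-noise synthetic salt series on the worked-example design."""
    model = default_model(noise_sd=1e-4, scatter_sd=0.005,
                          consecutive_drift=0.05)
    mapping = {lvl: 10.0 * lvl for lvl in range(1, 11)}
    return simulate_dataset(model, kcl_design, mapping, t_nominal=28.0)


@pytest.fixture(scope="session")
def grid601():
    return default_grid()
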