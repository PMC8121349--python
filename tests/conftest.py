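import numpy as np
import pandas as pd
import pytest

from krillspot.spde import build_mesh
from krillspot.synthetic import make_covariates, make_domain


@pytest.fixture(scope="session")
def small_grid():
    """A small synthetic domain (90 x 60 km) with covariates."""
    return make_covariates(make_domain(90.0, 60.0, 3.0), seed=0)


@pytest.fixture(scope="session")
def small_mesh():
    """A coarse mesh over the small domain."""
    rng = np.random.default_rng(7)
    locs = np.c_[rng.uniform(4, 86, 150), rng.uniform(4, 56, 150)]
    return build_mesh(locs, n_knots=30, cutoff_km=8.0, seed=0)


@pytest.fixture(scope="session")
def tiny_mesh():
    """A minimal mesh (few nodes) for dense-oracle comparisons."""
    pts = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0], [10.0, 10.0],
                    [5.0, 5.0]])
    return build_mesh(pts, n_knots=5, cutoff_km=1.0, buffer_km=6.0, seed=0)


@pytest.fixture()
def haul_frame():
    """A tiny hand-built long-format haul table."""
    rows = []
    for i, (yr, mo, day, bot, samp) in enumerate([
        (2005, 6, True, 200.0, 190.0),
        (2005, 7, True, 80.0, 78.0),
        (2010, 5, True, 300.0, 250.0),
    ]):
        for sp, st, sex, cnt in [
            ("E_pacifica", "S4", "female", 20.0),
            ("T_spinifera", "S4", "male", 10.0),
            ("E_pacifica", "s1", "", 30.0),
        ]:
            rows.append({
                "haul_id": f"H{i}", "station_id": f"S{i}", "year": yr,
                "month": mo, "x_km": 10.0 * i, "y_km": 5.0 * i,
                "bottom_depth_m": bot, "sampling_depth_m": samp,
                "volume_m3": 100.0, "daylight": day,
                "species": sp, "stage": st, "sex": sex,
                "count_per_haul": cnt, "subsample_fraction": 1.0,
            })
    return pd.DataFrame(rows)
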