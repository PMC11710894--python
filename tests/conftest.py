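import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import preyscape as ps
from preyscape import occupancy as occ
from preyscape import preprocess

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_landscape():
    cfg = ps.SimulationConfig(n_sites=300, grid_rows=25, grid_cols=25)
    return cfg, ps.simulate_landscape(cfg, seed=42)


@pytest.fixture(scope="session")
def willow_fit():
    """A converged willow-type removal fit on 400 synthetic sites, reused by
    inference/mapping tests."""
    cfg = ps.SimulationConfig(n_sites=400, grid_rows=30, grid_cols=30)
    land = ps.simulate_landscape(cfg, seed=7)
    sites = ps.simulate_sites(cfg, land, seed=8)
    scaler = preprocess.Scaler.fit(
        sites, columns=["tundra", "tussock", "tall_shrub", "elevation",
                        "day_of_year", "time_of_day", "wind_kmh"])
    counts = ps.simulate_point_counts(cfg, scaler.transform(sites), seed=9)
    data = ps.RemovalCountTable(site_id=counts.site_id, counts=counts.counts,
                                covariates=sites, latent_n=counts.latent_n)
    spec = ps.RemovalModelSpec(
        abundance=["tundra", "tussock", "tall_shrub", "elevation"],
        detection=["day_of_year", "time_of_day", "wind_kmh"])
    fit = ps.fit_removal(data, spec, seed=0)
    assert fit.convergence["converged"]
    return cfg, land, data, fit


@pytest.fixture(scope="session")
def occ_data_small():
    """Territory histories for 97 territories under the default design."""
    cfg = ps.SimulationConfig(n_territories=97)
    rng = np.random.default_rng(5)
    dens = pd.DataFrame({
        "territory_id": [f"t{i:03d}" for i in range(97)],
        "willow": rng.normal(0, 1, 97),
        "rock": rng.normal(0, 1, 97),
        "ags": rng.normal(0, 1, 97)})
    hist = ps.simulate_territory_histories(cfg, dens, seed=7)
    data = occ.OccupancyData.from_frames(
        hist, dens, occ.OccupancyModelSpec(density_cols=["willow", "rock", "ags"]))
    return cfg, dens, hist, data


@pytest.fixture(scope="session")
def occ_fit_small(occ_data_small):
    _, _, _, data = occ_data_small
    fit = occ.fit_occupancy(data, seed=0, n_starts=1)
    return fit
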