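"""Project a fitted abundance model onto the landscape and aggregate prey
density inside predator territories.

Cells above 500 m elevation or with covariates outside the training range
are masked; the study-area total comes with a CI from coefficient draws;
territory densities divide summed expected counts by the mask-corrected
territory area (animals per km^2).
"""

import numpy as np

import preyscape as ps

cfg = ps.SimulationConfig(n_sites=400, grid_rows=30, grid_cols=30)
landscape = ps.simulate_landscape(cfg, seed=1)
sites = ps.simulate_sites(cfg, landscape, seed=2)
scaled, _ = ps.standardize(sites, columns=[
    "tundra", "tussock", "tall_shrub", "elevation",
    "day_of_year", "time_of_day", "wind_kmh"])
counts = ps.simulate_point_counts(cfg, scaled, seed=3)
data = ps.RemovalCountTable(site_id=counts.site_id, counts=counts.counts,
                            covariates=sites)
spec = ps.RemovalModelSpec(
    abundance=["tundra", "tussock", "tall_shrub", "elevation"],
    detection=["day_of_year", "time_of_day", "wind_kmh"])
fit = ps.fit_removal(data, spec, seed=0)

grid = ps.build_prediction_grid(landscape, fit.scaler, fit.train_ranges,
                                fit.spec.abundance)
n_masked = int((~grid.table["valid"]).sum())
print(f"{grid.n_cells} cells, {n_masked} masked "
      "(elevation > 500 m or covariate out of training range)")

surface = ps.map_density(fit, grid, species="willow", n_draws=5000, seed=4)
per_cell = surface.table["mean"]
print(f"density per 0.64 km^2 cell: mean {per_cell.mean():.2f}, "
      f"range {per_cell.min():.2f}-{per_cell.max():.2f}")
print(f"per km^2: mean {ps.density_unit_convert(per_cell.mean()):.2f}")

total = ps.total_abundance(surface, n_draws=5000, seed=5)
print(f"study-area abundance {total['estimate']:.0f} "
      f"(95% CI {total['lower']:.0f}-{total['upper']:.0f})")

rng = np.random.default_rng(6)
centers = rng.uniform(2000, 22000, size=(5, 2))
for i, (x, y) in enumerate(centers):
    terr = ps.territory_from_center(grid, f"t{i}", (x, y), radius_m=5000)
    if terr.n_cells == 0:
        print(f"territory t{i}: fully masked, excluded")
        continue
    out = ps.territory_density(surface, terr, grid)
    print(f"territory t{i}: {out['density_per_km2']:.2f} males/km^2 over "
          f"{out['corrected_area_km2']:.1f} km^2 ({out['n_cells']} cells)")
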