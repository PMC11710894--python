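# preyscape

Prey abundance from time-removal point counts, density mapping, and
predator territory occupancy — a tested Python implementation of the
two-stage inference chain used in Arctic raptor-prey field studies (small
herbivores such as ptarmigan and ground squirrels as prey; a cliff-nesting
falcon as the predator).

**Who it is for.** Quantitative ecologists who have (or want to simulate)
point-count surveys split into removal intervals, gridded habitat
covariates, and multi-year detection/non-detection records at predator
territories, and who want abundance, density surfaces and
occupancy-vs-prey relationships with honest uncertainty.

## The models

**Abundance (N-mixture time-removal).** Site abundance
N_i ~ Poisson(λ_i), log λ_i = β′x_i + log A, with the surveyed area A as
an offset so exp(β′x) is density per km². A 10-min count is split into
five 2-min intervals; an individual is first detected in interval j with
probability π_j = p(1−p)^(j−1), logit p = α′w (date, time of day, wind,
observer). With Poisson mixing the interval counts are independent
Poisson with means λ_i π_j (multinomial–Poisson factorization), which is
the closed-form likelihood maximized here; the brute-force latent-N sum
is kept as a cross-checking oracle. Fit quality is assessed by parametric
bootstrap of Pearson's χ² and the dispersion ratio ĉ.

**Density mapping.** Fitted models are projected onto an 800 m lattice
(0.64 km² cells), masking cells above 500 m elevation or outside the
training covariate ranges; totals and intervals come from coefficient
draws. Prey density inside each predator territory is the summed expected
count of its unmasked cells divided by the mask-corrected area.

**Occupancy.** Each territory-year is a unit:
z_it ~ Bernoulli(ψ_it), logit ψ_it = γ′d_i + u_t with prey densities d_i
and a year random intercept; detections
y_ijt | z_it ~ Bernoulli(z_it p_ijt), logit p_ijt = δ₀ + δ₁·day + v_i
with a territory random intercept. The crossed random effects are
integrated by adaptive Gauss–Hermite quadrature over territories nested
inside a Laplace step over the (few, data-rich) year effects.
MacKenzie–Bailey bootstrap GOF on detection-history tallies.

A first-class synthetic-data generator reproduces the survey design (983
sites, 5 × 2-min intervals, 97 territories × 6 seasons × 2 surveys with
~60 missing) so the entire chain is testable without field data.

## Worked example

```python
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
fit = ps.fit_removal(data, ps.RemovalModelSpec(
    abundance=["tundra", "tussock", "tall_shrub", "elevation"],
    detection=["day_of_year", "time_of_day", "wind_kmh"]), seed=0)
print(ps.coefficient_table(fit).round(3))

grid = ps.build_prediction_grid(landscape, fit.scaler, fit.train_ranges,
                                fit.spec.abundance)
surface = ps.map_density(fit, grid, n_draws=5000, seed=4)
total = ps.total_abundance(surface, n_draws=5000, seed=5)
print(f"total {total['estimate']:.0f} "
      f"(95% CI {total['lower']:.0f}-{total['upper']:.0f})")
```

prints (abridged):

```
            coefficient  estimate     se  lower  upper  significant
    abundance:intercept     0.623  0.135  0.360  0.887         True
       abundance:tundra     0.574  0.153  0.273  0.875         True
      abundance:tussock     0.157  0.170 -0.177  0.491        False
   abundance:tall_shrub     0.369  0.148  0.080  0.658         True
    detection:intercept    -1.633  0.264 -2.150 -1.117         True
...
total 984 (95% CI 760-1288)
```

The abundance intercept is the log density (males/km²) at average
habitat — exp(0.62) ≈ 1.9 males/km² here; positive tundra and tall-shrub
coefficients mean higher density where those covers are above average
(covariates are standardized by two standard deviations, so effects are
per ~2 SD of cover). The total is the summed expected count over the
unmasked study-area cells with a draw-based interval.

The `examples/` directory has one narrative script per capability
(abundance fitting, bootstrap GOF, density mapping and territory
aggregation, the occupancy model, and the end-to-end pipeline); each
prints its numbers with a line on what they mean. A thin CLI wraps the
same functions (`preyscape run-all --seed 1 --out bundle/`,
`preyscape fit-abundance ...`; see `preyscape --help`).

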