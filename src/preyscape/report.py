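"""Summary tables, presentation rounding, and the end-to-end pipeline.

``run_pipeline`` chains every stage on synthetic data: landscape ->
point counts for three species -> covariate screening/filtering ->
removal-model fits -> bootstrap GOF -> density surfaces -> territory prey
densities -> occupancy fit -> MacKenzie-Bailey GOF -> summary report.
Every stage logs its seed and elapsed time; all randomness derives from a
single pipeline seed via numpy SeedSequence spawning, so a config plus seed
reproduces the bundle exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import density as dens_mod
from . import occupancy as occ_mod
from . import preprocess, removal, simulate

__all__ = [
    "summarize_counts",
    "proximity_report",
    "present",
    "PipelineConfig",
    "run_pipeline",
]

log = logging.getLogger("preyscape")


def present(value: float, decimals: int = 2) -> float:
    """Presentation rounding (round-half-even); serialized values stay at
    full precision, this is only for printed summaries."""
    return float(np.round(float(value), decimals))


def summarize_counts(counts, grouping: str = "year") -> pd.DataFrame:
    """Tally individuals counted and points with >= 1 detection per group.

    ``counts`` is a :class:`~preyscape.simulate.RemovalCountTable` whose
    covariates include the grouping column, or a DataFrame with the
    grouping column plus either interval columns (y1..yJ) or a ``count``
    column per site. Returns one row per group plus a TOTAL row.
    """
    if isinstance(counts, simulate.RemovalCountTable):
        if grouping not in counts.covariates.columns:
            raise ValueError(f"no {grouping!r} column in covariates")
        frame = pd.DataFrame({grouping: counts.covariates[grouping],
                              "count": counts.site_totals()})
    else:
        frame = counts.copy()
        if grouping not in frame.columns:
            raise ValueError(f"no {grouping!r} column")
        if "count" not in frame.columns:
            ycols = [c for c in frame.columns
                     if c.startswith("y") and c[1:].isdigit()]
            if not ycols:
                raise ValueError("need a 'count' column or y1..yJ columns")
            frame["count"] = frame[ycols].sum(axis=1)
    if len(frame) == 0:
        return pd.DataFrame(columns=[grouping, "individuals", "points"])
    tally = frame.groupby(grouping, sort=True).agg(
        individuals=("count", "sum"),
        points=("count", lambda s: int((s > 0).sum()))).reset_index()
    total = pd.DataFrame({grouping: ["TOTAL"],
                          "individuals": [tally["individuals"].sum()],
                          "points": [tally["points"].sum()]})
    return pd.concat([tally, total], ignore_index=True)


def proximity_report(site_distances, threshold_m: float = 200.0) -> dict:
    """Count and percentage of sites closer than ``threshold_m`` to a
    feature (e.g. the nearest road); percentage reported to one decimal."""
    d = np.asarray(site_distances, float)
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    below = int((d < threshold_m).sum())
    pct = present(100.0 * below / len(d), 1) if len(d) else 0.0
    return {"n_below": below, "n_total": int(len(d)),
            "percent_below": pct, "threshold_m": float(threshold_m)}


# ---------------------------------------------------------------------------
# pipeline


@dataclasses.dataclass
class PipelineConfig:
    """One config object that drives the whole synthetic pipeline."""

    out_dir: str = "pipeline_out"
    seed: int = 1
    species: tuple = ("willow", "rock", "ags")
    n_sites: int = 983
    n_territories: int = 97
    grid_rows: int = 60
    grid_cols: int = 60
    territory_radius_km: float = 15.0   # aggregation radius; no silent default downstream
    bootstrap_B: int = 100
    run_gof: bool = True
    mvn_draws: int = 5000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "species" in raw:
            raw["species"] = tuple(raw["species"])
        return cls(**raw)


def _stage(name: str):
    log.info("stage=%s starting", name)
    return time.perf_counter()


def _done(name: str, t0: float) -> None:
    log.info("stage=%s elapsed=%.2fs", name, time.perf_counter() - t0)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write versioned outputs under ``config.out_dir``.

    Returns a dict of results (also serialized as report.json). Any stage
    failure raises with the stage name in the message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(10)
    stage_seed = {name: int(s.generate_state(1)[0] % (2 ** 31))
                  for name, s in zip(
        ["landscape", "sites", "counts", "fit", "gof", "map",
         "territories", "histories", "occupancy", "occ_gof"], seeds)}
    report: dict = {"seed": config.seed, "stage_seeds": stage_seed}

    base_cfg = simulate.SimulationConfig(
        n_sites=config.n_sites, n_territories=config.n_territories,
        grid_rows=config.grid_rows, grid_cols=config.grid_cols)

    t0 = _stage("landscape")
    landscape = simulate.simulate_landscape(base_cfg, seed=stage_seed["landscape"])
    landscape.to_csv(out / "landscape.csv")
    _done("landscape", t0)

    t0 = _stage("sites")
    sites = simulate.simulate_sites(base_cfg, landscape, seed=stage_seed["sites"])
    sites, elev_report = preprocess.filter_sites_by_elevation(sites)
    flagged = preprocess.screen_collinearity(
        sites[["tundra", "tussock", "tall_shrub", "low_shrub", "sparse",
               "elevation"]])
    report["sites"] = {**elev_report,
                       "collinearity_flags": [
                           {"pair": list(f["pair"]), "r": None if pd.isna(f["r"])
                            else float(f["r"])} for f in flagged]}
    _done("sites", t0)

    # standardize habitat + survey covariates once per species model inside fit
    species_results = {}
    surfaces = {}
    sim_cfgs = {}
    t0 = _stage("counts+fit")
    for k, sp in enumerate(config.species):
        cfg = simulate.SimulationConfig.for_species(
            sp, n_sites=len(sites), n_territories=config.n_territories,
            grid_rows=config.grid_rows, grid_cols=config.grid_cols)
        sim_cfgs[sp] = cfg
        # simulate on the standardized covariate scale used by the fit
        scaler = preprocess.Scaler.fit(
            sites, columns=[c for c in sites.columns
                            if c in set(list(cfg.abundance_coefs)
                                        + list(cfg.detection_coefs))])
        sites_std = scaler.transform(sites)
        counts = simulate.simulate_point_counts(
            cfg, sites_std, seed=stage_seed["counts"] + k)
        # refit from the raw-scale table so the fitted scaler is the real one
        raw_counts = simulate.RemovalCountTable(
            site_id=counts.site_id, counts=counts.counts, covariates=sites,
            interval_minutes=cfg.interval_minutes, latent_n=counts.latent_n)
        raw_counts.to_csv(out / f"counts_{sp}.csv")
        spec = removal.RemovalModelSpec(
            abundance=[c for c in cfg.abundance_coefs if c != "intercept"],
            detection=[c for c in cfg.detection_coefs if c != "intercept"])
        fit = removal.fit_removal(raw_counts, spec, seed=stage_seed["fit"] + k)
        fit.to_json(out / f"model_{sp}.json")
        res = {"loglik": fit.loglik, "converged": fit.convergence["converged"],
               "coefficients": removal.coefficient_table(fit).to_dict("records")}
        if config.run_gof:
            gof = removal.gof_parametric_bootstrap(
                fit, B=config.bootstrap_B, seed=stage_seed["gof"] + k)
            res["gof"] = {"p_value": gof.p_value, "c_hat": gof.c_hat,
                          "B": gof.B}
        species_results[sp] = {"fit": fit, "summary": res}
    report["abundance"] = {sp: r["summary"] for sp, r in species_results.items()}
    _done("counts+fit", t0)

    t0 = _stage("map")
    densities_summary = {}
    for sp, r in species_results.items():
        fit = r["fit"]
        grid = dens_mod.build_prediction_grid(
            landscape, fit.scaler, fit.train_ranges, fit.spec.abundance)
        surface = dens_mod.map_density(fit, grid, species=sp, method="mvn",
                                       n_draws=config.mvn_draws,
                                       seed=stage_seed["map"])
        surface.to_csv(out / f"surface_{sp}.csv")
        surfaces[sp] = (surface, grid)
        tot = dens_mod.total_abundance(surface, n_draws=config.mvn_draws,
                                       seed=stage_seed["map"] + 1)
        per_cell = surface.table["mean"]
        densities_summary[sp] = {
            "mean_per_cell": float(per_cell.mean()),
            "min_per_cell": float(per_cell.min()),
            "max_per_cell": float(per_cell.max()),
            "mean_per_km2": float(per_cell.mean() / surface.cell_area_km2),
            "total_abundance": tot,
            "n_valid_cells": surface.n_cells,
        }
    report["density"] = densities_summary
    _done("map", t0)

    t0 = _stage("territories")
    rng_t = np.random.default_rng(stage_seed["territories"])
    side = landscape.cell_side_m
    extent_x = config.grid_cols * side
    extent_y = config.grid_rows * side
    centers = np.column_stack([rng_t.uniform(0, extent_x, config.n_territories),
                               rng_t.uniform(0, extent_y, config.n_territories)])
    radius_m = config.territory_radius_km * 1000.0
    # each species model has its own covariate-range mask, so territories are
    # collected (and their areas corrected) against that species' grid
    terr_table = pd.DataFrame(
        {"territory_id": [f"t{i:03d}" for i in range(config.n_territories)]})
    excluded_any = np.zeros(config.n_territories, dtype=bool)
    for sp in config.species:
        surface, grid = surfaces[sp]
        terrs = [dens_mod.territory_from_center(
            grid, f"t{i:03d}", (centers[i, 0], centers[i, 1]), radius_m)
            for i in range(config.n_territories)]
        tab = dens_mod.territory_density_table({sp: surface}, terrs, grid)
        terr_table[sp] = tab[sp].to_numpy()
        terr_table[f"{sp}_corrected_area_km2"] = tab["corrected_area_km2"].to_numpy()
        excluded_any |= tab["excluded"].to_numpy()
    terr_table["excluded"] = excluded_any
    terr_table.to_csv(out / "territory_densities.csv", index=False)
    report["territories"] = {
        "n": config.n_territories,
        "n_excluded": int(excluded_any.sum()),
        "radius_km": config.territory_radius_km,
    }
    _done("territories", t0)

    t0 = _stage("occupancy")
    occ_cfg = sim_cfgs[config.species[0]]
    dens_cols = {"willow": "willow", "rock": "rock", "ags": "ags"}
    dens_in = terr_table[~terr_table["excluded"]][
        ["territory_id"] + list(config.species)].rename(columns=dens_cols)
    # occupancy simulation uses standardized densities, matching psi_coefs scale
    dscaler = preprocess.Scaler.fit(dens_in, columns=list(config.species))
    hist = simulate.simulate_territory_histories(
        occ_cfg, dscaler.transform(dens_in), seed=stage_seed["histories"])
    hist.to_csv(out / "histories.csv", index=False)
    if len(dens_in) < 2:
        raise RuntimeError("stage=occupancy: not enough territories with "
                           "valid prey densities")
    spec_occ = occ_mod.OccupancyModelSpec(density_cols=list(config.species))
    occ_data = occ_mod.OccupancyData.from_frames(hist, dens_in, spec_occ)
    occ_fit = occ_mod.fit_occupancy(occ_data, seed=stage_seed["occupancy"])
    occ_fit.to_json(out / "occupancy.json")
    means = occ_mod.mean_psi_p(occ_fit)
    report["occupancy"] = {
        "loglik": occ_fit.loglik,
        "sigma_year": occ_fit.sigma_year,
        "sigma_territory": occ_fit.sigma_territory,
        "boundary_year": occ_fit.boundary_year,
        "boundary_territory": occ_fit.boundary_territory,
        "mean_psi": means["mean_psi"], "mean_p": means["mean_p"],
        "flat_ridge": occ_fit.convergence["flat_ridge"],
        "coefficients": (occ_mod.occupancy_coefficient_table(
            occ_fit).to_dict("records") if occ_fit.cov is not None else None),
        "n_dropped_cells": occ_data.n_dropped_cells,
    }
    _done("occupancy", t0)

    if config.run_gof:
        t0 = _stage("occ_gof")
        occ_gof = occ_mod.mb_gof(occ_fit, B=config.bootstrap_B,
                                 seed=stage_seed["occ_gof"])
        report["occupancy"]["gof"] = {k: occ_gof[k] for k in
                                      ("p_value", "c_hat", "B")}
        _done("occ_gof", t0)

    (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    return report
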