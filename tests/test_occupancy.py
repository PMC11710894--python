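import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import preyscape as ps
from preyscape import occupancy as occ


def _frames(detected, days=None, density=0.3, n_surv=2):
    """Build one-territory history/density frames from a per-(year, survey)
    detection array (NaN = missing survey)."""
    detected = np.asarray(detected, float)
    n_years = detected.shape[0]
    rows = []
    for t in range(n_years):
        for j in range(detected.shape[1]):
            day = 140.0 + 10 * j if days is None else days[t][j]
            rows.append(("a", 2016 + t, j + 1, detected[t, j], day))
    hist = pd.DataFrame(rows, columns=["territory_id", "year", "survey_index",
                                       "detected", "day_of_year"])
    dens = pd.DataFrame({"territory_id": ["a"], "willow": [density]})
    return hist, dens


def _data(detected, **kw):
    hist, dens = _frames(detected, **kw)
    return occ.OccupancyData.from_frames(
        hist, dens, occ.OccupancyModelSpec(density_cols=["willow"],
                                           standardize=False))


class TestCellLikelihood:
    def test_no_detections_closed_form(self):
        # psi (1-p)^2 + (1-psi) with psi = p = 0.5
        assert occ.occupancy_cell_lik(0.5, [0.5, 0.5], [0, 0]) == \
            pytest.approx(0.5 * 0.25 + 0.5)

    def test_missing_survey_skipped(self):
        assert occ.occupancy_cell_lik(0.5, [0.5], [1, float("nan")]) == \
            pytest.approx(0.25)

    def test_certain_everything(self):
        assert occ.occupancy_cell_lik(1.0, [1.0, 1.0], [1, 1]) == 1.0

    def test_detection_without_probability_rejected(self):
        with pytest.raises(ValueError):
            occ.occupancy_cell_lik(0.5, [], [1])


class TestMarginalReductions:
    def test_zero_variance_equals_cell_product(self):
        data = _data([[1, 0], [0, 0], [1, 1]])
        g = np.array([0.2, 0.8])
        d = np.array([0.1, -0.02])
        ll = occ.marginal_loglik(g, d, 0.0, 0.0, data)
        brute = 0.0
        for c in range(len(data.y)):
            psi = expit(data.Xpsi[c] @ g)
            p = [expit(d[0] + d[1] * data.day[c, j])
                 for j in range(2) if data.obs[c, j]]
            h = [data.y[c, j] for j in range(2) if data.obs[c, j]]
            brute += math.log(occ.occupancy_cell_lik(psi, p, h))
        assert abs(ll - brute) < 1e-12

    @pytest.mark.parametrize("sigma", [0.5, 1.5, 2.7])
    def test_territory_factor_matches_61_node_quadrature(self, sigma):
        data = _data([[1, 0], [0, 0], [1, 1], [0, 1]])
        g = np.array([0.2, 0.8])
        d = np.array([0.1, -0.02])
        prod = occ.marginal_loglik(g, d, 0.0, sigma, data)
        oracle = occ.agh_marginal_loglik(g, d, sigma, data,
                                         factor="territory")
        assert abs(prod - oracle) < 1e-4

    def test_year_factor_matches_quadrature(self, occ_data_small):
        _, _, _, data = occ_data_small
        g = np.array([0.1, 1.0, 0.4, 0.7])
        d = np.array([0.1, -0.5])
        prod = occ.marginal_loglik(g, d, 0.7, 0.0, data)
        oracle = occ.agh_marginal_loglik(g, d, 0.7, data, factor="year")
        assert abs(prod - oracle) < 1e-3

    def test_joint_laplace_close_to_nested_agh(self, occ_data_small):
        # two independent integration schemes for the crossed case
        _, _, _, data = occ_data_small
        g = np.array([0.1, 1.0, 0.4, 0.7])
        d = np.array([0.1, -0.5])
        agh = occ.marginal_loglik(g, d, 0.7, 1.5, data)
        lap = occ.marginal_loglik(g, d, 0.7, 1.5, data, method="laplace")
        assert abs(agh - lap) < 0.05 * abs(agh)

    def test_territory_relabeling_invariance(self, occ_data_small):
        cfg, dens, hist, data = occ_data_small
        perm = np.random.default_rng(1).permutation(len(dens))
        relabel = {dens.loc[i, "territory_id"]: f"z{k:03d}"
                   for k, i in enumerate(perm)}
        hist2 = hist.assign(territory_id=hist["territory_id"].map(relabel))
        dens2 = dens.assign(territory_id=dens["territory_id"].map(relabel))
        order = np.argsort(dens2["territory_id"].to_numpy())
        data2 = occ.OccupancyData.from_frames(
            hist2, dens2.iloc[order].reset_index(drop=True),
            occ.OccupancyModelSpec(density_cols=["willow", "rock", "ags"]))
        g = np.array([0.1, 1.0, 0.4, 0.7])
        d = np.array([0.1, -0.5])
        a = occ.marginal_loglik(g, d, 0.0, 1.5, data)
        b = occ.marginal_loglik(g, d, 0.0, 1.5, data2)
        assert abs(a - b) < 1e-8

    def test_all_missing_survey_column_is_inert(self):
        base = _data(np.array([[1.0, 0.0], [0.0, 0.0], [1.0, 1.0]]))
        padded = _data(np.column_stack([
            np.array([[1.0, 0.0], [0.0, 0.0], [1.0, 1.0]]),
            np.full(3, np.nan)]))
        g = np.array([0.2, 0.8])
        d = np.array([0.1, -0.02])
        for sy, st in ((0.0, 0.0), (0.0, 1.5), (0.6, 1.5)):
            assert occ.marginal_loglik(g, d, sy, st, base) == pytest.approx(
                occ.marginal_loglik(g, d, sy, st, padded), abs=1e-8)

    def test_negative_sigma_rejected(self):
        data = _data([[1, 0]])
        with pytest.raises(ValueError):
            occ.marginal_loglik(np.zeros(2), np.zeros(2), -1.0, 0.5, data)


class TestFit:
    def test_recovery_on_default_design(self, occ_data_small, occ_fit_small):
        cfg, dens, _, data = occ_data_small
        fit = occ_fit_small
        assert fit.cov is not None
        # truth on the fitted 2-SD scale
        dsc = data.density_scaler
        se = np.sqrt(np.diag(fit.cov))
        for k, name in enumerate(("willow", "rock", "ags")):
            true = cfg.psi_coefs[name] * 2 * dsc.sds[name]
            assert abs(fit.gamma[k + 1] - true) < 3 * se[k + 1]
        assert fit.sigma_territory > 0.5  # strong heterogeneity is detected

    def test_mean_psi_p_matches_direct_average(self, occ_data_small,
                                               occ_fit_small):
        _, _, _, data = occ_data_small
        fit = occ_fit_small
        out = occ.mean_psi_p(fit)
        psi_vals, p_vals = [], []
        for c in range(len(data.y)):
            psi_vals.append(expit(float(data.Xpsi[c] @ fit.gamma)
                                  + fit.u_mode[data.t_idx[c]]))
            for j in range(data.y.shape[1]):
                if data.obs[c, j]:
                    p_vals.append(expit(fit.delta[0]
                                        + fit.delta[1] * data.day[c, j]
                                        + fit.v_mode[data.i_idx[c]]))
        assert out["mean_psi"] == pytest.approx(np.mean(psi_vals))
        assert out["mean_p"] == pytest.approx(np.mean(p_vals))

    def test_saturated_data_pushes_psi_to_one(self):
        detected = np.ones((6, 2))
        hist, dens = _frames(detected)
        hists, denss = [], []
        for i in range(30):
            h = hist.copy()
            h["territory_id"] = f"t{i:02d}"
            d = dens.copy()
            d["territory_id"] = f"t{i:02d}"
            hists.append(h)
            denss.append(d)
        data = occ.OccupancyData.from_frames(
            pd.concat(hists, ignore_index=True),
            pd.concat(denss, ignore_index=True).assign(
                willow=np.random.default_rng(0).normal(0, 1, 30)),
            occ.OccupancyModelSpec(density_cols=["willow"]))
        fit = occ.fit_occupancy(data, seed=0, n_starts=1, compute_cov=False)
        assert occ.mean_psi_p(fit)["mean_psi"] > 0.99

    def test_single_survey_no_covariate_flags_flat_ridge(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(60):
            for t in range(4):
                rows.append((f"t{i:02d}", 2016 + t, 1,
                             float(rng.integers(0, 2)), 0.0))
        hist = pd.DataFrame(rows, columns=["territory_id", "year",
                                           "survey_index", "detected",
                                           "day_of_year"])
        dens = pd.DataFrame({"territory_id": [f"t{i:02d}" for i in range(60)]})
        data = occ.OccupancyData.from_frames(
            hist, dens, occ.OccupancyModelSpec(density_cols=[],
                                               standardize=False))
        fit = occ.fit_occupancy(data, seed=0, n_starts=1)
        assert fit.convergence["flat_ridge"]

    def test_all_missing_territory_years_dropped(self):
        detected = np.array([[1.0, 0.0], [np.nan, np.nan], [0.0, 1.0]])
        data = _data(detected)
        assert data.n_dropped_cells == 1
        assert len(data.y) == 2


class TestMarginalEffect:
    def test_flat_when_coefficient_zero(self, occ_fit_small):
        fit = occ_fit_small
        fit0 = occ.FittedOccupancyModel(**{**fit.__dict__})
        fit0.gamma = fit.gamma.copy()
        fit0.gamma[1] = 0.0
        curve = occ.occupancy_marginal_effect(fit0, "willow")
        assert np.allclose(curve["psi"], expit(fit0.gamma[0]))

    def test_monotone_when_coefficient_positive(self, occ_fit_small):
        curve = occ.occupancy_marginal_effect(occ_fit_small, "willow")
        sign = np.sign(occ_fit_small.gamma[1])
        diffs = np.diff(curve["psi"].to_numpy()) * sign
        assert (diffs >= 0).all()

    def test_band_is_inverse_logit_of_linear_ci(self, occ_fit_small):
        fit = occ_fit_small
        grid = np.array([0.5])
        curve = occ.occupancy_marginal_effect(fit, "willow", density_grid=grid)
        std = fit.data.density_scaler.transform_array(grid, "willow")
        x = np.zeros(len(fit.gamma))
        x[0] = 1.0
        x[1] = std[0]
        eta = float(x @ fit.gamma)
        se = math.sqrt(float(x @ fit.cov[:len(fit.gamma), :len(fit.gamma)] @ x))
        assert curve["lower"].iloc[0] == pytest.approx(expit(eta - 1.959964 * se), rel=1e-5)
        assert curve["upper"].iloc[0] == pytest.approx(expit(eta + 1.959964 * se), rel=1e-5)

    def test_unknown_species(self, occ_fit_small):
        with pytest.raises(ValueError):
            occ.occupancy_marginal_effect(occ_fit_small, "lemming")


class TestMacKenzieBaileyGof:
    def test_chisq_zero_when_tallies_match(self):
        cohorts = {(True, True): {
            "obs": {(0, 0): 4, (1, 0): 2, (0, 1): 2, (1, 1): 2},
            "exp": {(0, 0): 4.0, (1, 0): 2.0, (0, 1): 2.0, (1, 1): 2.0},
            "slots": [0, 1]}}
        assert occ._mb_chisq(cohorts) == 0.0

    def test_small_expected_cells_pooled(self):
        cohorts = {(True, True): {
            "obs": {(0, 0): 8, (1, 0): 1, (0, 1): 1, (1, 1): 0},
            "exp": {(0, 0): 8.0, (1, 0): 0.8, (0, 1): 0.7, (1, 1): 0.5},
            "slots": [0, 1]}}
        # pooled cell: obs 2 vs exp 2.0 -> chi-square stays 0
        assert occ._mb_chisq(cohorts, pool_threshold=2.0) == pytest.approx(0.0)

    def test_tallies_count_every_unit(self, occ_data_small, occ_fit_small):
        _, _, _, data = occ_data_small
        fit = occ_fit_small
        cohorts = occ._history_tallies(fit.gamma, fit.delta,
                                       fit.sigma_year, fit.sigma_territory,
                                       data)
        n_obs = sum(sum(c["obs"].values()) for c in cohorts.values())
        n_exp = sum(sum(c["exp"].values()) for c in cohorts.values())
        assert n_obs == len(data.y)
        assert n_exp == pytest.approx(len(data.y))

    def test_null_calibration(self):
        """Data simulated inside the model family: c-hat averages near 1
        over datasets (a single dataset's c-hat is a noisy few-df ratio)."""
        cfg = ps.SimulationConfig(n_territories=40,
                                  years=(2016, 2017, 2018, 2019),
                                  sigma_territory=1.0)
        rng = np.random.default_rng(12)
        dens = pd.DataFrame({"territory_id": [f"t{i:02d}" for i in range(40)],
                             "willow": rng.normal(0, 1, 40),
                             "rock": rng.normal(0, 1, 40),
                             "ags": rng.normal(0, 1, 40)})
        spec = occ.OccupancyModelSpec(density_cols=["willow", "rock", "ags"])
        chats, pvals = [], []
        for sd in range(6):
            hist = ps.simulate_territory_histories(cfg, dens, seed=20 + sd)
            data = occ.OccupancyData.from_frames(hist, dens, spec)
            fit = occ.fit_occupancy(data, seed=0, n_starts=1,
                                    compute_cov=False)
            res = occ.mb_gof(fit, B=30, seed=3 + sd)
            assert res["n_failed_refits"] <= 2
            chats.append(res["c_hat"])
            pvals.append(res["p_value"])
        assert 0.5 < np.mean(chats) < 1.6, chats
        assert min(pvals) >= 0.01 and max(pvals) <= 1.0


def test_serialization(occ_fit_small, tmp_path):
    path = tmp_path / "occ.json"
    d = occ_fit_small.to_json(path)
    assert path.exists()
    assert d["sigma_territory"] == occ_fit_small.sigma_territory
    assert len(d["v_mode"]) == 97
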