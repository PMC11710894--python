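import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit
from scipy.stats import poisson

import preyscape as ps
from preyscape import removal as rm


def _tiny_design(n=4, seed=0, n_int=5):
    rng = np.random.default_rng(seed)
    Xa = np.column_stack([np.ones(n), rng.normal(0, 0.5, n)])
    Xd = np.column_stack([np.ones(n), rng.normal(0, 0.5, n)])
    return Xa, Xd


class TestRemovalCellProbs:
    def test_geometric_halving(self):
        pi, miss = rm.removal_cell_probs(0.5, 5)
        assert np.allclose(pi, [0.5, 0.25, 0.125, 0.0625, 0.03125])
        assert np.isclose(miss, 0.03125)

    def test_certain_detection(self):
        pi, miss = rm.removal_cell_probs(1.0, 5)
        assert np.allclose(pi, [1, 0, 0, 0, 0]) and miss == 0.0

    def test_never_detected(self):
        pi, miss = rm.removal_cell_probs(0.0, 5)
        assert np.allclose(pi, 0.0) and miss == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rm.removal_cell_probs(1.2, 5)

    @given(st.floats(0.0, 1.0))
    def test_conservation(self, p):
        pi, miss = rm.removal_cell_probs(p, 5)
        assert math.isclose(pi.sum() + miss, 1.0, abs_tol=1e-12)


class TestLoglikMPN:
    def test_all_zero_counts_closed_form(self):
        Xa, Xd = _tiny_design()
        params = np.array([0.3, 0.2, -0.5, 0.1])
        y = np.zeros((4, 5))
        lam = np.exp(Xa @ params[:2])
        p = expit(Xd @ params[2:])
        expected = -np.sum(lam * (1 - (1 - p) ** 5))
        assert np.isclose(rm.loglik_mpn(params, y, Xa, Xd, 0.0), expected)

    def test_matches_independent_poisson_sum(self):
        # direct evaluation with scipy's Poisson pmf as the oracle
        Xa = np.ones((1, 1))
        Xd = np.ones((1, 1))
        lam, p = 2.0, 0.3
        params = np.array([np.log(lam), np.log(p / (1 - p))])
        y = np.array([[1, 0, 1, 0, 0]], dtype=float)
        pi, _ = rm.removal_cell_probs(p, 5)
        oracle = sum(poisson.logpmf(int(y[0, j]), lam * pi[j]) for j in range(5))
        assert np.isclose(rm.loglik_mpn(params, y, Xa, Xd, 0.0), oracle)

    def test_negative_counts_rejected(self):
        Xa, Xd = _tiny_design()
        y = np.zeros((4, 5))
        y[0, 0] = -1
        with pytest.raises(ValueError):
            rm.loglik_mpn(np.zeros(4), y, Xa, Xd, 0.0)

    def test_interval_order_matters(self):
        # permuting intervals against the geometric cell order changes the value
        Xa = np.ones((1, 1))
        Xd = np.ones((1, 1))
        params = np.array([np.log(2.0), np.log(0.3 / 0.7)])
        y = np.array([[3, 1, 0, 0, 0]], dtype=float)
        ll = rm.loglik_mpn(params, y, Xa, Xd, 0.0)
        ll_perm = rm.loglik_mpn(params, y[:, ::-1].copy(), Xa, Xd, 0.0)
        assert abs(ll - ll_perm) > 1e-6

    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        Xa, Xd = _tiny_design(6, 3)
        y = rng.poisson(1.0, size=(6, 5)).astype(float)
        params = rng.normal(0, 0.3, 4)
        _, grad = rm._loglik_grad(params, y, Xa, Xd, math.log(0.5))
        h = 1e-6
        for j in range(4):
            tp, tm = params.copy(), params.copy()
            tp[j] += h
            tm[j] -= h
            fd = (rm.loglik_mpn(tp, y, Xa, Xd, math.log(0.5))
                  - rm.loglik_mpn(tm, y, Xa, Xd, math.log(0.5))) / (2 * h)
            assert np.isclose(grad[j], fd, atol=1e-5)


class TestTruncatedOracle:
    def test_perfect_detection_single_term(self):
        Xa = np.ones((1, 1))
        Xd = np.ones((1, 1))
        lam = 1.7
        params = np.array([np.log(lam), 30.0])  # p ~ 1
        y = np.array([[3, 0, 0, 0, 0]], dtype=float)
        ll = rm.loglik_nmix_truncated(params, y, Xa, Xd, 0.0, K=3)
        assert np.isclose(ll, poisson.logpmf(3, lam))

    def test_k_zero_all_zero_counts(self):
        Xa, Xd = _tiny_design()
        params = np.array([0.1, 0.0, 0.0, 0.0])
        y = np.zeros((4, 5))
        lam = np.exp(Xa @ params[:2])
        ll = rm.loglik_nmix_truncated(params, y, Xa, Xd, 0.0, K=0)
        assert np.isclose(ll, poisson.logpmf(0, lam).sum())

    def test_k_below_observed_total_rejected(self):
        Xa = np.ones((1, 1))
        Xd = np.ones((1, 1))
        y = np.array([[2, 1, 0, 0, 0]], dtype=float)
        with pytest.raises(ValueError):
            rm.loglik_nmix_truncated(np.zeros(2), y, Xa, Xd, 0.0, K=2)

    def test_factorization_identity(self):
        rng = np.random.default_rng(4)
        Xa, Xd = _tiny_design(5, 5)
        y = rng.poisson(1.5, size=(5, 5)).astype(float)
        params = np.array([0.5, 0.3, -0.8, 0.2])
        mpn = rm.loglik_mpn(params, y, Xa, Xd, 0.0)
        trunc = rm.loglik_nmix_truncated(params, y, Xa, Xd, 0.0, K=100)
        assert abs(mpn - trunc) < 1e-8


class TestFitRemoval:
    def test_parameter_recovery_intercepts(self):
        lam, p, n = 2.0, 0.3, 1000
        rng = np.random.default_rng(6)
        cov = pd.DataFrame({"x": rng.normal(0, 0.5, n)})
        cfg = ps.SimulationConfig(
            n_sites=n, survey_area_km2=1.0,
            abundance_coefs={"intercept": np.log(lam), "x": 0.0},
            detection_coefs={"intercept": float(np.log(p / (1 - p))),
                             "x": 0.0},
            observer_offsets={})
        counts = ps.simulate_point_counts(cfg, cov, seed=7)
        data = ps.RemovalCountTable(site_id=np.arange(n), counts=counts.counts,
                                    covariates=cov)
        spec = ps.RemovalModelSpec(abundance=["x"], detection=["x"],
                                   observer_col=None, offset_area_km2=1.0)
        fit = ps.fit_removal(data, spec, seed=0, standardize=False)
        assert fit.convergence["converged"]
        se0 = np.sqrt(fit.cov[0, 0])
        assert abs(fit.beta[0] - np.log(lam)) < 3 * se0

    def test_oracle_likelihood_reaches_same_optimum(self, willow_fit):
        # refitting against the brute-force truncated likelihood lands on the
        # same coefficients, confirming the factorized production path
        from scipy.optimize import minimize
        rng = np.random.default_rng(8)
        n = 60
        cov = pd.DataFrame({"x": rng.normal(0, 0.5, n)})
        cfg = ps.SimulationConfig(
            n_sites=n, survey_area_km2=1.0,
            abundance_coefs={"intercept": 0.7, "x": 0.5},
            detection_coefs={"intercept": -1.0}, observer_offsets={})
        counts = ps.simulate_point_counts(cfg, cov, seed=9)
        data = ps.RemovalCountTable(site_id=np.arange(n), counts=counts.counts,
                                    covariates=cov)
        spec = ps.RemovalModelSpec(abundance=["x"], detection=[],
                                   observer_col=None, offset_area_km2=1.0)
        fit = ps.fit_removal(data, spec, seed=0, standardize=False)
        y = data.counts.astype(float)
        Xa = np.column_stack([np.ones(n), cov["x"]])
        Xd = np.ones((n, 1))
        res = minimize(
            lambda t: -rm.loglik_nmix_truncated(t, y, Xa, Xd, 0.0, K=60),
            fit.params + 0.05, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
        assert np.allclose(res.x, fit.params, atol=1e-4)

    def test_all_zero_counts_hits_boundary(self):
        n = 40
        cov = pd.DataFrame({"x": np.linspace(-1, 1, n)})
        data = ps.RemovalCountTable(site_id=np.arange(n),
                                    counts=np.zeros((n, 5), dtype=int),
                                    covariates=cov)
        spec = ps.RemovalModelSpec(abundance=[], detection=[],
                                   observer_col=None, offset_area_km2=1.0)
        fit = ps.fit_removal(data, spec, seed=0, standardize=False,
                             compute_cov=False)
        assert not fit.convergence["converged"]
        assert fit.convergence["at_bound"]

    def test_offset_doubling_shifts_intercept_only(self, willow_fit):
        cfg, land, data, fit = willow_fit
        spec2 = ps.RemovalModelSpec(
            abundance=fit.spec.abundance, detection=fit.spec.detection,
            offset_area_km2=2 * fit.spec.offset_area_km2)
        fit2 = ps.fit_removal(data, spec2, seed=0)
        delta = fit2.params - fit.params
        assert np.isclose(delta[0], -np.log(2), atol=1e-4)
        assert np.allclose(delta[1:], 0.0, atol=1e-4)


class TestInference:
    def _fake_fit(self):
        spec = ps.RemovalModelSpec(abundance=["x"], detection=[],
                                   observer_col=None)
        return rm.FittedRemovalModel(
            spec=spec, params=np.array([1.0, 0.1, 0.0]),
            names_abundance=["intercept", "x"], names_detection=["intercept"],
            cov=np.diag([0.1 ** 2, 0.1 ** 2, 0.2 ** 2]), loglik=0.0,
            scaler=None, observer_levels=[], train_ranges={"x": (-1.0, 1.0)},
            convergence={"converged": True})

    def test_wald_interval_values(self):
        table = rm.coefficient_table(self._fake_fit())
        row = table.iloc[0]
        assert np.isclose(row["lower"], 1.0 - 1.959963 * 0.1, atol=1e-4)
        assert np.isclose(row["upper"], 1.0 + 1.959963 * 0.1, atol=1e-4)
        assert bool(row["significant"])
        assert not bool(table.iloc[1]["significant"])  # 0.1 +/- 0.196

    def test_marginal_effect_closed_form_and_flat(self):
        fit = self._fake_fit()
        curve = rm.marginal_effect(fit, "x", values=np.linspace(-1, 1, 9))
        # log link: curve is exp(beta0 + b x); slope b on the log scale
        logm = np.log(curve["mean"].to_numpy())
        slopes = np.diff(logm) / np.diff(curve["value"].to_numpy())
        assert np.allclose(slopes, 0.1)
        flat_fit = self._fake_fit()
        flat_fit.params[1] = 0.0
        flat = rm.marginal_effect(flat_fit, "x", values=np.linspace(-1, 1, 5))
        assert np.allclose(flat["mean"], np.exp(1.0))

    def test_marginal_effect_mvn_agrees_with_delta(self, willow_fit):
        _, _, _, fit = willow_fit
        d = rm.marginal_effect(fit, "tundra", method="delta")
        m = rm.marginal_effect(fit, "tundra", method="mvn", n_draws=20000,
                               seed=1)
        # Monte-Carlo agreement on the log scale
        assert np.allclose(np.log(d["lower"]), np.log(m["lower"]), atol=0.05)
        assert np.allclose(np.log(d["upper"]), np.log(m["upper"]), atol=0.05)

    def test_unknown_predictor(self, willow_fit):
        with pytest.raises(ValueError):
            rm.marginal_effect(willow_fit[3], "bog")


class TestGof:
    def test_chisq_zero_when_observed_equals_expected(self):
        mu = np.array([[1.0, 0.5], [2.0, 0.25]])
        chi, n_excl = rm._pearson_chisq(mu.copy(), mu)
        assert chi == 0.0 and n_excl == 0

    def test_c_hat_one_for_identical_replicates(self):
        res = rm.GofResult(chisq_observed=5.0, chisq_boot=np.full(10, 5.0),
                           p_value=1.0, c_hat=5.0 / 5.0, B=10, seed=0)
        assert res.c_hat == 1.0 and res.p_value == 1.0

    def test_bootstrap_p_and_chat_reasonable(self, willow_fit):
        _, _, _, fit = willow_fit
        res = rm.gof_parametric_bootstrap(fit, B=60, seed=3)
        assert 0.0 <= res.p_value <= 1.0
        # data were generated from the model family, so no overdispersion
        assert 0.7 < res.c_hat < 1.3
        assert res.n_failed_refits <= 2


def test_serialization_round_trip(willow_fit, tmp_path):
    _, _, _, fit = willow_fit
    path = tmp_path / "model.json"
    fit.to_json(path)
    back = rm.FittedRemovalModel.from_json(path)
    assert np.allclose(back.params, fit.params)
    assert np.allclose(back.cov, fit.cov)
    assert back.spec.offset_area_km2 == fit.spec.offset_area_km2
    assert back.scaler.means == fit.scaler.means
    assert back.train_ranges == fit.train_ranges
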