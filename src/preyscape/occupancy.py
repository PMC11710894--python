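"""Stacked multi-year occupancy model with imperfect detection.

Each territory-year is an occupancy unit: latent presence
z_it ~ Bernoulli(psi_it) with logit psi_it = gamma' d_i + u_t, where d_i are
per-territory prey densities (2-SD standardized, time-constant) and
u_t ~ N(0, sigma_year^2) is a year random intercept. Detection on survey j
is y_ijt | z_it ~ Bernoulli(z_it p_ijt) with
logit p_ijt = delta_0 + delta_day day_ijt + v_i and a territory random
intercept v_i ~ N(0, sigma_territory^2) shared across years. Missing
surveys contribute nothing to the likelihood.

Marginalizing the crossed year x territory random effects: conditional on
the year effects u, the likelihood factorizes over territories, each
contributing a one-dimensional integral over v_i that is evaluated with
adaptive Gauss-Hermite quadrature (nodes centered and scaled at the
conditional mode). The remaining low-dimensional integral over u (one
dimension per season, each informed by ~100 territories) is handled by a
Laplace approximation. The scheme is exact when both variances are zero,
reduces to pure adaptive quadrature when one variance is zero, and a plain
joint Laplace approximation is retained as ``method="laplace"`` for
cross-checks.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit, logsumexp
from scipy.stats import norm

from . import _kernels
from .preprocess import Scaler

__all__ = [
    "OccupancyModelSpec",
    "OccupancyData",
    "FittedOccupancyModel",
    "occupancy_cell_lik",
    "marginal_loglik",
    "agh_marginal_loglik",
    "fit_occupancy",
    "occupancy_coefficient_table",
    "occupancy_marginal_effect",
    "mb_gof",
    "mean_psi_p",
]

_SIGMA_FLOOR = 1e-6        # lower bound for sigma during optimization
_SIGMA_BOUNDARY = 1e-4     # estimates below this are reported as 0
_DEFAULT_AGH_NODES = 15


@dataclasses.dataclass
class OccupancyModelSpec:
    """Covariate structure: which density columns drive occupancy and which
    survey covariate drives detection."""

    density_cols: list
    detection_col: str = "day_of_year"
    standardize: bool = True


def occupancy_cell_lik(psi: float, p_vector, history) -> float:
    """Likelihood of one territory-year's detection history.

    L = psi * prod_j p_j^y_j (1-p_j)^(1-y_j) + (1-psi) * 1[all y_j = 0],
    with missing surveys (None/NaN) skipped. ``p_vector`` supplies one
    detection probability per non-missing survey, in order.
    """
    ys = [y for y in history if y is not None and not (
        isinstance(y, float) and math.isnan(y))]
    p_vector = list(np.atleast_1d(p_vector))
    if len(ys) and not len(p_vector):
        raise ValueError("history has observations but no detection "
                         "probabilities were supplied")
    cond = 1.0
    for y, p in zip(ys, p_vector):
        cond *= p if y else (1.0 - p)
    return psi * cond + (1.0 - psi) * (1.0 if all(y == 0 for y in ys) else 0.0)


# ---------------------------------------------------------------------------
# data container


@dataclasses.dataclass
class OccupancyData:
    """Stacked territory-year arrays ready for likelihood evaluation."""

    i_idx: np.ndarray          # (n_cells,) territory index
    t_idx: np.ndarray          # (n_cells,) year index
    Xpsi: np.ndarray           # (n_cells, 1 + n_density) standardized
    day: np.ndarray            # (n_cells, S) standardized day of year
    obs: np.ndarray            # (n_cells, S) bool, survey not missing
    y: np.ndarray              # (n_cells, S) 0/1 (0 where missing)
    territory_ids: list
    years: list
    density_scaler: Scaler | None = None
    day_scaler: Scaler | None = None
    n_dropped_cells: int = 0
    density_cols: list = dataclasses.field(default_factory=list)

    @property
    def n_territories(self) -> int:
        return len(self.territory_ids)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def detected_any(self) -> np.ndarray:
        return (self.y * self.obs).any(axis=1)

    @classmethod
    def from_frames(cls, histories: pd.DataFrame, densities: pd.DataFrame,
                    spec: OccupancyModelSpec) -> "OccupancyData":
        """Assemble arrays from a long detection-history table and a
        per-territory density table.

        ``histories`` needs columns territory_id, year, survey_index,
        detected (0/1/NaN) and the detection covariate; ``densities`` needs
        territory_id plus ``spec.density_cols`` (animals per km^2).
        Territory-years with every survey missing are dropped (counted in
        ``n_dropped_cells``).
        """
        dens = densities.reset_index(drop=True)
        missing_cols = [c for c in spec.density_cols if c not in dens.columns]
        if missing_cols:
            raise ValueError(f"density table missing columns: {missing_cols}")
        terr_ids = list(dens["territory_id"])
        terr_pos = {tid: k for k, tid in enumerate(terr_ids)}
        years = sorted(histories["year"].unique())
        year_pos = {yr: k for k, yr in enumerate(years)}
        n_surv = int(histories["survey_index"].max())

        density_scaler = None
        dens_model = dens
        if spec.standardize:
            density_scaler = Scaler.fit(dens, columns=list(spec.density_cols))
            dens_model = density_scaler.transform(dens)

        day_scaler = None
        hist = histories.copy()
        if spec.standardize:
            observed_days = hist.loc[hist["detected"].notna(), spec.detection_col]
            day_scaler = Scaler.fit(pd.DataFrame({spec.detection_col: observed_days}),
                                    columns=[spec.detection_col])
            hist[spec.detection_col] = day_scaler.transform(
                hist[[spec.detection_col]])[spec.detection_col]

        cells: dict[tuple, dict] = {}
        for rec in hist.itertuples(index=False):
            tid = getattr(rec, "territory_id")
            if tid not in terr_pos:
                raise ValueError(f"territory {tid!r} has no density record")
            key = (terr_pos[tid], year_pos[getattr(rec, "year")])
            cell = cells.setdefault(key, {
                "y": np.zeros(n_surv), "obs": np.zeros(n_surv, bool),
                "day": np.zeros(n_surv)})
            j = int(getattr(rec, "survey_index")) - 1
            det = getattr(rec, "detected")
            day = getattr(rec, spec.detection_col)
            if det is not None and not pd.isna(det):
                cell["y"][j] = float(det)
                cell["obs"][j] = True
                cell["day"][j] = float(day) if not pd.isna(day) else 0.0

        keys = sorted(cells)
        keep = [k for k in keys if cells[k]["obs"].any()]
        n_dropped = len(keys) - len(keep)
        i_idx = np.array([k[0] for k in keep], dtype=int)
        t_idx = np.array([k[1] for k in keep], dtype=int)
        y = np.stack([cells[k]["y"] for k in keep])
        obs = np.stack([cells[k]["obs"] for k in keep])
        day = np.stack([cells[k]["day"] for k in keep])
        Xd = dens_model.loc[i_idx, list(spec.density_cols)].to_numpy(dtype=float)
        Xpsi = np.column_stack([np.ones(len(keep)), Xd])
        return cls(i_idx=i_idx, t_idx=t_idx, Xpsi=Xpsi, day=day, obs=obs,
                   y=y, territory_ids=terr_ids, years=years,
                   density_scaler=density_scaler, day_scaler=day_scaler,
                   n_dropped_cells=n_dropped,
                   density_cols=list(spec.density_cols))


# ---------------------------------------------------------------------------
# joint likelihood pieces (vectorized over cells)


def _cell_terms(gamma, delta, u, v, data: OccupancyData):
    """Per-cell log-likelihood and first/second derivatives with respect to
    the occupancy logit (through u_t) and the shared detection logit shift
    (through v_i).

    Returns (ll, g_eta, h_eta, g_v, h_v, cross) with shapes (n_cells,).
    """
    eta_psi = data.Xpsi @ gamma + u[data.t_idx]
    psi = expit(eta_psi)
    eta_p = delta[0] + delta[1] * data.day + v[data.i_idx][:, None]
    p = expit(eta_p)
    obs = data.obs
    yob = data.y * obs

    det = (yob > 0).any(axis=1)
    pc = np.clip(p, 1e-12, 1.0 - 1e-12)

    # detected cells: logL = log psi + sum_obs bernoulli
    bern = np.where(obs, yob * np.log(pc) + (1 - data.y) * np.log1p(-pc) * obs, 0.0)
    ll_det = np.log(np.clip(psi, 1e-300, 1.0)) + bern.sum(axis=1)
    g_eta_det = 1.0 - psi
    h_eta_det = -psi * (1.0 - psi)
    g_v_det = ((yob - p) * obs).sum(axis=1)
    h_v_det = -(p * (1.0 - p) * obs).sum(axis=1)

    # non-detected cells: L = psi q + (1 - psi), q = prod_obs (1 - p_j)
    log_q = (np.log1p(-pc) * obs).sum(axis=1)
    q = np.exp(log_q)
    s = (p * obs).sum(axis=1)
    s2 = (p * (1.0 - p) * obs).sum(axis=1)
    L = np.clip(psi * q + (1.0 - psi), 1e-300, None)
    dpsi = psi * (1.0 - psi)
    L_eta = dpsi * (q - 1.0)
    L_etaeta = dpsi * (1.0 - 2.0 * psi) * (q - 1.0)
    q_v = -q * s
    q_vv = q * s * s - q * s2
    L_v = psi * q_v
    L_vv = psi * q_vv
    L_etav = dpsi * q_v
    g_eta_nd = L_eta / L
    g_v_nd = L_v / L
    h_eta_nd = L_etaeta / L - g_eta_nd ** 2
    h_v_nd = L_vv / L - g_v_nd ** 2
    cross_nd = L_etav / L - g_eta_nd * g_v_nd
    ll_nd = np.log(L)

    ll = np.where(det, ll_det, ll_nd)
    g_eta = np.where(det, g_eta_det, g_eta_nd)
    h_eta = np.where(det, h_eta_det, h_eta_nd)
    g_v = np.where(det, g_v_det, g_v_nd)
    h_v = np.where(det, h_v_det, h_v_nd)
    cross = np.where(det, 0.0, cross_nd)
    return ll, g_eta, h_eta, g_v, h_v, cross


def _penalized_joint(gamma, delta, u, v, sig_y, sig_t, data):
    """Penalized joint log-likelihood g(u, v), including the Gaussian
    normalizing constants of the active random effects."""
    ll = _cell_terms(gamma, delta, u, v, data)[0].sum()
    g = float(ll)
    if sig_y > 0:
        g += float(-0.5 * np.sum(u ** 2) / sig_y ** 2
                   - data.n_years * 0.5 * math.log(2 * math.pi * sig_y ** 2))
    if sig_t > 0:
        g += float(-0.5 * np.sum(v ** 2) / sig_t ** 2
                   - data.n_territories * 0.5 * math.log(2 * math.pi * sig_t ** 2))
    return g


# ---------------------------------------------------------------------------
# joint Laplace (cross-check path)


def _inner_newton(gamma, delta, sig_y, sig_t, data: OccupancyData,
                  u0=None, v0=None, tol: float = 1e-10, max_iter: int = 100):
    """Joint random-effect mode by damped Newton with a Schur complement on
    the (small) year block. Returns (u, v, logdet_H, g_mode, converged)."""
    T, Y = data.n_territories, data.n_years
    use_u, use_v = sig_y > 0, sig_t > 0
    u = np.zeros(Y) if u0 is None or not use_u else np.asarray(u0, float).copy()
    v = np.zeros(T) if v0 is None or not use_v else np.asarray(v0, float).copy()
    if not use_u and not use_v:
        return u, v, 0.0, _penalized_joint(gamma, delta, u, v, sig_y, sig_t,
                                           data), True

    inv_sy2 = 1.0 / sig_y ** 2 if use_u else 0.0
    inv_st2 = 1.0 / sig_t ** 2 if use_v else 0.0
    floor_u = max(inv_sy2, 1e-3)
    floor_v = max(inv_st2, 1e-3)
    g_cur = _penalized_joint(gamma, delta, u, v, sig_y, sig_t, data)
    converged = False

    def _try_step(du, dv):
        nonlocal u, v, g_cur
        cap = max(np.max(np.abs(du)) if use_u else 0.0,
                  np.max(np.abs(dv)) if use_v else 0.0)
        if cap > 10.0:  # trust region on the random-effect scale
            du, dv = du * (10.0 / cap), dv * (10.0 / cap)
        step = 1.0
        for _ls in range(25):
            u_new = u + step * du if use_u else u
            v_new = v + step * dv if use_v else v
            g_new = _penalized_joint(gamma, delta, u_new, v_new,
                                     sig_y, sig_t, data)
            if g_new >= g_cur - 1e-13:
                u, v, g_cur = u_new, v_new, g_new
                return True
            step *= 0.5
        return False

    for _ in range(max_iter):
        _, g_eta, h_eta, g_v, h_v, cross = _cell_terms(gamma, delta, u, v, data)
        grad_u = np.bincount(data.t_idx, weights=g_eta, minlength=Y) - u * inv_sy2
        grad_v = np.bincount(data.i_idx, weights=g_v, minlength=T) - v * inv_st2
        Hu = -(np.bincount(data.t_idx, weights=h_eta, minlength=Y)) + inv_sy2
        Hv = -(np.bincount(data.i_idx, weights=h_v, minlength=T)) + inv_st2

        sup = max(np.max(np.abs(grad_u)) if use_u else 0.0,
                  np.max(np.abs(grad_v)) if use_v else 0.0)
        if sup < tol:
            converged = True
            break

        Hu_c = np.maximum(Hu, floor_u)
        Hv_c = np.maximum(Hv, floor_v)
        if use_u and use_v:
            C = np.zeros((T, Y))
            np.add.at(C, (data.i_idx, data.t_idx), -cross)
            S = np.diag(Hu_c) - C.T @ (C / Hv_c[:, None])
            rhs = grad_u - C.T @ (grad_v / Hv_c)
            try:
                du = np.linalg.solve(S, rhs)
            except np.linalg.LinAlgError:
                du = np.linalg.solve(S + 1e-6 * np.eye(Y), rhs)
            dv = (grad_v - C @ du) / Hv_c
        elif use_v:
            dv = grad_v / Hv_c
            du = np.zeros(Y)
        else:
            du = grad_u / Hu_c
            dv = np.zeros(T)

        if not _try_step(du, dv):
            if not _try_step(grad_u / floor_u, grad_v / floor_v):
                break

    # exact log-determinant of the negative joint Hessian at the mode
    _, g_eta, h_eta, g_v, h_v, cross = _cell_terms(gamma, delta, u, v, data)
    Hu = -(np.bincount(data.t_idx, weights=h_eta, minlength=Y)) + inv_sy2
    Hv = -(np.bincount(data.i_idx, weights=h_v, minlength=T)) + inv_st2
    if use_u and use_v:
        C = np.zeros((T, Y))
        np.add.at(C, (data.i_idx, data.t_idx), -cross)
        Hv_c = np.maximum(Hv, 1e-12)
        S = np.diag(Hu) - C.T @ (C / Hv_c[:, None])
        sign, logdet_S = np.linalg.slogdet(S)
        if sign <= 0:
            logdet_S = np.linalg.slogdet(S + 1e-8 * np.eye(Y))[1]
        logdet = float(np.sum(np.log(Hv_c)) + logdet_S)
    elif use_v:
        logdet = float(np.sum(np.log(np.maximum(Hv, 1e-12))))
    else:
        logdet = float(np.sum(np.log(np.maximum(Hu, 1e-12))))
    return u, v, logdet, g_cur, converged


# ---------------------------------------------------------------------------
# adaptive Gauss-Hermite machinery (production path)


def _prep_cond(gamma, delta, u, data: OccupancyData):
    """Quantities that do not depend on v: occupancy probabilities and the
    detection linear predictor without the territory intercept."""
    psi = expit(data.Xpsi @ gamma + u[data.t_idx])
    base_p = delta[0] + delta[1] * data.day       # (n_cells, S)
    det = data.detected_any
    starts = np.searchsorted(data.i_idx, np.arange(data.n_territories))
    ends = np.searchsorted(data.i_idx, np.arange(data.n_territories) + 1)
    return {"psi": psi, "base_p": base_p, "det": det,
            "starts": starts, "ends": ends}


def _group_sum(arr, starts, ends):
    """Sum rows of ``arr`` over contiguous groups (cells sorted by
    territory); handles empty groups, works for 1-D and 2-D arrays."""
    cs = np.concatenate([np.zeros((1,) + arr.shape[1:]),
                         np.cumsum(arr, axis=0)], axis=0)
    return cs[ends] - cs[starts]


def _v_newton_given_u(prep, data: OccupancyData, sig_t: float, v0=None,
                      tol: float = 1e-8, max_iter: int = 60):
    """Conditional territory modes v_hat(u) and curvatures h_i > 0 of the
    per-territory penalized log-integrands (diagonal Newton).

    Acceptance slack (1e-9) sits above the float noise of the grouped sums
    so near-converged territories do not bounce in the backtracking loop.
    """
    T = data.n_territories
    inv_st2 = 1.0 / sig_t ** 2
    slack = 1e-9
    starts, ends = prep["starts"], prep["ends"]
    v = np.zeros(T) if v0 is None else np.asarray(v0, float).copy()

    def derivs(vv):
        return _kernels.v_derivs(prep["base_p"], data.y, data.obs,
                                 prep["psi"], prep["det"], vv[data.i_idx])

    ll, g, h = derivs(v)
    f_cur = _group_sum(ll, starts, ends) - 0.5 * v ** 2 * inv_st2
    for _ in range(max_iter):
        grad = _group_sum(g, starts, ends) - v * inv_st2
        if np.max(np.abs(grad)) < tol:
            break
        Hv = np.maximum(-_group_sum(h, starts, ends) + inv_st2, 1e-3)
        dv = np.clip(grad / Hv, -10.0, 10.0)
        step = np.ones(T)
        for _ls in range(20):  # separable objective: per-territory backtracking
            ll_n, g_n, h_n = derivs(v + step * dv)
            f_new = _group_sum(ll_n, starts, ends) \
                - 0.5 * (v + step * dv) ** 2 * inv_st2
            bad = f_new < f_cur - slack
            if not bad.any():
                break
            step[bad] *= 0.5
        still_bad = f_new < f_cur - slack
        if still_bad.any():
            step[still_bad] = 0.0
            ll_n, g_n, h_n = derivs(v + step * dv)
            f_new = _group_sum(ll_n, starts, ends) \
                - 0.5 * (v + step * dv) ** 2 * inv_st2
        v = v + step * dv
        f_cur = np.maximum(f_new, f_cur - slack)
        g, h = g_n, h_n
        if (step == 0).all():
            break
    Hv = np.maximum(-_group_sum(h, starts, ends) + inv_st2, 1e-10)
    return v, Hv


def _agh_territory(gamma, delta, u, sig_t, data: OccupancyData,
                   n_nodes: int, v0=None, want_derivs: bool = False):
    """Adaptive Gauss-Hermite integration of every territory's v_i integral,
    conditional on the year effects u.

    Returns (logG, v_hat, extras); ``extras`` carries the node-weighted
    expectations needed for the outer Laplace over u when ``want_derivs``.
    """
    T, Y = data.n_territories, data.n_years
    inv_st2 = 1.0 / sig_t ** 2
    prep = _prep_cond(gamma, delta, u, data)
    starts, ends = prep["starts"], prep["ends"]
    vhat, Hv = _v_newton_given_u(prep, data, sig_t, v0=v0)
    s_i = np.sqrt(2.0 / Hv)                       # (T,)
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    logw = np.log(weights)

    v_terr_nodes = vhat[:, None] + s_i[:, None] * nodes[None, :]   # (T, K)
    v_cells = v_terr_nodes[data.i_idx]                             # (n_cells, K)
    bern, q = _kernels.rule_setup(prep["base_p"], data.y, data.obs, v_cells)
    ll, a_cell, b_cell = _kernels.eval_ll(prep["psi"], prep["det"], bern, q,
                                          want_derivs)
    const = -0.5 * math.log(2 * math.pi * sig_t ** 2)
    psi_nodes = (_group_sum(ll, starts, ends)
                 - 0.5 * v_terr_nodes ** 2 * inv_st2 + const)      # (T, K)

    log_terms = logw[None, :] + psi_nodes + nodes[None, :] ** 2
    logG = np.log(s_i) + logsumexp(log_terms, axis=1)
    extras = None
    if want_derivs:
        # posterior node weights per territory (rows sum to 1)
        W = np.exp(log_terms - logsumexp(log_terms, axis=1)[:, None])
        Ag = np.zeros((T, Y, n_nodes))
        Ag[data.i_idx, data.t_idx, :] = a_cell
        m2 = (W[data.i_idx, :] * b_cell).sum(axis=1)
        Bg_sum = np.bincount(data.t_idx, weights=m2, minlength=Y)
        E1 = np.einsum("itk,ik->it", Ag, W)        # E_i[a_t]
        E2 = np.einsum("ik,itk,isk->ts", W, Ag, Ag)
        Hlog = E2 - np.einsum("it,is->ts", E1, E1) + np.diag(Bg_sum)
        extras = {"grad_u": E1.sum(axis=0), "Hlog": Hlog}
    return logG, vhat, extras


def _marginal_nested(gamma, delta, sig_y, sig_t, data: OccupancyData,
                     n_agh: int, u0=None, v0=None,
                     tol: float = 1e-8, max_rule_iters: int = 8):
    """Production marginal for the crossed case: AGH over territories,
    Laplace over years.

    The quadrature rule (conditional modes and scales of the v integrals)
    is frozen while the year effects are optimized — under a frozen rule
    only the occupancy side depends on u, so those Newton iterations are
    cheap and their gradients exact — then the rule is re-adapted at the
    new u until the modes stabilize.
    """
    Y, T = data.n_years, data.n_territories
    n_cells = len(data.y)
    u = np.zeros(Y) if u0 is None else np.asarray(u0, float).copy()
    vhat_prev = v0
    inv_sy2 = 1.0 / sig_y ** 2
    inv_st2 = 1.0 / sig_t ** 2
    const_t = -0.5 * math.log(2 * math.pi * sig_t ** 2)
    const_y = -Y * 0.5 * math.log(2 * math.pi * sig_y ** 2)
    nodes, weights = np.polynomial.hermite.hermgauss(n_agh)
    logw_x2 = np.log(weights) + nodes ** 2
    det = data.detected_any
    i_idx, t_idx = data.i_idx, data.t_idx

    converged = False
    F_cur = -np.inf
    H_F = None
    for rule_it in range(max_rule_iters):
        prep = _prep_cond(gamma, delta, u, data)
        starts, ends = prep["starts"], prep["ends"]
        vhat, Hv = _v_newton_given_u(prep, data, sig_t, v0=vhat_prev)
        s_i = np.sqrt(2.0 / Hv)
        v_terr_nodes = vhat[:, None] + s_i[:, None] * nodes[None, :]   # (T,K)
        v_cells = v_terr_nodes[i_idx]                                  # (n,K)
        # detection-side quantities are fixed under the frozen rule
        bern, q = _kernels.rule_setup(prep["base_p"], data.y, data.obs,
                                      v_cells)
        pen_terr = -0.5 * v_terr_nodes ** 2 * inv_st2 + const_t \
            + np.log(s_i)[:, None] + logw_x2[None, :]                  # (T,K)

        def eval_u(u_val, want: int):
            """want 0: F only; 1: + gradient and the pieces (W, a, b) the
            6x6 Hessian needs, built lazily by ``make_H``."""
            psi = expit(data.Xpsi @ gamma + u_val[t_idx])
            ll, a, b = _kernels.eval_ll(psi, det, bern, q, want >= 1)
            log_terms = _group_sum(ll, starts, ends) + pen_terr        # (T,K)
            mx = log_terms.max(axis=1)
            W = np.exp(log_terms - mx[:, None])
            sw = W.sum(axis=1)
            logG = mx + np.log(sw)
            F = float(logG.sum()) - 0.5 * float(u_val @ u_val) * inv_sy2 \
                + const_y
            if want == 0:
                return F, None, None
            W /= sw[:, None]
            Wc = W[i_idx]
            grad = (np.bincount(t_idx, weights=(Wc * a).sum(axis=1),
                                minlength=Y) - u_val * inv_sy2)
            return F, grad, (W, Wc, a, b)

        def make_H(pieces):
            W, Wc, a, b = pieces
            Ag = np.zeros((T, Y, n_agh))
            Ag[i_idx, t_idx, :] = a
            m2 = (Wc * b).sum(axis=1)
            E1 = np.einsum("itk,ik->it", Ag, W)
            E2 = np.einsum("ik,itk,isk->ts", W, Ag, Ag)
            Hlog = (E2 - np.einsum("it,is->ts", E1, E1)
                    + np.diag(np.bincount(t_idx, weights=m2, minlength=Y)))
            return -Hlog + np.eye(Y) * inv_sy2

        # exact Newton over u under the frozen rule
        F_cur, grad, pieces = eval_u(u, 1)
        for _ in range(50):
            if np.max(np.abs(grad)) < tol:
                break
            H_F = make_H(pieces)
            try:
                du = np.linalg.solve(H_F, grad)
            except np.linalg.LinAlgError:
                du = np.linalg.solve(H_F + 1e-6 * np.eye(Y), grad)
            cap = np.max(np.abs(du))
            if cap > 10.0:
                du *= 10.0 / cap
            step = 1.0
            accepted = False
            for _ls in range(20):
                F_try, _, _ = eval_u(u + step * du, 0)
                if F_try >= F_cur - 1e-9:
                    u = u + step * du
                    improvement = F_try - F_cur
                    F_cur, grad, pieces = eval_u(u, 1)
                    accepted = improvement > 1e-10
                    break
                step *= 0.5
            if not accepted:
                break
        H_F = make_H(pieces)

        drift = (np.inf if vhat_prev is None
                 else float(np.max(np.abs(vhat - vhat_prev))))
        vhat_prev = vhat
        if drift < 1e-5:
            converged = True
            break
    else:
        converged = np.max(np.abs(grad)) < 1e-4

    sign, logdet = np.linalg.slogdet(H_F)
    if sign <= 0:
        logdet = np.linalg.slogdet(H_F + 1e-8 * np.eye(Y))[1]
    ll = F_cur + 0.5 * Y * math.log(2 * math.pi) - 0.5 * float(logdet)
    return float(ll), u, vhat_prev, bool(converged)


def _agh_year_only(gamma, delta, sig_y, data: OccupancyData, n_nodes: int):
    """Adaptive Gauss-Hermite over the year effects when the territory
    variance is zero (cells factorize over years)."""
    Y = data.n_years
    inv_sy2 = 1.0 / sig_y ** 2
    v0 = np.zeros(data.n_territories)
    # year modes via the joint-Laplace Newton restricted to u
    u, _, _, _, _ = _inner_newton(gamma, delta, sig_y, 0.0, data)
    _, _, h_eta, _, _, _ = _cell_terms(gamma, delta, u, v0, data)
    Hu = np.maximum(-(np.bincount(data.t_idx, weights=h_eta,
                                  minlength=Y)) + inv_sy2, 1e-10)
    s_t = np.sqrt(2.0 / Hu)
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    logw = np.log(weights)
    psi_nodes = np.empty((Y, n_nodes))
    const = -0.5 * math.log(2 * math.pi * sig_y ** 2)
    for k in range(n_nodes):
        uk = u + s_t * nodes[k]
        ll = _cell_terms(gamma, delta, uk, v0, data)[0]
        psi_nodes[:, k] = (np.bincount(data.t_idx, weights=ll, minlength=Y)
                           - 0.5 * uk ** 2 * inv_sy2 + const)
    log_terms = logw[None, :] + psi_nodes + nodes[None, :] ** 2
    logG = np.log(s_t) + logsumexp(log_terms, axis=1)
    return float(logG.sum()), u


def marginal_loglik(gamma, delta, sigma_year: float, sigma_territory: float,
                    data: OccupancyData, u0=None, v0=None,
                    method: str = "auto", n_agh: int = _DEFAULT_AGH_NODES,
                    return_mode: bool = False):
    """Marginal log-likelihood of the stacked occupancy model.

    ``method='auto'`` (production): exact when both variances are zero,
    adaptive Gauss-Hermite for a single active factor, nested AGH/Laplace
    for the crossed case. ``method='laplace'`` forces the plain joint
    Laplace approximation.
    """
    gamma = np.asarray(gamma, float)
    delta = np.asarray(delta, float)
    if sigma_year < 0 or sigma_territory < 0:
        raise ValueError("random-effect SDs must be non-negative")

    if method == "laplace":
        u, v, logdet, g_mode, conv = _inner_newton(
            gamma, delta, sigma_year, sigma_territory, data, u0=u0, v0=v0)
        dim = (data.n_years if sigma_year > 0 else 0) + \
              (data.n_territories if sigma_territory > 0 else 0)
        ll = g_mode + 0.5 * dim * math.log(2 * math.pi) - 0.5 * logdet
        mode = {"u": u, "v": v, "converged": conv}
    elif method == "auto":
        if sigma_territory == 0 and sigma_year == 0:
            u = np.zeros(data.n_years)
            v = np.zeros(data.n_territories)
            ll = float(_cell_terms(gamma, delta, u, v, data)[0].sum())
            mode = {"u": u, "v": v, "converged": True}
        elif sigma_territory == 0:
            ll, u = _agh_year_only(gamma, delta, sigma_year, data, n_agh)
            mode = {"u": u, "v": np.zeros(data.n_territories),
                    "converged": True}
        elif sigma_year == 0:
            logG, vhat, _ = _agh_territory(gamma, delta,
                                           np.zeros(data.n_years),
                                           sigma_territory, data, n_agh,
                                           v0=v0)
            ll = float(logG.sum())
            mode = {"u": np.zeros(data.n_years), "v": vhat, "converged": True}
        else:
            ll, u, v, conv = _marginal_nested(
                gamma, delta, sigma_year, sigma_territory, data, n_agh,
                u0=u0, v0=v0)
            mode = {"u": u, "v": v, "converged": conv}
    else:
        raise ValueError("method must be 'auto' or 'laplace'")
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite marginal log-likelihood")
    if return_mode:
        return ll, mode
    return ll


def agh_marginal_loglik(gamma, delta, sigma: float, data: OccupancyData,
                        factor: str = "territory", n_nodes: int = 61) -> float:
    """Scalar adaptive Gauss-Hermite oracle for single-factor random
    effects.

    Integrates each factor level's likelihood independently with
    ``n_nodes`` nodes centered and scaled at the integrand's mode, found by
    scalar optimization with numerical curvature. Deliberately independent
    of the vectorized production path; quadratically slow, for tests.
    """
    gamma = np.asarray(gamma, float)
    delta = np.asarray(delta, float)
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    if factor == "territory":
        groups, n_groups = data.i_idx, data.n_territories
    elif factor == "year":
        groups, n_groups = data.t_idx, data.n_years
    else:
        raise ValueError("factor must be 'territory' or 'year'")

    def group_loglik(level: int, r: float) -> float:
        sel = groups == level
        u = np.zeros(data.n_years)
        v = np.zeros(data.n_territories)
        if factor == "territory":
            v[level] = r
        else:
            u[level] = r
        ll = _cell_terms(gamma, delta, u, v, data)[0]
        return float(ll[sel].sum())

    total = 0.0
    for level in range(n_groups):
        def f(r):
            return (group_loglik(level, float(r))
                    - 0.5 * r ** 2 / sigma ** 2
                    - 0.5 * math.log(2 * math.pi * sigma ** 2))
        res = optimize.minimize_scalar(lambda r: -f(r),
                                       bounds=(-12 * sigma, 12 * sigma),
                                       method="bounded",
                                       options={"xatol": 1e-10})
        m = float(res.x)
        h = 1e-4 * max(1.0, abs(m))
        curv = -(f(m + h) - 2 * f(m) + f(m - h)) / h ** 2
        curv = max(curv, 1.0 / (100.0 * sigma ** 2))
        scale = math.sqrt(2.0 / curv)
        vals = np.array([f(m + scale * x) + x * x for x in nodes])
        total += float(np.log(scale * np.dot(weights, np.exp(vals - vals.max())))
                       + vals.max())
    return total


# ---------------------------------------------------------------------------
# fitting


@dataclasses.dataclass
class FittedOccupancyModel:
    """MLE of the stacked occupancy model.

    ``sigma_year`` / ``sigma_territory`` are the random-intercept SDs
    (reported as exactly 0, with a boundary flag, when the estimate hit the
    lower boundary); ``cov`` covers the free parameters in ``param_names``
    order (NaN rows for boundary variances). ``u_mode`` / ``v_mode`` are
    the conditional modes of the random effects at the optimum.
    """

    gamma: np.ndarray
    delta: np.ndarray
    names_psi: list
    names_det: list
    sigma_year: float
    sigma_territory: float
    boundary_year: bool
    boundary_territory: bool
    cov: np.ndarray | None
    param_names: list
    loglik: float
    u_mode: np.ndarray
    v_mode: np.ndarray
    convergence: dict
    n_agh: int = _DEFAULT_AGH_NODES
    data: OccupancyData | None = None

    def to_json(self, path: str | Path | None = None) -> dict:
        d = {
            "gamma": self.gamma.tolist(), "delta": self.delta.tolist(),
            "names_psi": list(self.names_psi), "names_det": list(self.names_det),
            "sigma_year": self.sigma_year,
            "sigma_territory": self.sigma_territory,
            "boundary_year": self.boundary_year,
            "boundary_territory": self.boundary_territory,
            "cov": None if self.cov is None else self.cov.tolist(),
            "param_names": list(self.param_names),
            "loglik": self.loglik,
            "n_agh": self.n_agh,
            "u_mode": self.u_mode.tolist(), "v_mode": self.v_mode.tolist(),
            "convergence": self.convergence,
            "density_scaler": (None if self.data is None or
                               self.data.density_scaler is None
                               else self.data.density_scaler.to_dict()),
        }
        if path is not None:
            Path(path).write_text(json.dumps(d, indent=1))
        return d


def _theta_split(theta, k_psi):
    gamma = theta[:k_psi]
    delta = theta[k_psi:k_psi + 2]
    sig_y = math.exp(theta[k_psi + 2])
    sig_t = math.exp(theta[k_psi + 3])
    return gamma, delta, sig_y, sig_t


def fit_occupancy(data: OccupancyData, n_starts: int = 2, seed: int = 0,
                  start=None, compute_cov: bool = True,
                  n_agh: int = _DEFAULT_AGH_NODES,
                  method: str = "auto") -> FittedOccupancyModel:
    """Maximize the marginal likelihood.

    Random-effect SDs are estimated on the log scale with a hard floor;
    estimates reaching the floor (below 1e-4) are reported as 0 with a
    boundary flag. Wald covariance for the free parameters comes from a
    finite-difference Hessian of the marginal log-likelihood; a
    near-singular information matrix raises a flat-ridge warning flag (for
    example one survey per season with no covariates, where occupancy and
    detection are confounded).
    """
    k_psi = data.Xpsi.shape[1]
    k = k_psi + 4
    cache = {"u": None, "v": None}

    def negll(theta):
        gamma, delta, sig_y, sig_t = _theta_split(theta, k_psi)
        ll, mode = marginal_loglik(gamma, delta, sig_y, sig_t, data,
                                   u0=cache["u"], v0=cache["v"],
                                   method=method, n_agh=n_agh,
                                   return_mode=True)
        cache["u"], cache["v"] = mode["u"], mode["v"]
        return -ll

    det_any = data.detected_any
    naive_psi = float(np.clip(det_any.mean(), 0.05, 0.95))
    obs_det = data.y[data.obs & (det_any[:, None])]
    naive_p = float(np.clip(obs_det.mean() if obs_det.size else 0.5, 0.05, 0.95))
    base = np.zeros(k)
    base[0] = logit(naive_psi)
    base[k_psi] = logit(naive_p)
    base[k_psi + 2] = math.log(0.5)
    base[k_psi + 3] = math.log(1.0)

    rng = np.random.default_rng(seed)
    starts = [np.asarray(start, float)] if start is not None else [base]
    for _ in range(max(0, n_starts - 1)):
        starts.append(base + rng.normal(0, 0.3, size=k))

    def negll_coarse(theta):
        gamma, delta, sig_y, sig_t = _theta_split(theta, k_psi)
        ll, mode = marginal_loglik(gamma, delta, sig_y, sig_t, data,
                                   u0=cache["u"], v0=cache["v"],
                                   method=method, n_agh=7, return_mode=True)
        cache["u"], cache["v"] = mode["u"], mode["v"]
        return -ll

    lb = math.log(_SIGMA_FLOOR)
    bounds = [(-15.0, 15.0)] * (k_psi + 2) + [(lb, math.log(10.0))] * 2
    best = None
    for s in starts:
        cache["u"] = cache["v"] = None
        if start is None:
            # coarse pass with a cheap 7-node rule, then refine in full
            s = optimize.minimize(negll_coarse, s, method="L-BFGS-B",
                                  bounds=bounds,
                                  options={"maxiter": 300, "ftol": 1e-8}).x
        res = optimize.minimize(negll, s, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 200, "ftol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res

    # boundary candidates: the profile in log sigma is nearly flat near zero,
    # so when a variance estimate comes out small, also try the fit with that
    # variance pinned at the floor and keep the better optimum
    for idx in (k_psi + 2, k_psi + 3):
        if math.exp(best.x[idx]) < 0.3:
            b2 = list(bounds)
            b2[idx] = (lb, lb)
            s2 = best.x.copy()
            s2[idx] = lb
            cache["u"] = cache["v"] = None
            res_b = optimize.minimize(negll, s2, method="L-BFGS-B", bounds=b2,
                                      options={"maxiter": 100, "ftol": 1e-9})
            if res_b.fun <= best.fun:
                best = res_b
    theta = best.x
    gamma, delta, sig_y, sig_t = _theta_split(theta, k_psi)
    boundary_y = sig_y < _SIGMA_BOUNDARY
    boundary_t = sig_t < _SIGMA_BOUNDARY

    ll, mode = marginal_loglik(gamma, delta, sig_y, sig_t, data,
                               method=method, n_agh=n_agh, return_mode=True)
    names_psi = ["intercept"] + list(data.density_cols)
    names_det = ["intercept", "day_of_year"]
    param_names = ([f"psi:{n}" for n in names_psi]
                   + [f"p:{n}" for n in names_det]
                   + ["log_sigma_year", "log_sigma_territory"])

    free = list(range(k_psi + 2))
    if not boundary_y:
        free.append(k_psi + 2)
    if not boundary_t:
        free.append(k_psi + 3)

    cov = None
    flags = {"converged": bool(best.success), "message": str(best.message),
             "flat_ridge": False, "inner_converged": bool(mode["converged"])}
    if compute_cov:
        def fd_hessian(idx):
            nf = len(idx)
            H = np.zeros((nf, nf))
            steps = [1e-3 * max(1.0, abs(theta[j])) for j in idx]
            for a, ja in enumerate(idx):
                for b in range(a + 1):
                    jb = idx[b]
                    ha, hb = steps[a], steps[b]
                    tpp = theta.copy(); tpp[ja] += ha; tpp[jb] += hb
                    tpm = theta.copy(); tpm[ja] += ha; tpm[jb] -= hb
                    tmp = theta.copy(); tmp[ja] -= ha; tmp[jb] += hb
                    tmm = theta.copy(); tmm[ja] -= ha; tmm[jb] -= hb
                    H[a, b] = H[b, a] = (negll(tpp) - negll(tpm) - negll(tmp)
                                         + negll(tmm)) / (4 * ha * hb)
            return H

        H = fd_hessian(free)
        eig = np.linalg.eigvalsh(H)
        if eig.min() <= 0 and (k_psi + 2) in free:
            # the year-variance direction is often nearly flat; profile it
            # out rather than report an indefinite information matrix
            free = [j for j in free if j != k_psi + 2]
            flags["sigma_year_profiled"] = True
            H = fd_hessian(free)
            eig = np.linalg.eigvalsh(H)
        if eig.min() < 1e-10 * max(eig.max(), 1.0):
            flags["flat_ridge"] = True
        if eig.min() > 0:
            cov_free = np.linalg.inv(H)
        else:
            # last resort: eigenvalue-repaired inverse, clearly flagged
            flags["flat_ridge"] = True
            w, V = np.linalg.eigh(H)
            w = np.maximum(np.abs(w), 1e-8 * max(abs(eig.max()), 1.0))
            cov_free = (V / w) @ V.T
        cov = np.full((k, k), np.nan)
        for a, ja in enumerate(free):
            for b, jb in enumerate(free):
                cov[ja, jb] = cov_free[a, b]

    return FittedOccupancyModel(
        gamma=gamma, delta=delta, names_psi=names_psi, names_det=names_det,
        sigma_year=0.0 if boundary_y else sig_y,
        sigma_territory=0.0 if boundary_t else sig_t,
        boundary_year=boundary_y, boundary_territory=boundary_t,
        cov=cov, param_names=param_names, loglik=float(ll),
        u_mode=mode["u"], v_mode=mode["v"], convergence=flags,
        n_agh=n_agh, data=data)


def occupancy_coefficient_table(fit: FittedOccupancyModel,
                                level: float = 0.95) -> pd.DataFrame:
    """Wald table for the fixed effects (logit scale)."""
    if fit.cov is None:
        raise ValueError("covariance unavailable")
    k_psi = len(fit.gamma)
    est = np.concatenate([fit.gamma, fit.delta])
    se = np.sqrt(np.diag(fit.cov)[:k_psi + 2])
    z = norm.ppf(0.5 + level / 2.0)
    lo, hi = est - z * se, est + z * se
    names = ([f"psi:{n}" for n in fit.names_psi]
             + [f"p:{n}" for n in fit.names_det])
    return pd.DataFrame({"coefficient": names, "estimate": est, "se": se,
                         "lower": lo, "upper": hi,
                         "significant": (lo > 0) | (hi < 0)})


def occupancy_marginal_effect(fit: FittedOccupancyModel, species: str,
                              density_grid=None, n_points: int = 50,
                              level: float = 0.95) -> pd.DataFrame:
    """Occupancy probability versus one prey species' density, the other
    densities at their means and random effects at zero. The band is the
    inverse-logit image of the Wald CI on the linear predictor (a monotone
    transform, so the endpoints map exactly)."""
    if species not in fit.names_psi[1:]:
        raise ValueError(f"species {species!r} not in occupancy model")
    scaler = None if fit.data is None else fit.data.density_scaler
    if density_grid is None:
        if scaler is not None:
            mu, sd = scaler.means[species], scaler.sds[species]
            density_grid = np.linspace(max(0.0, mu - 2 * sd), mu + 2 * sd,
                                       n_points)
        else:
            density_grid = np.linspace(-1, 1, n_points)
    density_grid = np.asarray(density_grid, float)
    std = (scaler.transform_array(density_grid, species)
           if scaler is not None else density_grid)
    X = np.zeros((len(std), len(fit.names_psi)))
    X[:, 0] = 1.0
    X[:, fit.names_psi.index(species)] = std
    eta = X @ fit.gamma
    if fit.cov is not None:
        k_psi = len(fit.gamma)
        sig = fit.cov[:k_psi, :k_psi]
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, sig, X), 0.0))
    else:
        se = np.zeros(len(std))
    z = norm.ppf(0.5 + level / 2.0)
    return pd.DataFrame({"density_per_km2": density_grid,
                         "psi": expit(eta),
                         "lower": expit(eta - z * se),
                         "upper": expit(eta + z * se)})


def mean_psi_p(fit: FittedOccupancyModel, data: OccupancyData | None = None) -> dict:
    """Mean fitted occupancy and detection probabilities over the observed
    units, random effects at their conditional modes."""
    data = data if data is not None else fit.data
    psi = expit(data.Xpsi @ fit.gamma + fit.u_mode[data.t_idx])
    eta_p = fit.delta[0] + fit.delta[1] * data.day + fit.v_mode[data.i_idx][:, None]
    p = expit(eta_p)[data.obs]
    return {"mean_psi": float(psi.mean()), "mean_p": float(p.mean()),
            "method": "random effects at conditional modes"}


# ---------------------------------------------------------------------------
# MacKenzie-Bailey goodness of fit


def _history_tallies(gamma, delta, sigma_year, sigma_territory,
                     data: OccupancyData, n_nodes: int = 21):
    """Observed and model-expected tallies of detection histories, grouped
    into cohorts by missingness pattern.

    Expected counts are the *marginal* probabilities of each history under
    the fitted model — the random effects integrated out with fixed
    Gauss-Hermite quadrature — so the statistic is comparable between the
    observed data and parametric replicates.
    """
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    weights = weights / math.sqrt(math.pi)
    u_nodes = math.sqrt(2.0) * sigma_year * nodes if sigma_year > 0 \
        else np.zeros(1)
    u_w = weights if sigma_year > 0 else np.ones(1)
    v_nodes = math.sqrt(2.0) * sigma_territory * nodes \
        if sigma_territory > 0 else np.zeros(1)
    v_w = weights if sigma_territory > 0 else np.ones(1)

    eta_psi = data.Xpsi @ gamma                              # (n_cells,)
    psi_marg = (expit(eta_psi[:, None] + u_nodes[None, :]) @ u_w)
    n_surv = data.y.shape[1]
    cohorts: dict[tuple, dict] = {}
    for c in range(len(data.y)):
        pattern = tuple(bool(b) for b in data.obs[c])
        slots = [j for j in range(n_surv) if pattern[j]]
        coh = cohorts.setdefault(pattern, {"obs": {}, "exp": {}, "slots": slots})
        hist = tuple(int(data.y[c, j]) for j in slots)
        coh["obs"][hist] = coh["obs"].get(hist, 0) + 1
        # detection probabilities at the territory-effect nodes
        p = expit(delta[0] + delta[1] * data.day[c, slots][None, :]
                  + v_nodes[:, None])                        # (K, n_slots)
        for m in range(2 ** len(slots)):
            h = tuple((m >> b) & 1 for b in range(len(slots)))
            harr = np.array(h, dtype=float)
            cond = float(np.prod(np.where(harr > 0, p, 1.0 - p), axis=1) @ v_w)
            val = psi_marg[c] * cond \
                + (1.0 - psi_marg[c]) * (1.0 if not any(h) else 0.0)
            coh["exp"][h] = coh["exp"].get(h, 0.0) + val
    return cohorts


def _mb_chisq(cohorts: dict, pool_threshold: float = 2.0) -> float:
    chi = 0.0
    for coh in cohorts.values():
        hists = sorted(coh["exp"])
        big = [(coh["obs"].get(h, 0), coh["exp"][h]) for h in hists
               if coh["exp"][h] >= pool_threshold]
        small = [(coh["obs"].get(h, 0), coh["exp"][h]) for h in hists
                 if coh["exp"][h] < pool_threshold]
        cells = list(big)
        if small:
            cells.append((sum(o for o, _ in small), sum(e for _, e in small)))
        for o, e in cells:
            if e > 0:
                chi += (o - e) ** 2 / e
    return float(chi)


def mb_gof(fit: FittedOccupancyModel, B: int = 200, seed: int = 0,
           pool_threshold: float = 2.0) -> dict:
    """MacKenzie-Bailey parametric bootstrap: Pearson chi-square on tallies
    of detection histories (cohorts = missingness patterns; expected cells
    below ``pool_threshold`` pooled), with B replicates simulated from the
    fitted model and refitted (warm-started from the original optimum)."""
    data = fit.data
    if data is None:
        raise ValueError("fit carries no data")
    chi_obs = _mb_chisq(_history_tallies(fit.gamma, fit.delta,
                                         fit.sigma_year,
                                         fit.sigma_territory, data),
                        pool_threshold)
    rng = np.random.default_rng(seed)
    theta_hat = np.concatenate([
        fit.gamma, fit.delta,
        [math.log(max(fit.sigma_year, _SIGMA_FLOOR)),
         math.log(max(fit.sigma_territory, _SIGMA_FLOOR))]])
    boot = np.empty(B)
    failed = 0
    for b in range(B):
        u_star = rng.normal(0, fit.sigma_year, data.n_years) \
            if fit.sigma_year > 0 else np.zeros(data.n_years)
        v_star = rng.normal(0, fit.sigma_territory, data.n_territories) \
            if fit.sigma_territory > 0 else np.zeros(data.n_territories)
        psi = expit(data.Xpsi @ fit.gamma + u_star[data.t_idx])
        p = expit(fit.delta[0] + fit.delta[1] * data.day
                  + v_star[data.i_idx][:, None])
        z = rng.binomial(1, psi)
        yb = rng.binomial(1, z[:, None] * p) * data.obs
        data_b = dataclasses.replace(data, y=yb.astype(float))
        try:
            fit_b = fit_occupancy(data_b, n_starts=1, start=theta_hat,
                                  compute_cov=False, n_agh=fit.n_agh)
            boot[b] = _mb_chisq(_history_tallies(
                fit_b.gamma, fit_b.delta, fit_b.sigma_year,
                fit_b.sigma_territory, data_b), pool_threshold)
        except (FloatingPointError, np.linalg.LinAlgError):
            failed += 1
            boot[b] = np.nan
    ok = np.isfinite(boot)
    p_val = float(np.mean(boot[ok] >= chi_obs))
    c_hat = float(chi_obs / np.mean(boot[ok]))
    return {"chisq_observed": chi_obs, "p_value": p_val, "c_hat": c_hat,
            "B": B, "seed": seed, "n_failed_refits": failed,
            "pool_threshold": pool_threshold}
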