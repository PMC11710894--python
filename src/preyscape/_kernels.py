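"""Hot numerical kernels for the occupancy marginal likelihood.

Compiled with numba when available (single-pass loops, no temporaries);
otherwise vectorized numpy fallbacks with identical signatures. All
detection-side quantities use numerically stable log-sigmoid forms.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap(args[0]) if args and callable(args[0]) else wrap


@njit(cache=True, fastmath=True)
def _rule_setup_nb(base_p, y, obs, v_cells):
    """Per cell x node: Bernoulli log-likelihood of the observed surveys
    (``bern``) and the probability of an all-zero history (``q``)."""
    n, K = v_cells.shape
    S = base_p.shape[1]
    bern = np.zeros((n, K))
    q = np.zeros((n, K))
    for c in range(n):
        for k in range(K):
            b = 0.0
            lq = 0.0
            for j in range(S):
                if obs[c, j]:
                    eta = base_p[c, j] + v_cells[c, k]
                    if eta > 0.0:
                        lp = -math.log1p(math.exp(-eta))
                        l1p = -eta + lp
                    else:
                        l1p = -math.log1p(math.exp(eta))
                        lp = eta + l1p
                    if y[c, j] > 0.0:
                        b += lp
                    else:
                        b += l1p
                    lq += l1p
            bern[c, k] = b
            q[c, k] = math.exp(lq)
    return bern, q


@njit(cache=True, fastmath=True)
def _eval_ll_nb(psi, det, bern, q, want_derivs):
    """Cell log-likelihoods plus occupancy-logit derivatives for fixed
    detection-side quantities."""
    n, K = bern.shape
    ll = np.empty((n, K))
    a = np.zeros((n, K))
    b = np.zeros((n, K))
    for c in range(n):
        ps = psi[c]
        dp = ps * (1.0 - ps)
        if det[c]:
            lp = math.log(ps) if ps > 1e-300 else -690.0
            for k in range(K):
                ll[c, k] = lp + bern[c, k]
                if want_derivs:
                    a[c, k] = 1.0 - ps
                    b[c, k] = -dp
        else:
            for k in range(K):
                L = ps * q[c, k] + 1.0 - ps
                if L < 1e-300:
                    L = 1e-300
                ll[c, k] = math.log(L)
                if want_derivs:
                    g = dp * (q[c, k] - 1.0) / L
                    a[c, k] = g
                    b[c, k] = dp * (1.0 - 2.0 * ps) * (q[c, k] - 1.0) / L - g * g
    return ll, a, b


@njit(cache=True, fastmath=True)
def _v_derivs_nb(base_p, y, obs, psi, det, v_cells):
    """Cell log-likelihood and first/second derivatives with respect to the
    territory detection intercept, at one v value per cell."""
    n = base_p.shape[0]
    S = base_p.shape[1]
    ll = np.empty(n)
    g = np.empty(n)
    h = np.empty(n)
    for c in range(n):
        ps = psi[c]
        if det[c]:
            tot = math.log(ps) if ps > 1e-300 else -690.0
            gg = 0.0
            hh = 0.0
            for j in range(S):
                if obs[c, j]:
                    eta = base_p[c, j] + v_cells[c]
                    if eta > 0.0:
                        lp = -math.log1p(math.exp(-eta))
                        l1p = -eta + lp
                    else:
                        l1p = -math.log1p(math.exp(eta))
                        lp = eta + l1p
                    p = math.exp(lp)
                    tot += lp if y[c, j] > 0.0 else l1p
                    gg += y[c, j] - p
                    hh -= p * (1.0 - p)
            ll[c] = tot
            g[c] = gg
            h[c] = hh
        else:
            lq = 0.0
            s = 0.0
            s2 = 0.0
            for j in range(S):
                if obs[c, j]:
                    eta = base_p[c, j] + v_cells[c]
                    if eta > 0.0:
                        l1p = -eta - math.log1p(math.exp(-eta))
                    else:
                        l1p = -math.log1p(math.exp(eta))
                    p = 1.0 - math.exp(l1p)
                    lq += l1p
                    s += p
                    s2 += p * (1.0 - p)
            q = math.exp(lq)
            L = ps * q + 1.0 - ps
            if L < 1e-300:
                L = 1e-300
            gg = ps * (-q * s) / L
            ll[c] = math.log(L)
            g[c] = gg
            h[c] = ps * (q * s * s - q * s2) / L - gg * gg
    return ll, g, h


if _HAVE_NUMBA:
    rule_setup = _rule_setup_nb
    eval_ll = _eval_ll_nb
    v_derivs = _v_derivs_nb
else:  # pragma: no cover - numpy fallbacks, same contracts

    def rule_setup(base_p, y, obs, v_cells):
        from scipy.special import expit
        p = np.clip(expit(base_p[:, :, None] + v_cells[:, None, :]),
                    1e-12, 1.0 - 1e-12)
        obs3 = obs[:, :, None]
        y3 = y[:, :, None]
        bern = ((y3 * np.log(p) + (1.0 - y3) * np.log1p(-p)) * obs3).sum(axis=1)
        q = np.exp((np.log1p(-p) * obs3).sum(axis=1))
        return bern, q

    def eval_ll(psi, det, bern, q, want_derivs):
        psi2 = psi[:, None]
        L = np.clip(psi2 * q + 1.0 - psi2, 1e-300, None)
        ll = np.where(det[:, None],
                      np.log(np.clip(psi2, 1e-300, 1.0)) + bern, np.log(L))
        a = b = np.zeros_like(ll)
        if want_derivs:
            dp = psi2 * (1.0 - psi2)
            g_nd = dp * (q - 1.0) / L
            a = np.where(det[:, None], 1.0 - psi2, g_nd)
            b = np.where(det[:, None], -dp,
                         dp * (1.0 - 2.0 * psi2) * (q - 1.0) / L - g_nd ** 2)
        return ll, a, b

    def v_derivs(base_p, y, obs, psi, det, v_cells):
        from scipy.special import expit
        p = np.clip(expit(base_p + v_cells[:, None]), 1e-12, 1.0 - 1e-12)
        yob = y * obs
        g_det = ((yob - p) * obs).sum(axis=1)
        h_det = -(p * (1.0 - p) * obs).sum(axis=1)
        log_q = (np.log1p(-p) * obs).sum(axis=1)
        q = np.exp(log_q)
        s = (p * obs).sum(axis=1)
        s2 = (p * (1.0 - p) * obs).sum(axis=1)
        L = np.clip(psi * q + 1.0 - psi, 1e-300, None)
        g_nd = psi * (-q * s) / L
        h_nd = psi * (q * s * s - q * s2) / L - g_nd ** 2
        ll_det = np.log(np.clip(psi, 1e-300, 1.0)) + (
            (yob * np.log(p) + (1.0 - y) * np.log1p(-p) * obs) * obs).sum(axis=1)
        ll = np.where(det, ll_det, np.log(L))
        g = np.where(det, g_det, g_nd)
        h = np.where(det, h_det, h_nd)
        return ll, g, h
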