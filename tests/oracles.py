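"""Independent reference implementations used as test oracles.

These deliberately use different algorithms from the package: the prox is
checked against Douglas-Rachford splitting built from the two single-norm
proximal maps, the lasso limit against cyclic coordinate descent, the group
lasso limit against block coordinate descent with an exact scalar root find
per block, and KKT stationarity against a from-scratch subgradient checker.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq


# ---------------------------------------------------------------------------
# Numerical minimization of the prox objective (Douglas-Rachford)
# ---------------------------------------------------------------------------

def dr_prox(v, step, alpha, lam, groups, weights, iters=2000, tol=1e-13):
    """argmin_z 0.5||z-v||^2 + step*(alpha*lam*||z||_1
    + (1-alpha)*lam*sum_l w_l ||z^(l)||_2), by Douglas-Rachford splitting
    of f(z) = 0.5||z-v||^2 + a||z||_1 and g(z) = b||z||_2 per group."""
    v = np.asarray(v, dtype=float)
    out = np.empty_like(v)
    a = step * alpha * lam
    for ell, g in enumerate(groups):
        vg = v[np.asarray(g)]
        b = step * (1.0 - alpha) * lam * weights[ell]
        x = vg.copy()
        for _ in range(iters):
            n = np.linalg.norm(x)
            z = np.zeros_like(x) if n <= b else (1.0 - b / n) * x
            r = 2.0 * z - x
            # prox of f with unit DR step: argmin f + 0.5||.-r||^2
            pf = np.sign(vg + r) * np.maximum(np.abs(vg + r) / 2 - a / 2, 0)
            x_new = x + pf - z
            if np.max(np.abs(x_new - x)) < tol:
                x = x_new
                break
            x = x_new
        n = np.linalg.norm(x)
        out[np.asarray(g)] = np.zeros_like(x) if n <= b else (1 - b / n) * x
    return out


def prox_objective(z, v, step, alpha, lam, groups, weights):
    z = np.asarray(z, dtype=float)
    pen = alpha * lam * np.sum(np.abs(z)) + (1 - alpha) * lam * sum(
        w * np.linalg.norm(z[np.asarray(g)]) for g, w in zip(groups, weights)
    )
    return 0.5 * float(np.sum((z - v) ** 2)) + step * pen


# ---------------------------------------------------------------------------
# Cyclic coordinate-descent lasso (alpha = 1 limit)
# ---------------------------------------------------------------------------

def cd_lasso(X, y, lam, max_iter=20000, tol=1e-12):
    """minimize 0.5||y - b0 - X beta||^2 + lam ||beta||_1 by cyclic CD."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    xm = X.mean(axis=0)
    ym = float(y.mean())
    Xc = X - xm
    yc = y - ym
    n, p = Xc.shape
    col_sq = np.sum(Xc * Xc, axis=0)
    beta = np.zeros(p)
    r = yc.copy()
    for _ in range(max_iter):
        delta = 0.0
        for j in range(p):
            if col_sq[j] == 0:
                continue
            rho = Xc[:, j] @ r + col_sq[j] * beta[j]
            new = np.sign(rho) * max(abs(rho) - lam, 0.0) / col_sq[j]
            if new != beta[j]:
                r += Xc[:, j] * (beta[j] - new)
                delta = max(delta, abs(new - beta[j]))
                beta[j] = new
        if delta < tol:
            break
    return beta, ym - float(xm @ beta)


# ---------------------------------------------------------------------------
# Block coordinate-descent group lasso (alpha = 0 limit)
# ---------------------------------------------------------------------------

def bcd_group_lasso(X, y, lam, groups, weights, max_iter=5000, tol=1e-12):
    """minimize 0.5||y - b0 - X beta||^2 + lam sum w_l ||beta^(l)||_2.

    Each block update is exact: the block is zeroed when the partial
    gradient norm is below its threshold, otherwise solved through the
    eigendecomposition of X_l^T X_l and a scalar root find on ||beta_l||.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    xm = X.mean(axis=0)
    ym = float(y.mean())
    Xc = X - xm
    yc = y - ym
    p = Xc.shape[1]
    beta = np.zeros(p)
    r = yc.copy()  # residual yc - Xc beta
    eig = []
    for g in groups:
        G = Xc[:, np.asarray(g)]
        lamb, Q = np.linalg.eigh(G.T @ G)
        eig.append((np.maximum(lamb, 0.0), Q))
    for _ in range(max_iter):
        delta = 0.0
        for ell, g in enumerate(groups):
            g = np.asarray(g)
            G = Xc[:, g]
            old = beta[g].copy()
            a = G.T @ (r + G @ old)  # gradient-free target X^T r_{-l}
            thr = lam * weights[ell]
            if np.linalg.norm(a) <= thr:
                new = np.zeros(len(g))
            else:
                lamb, Q = eig[ell]
                b = Q.T @ a

                def norm_eq(t):
                    return np.linalg.norm(b / (lamb + thr / t)) - t

                # norm_eq > 0 at tiny t (since ||a|| > thr), < 0 at large t
                lo, hi = 1e-12, 1.0
                while norm_eq(hi) > 0 and hi < 1e12:
                    hi *= 10
                t = brentq(norm_eq, lo, hi, xtol=1e-14, rtol=1e-15)
                new = Q @ (b / (lamb + thr / t))
            if np.any(new != old):
                r += G @ (old - new)
                delta = max(delta, np.max(np.abs(new - old)))
                beta[g] = new
        if delta < tol:
            break
    return beta, ym - float(xm @ beta)


# ---------------------------------------------------------------------------
# Independent KKT stationarity checker
# ---------------------------------------------------------------------------

def kkt_violation(X, y, beta, intercept, alpha, lam, groups, weights,
                  loss="squared"):
    """Largest violation of the first-order conditions at (intercept, beta),
    written from the subgradient calculus directly."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if loss == "squared":
        resid = y - intercept - X @ beta
        grad = -X.T @ resid
        worst = abs(np.sum(resid))  # intercept stationarity
    else:
        z = intercept + X @ beta
        prob = 1.0 / (1.0 + np.exp(-z))
        grad = X.T @ (prob - y)
        worst = abs(np.sum(prob - y))
    a = alpha * lam
    for ell, g in enumerate(groups):
        g = np.asarray(g)
        gl, bl = grad[g], beta[g]
        b = (1 - alpha) * lam * weights[ell]
        if np.all(bl == 0):
            # need: exists u in [-a,a]^p, s with ||s||<=b, gl + u + s = 0
            shrunk = np.sign(gl) * np.maximum(np.abs(gl) - a, 0.0)
            worst = max(worst, np.linalg.norm(shrunk) - b)
        else:
            direction = bl / np.linalg.norm(bl)
            for j in range(len(g)):
                gj = gl[j] + b * direction[j]
                if bl[j] != 0:
                    worst = max(worst, abs(gj + a * np.sign(bl[j])))
                else:
                    worst = max(worst, abs(gj) - a)
    return float(worst)
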