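"""Binomial (logit) mixed model with independent random intercepts.

Fitting follows the standard Laplace approximation used for generalized
linear mixed models: for candidate variance components the fixed effects
and random intercepts are found jointly by penalized iteratively reweighted
least squares (PIRLS), and the Laplace-approximate marginal log-likelihood

    l(beta, sigma^2) = loglik(y | eta_hat)
                       - 1/2 u_hat' D^-1 u_hat
                       - 1/2 log det D - 1/2 log det(Z' W Z + D^-1)

is maximized over the variance components by a derivative-free outer
search.  The fixed-effect covariance is the conditional (on the variance
components) information matrix, as in lme4's ``glmer`` with ``nAGQ=1``.

Only independent random intercepts are supported (one variance per
grouping factor), which covers grouping by participant, group/session,
group size or avatar type.  A single grouping factor uses a fast
diagonal-Schur solve; multiple (crossed) factors use a dense solve over
the concatenated random-effect block and are intended for the small
trial-level tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import expit

_CLIP_W = 1e-10


@dataclass
class BinomialMixedFit:
    beta: np.ndarray
    cov_beta: np.ndarray
    vc: dict[str, float]                 # variance per grouping factor
    loglike: float
    converged: bool
    u: dict[str, np.ndarray] = field(default_factory=dict)
    n_obs: int = 0


def _pirls(X: np.ndarray, y: np.ndarray, codes: list[np.ndarray],
           qs: list[int], sigma2: np.ndarray, maxiter: int = 60,
           tol: float = 1e-9):
    """Joint (beta, u) mode for fixed variance components.

    Returns (beta, u_list, cov_beta, laplace_loglike, converged).
    """
    n, p = X.shape
    F = len(codes)
    beta = np.zeros(p)
    us = [np.zeros(q) for q in qs]
    dense = F > 1
    qtot = int(sum(qs))
    offs = np.cumsum([0] + qs)
    eta = X @ beta
    ok = False
    for it in range(maxiter):
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), _CLIP_W, None)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        A = X.T @ Xw                                    # (p, p)
        rx = X.T @ (w * z)
        if dense:
            C = np.zeros((qtot, qtot))
            B = np.zeros((p, qtot))
            rz = np.zeros(qtot)
            for f in range(F):
                sl = slice(offs[f], offs[f + 1])
                np.add.at(B.T[sl], codes[f], Xw)
                rz[sl] = np.bincount(codes[f], weights=w * z, minlength=qs[f])
                C[sl, sl][np.diag_indices(qs[f])] += 1.0 / sigma2[f]
                for g in range(F):
                    slg = slice(offs[g], offs[g + 1])
                    block = np.zeros((qs[f], qs[g]))
                    np.add.at(block, (codes[f], codes[g]), w)
                    C[sl, slg] += block
            M = np.block([[A, B], [B.T, C]])
            rhs = np.concatenate([rx, rz])
            sol = np.linalg.solve(M, rhs)
            beta_new, uvec = sol[:p], sol[p:]
            us_new = [uvec[offs[f]:offs[f + 1]] for f in range(F)]
        else:
            c0 = codes[0]
            cdiag = np.bincount(c0, weights=w, minlength=qs[0]) + 1.0 / sigma2[0]
            B = np.zeros((qs[0], p))
            np.add.at(B, c0, Xw)                        # B = Z'WX
            rz = np.bincount(c0, weights=w * z, minlength=qs[0])
            S = A - (B.T / cdiag) @ B
            rhs = rx - B.T @ (rz / cdiag)
            beta_new = np.linalg.solve(S, rhs)
            u_new = (rz - B @ beta_new) / cdiag
            us_new = [u_new]
        eta_new = X @ beta_new
        for f in range(F):
            eta_new = eta_new + us_new[f][codes[f]]
        delta = np.max(np.abs(eta_new - eta)) if n else 0.0
        beta, us, eta = beta_new, us_new, eta_new
        if delta < tol:
            ok = True
            break

    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), _CLIP_W, None)
    loglik = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    pen = float(sum((us[f] ** 2).sum() / (2.0 * sigma2[f]) for f in range(F)))
    logdet_d = float(sum(qs[f] * np.log(sigma2[f]) for f in range(F)))
    Xw = X * w[:, None]
    if dense:
        C = np.zeros((qtot, qtot))
        for f in range(F):
            sl = slice(offs[f], offs[f + 1])
            C[sl, sl][np.diag_indices(qs[f])] += 1.0 / sigma2[f]
            for g in range(F):
                slg = slice(offs[g], offs[g + 1])
                block = np.zeros((qs[f], qs[g]))
                np.add.at(block, (codes[f], codes[g]), w)
                C[sl, slg] += block
        sign, logdet_h = np.linalg.slogdet(C)
        B = np.zeros((p, qtot))
        for f in range(F):
            sl = slice(offs[f], offs[f + 1])
            np.add.at(B.T[sl], codes[f], Xw)
        S = X.T @ Xw - B @ np.linalg.solve(C, B.T)
    else:
        c0 = codes[0]
        cdiag = np.bincount(c0, weights=w, minlength=qs[0]) + 1.0 / sigma2[0]
        logdet_h = float(np.sum(np.log(cdiag)))
        B = np.zeros((qs[0], p))
        np.add.at(B, c0, Xw)
        S = X.T @ Xw - (B.T / cdiag) @ B
    lap = loglik - pen - 0.5 * logdet_d - 0.5 * logdet_h
    cov_beta = np.linalg.inv(S)
    return beta, us, cov_beta, lap, ok


def _solve_u(X, y, codes, qs, sigma2, beta, us, maxiter=40, tol=1e-10):
    """Conditional mode of the random effects for fixed beta and variances."""
    F = len(codes)
    xb = X @ beta
    us = [u.copy() for u in us]
    qtot = int(sum(qs))
    offs = np.cumsum([0] + qs)
    for _ in range(maxiter):
        eta = xb.copy()
        for f in range(F):
            eta += us[f][codes[f]]
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), _CLIP_W, None)
        resid = y - mu
        if F == 1:
            g = np.bincount(codes[0], weights=resid, minlength=qs[0]) \
                - us[0] / sigma2[0]
            h = np.bincount(codes[0], weights=w, minlength=qs[0]) + 1.0 / sigma2[0]
            step = g / h
            us[0] = us[0] + step
            if np.max(np.abs(step)) < tol:
                break
        else:
            g = np.concatenate([
                np.bincount(codes[f], weights=resid, minlength=qs[f])
                - us[f] / sigma2[f] for f in range(F)])
            H = np.zeros((qtot, qtot))
            for f in range(F):
                sl = slice(offs[f], offs[f + 1])
                H[sl, sl][np.diag_indices(qs[f])] += 1.0 / sigma2[f]
                for gf in range(F):
                    slg = slice(offs[gf], offs[gf + 1])
                    block = np.zeros((qs[f], qs[gf]))
                    np.add.at(block, (codes[f], codes[gf]), w)
                    H[sl, slg] += block
            step = np.linalg.solve(H, g)
            for f in range(F):
                us[f] = us[f] + step[offs[f]:offs[f + 1]]
            if np.max(np.abs(step)) < tol:
                break
    return us


def _laplace_objective(X, y, codes, qs, sigma2, beta, us):
    """Laplace log-marginal at the conditional mode of u (beta fixed)."""
    F = len(codes)
    us = _solve_u(X, y, codes, qs, sigma2, beta, us)
    eta = X @ beta
    for f in range(F):
        eta = eta + us[f][codes[f]]
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), _CLIP_W, None)
    loglik = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    pen = float(sum((us[f] ** 2).sum() / (2.0 * sigma2[f]) for f in range(F)))
    logdet_d = float(sum(qs[f] * np.log(sigma2[f]) for f in range(F)))
    if F == 1:
        cdiag = np.bincount(codes[0], weights=w, minlength=qs[0]) + 1.0 / sigma2[0]
        logdet_h = float(np.sum(np.log(cdiag)))
    else:
        qtot = int(sum(qs))
        offs = np.cumsum([0] + qs)
        C = np.zeros((qtot, qtot))
        for f in range(F):
            sl = slice(offs[f], offs[f + 1])
            C[sl, sl][np.diag_indices(qs[f])] += 1.0 / sigma2[f]
            for g in range(F):
                slg = slice(offs[g], offs[g + 1])
                block = np.zeros((qs[f], qs[g]))
                np.add.at(block, (codes[f], codes[g]), w)
                C[sl, slg] += block
        _, logdet_h = np.linalg.slogdet(C)
    return loglik - pen - 0.5 * logdet_d - 0.5 * logdet_h, us


def fit_binomial_mixed(X: np.ndarray, y: np.ndarray,
                       factors: dict[str, np.ndarray],
                       maxiter: int = 200) -> BinomialMixedFit:
    """Fit a logistic model with independent random intercepts.

    Parameters
    ----------
    X : (n, p) fixed-effect design matrix (including intercept column).
    y : (n,) 0/1 response.
    factors : mapping factor name -> (n,) integer level codes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("binomial response must be 0/1")
    if not factors:
        raise ValueError("need at least one grouping factor")
    names = list(factors)
    codes = []
    qs = []
    for name in names:
        c = np.asarray(factors[name])
        _, inv = np.unique(c, return_inverse=True)
        codes.append(inv.astype(np.int64))
        qs.append(int(inv.max()) + 1)

    state: dict = {}

    def negll(log_s2: np.ndarray) -> float:
        s2 = np.exp(np.clip(log_s2, -12.0, 8.0))
        beta, us, cov, lap, ok = _pirls(X, y, codes, qs, s2, maxiter=60)
        state["last"] = (s2, beta, us, cov, lap, ok)
        return -lap

    x0 = np.zeros(len(names))
    res = optimize.minimize(negll, x0, method="Nelder-Mead",
                            options={"maxiter": maxiter, "xatol": 1e-4,
                                     "fatol": 1e-6})
    negll(res.x)  # ensure state matches the optimum
    s2, beta, us, cov, lap, inner_ok = state["last"]

    # refine (beta, log sigma^2) jointly on the Laplace criterion with the
    # random effects profiled out (moves from the joint-mode beta, as in
    # lme4's nAGQ=0, to the full Laplace optimum)
    p = X.shape[1]
    warm = {"us": [u.copy() for u in us]}

    def neg_joint(theta: np.ndarray) -> float:
        b = theta[:p]
        s2_ = np.exp(np.clip(theta[p:], -12.0, 8.0))
        lap_, us_ = _laplace_objective(X, y, codes, qs, s2_, b, warm["us"])
        warm["us"] = us_
        return -lap_

    theta0 = np.concatenate([beta, np.log(s2)])
    try:
        res2 = optimize.minimize(neg_joint, theta0, method="L-BFGS-B",
                                 options={"maxiter": 100, "ftol": 1e-10})
        if np.isfinite(res2.fun) and res2.fun <= -lap + 1e-8:
            beta = res2.x[:p]
            s2 = np.exp(np.clip(res2.x[p:], -12.0, 8.0))
            lap = -res2.fun
            us = _solve_u(X, y, codes, qs, s2, beta, warm["us"])
            cov = _beta_cov(X, y, codes, qs, s2, beta, us)
    except Exception:
        pass
    return BinomialMixedFit(
        beta=beta, cov_beta=cov,
        vc={name: float(s2[f]) for f, name in enumerate(names)},
        loglike=float(lap), converged=bool(res.success and inner_ok),
        u={name: us[f] for f, name in enumerate(names)}, n_obs=len(y))


def _beta_cov(X, y, codes, qs, sigma2, beta, us):
    """Conditional fixed-effect covariance at (beta, u-hat)."""
    F = len(codes)
    eta = X @ beta
    for f in range(F):
        eta = eta + us[f][codes[f]]
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), _CLIP_W, None)
    Xw = X * w[:, None]
    p = X.shape[1]
    if F == 1:
        cdiag = np.bincount(codes[0], weights=w, minlength=qs[0]) + 1.0 / sigma2[0]
        B = np.zeros((qs[0], p))
        np.add.at(B, codes[0], Xw)
        S = X.T @ Xw - (B.T / cdiag) @ B
    else:
        qtot = int(sum(qs))
        offs = np.cumsum([0] + qs)
        C = np.zeros((qtot, qtot))
        B = np.zeros((p, qtot))
        for f in range(F):
            sl = slice(offs[f], offs[f + 1])
            np.add.at(B.T[sl], codes[f], Xw)
            C[sl, sl][np.diag_indices(qs[f])] += 1.0 / sigma2[f]
            for g in range(F):
                slg = slice(offs[g], offs[g + 1])
                block = np.zeros((qs[f], qs[g]))
                np.add.at(block, (codes[f], codes[g]), w)
                C[sl, slg] += block
        S = X.T @ Xw - B @ np.linalg.solve(C, B.T)
    return np.linalg.inv(S)
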