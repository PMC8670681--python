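"""Check-loss quantile regression: the numerical engine.

The tau-th regression quantile solves

    min_b  sum_t rho_tau(y_t - x_t' b),    rho_tau(u) = u * (tau - 1{u <= 0}).

This is a linear program; we solve its bounded-variable dual

    max_a  y'a   s.t.  X'a = (1 - tau) X'1,   0 <= a <= 1,

with a Mehrotra predictor-corrector interior-point iteration (the
Frisch-Newton algorithm of Portnoy & Koenker).  The dual variable of the
equality constraint is exactly the coefficient vector b.  Every linear
algebra step is expressed over a leading batch axis, so thousands of small
problems sharing one shape (as in grid-profiled instrumental-variable
estimation) are solved simultaneously; a single problem is the batch of
size one.

``fit_qr_fe`` solves the pooled fixed-effects variant in which one
intercept per unit enters the design: the unit-dummy block is concentrated
out of each Newton system through its diagonal Schur complement, so the
cost per iteration stays linear in the panel size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["QrFit", "check_loss", "fit_qr", "fit_qr_batch", "fit_qr_fe"]


def check_loss(u, tau: float):
    """Check (pinball) loss rho_tau(u) = u * (tau - 1{u <= 0})."""
    if not 0 < tau < 1:
        raise ValueError(f"tau must lie in (0, 1), got {tau}")
    u = np.asarray(u, float)
    out = u * (tau - (u <= 0))
    return out if out.ndim else float(out)


@dataclass
class QrFit:
    """Result of one quantile-regression fit."""

    coefficients: np.ndarray
    residuals: np.ndarray
    tau: float
    objective: float
    converged: bool
    rank_deficient: bool = False


def _steplength(x: np.ndarray, dx: np.ndarray, cap: float) -> np.ndarray:
    """Largest alpha <= cap with x + alpha*dx >= 0, per batch row."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(dx < 0, -x / np.where(dx < 0, dx, -1.0), np.inf)
    return np.minimum(t.min(axis=tuple(range(1, x.ndim))), cap)


def fit_qr_batch(Y: np.ndarray, X: np.ndarray, tau: float, *,
                 max_iter: int = 60, eps: float = 1e-10,
                 step_factor: float = 0.99995):
    """Solve a batch of quantile regressions by Frisch-Newton interior point.

    Parameters
    ----------
    Y : ndarray (B, n)
        Responses, one row per problem.
    X : ndarray (B, n, k)
        Design matrices (shared shape across the batch).
    tau : float
        Quantile level in (0, 1).

    Returns
    -------
    coef : ndarray (B, k)
    converged : ndarray of bool (B,)
        Complementarity gap below tolerance at exit.
    """
    if not 0 < tau < 1:
        raise ValueError(f"tau must lie in (0, 1), got {tau}")
    Y = np.asarray(Y, float)
    X = np.asarray(X, float)
    if Y.ndim != 2 or X.ndim != 3 or X.shape[:2] != Y.shape:
        raise ValueError("Y must be (B, n) and X (B, n, k) with matching (B, n)")
    B, n, k = X.shape
    if n <= k:
        raise ValueError(f"need more observations than regressors (n={n}, k={k})")

    c = Y
    # dual variables a in [0,1]; init strictly interior and exactly feasible
    a = np.full((B, n), 1.0 - tau)
    s = np.full((B, n), tau)
    b_eq = (1.0 - tau) * X.sum(axis=1)

    ridge = 1e-11 * np.eye(k)
    AAt = np.einsum("bnk,bnl->bkl", X, X)
    v = np.linalg.solve(AAt + ridge, np.einsum("bnk,bn->bk", X, c)[..., None])[..., 0]
    r = c - np.einsum("bnk,bk->bn", X, v)
    guard = 1e-4 * np.maximum(np.abs(r).mean(axis=1, keepdims=True), 1e-8)
    w = np.maximum(r, 0.0) + guard
    z = np.maximum(-r, 0.0) + guard
    scale = np.maximum(np.abs(c).mean(axis=1), 1.0)

    # Converged problems are compacted out of the working set so that late
    # stragglers do not pay for the whole batch.
    out_v = np.empty((B, k))
    out_gap = np.empty(B)
    idx = np.arange(B)

    for _ in range(max_iter):
        gap = np.einsum("bn,bn->b", a, z) + np.einsum("bn,bn->b", s, w)
        active = gap > eps * n * scale
        if not active.all():
            done = ~active
            out_v[idx[done]] = v[done]
            out_gap[idx[done]] = gap[done]
            if not active.any():
                idx = idx[active]
                break
            idx = idx[active]
            X = X[active]
            c = c[active]
            b_eq = b_eq[active]
            a, s, z, w, v = a[active], s[active], z[active], w[active], v[active]
            scale = scale[active]
            gap = gap[active]
        B_act = idx.size
        mu = gap / (2 * n)
        with np.errstate(over="ignore"):
            q = 1.0 / np.maximum(z / a + w / s, 1e-300)
        Xv = np.einsum("bnk,bk->bn", X, v)
        r_d = c - Xv - w + z
        r_p = b_eq - np.einsum("bnk,bn->bk", X, a)
        r_u = 1.0 - a - s

        def newton(gamma, cxz, csw):
            h = r_d + w - z - (gamma - csw) / s + (gamma - cxz) / a + (w / s) * r_u
            Xq = X * q[:, :, None]
            M = np.einsum("bnk,bnl->bkl", Xq, X) + ridge
            rhs = np.einsum("bnk,bn->bk", Xq, h) - r_p
            dv = np.linalg.solve(M, rhs[..., None])[..., 0]
            da = q * (h - np.einsum("bnk,bk->bn", X, dv))
            ds = r_u - da
            dz = (gamma - cxz) / a - z - (z / a) * da
            dw = (gamma - csw) / s - w - (w / s) * ds
            return dv, da, ds, dz, dw

        zero = np.zeros((B_act, 1))
        dv, da, ds, dz, dw = newton(zero, 0.0, 0.0)
        cap = 1.0 / step_factor
        ap = np.minimum(_steplength(a, da, cap), _steplength(s, ds, cap)) * step_factor
        ad = np.minimum(_steplength(z, dz, cap), _steplength(w, dw, cap)) * step_factor

        # Mehrotra centering: sigma = (gap_affine / gap)^3
        ga = (np.einsum("bn,bn->b", a + ap[:, None] * da, z + ad[:, None] * dz)
              + np.einsum("bn,bn->b", s + ap[:, None] * ds, w + ad[:, None] * dw))
        sigma = np.clip((ga / np.maximum(gap, 1e-300)) ** 3, 0.0, 1.0)
        gamma = (sigma * mu)[:, None]
        dv, da, ds, dz, dw = newton(gamma, da * dz, ds * dw)
        ap = np.minimum(_steplength(a, da, cap), _steplength(s, ds, cap)) * step_factor
        ad = np.minimum(_steplength(z, dz, cap), _steplength(w, dw, cap)) * step_factor

        a = a + ap[:, None] * da
        s = s + ap[:, None] * ds
        z = z + ad[:, None] * dz
        w = w + ad[:, None] * dw
        v = v + ad[:, None] * dv

    if idx.size:
        out_v[idx] = v
        out_gap[idx] = (np.einsum("bn,bn->b", a, z)
                        + np.einsum("bn,bn->b", s, w))
    scale_full = np.maximum(np.abs(Y).mean(axis=1), 1.0)
    converged = out_gap <= 10.0 * eps * n * scale_full
    return out_v, converged


def fit_qr(y: np.ndarray, X: np.ndarray, tau: float, *,
           max_iter: int = 60, eps: float = 1e-10) -> QrFit:
    """Fit one quantile regression of y on the columns of X.

    Rank-deficient designs are handled by dropping dependent columns
    (pivoted QR factorization); the corresponding coefficients are zero in
    the returned vector and the fit is flagged ``rank_deficient``.
    """
    y = np.asarray(y, float).ravel()
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if y.shape[0] != n:
        raise ValueError("y and X have different numbers of observations")
    if n <= k:
        raise ValueError(f"need n > p (n={n}, p={k})")

    keep = np.arange(k)
    rank_deficient = False
    # detect collinearity via pivoted QR of the design
    _, R, piv = _qr_pivoted(X)
    diag = np.abs(np.diag(R))
    tol = diag.max(initial=0.0) * max(n, k) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < k:
        rank_deficient = True
        keep = np.sort(piv[:rank])
        X_use = X[:, keep]
    else:
        X_use = X

    coef_use, conv = fit_qr_batch(y[None, :], X_use[None, :, :], tau,
                                  max_iter=max_iter, eps=eps)
    coef = np.zeros(k)
    coef[keep] = coef_use[0]
    resid = y - X @ coef
    return QrFit(
        coefficients=coef,
        residuals=resid,
        tau=tau,
        objective=float(np.sum(check_loss(resid, tau))),
        converged=bool(conv[0]),
        rank_deficient=rank_deficient,
    )


def _qr_pivoted(X: np.ndarray):
    from scipy.linalg import qr

    Q, R, piv = qr(X, mode="economic", pivoting=True)
    return Q, R, piv


def fit_qr_fe(Y: np.ndarray, X: np.ndarray, tau: float, *,
              max_iter: int = 60, eps: float = 1e-10,
              step_factor: float = 0.99995):
    """Batched pooled quantile regression with one intercept per unit.

    Parameters
    ----------
    Y : ndarray (B, N, T)
        Responses, stacked unit-major; one (N, T) panel per batch problem.
    X : ndarray (B, N, T, k)
        Slope design (no intercept; the N unit dummies are implicit).

    Returns
    -------
    coef : ndarray (B, k)
        Slope coefficients.
    fe : ndarray (B, N)
        Unit intercepts.
    converged : ndarray of bool (B,)

    The Newton systems of the interior-point iteration are solved by
    eliminating the unit-dummy block: its weighted Gram matrix is diagonal,
    so only a k x k Schur complement is factorized each step.
    """
    if not 0 < tau < 1:
        raise ValueError(f"tau must lie in (0, 1), got {tau}")
    Y = np.asarray(Y, float)
    X = np.asarray(X, float)
    B, N, T, k = X.shape
    if Y.shape != (B, N, T):
        raise ValueError("Y must be (B, N, T) matching X")
    if T <= k + 1:
        raise ValueError(f"need T > k + 1 per unit (T={T}, k={k})")
    n = N * T
    c = Y
    b_s = (1.0 - tau) * X.sum(axis=(1, 2))
    b_z = np.full((B, N), (1.0 - tau) * T)
    a = np.full((B, N, T), 1.0 - tau)
    s = np.full((B, N, T), tau)
    ridge = 1e-11 * np.eye(k)

    def fe_solve(q, h, rp_s, rp_z):
        qh = q * h
        rhs_s = np.einsum("bntk,bnt->bk", X, qh) - rp_s
        rhs_z = qh.sum(axis=2) - rp_z
        D = q.sum(axis=2)
        Bm = np.einsum("bntk,bnt->bnk", X, q)
        S = (np.einsum("bntk,bnt,bntl->bkl", X, q, X)
             - np.einsum("bnk,bn,bnl->bkl", Bm, 1.0 / D, Bm))
        r2 = rhs_s - np.einsum("bnk,bn->bk", Bm, rhs_z / D)
        dv = np.linalg.solve(S + ridge, r2[..., None])[..., 0]
        dfe = (rhs_z - np.einsum("bnk,bk->bn", Bm, dv)) / D
        return dv, dfe

    ones = np.ones((B, N, T))
    v, fe = fe_solve(ones, c, 0.0, 0.0)
    r = c - np.einsum("bntk,bk->bnt", X, v) - fe[:, :, None]
    guard = 1e-4 * np.maximum(np.abs(r).mean(axis=(1, 2), keepdims=True), 1e-8)
    w = np.maximum(r, 0.0) + guard
    z = np.maximum(-r, 0.0) + guard
    scale = np.maximum(np.abs(c).mean(axis=(1, 2)), 1.0)

    for _ in range(max_iter):
        gap = np.einsum("bnt,bnt->b", a, z) + np.einsum("bnt,bnt->b", s, w)
        active = gap > eps * n * scale
        if not active.any():
            break
        mu = gap / (2 * n)
        with np.errstate(over="ignore"):
            q = 1.0 / np.maximum(z / a + w / s, 1e-300)
        Av = np.einsum("bntk,bk->bnt", X, v) + fe[:, :, None]
        r_d = c - Av - w + z
        rp_s = b_s - np.einsum("bntk,bnt->bk", X, a)
        rp_z = b_z - a.sum(axis=2)
        r_u = 1.0 - a - s

        def newton(gamma, cxz, csw):
            h = r_d + w - z - (gamma - csw) / s + (gamma - cxz) / a + (w / s) * r_u
            dv, dfe = fe_solve(q, h, rp_s, rp_z)
            da = q * (h - np.einsum("bntk,bk->bnt", X, dv) - dfe[:, :, None])
            ds = r_u - da
            dz = (gamma - cxz) / a - z - (z / a) * da
            dw = (gamma - csw) / s - w - (w / s) * ds
            return dv, dfe, da, ds, dz, dw

        zero = np.zeros((B, 1, 1))
        dv, dfe, da, ds, dz, dw = newton(zero, 0.0, 0.0)
        cap = 1.0 / step_factor
        ap = np.minimum(_steplength(a, da, cap), _steplength(s, ds, cap)) * step_factor
        ad = np.minimum(_steplength(z, dz, cap), _steplength(w, dw, cap)) * step_factor
        ga = (np.einsum("bnt,bnt->b", a + ap[:, None, None] * da,
                        z + ad[:, None, None] * dz)
              + np.einsum("bnt,bnt->b", s + ap[:, None, None] * ds,
                          w + ad[:, None, None] * dw))
        sigma = np.clip((ga / np.maximum(gap, 1e-300)) ** 3, 0.0, 1.0)
        gamma = (sigma * mu)[:, None, None]
        dv, dfe, da, ds, dz, dw = newton(gamma, da * dz, ds * dw)
        ap = np.minimum(_steplength(a, da, cap), _steplength(s, ds, cap)) * step_factor
        ad = np.minimum(_steplength(z, dz, cap), _steplength(w, dw, cap)) * step_factor
        ap = np.where(active, ap, 0.0)
        ad = np.where(active, ad, 0.0)
        a = a + ap[:, None, None] * da
        s = s + ap[:, None, None] * ds
        z = z + ad[:, None, None] * dz
        w = w + ad[:, None, None] * dw
        v = v + ad[:, None] * dv
        fe = fe + ad[:, None] * dfe

    gap = np.einsum("bnt,bnt->b", a, z) + np.einsum("bnt,bnt->b", s, w)
    converged = gap <= 10.0 * eps * n * scale
    return v, fe, converged
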