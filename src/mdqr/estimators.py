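"""MDQR, IV-MDQR and pooled IV-FEQR estimators for SAR panels.

Model: the tau-th conditional quantile of the response is

    Q_tau(y_it | D_it, X_it, i) = rho(tau) D_it + X_it' beta(tau) + eta_i(tau),

with the spatial lag D_it = sum_j w_ij y_jt endogenous by construction.

Estimators
----------
``fit_mdqr``
    Two-step minimum-distance estimator: a per-unit time-series quantile
    regression of y on [D, X, 1] gives theta_i = (rho_i, beta_i); the
    units are combined by inverse-covariance weighting,
    theta = (sum_i V_i^-1)^-1 sum_i V_i^-1 theta_i.  Because D is
    endogenous the per-unit fits (and hence the combination) are biased;
    this estimator is the uncorrected baseline.
``fit_iv_mdqr``
    Instrumental-variable version.  For each unit and each rho_j on a
    finite grid, regress y - rho_j D on [X, 1, omega]; the instrument
    coefficient gamma_i(rho_j) is driven to zero exactly when rho_j equals
    the true spatial coefficient, so rho_i = argmin_j ||gamma_i(rho_j)||.
    Per-unit sandwich covariances V~_i = J_i^-1 S_i J_i^-T then weight the
    minimum-distance combination.
``fit_iv_feqr``
    Pooled comparison estimator: one fixed-effects quantile regression
    with all unit intercepts estimated jointly, grid-profiled over rho the
    same way.

Covariance estimation uses Powell kernel density estimates of the residual
density at zero with a Hall-Sheather (default) or Bofinger bandwidth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .qr_core import fit_qr, fit_qr_batch, fit_qr_fe
from .simulate import InstrumentSet, PanelData, compute_spatial_lag, make_instruments
from .weights import SpatialWeightMatrix

__all__ = [
    "QuantileModelSpec",
    "IndividualEstimate",
    "CombinedEstimate",
    "UnitQrResult",
    "default_rho_grid",
    "fit_unit_qr",
    "fit_unit_ivqr",
    "estimate_Si",
    "estimate_Ji",
    "estimate_Vi_iv",
    "combine_md",
    "fit_mdqr",
    "fit_iv_mdqr",
    "fit_iv_feqr",
    "confidence_intervals",
    "quantile_process",
]


def default_rho_grid(step: float = 0.05, lo: float = -1.0, hi: float = 1.0) -> np.ndarray:
    """The replication search grid {step*k, lo <= step*k <= hi}."""
    kmax = int(np.floor(hi / step + 1e-9))
    kmin = int(np.ceil(lo / step - 1e-9))
    return step * np.arange(kmin, kmax + 1)


@dataclass(frozen=True)
class QuantileModelSpec:
    """Settings shared by all quantile estimators.

    Parameters
    ----------
    tau : float
        Quantile level in (0, 1).
    rho_grid : ndarray
        Ascending candidate values for the spatial coefficient, within
        [-1, 1].  Default: the 0.05-spaced replication grid over [-1, 1].
    instrument_kind : str
        Which instrument ``make_instruments`` builds when none is supplied.
        Default ``spatial_lag_X`` (w_i'X_t), which is informative about the
        spatial lag within every unit's time series.
    density_bandwidth_rule : str
        Bandwidth rule for the residual density at zero: ``hall_sheather``
        (default), ``bofinger`` or ``fixed``.
    fixed_bandwidth : float
        Residual-scale bandwidth used when the rule is ``fixed``.
    gamma_norm : str
        Distance on the instrument coefficient minimized over the grid:
        ``euclidean`` (default; coincides with |gamma| for one instrument),
        ``abs`` (sum of absolute values) or ``wald`` (gamma' Omega^-1 gamma
        with Omega the estimated covariance of gamma).
    density_mode : str
        ``unit_average`` (default) replaces each unit's per-observation
        kernel density estimates by their within-unit mean, appropriate
        when the error density at zero does not vary with the regressors;
        ``local`` keeps the per-observation Powell estimates.
    sandwich_intercept : bool
        Include the intercept column in the sandwich moment matrices and
        report the (rho, beta) block of the full covariance (default);
        if False, use the bare [omega, X] / [D, X] moments.
    ridge_eps : float
        Eigenvalue floor applied when a covariance estimate is not
        positive definite.
    density_floor : float
        Lower bound on kernel density estimates at zero.
    """

    tau: float = 0.5
    rho_grid: np.ndarray = field(default_factory=default_rho_grid)
    instrument_kind: Literal["lagged_response", "spatial_lag_X"] = "spatial_lag_X"
    density_bandwidth_rule: Literal["hall_sheather", "bofinger", "fixed"] = "hall_sheather"
    fixed_bandwidth: float = 1.0
    gamma_norm: Literal["euclidean", "abs", "wald"] = "euclidean"
    density_mode: Literal["unit_average", "local"] = "unit_average"
    sandwich_intercept: bool = True
    ridge_eps: float = 1e-8
    density_floor: float = 1e-4

    def __post_init__(self) -> None:
        if not 0 < self.tau < 1:
            raise ValueError(f"tau must lie in (0, 1), got {self.tau}")
        grid = np.sort(np.atleast_1d(np.asarray(self.rho_grid, float)))
        if grid.size == 0:
            raise ValueError("rho_grid must be nonempty")
        if grid.min() < -1 or grid.max() > 1:
            raise ValueError("rho_grid must lie within [-1, 1]")
        object.__setattr__(self, "rho_grid", grid)


class UnitQrResult(NamedTuple):
    theta: np.ndarray          # (rho_i, beta_i')
    eta: float
    residuals: np.ndarray
    rank_deficient: bool


@dataclass
class IndividualEstimate:
    """Per-unit IVQR estimate with its sandwich covariance."""

    unit_id: object
    tau: float
    rho_hat: float
    beta_hat: np.ndarray
    eta_hat: float
    gamma_hat: np.ndarray
    gamma_profile: np.ndarray      # (G, q) instrument coefficients along the grid
    rho_grid: np.ndarray
    V_hat: np.ndarray              # (p+1, p+1) covariance of (rho_i, beta_i)
    flagged: bool = False

    @property
    def theta_hat(self) -> np.ndarray:
        return np.concatenate([[self.rho_hat], np.atleast_1d(self.beta_hat)])


@dataclass
class CombinedEstimate:
    """Minimum-distance combination across units."""

    theta_hat: np.ndarray
    V_combined: np.ndarray
    n_units: int
    n_periods: int
    tau: float
    method: Literal["mdqr", "iv_mdqr", "iv_feqr"]
    n_excluded: int = 0
    theta_units: np.ndarray | None = None   # (N, p+1) per-unit estimates
    eta_hat: np.ndarray | None = None

    @property
    def rho_hat(self) -> float:
        return float(self.theta_hat[0])

    @property
    def beta_hat(self) -> np.ndarray:
        return self.theta_hat[1:]

    def to_dict(self) -> dict:
        out = {
            "method": self.method,
            "tau": self.tau,
            "rho_hat": self.rho_hat,
            "beta_hat": self.beta_hat.tolist(),
            "theta_hat": self.theta_hat.tolist(),
            "V_combined": self.V_combined.tolist(),
            "n_units": self.n_units,
            "n_periods": self.n_periods,
            "n_excluded": self.n_excluded,
        }
        ci = confidence_intervals(self, 0.95)
        out["ci95"] = {"lower": ci[:, 0].tolist(), "upper": ci[:, 1].tolist()}
        return out


# ---------------------------------------------------------------------------
# bandwidths and density estimation
# ---------------------------------------------------------------------------

def _tau_bandwidth(tau: float, n: int, rule: str) -> float:
    """Half-width in quantile space (Hall-Sheather or Bofinger rule)."""
    zt = stats.norm.ppf(tau)
    phi = stats.norm.pdf(zt)
    if rule == "hall_sheather":
        za = stats.norm.ppf(1 - 0.05 / 2)
        h = n ** (-1 / 3) * za ** (2 / 3) * (1.5 * phi ** 2 / (2 * zt ** 2 + 1)) ** (1 / 3)
    elif rule == "bofinger":
        h = n ** (-0.2) * (4.5 * phi ** 4 / (2 * zt ** 2 + 1) ** 2) ** 0.2
    else:
        raise ValueError(f"unknown bandwidth rule {rule!r}")
    while tau + h >= 1 or tau - h <= 0:
        h /= 2
    return h


def _powell_bandwidth(resid: np.ndarray, tau: float, rule: str,
                      fixed: float = 1.0) -> np.ndarray:
    """Residual-scale kernel bandwidth per row of ``resid`` (..., T).

    The quantile-space half-width is mapped to the residual scale through
    the normal quantile function and a robust scale estimate
    min(sd, IQR/1.34), the standard kernel-sandwich practice.
    """
    resid = np.asarray(resid, float)
    T = resid.shape[-1]
    if rule == "fixed":
        return np.full(resid.shape[:-1], float(fixed))
    htau = _tau_bandwidth(tau, T, rule)
    sd = resid.std(axis=-1, ddof=1)
    q75, q25 = np.quantile(resid, [0.75, 0.25], axis=-1)
    iqr = (q75 - q25) / 1.34
    robust = np.where(iqr > 0, np.minimum(sd, iqr), sd)
    h = (stats.norm.ppf(tau + htau) - stats.norm.ppf(tau - htau)) * robust
    return np.maximum(h, 1e-12)


def _density_at_zero(resid: np.ndarray, tau: float, rule: str, floor: float,
                     mode: str, fixed: float = 1.0) -> np.ndarray:
    """Gaussian-kernel estimates of the residual density at zero, (..., T)."""
    h = _powell_bandwidth(resid, tau, rule, fixed)[..., None]
    f = stats.norm.pdf(resid / h) / h
    if mode == "unit_average":
        f = np.broadcast_to(f.mean(axis=-1, keepdims=True), f.shape).copy()
    elif mode != "local":
        raise ValueError(f"unknown density mode {mode!r}")
    return np.maximum(f, floor)


# ---------------------------------------------------------------------------
# spec-level moment operations (per unit)
# ---------------------------------------------------------------------------

def estimate_Si(omega_i: np.ndarray, X_i: np.ndarray, tau: float,
                include_intercept: bool = False) -> np.ndarray:
    """Instrument-side moment S_i = tau(1-tau) (1/T) sum_t x*_t x*_t'.

    x*_t = [omega_t', X_t']' (optionally augmented with a constant).
    """
    xs = _stack_star(omega_i, X_i, include_intercept)
    T = xs.shape[0]
    return tau * (1 - tau) * (xs.T @ xs) / T


def estimate_Ji(residuals_i: np.ndarray, omega_i: np.ndarray, D_i: np.ndarray,
                X_i: np.ndarray, tau: float,
                bandwidth_rule: str = "hall_sheather",
                density_floor: float = 1e-4,
                density_mode: str = "local",
                fixed_bandwidth: float = 1.0,
                include_intercept: bool = False):
    """Jacobian moment J_i = (1/T) sum_t f_t x*_t xtilde_t' and diagnostics.

    f_t is a Powell-type Gaussian-kernel estimate of the residual density
    at zero, K(e_t/h)/h, floored at ``density_floor``.  Returns ``(J,
    diagnostics)`` with the bandwidth and mean density in the diagnostics.
    """
    resid = np.asarray(residuals_i, float).ravel()
    if resid.std() == 0:
        raise ValueError("degenerate residuals: all values identical")
    f = _density_at_zero(resid, tau, bandwidth_rule, density_floor,
                         density_mode, fixed_bandwidth)
    xs = _stack_star(omega_i, X_i, include_intercept)
    xt = _stack_tilde(D_i, X_i, include_intercept)
    T = xs.shape[0]
    J = (xs * f[:, None]).T @ xt / T
    diagnostics = {
        "bandwidth": float(_powell_bandwidth(resid, tau, bandwidth_rule,
                                             fixed_bandwidth)),
        "mean_density": float(f.mean()),
    }
    return J, diagnostics


def estimate_Vi_iv(Ji: np.ndarray, Si: np.ndarray,
                   ridge_eps: float = 1e-8) -> np.ndarray:
    """Sandwich V~_i = J_i^-1 S_i [J_i^-1]' (pseudo-inverse if overidentified).

    The result is symmetrized and its eigenvalues floored at ``ridge_eps``.
    Raises ``np.linalg.LinAlgError`` if J_i is numerically rank deficient.
    """
    Ji = np.asarray(Ji, float)
    Si = np.asarray(Si, float)
    if np.linalg.cond(Ji.T @ Ji) > 1e14:
        raise np.linalg.LinAlgError("J_i numerically rank deficient")
    if Ji.shape[0] == Ji.shape[1]:
        Jinv = np.linalg.inv(Ji)
    else:
        # overidentified: least-squares pseudo-inverse, (p+1) x (p+q)
        Jinv = np.linalg.pinv(Ji, rcond=1e-12)
    V = Jinv @ Si @ Jinv.T
    return _make_pd(V, ridge_eps)


def _make_pd(V: np.ndarray, ridge_eps: float) -> np.ndarray:
    V = 0.5 * (V + V.T)
    evals = np.linalg.eigvalsh(V)
    if evals.min() < ridge_eps:
        V = V + (ridge_eps - min(evals.min(), 0.0)) * np.eye(V.shape[0])
    return V


def _stack_star(omega_i, X_i, include_intercept: bool) -> np.ndarray:
    om = np.atleast_2d(np.asarray(omega_i, float))
    if om.shape[0] == 1 and om.shape[1] > 1:
        om = om.T
    X = np.atleast_2d(np.asarray(X_i, float))
    if X.shape[0] == 1 and X.shape[1] > 1:
        X = X.T
    cols = [om, X]
    if include_intercept:
        cols.append(np.ones((X.shape[0], 1)))
    return np.hstack(cols)


def _stack_tilde(D_i, X_i, include_intercept: bool) -> np.ndarray:
    D = np.asarray(D_i, float).reshape(-1, 1)
    X = np.atleast_2d(np.asarray(X_i, float))
    if X.shape[0] == 1 and X.shape[1] > 1:
        X = X.T
    cols = [D, X]
    if include_intercept:
        cols.append(np.ones((X.shape[0], 1)))
    return np.hstack(cols)


# ---------------------------------------------------------------------------
# per-unit estimation
# ---------------------------------------------------------------------------

def fit_unit_qr(y_i: np.ndarray, D_i: np.ndarray, X_i: np.ndarray,
                tau: float) -> UnitQrResult:
    """Per-unit quantile regression of y on [D, X, 1] (endogeneity ignored)."""
    y_i = np.asarray(y_i, float).ravel()
    X = _stack_tilde(D_i, X_i, include_intercept=True)
    T, k = X.shape
    if T <= k + 1:
        raise ValueError(f"unit series too short: T={T} for {k} parameters")
    fit = fit_qr(y_i, X, tau)
    theta = fit.coefficients[:-1]
    eta = float(fit.coefficients[-1])
    return UnitQrResult(theta=theta, eta=eta, residuals=fit.residuals,
                        rank_deficient=fit.rank_deficient)


def _gamma_distance(gamma: np.ndarray, spec: QuantileModelSpec,
                    gamma_cov: np.ndarray | None = None) -> np.ndarray:
    """Distance-to-zero of instrument coefficients, shape (..., q) -> (...)."""
    if spec.gamma_norm == "euclidean":
        return np.sqrt((gamma ** 2).sum(axis=-1))
    if spec.gamma_norm == "abs":
        return np.abs(gamma).sum(axis=-1)
    if spec.gamma_norm == "wald":
        if gamma_cov is None:
            raise ValueError("wald norm requires the gamma covariance")
        sol = np.linalg.solve(gamma_cov, gamma[..., None])[..., 0]
        return (gamma * sol).sum(axis=-1)
    raise ValueError(f"unknown gamma norm {spec.gamma_norm!r}")


def _select_grid_index(dist: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Argmin along the last (grid) axis; ties within 1e-12 resolved by the
    rho closest to zero, then the smaller rho."""
    dmin = dist.min(axis=-1, keepdims=True)
    tied = dist <= dmin + 1e-12
    # rank candidates: (|rho|, rho) lexicographic among tied entries
    key = np.abs(grid) + 1e-9 * grid
    key = np.where(tied, key, np.inf)
    return key.argmin(axis=-1)


def _ivqr_grid_profile(ye, D, Xe, om, spec: QuantileModelSpec):
    """Grid-profiled IVQR for all units at once.

    ye, D: (N, T); Xe: (N, T, p); om: (N, T, q).  Returns a dict of
    per-unit arrays (selected rho, beta, eta, gamma, residuals, profile,
    convergence flags).
    """
    N, T = ye.shape
    p = Xe.shape[2]
    q = om.shape[2]
    grid = spec.rho_grid
    G = grid.size
    k = p + 1 + q
    design = np.empty((N, T, k))
    design[:, :, :p] = Xe
    design[:, :, p] = 1.0
    design[:, :, p + 1:] = om
    design_b = np.repeat(design, G, axis=0)                      # (N*G, T, k)
    resp = (np.repeat(ye, G, axis=0)
            - np.tile(grid, N)[:, None] * np.repeat(D, G, axis=0))
    coef, conv = fit_qr_batch(resp, design_b, spec.tau)
    coef = coef.reshape(N, G, k)
    conv = conv.reshape(N, G)
    gamma = coef[:, :, p + 1:]                                   # (N, G, q)

    if spec.gamma_norm == "wald":
        rr = (resp - np.einsum("btk,bk->bt", design_b, coef.reshape(N * G, k)))
        f = _density_at_zero(rr, spec.tau, spec.density_bandwidth_rule,
                             spec.density_floor, spec.density_mode,
                             spec.fixed_bandwidth)
        Jf = np.einsum("btk,bt,btl->bkl", design_b, f, design_b) / T
        Sf = (spec.tau * (1 - spec.tau)
              * np.einsum("btk,btl->bkl", design_b, design_b) / T)
        Jin = np.linalg.inv(Jf)
        Om = (Jin @ Sf @ np.swapaxes(Jin, 1, 2))[:, p + 1:, p + 1:]
        dist = _gamma_distance(coef.reshape(N * G, k)[:, p + 1:], spec,
                               Om).reshape(N, G)
    else:
        dist = _gamma_distance(gamma, spec)

    jsel = _select_grid_index(dist, grid)
    idx = np.arange(N)
    rho_i = grid[jsel]
    beta_i = coef[idx, jsel, :p]
    eta_i = coef[idx, jsel, p]
    gamma_i = coef[idx, jsel, p + 1:]
    resid = (ye - rho_i[:, None] * D
             - np.einsum("ntp,np->nt", Xe, beta_i)
             - eta_i[:, None]
             - np.einsum("ntq,nq->nt", om, gamma_i))
    return {
        "rho": rho_i, "beta": beta_i, "eta": eta_i, "gamma": gamma_i,
        "residuals": resid, "profile": gamma, "converged": conv[idx, jsel],
        "grid": grid,
    }


def _iv_sandwich_batch(resid, om, D, Xe, spec: QuantileModelSpec):
    """Per-unit V~_i for all units; returns (V (N,p+1,p+1), flags)."""
    N, T = resid.shape
    p = Xe.shape[2]
    f = _density_at_zero(resid, spec.tau, spec.density_bandwidth_rule,
                         spec.density_floor, spec.density_mode,
                         spec.fixed_bandwidth)
    cols_s = [om, Xe]
    cols_t = [D[:, :, None], Xe]
    if spec.sandwich_intercept:
        one = np.ones((N, T, 1))
        cols_s.append(one)
        cols_t.append(one)
    xs = np.concatenate(cols_s, axis=2)
    xt = np.concatenate(cols_t, axis=2)
    J = np.einsum("ntk,nt,ntl->nkl", xs, f, xt) / T
    S = (spec.tau * (1 - spec.tau)) * np.einsum("ntk,ntl->nkl", xs, xs) / T
    flags = np.zeros(N, bool)
    V = np.empty((N, p + 1, p + 1))
    for i in range(N):
        try:
            if J.shape[1] == J.shape[2]:
                Jin = np.linalg.inv(J[i])
            else:
                Jin = np.linalg.pinv(J[i], rcond=1e-12)
            Vi_full = Jin @ S[i] @ Jin.T
            V[i] = _make_pd(Vi_full[:p + 1, :p + 1], spec.ridge_eps)
        except np.linalg.LinAlgError:
            flags[i] = True
            V[i] = np.eye(p + 1)
    return V, flags


def fit_unit_ivqr(y_i, D_i, X_i, omega_i, spec: QuantileModelSpec,
                  unit_id=0) -> IndividualEstimate:
    """Grid-profiled IVQR for a single unit's time series.

    For each rho_j on ``spec.rho_grid`` the quantile regression of
    y - rho_j D on [X, 1, omega] is solved; rho_hat minimizes the
    configured distance of the instrument coefficient to zero.
    """
    y_i = np.asarray(y_i, float).ravel()
    D_i = np.asarray(D_i, float).ravel()
    X_i = np.atleast_2d(np.asarray(X_i, float))
    if X_i.shape[0] != y_i.shape[0]:
        X_i = X_i.T
    om = np.atleast_2d(np.asarray(omega_i, float))
    if om.shape[0] != y_i.shape[0]:
        om = om.T
    T = y_i.shape[0]
    p, q = X_i.shape[1], om.shape[1]
    if T <= p + q + 2:
        raise ValueError(f"unit series too short: T={T} for p={p}, q={q}")
    full = np.hstack([X_i, np.ones((T, 1)), om])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise ValueError("collinear design: instruments or covariates are "
                         "linearly dependent with the regressors")
    res = _ivqr_grid_profile(y_i[None], D_i[None], X_i[None], om[None], spec)
    V, flags = _iv_sandwich_batch(res["residuals"], om[None], D_i[None],
                                  X_i[None], spec)
    return IndividualEstimate(
        unit_id=unit_id, tau=spec.tau,
        rho_hat=float(res["rho"][0]), beta_hat=res["beta"][0],
        eta_hat=float(res["eta"][0]), gamma_hat=res["gamma"][0],
        gamma_profile=res["profile"][0], rho_grid=res["grid"],
        V_hat=V[0], flagged=bool(flags[0] or not res["converged"][0]),
    )


# ---------------------------------------------------------------------------
# combination and full-panel estimators
# ---------------------------------------------------------------------------

def combine_md(estimates: Sequence[IndividualEstimate],
               n_periods: int | None = None) -> CombinedEstimate:
    """Inverse-covariance (minimum-distance) combination of unit estimates.

    theta = (sum_i V_i^-1)^-1 sum_i V_i^-1 theta_i over the non-flagged
    units; V_combined = N_used * (sum_i V_i^-1)^-1.  Aborts if more than
    20% of units are flagged.
    """
    if len(estimates) == 0:
        raise ValueError("no estimates to combine")
    taus = {e.tau for e in estimates}
    if len(taus) != 1:
        raise ValueError("estimates mix different quantile levels")
    dims = {e.theta_hat.shape[0] for e in estimates}
    if len(dims) != 1:
        raise ValueError("estimates have inconsistent dimensions")
    usable = [e for e in estimates if not e.flagged]
    n_excluded = len(estimates) - len(usable)
    if n_excluded > 0.2 * len(estimates) or not usable:
        raise ValueError(
            f"{n_excluded}/{len(estimates)} units flagged; combination aborted")
    theta = np.stack([e.theta_hat for e in usable])
    Vin = np.stack([np.linalg.inv(e.V_hat) for e in usable])
    Vin_sum = Vin.sum(axis=0)
    theta_hat = np.linalg.solve(Vin_sum, np.einsum("nkl,nl->k", Vin, theta))
    V_combined = len(usable) * np.linalg.inv(Vin_sum)
    return CombinedEstimate(
        theta_hat=theta_hat, V_combined=_make_pd(V_combined, 0.0),
        n_units=len(usable), n_periods=n_periods or 0,
        tau=usable[0].tau, method="iv_mdqr", n_excluded=n_excluded,
        theta_units=theta,
    )


def _align(panel: PanelData, w: SpatialWeightMatrix,
           instruments: InstrumentSet | None):
    """Slice panel arrays to the common estimation window of the instruments."""
    D = compute_spatial_lag(panel, w)
    off = instruments.t_offset if instruments is not None else 0
    ye = panel.y[:, off:]
    Xe = panel.X[:, off:, :]
    De = D[:, off:]
    om = instruments.omega if instruments is not None else None
    if om is not None and om.shape[1] != ye.shape[1]:
        raise ValueError(
            f"instruments cover {om.shape[1]} periods but the estimation "
            f"window has {ye.shape[1]}")
    return ye, De, Xe, om


def fit_mdqr(panel: PanelData, w: SpatialWeightMatrix,
             spec: QuantileModelSpec) -> CombinedEstimate:
    """Two-step minimum-distance QR (no instrument; endogeneity uncorrected)."""
    ye, De, Xe, _ = _align(panel, w, None)
    N, T = ye.shape
    p = Xe.shape[2]
    design = np.concatenate([De[:, :, None], Xe, np.ones((N, T, 1))], axis=2)
    coef, conv = fit_qr_batch(ye, design, spec.tau)
    theta_units = coef[:, :p + 1]
    eta_units = coef[:, p + 1]
    resid = ye - np.einsum("ntk,nk->nt", design, coef)
    f = _density_at_zero(resid, spec.tau, spec.density_bandwidth_rule,
                         spec.density_floor, spec.density_mode,
                         spec.fixed_bandwidth)
    cols = [De[:, :, None], Xe]
    if spec.sandwich_intercept:
        cols.append(np.ones((N, T, 1)))
    xt = np.concatenate(cols, axis=2)
    A = np.einsum("ntk,nt,ntl->nkl", xt, f, xt) / T
    S = spec.tau * (1 - spec.tau) * np.einsum("ntk,ntl->nkl", xt, xt) / T
    Vin_sum = np.zeros((p + 1, p + 1))
    acc = np.zeros(p + 1)
    used = 0
    for i in range(N):
        try:
            Ain = np.linalg.inv(A[i])
            Vi = _make_pd((Ain @ S[i] @ Ain.T)[:p + 1, :p + 1], spec.ridge_eps)
            Vin = np.linalg.inv(Vi)
        except np.linalg.LinAlgError:
            continue
        Vin_sum += Vin
        acc += Vin @ theta_units[i]
        used += 1
    if used < 0.8 * N:
        raise ValueError(f"only {used}/{N} units usable; aborting combination")
    theta_hat = np.linalg.solve(Vin_sum, acc)
    return CombinedEstimate(
        theta_hat=theta_hat,
        V_combined=_make_pd(used * np.linalg.inv(Vin_sum), 0.0),
        n_units=used, n_periods=T, tau=spec.tau, method="mdqr",
        n_excluded=N - used, theta_units=theta_units, eta_hat=eta_units,
    )


def fit_iv_mdqr(panel: PanelData, w: SpatialWeightMatrix,
                instruments: InstrumentSet | None,
                spec: QuantileModelSpec) -> CombinedEstimate:
    """IV-MDQR: per-unit grid-profiled IVQR + minimum-distance combination."""
    if instruments is None:
        instruments = make_instruments(panel, w, spec.instrument_kind)
    ye, De, Xe, om = _align(panel, w, instruments)
    N, T = ye.shape
    p = Xe.shape[2]
    res = _ivqr_grid_profile(ye, De, Xe, om, spec)
    V, flags = _iv_sandwich_batch(res["residuals"], om, De, Xe, spec)
    flags = flags | ~res["converged"]
    theta_units = np.concatenate([res["rho"][:, None], res["beta"]], axis=1)
    usable = ~flags
    n_excluded = int(flags.sum())
    if n_excluded > 0.2 * N:
        raise ValueError(f"{n_excluded}/{N} units flagged; combination aborted")
    Vin = np.linalg.inv(V[usable])
    Vin_sum = Vin.sum(axis=0)
    theta_hat = np.linalg.solve(
        Vin_sum, np.einsum("nkl,nl->k", Vin, theta_units[usable]))
    return CombinedEstimate(
        theta_hat=theta_hat,
        V_combined=_make_pd(int(usable.sum()) * np.linalg.inv(Vin_sum), 0.0),
        n_units=int(usable.sum()), n_periods=T, tau=spec.tau,
        method="iv_mdqr", n_excluded=n_excluded,
        theta_units=theta_units, eta_hat=res["eta"],
    )


def fit_iv_feqr(panel: PanelData, w: SpatialWeightMatrix,
                instruments: InstrumentSet | None,
                spec: QuantileModelSpec) -> CombinedEstimate:
    """Pooled fixed-effects IVQR baseline, grid-profiled over rho.

    For each grid rho_j one pooled quantile regression of y - rho_j D on
    [X, unit dummies, omega] is solved (dummies concentrated out);
    rho_hat minimizes the configured gamma-distance of the pooled
    instrument coefficient.
    """
    if instruments is None:
        instruments = make_instruments(panel, w, spec.instrument_kind)
    ye, De, Xe, om = _align(panel, w, instruments)
    N, T = ye.shape
    p = Xe.shape[2]
    q = om.shape[2]
    grid = spec.rho_grid
    G = grid.size
    small = np.concatenate([Xe, om], axis=2)                  # (N, T, p+q)
    Sm = np.broadcast_to(small, (G, N, T, p + q)).copy()
    Ym = ye[None] - grid[:, None, None] * De[None]
    coef, fe, conv = fit_qr_fe(Ym, Sm, spec.tau)
    gamma = coef[:, p:]
    dist = _gamma_distance(gamma, spec) if spec.gamma_norm != "wald" \
        else _gamma_distance(gamma, replace(spec, gamma_norm="euclidean"))
    j = int(_select_grid_index(dist[None, :], grid)[0])
    theta_hat = np.concatenate([[grid[j]], coef[j, :p]])
    # pooled sandwich on within-demeaned moments (unit dummies partialled out)
    resid = (Ym[j] - np.einsum("ntk,k->nt", small, coef[j])
             - fe[j][:, None])
    f = _density_at_zero(resid.reshape(1, -1), spec.tau,
                         spec.density_bandwidth_rule, spec.density_floor,
                         spec.density_mode, spec.fixed_bandwidth).reshape(N, T)
    xs = np.concatenate([om, Xe], axis=2)
    xt = np.concatenate([De[:, :, None], Xe], axis=2)
    xs = xs - xs.mean(axis=1, keepdims=True)
    xt = xt - xt.mean(axis=1, keepdims=True)
    xsf = xs.reshape(-1, p + q)
    xtf = xt.reshape(-1, p + 1)
    ff = f.reshape(-1)
    J = (xsf * ff[:, None]).T @ xtf / (N * T)
    S = spec.tau * (1 - spec.tau) * xsf.T @ xsf / (N * T)
    Jin = np.linalg.inv(J) if J.shape[0] == J.shape[1] else np.linalg.pinv(J)
    V = _make_pd((Jin @ S @ Jin.T) * N, spec.ridge_eps)
    return CombinedEstimate(
        theta_hat=theta_hat, V_combined=V, n_units=N, n_periods=T,
        tau=spec.tau, method="iv_feqr", eta_hat=fe[j],
    )


def confidence_intervals(est: CombinedEstimate, level: float = 0.95) -> np.ndarray:
    """Pointwise normal-theory intervals theta_k +/- z sqrt(V_kk / (N T)).

    Returns an array of shape (p+1, 2) with lower/upper bounds.
    """
    if not 0 < level < 1:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    z = stats.norm.ppf(0.5 + level / 2)
    nt = max(est.n_units * est.n_periods, 1)
    half = z * np.sqrt(np.diag(est.V_combined) / nt)
    return np.column_stack([est.theta_hat - half, est.theta_hat + half])


def quantile_process(panel: PanelData, w: SpatialWeightMatrix,
                     instruments: InstrumentSet | None,
                     spec_base: QuantileModelSpec,
                     tau_grid: Sequence[float], level: float = 0.95):
    """IV-MDQR along a grid of quantile levels with pointwise intervals.

    Returns a pandas DataFrame sorted by tau with one row per (tau,
    parameter); taus whose fit fails are reported with NaN values.
    """
    import pandas as pd

    rows = []
    for tau in sorted(tau_grid):
        try:
            est = fit_iv_mdqr(panel, w, instruments,
                              replace(spec_base, tau=float(tau)))
            ci = confidence_intervals(est, level)
            for k, name in enumerate(_param_names(est.theta_hat.size)):
                rows.append({"tau": float(tau), "param": name,
                             "estimate": float(est.theta_hat[k]),
                             "lower": float(ci[k, 0]),
                             "upper": float(ci[k, 1]),
                             "error": ""})
        except (ValueError, np.linalg.LinAlgError) as exc:
            for name in _param_names(panel.n_covariates + 1):
                rows.append({"tau": float(tau), "param": name,
                             "estimate": np.nan, "lower": np.nan,
                             "upper": np.nan, "error": str(exc)})
    return pd.DataFrame(rows)


def _param_names(dim: int) -> list[str]:
    return ["rho"] + [f"beta{j}" for j in range(1, dim)]
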