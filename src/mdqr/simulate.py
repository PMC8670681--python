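"""Synthetic SAR panel data and instrument construction.

The data-generating process is the spatial autoregressive panel model with
individual fixed effects,

    y_t = (I - rho * W)^(-1) (X_t beta + eta + u_t),      t = 1, ..., T,

with scalar spatial coefficient |rho| < 1, covariates X_it ~ U(-2, 2)
drawn i.i.d. across units and periods, fixed effects eta_i ~ N(0, 1) drawn
once per panel, and disturbances

    u_it = eps_it                      (homoscedastic design)
    u_it = (1 + 0.1 * X_it) * eps_it   (heteroscedastic design)

where eps_it = e_it - F^{-1}(tau) is the raw error recentered so that its
tau-quantile is exactly zero; by construction the conditional tau-quantile
of y_it given (D_it, X_it, unit) is then rho*D_it + X_it'beta + eta_i,
D_it = sum_j w_ij y_jt being the spatial lag.  The default error law is
standard normal; any distribution exposing a sampler and an inverse CDF
can be plugged in.

Defaults (rho = 0.5, beta = 1, U(-2,2) covariates, N(0,1) effects and
errors, the block weight matrix) are the replication study conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Protocol

import numpy as np
from scipy import stats

from .weights import SpatialWeightMatrix

__all__ = [
    "ModelParams",
    "PanelData",
    "InstrumentSet",
    "NormalErrors",
    "center_errors",
    "generate_panel",
    "make_instruments",
    "compute_spatial_lag",
]


class ErrorDistribution(Protocol):
    """Error law: must expose ``rvs(size, rng)`` and ``ppf(q)``."""

    def rvs(self, size, rng: np.random.Generator) -> np.ndarray: ...

    def ppf(self, q: float) -> float: ...


class NormalErrors:
    """Standard normal error law (the replication default)."""

    def rvs(self, size, rng: np.random.Generator) -> np.ndarray:
        return rng.standard_normal(size)

    def ppf(self, q: float) -> float:
        return float(stats.norm.ppf(q))


@dataclass(frozen=True)
class ModelParams:
    """Structural parameters of the SAR panel model."""

    rho: float
    beta: np.ndarray
    eta: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta", np.atleast_1d(np.asarray(self.beta, float)))
        object.__setattr__(self, "eta", np.asarray(self.eta, float))
        if not abs(self.rho) < 1:
            raise ValueError(f"|rho| must be < 1, got {self.rho}")


@dataclass
class PanelData:
    """Balanced panel: y (N, T), X (N, T, p).

    ``y_burn`` optionally holds extra leading response periods generated
    before t=1 (burn-in); they are used only to construct lagged-response
    instruments so that no estimation period is lost.
    """

    y: np.ndarray
    X: np.ndarray
    unit_ids: np.ndarray | None = None
    time_ids: np.ndarray | None = None
    y_burn: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, float)
        self.X = np.asarray(self.X, float)
        if self.X.ndim == 2:
            self.X = self.X[:, :, None]
        if self.y.shape != self.X.shape[:2]:
            raise ValueError(f"y shape {self.y.shape} and X shape {self.X.shape} disagree")
        if self.unit_ids is None:
            self.unit_ids = np.arange(self.n_units)
        if self.time_ids is None:
            self.time_ids = np.arange(1, self.n_periods + 1)
        self.unit_ids = np.asarray(self.unit_ids)
        self.time_ids = np.asarray(self.time_ids)

    @property
    def n_units(self) -> int:
        return self.y.shape[0]

    @property
    def n_periods(self) -> int:
        return self.y.shape[1]

    @property
    def n_covariates(self) -> int:
        return self.X.shape[2]


@dataclass(frozen=True)
class InstrumentSet:
    """Instruments omega (N, T_eff, q) aligned with periods t_offset..T-1."""

    omega: np.ndarray
    kind: Literal["lagged_response", "spatial_lag_X", "user_supplied"]
    t_offset: int = 0

    def __post_init__(self) -> None:
        om = np.asarray(self.omega, float)
        if om.ndim == 2:
            om = om[:, :, None]
        object.__setattr__(self, "omega", om)
        if om.shape[2] < 1:
            raise ValueError("at least one instrument column required")
        if self.t_offset not in (0, 1):
            raise ValueError("t_offset must be 0 or 1")

    @property
    def n_instruments(self) -> int:
        return self.omega.shape[2]


def center_errors(raw_draws: np.ndarray, tau: float,
                  dist: ErrorDistribution | None = None) -> np.ndarray:
    """Shift raw error draws so their population tau-quantile is zero.

    Returns ``raw_draws - F^{-1}(tau)`` where F is the error CDF.
    """
    if not 0 < tau < 1:
        raise ValueError(f"tau must lie in (0, 1), got {tau}")
    dist = dist or NormalErrors()
    return np.asarray(raw_draws, float) - dist.ppf(tau)


def generate_panel(params: ModelParams, w: SpatialWeightMatrix, n_periods: int,
                   tau: float, design: Literal["homoscedastic", "heteroscedastic"],
                   seed: int | np.random.Generator,
                   burn_in_periods: int = 1,
                   dist: ErrorDistribution | None = None,
                   x_low: float = -2.0, x_high: float = 2.0) -> PanelData:
    """Simulate a balanced SAR panel under one of the two study designs.

    Each period solves the N x N linear system y_t = (I-rho W)^{-1}
    (X_t beta + eta + u_t).  ``burn_in_periods`` extra leading periods are
    generated and stored separately on the returned panel (``y_burn``); the
    default of 1 supplies y_{i,0} so a lagged-response instrument covers
    all T estimation periods.  Identical seeds give identical panels.
    """
    if design not in ("homoscedastic", "heteroscedastic"):
        raise ValueError(f"unknown design {design!r}")
    if not 0 < tau < 1:
        raise ValueError(f"tau must lie in (0, 1), got {tau}")
    if burn_in_periods < 0:
        raise ValueError("burn_in_periods must be nonnegative")
    dist = dist or NormalErrors()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    N = w.n_units
    if params.eta.shape[0] != N:
        raise ValueError(f"eta has length {params.eta.shape[0]}, weights have {N} units")
    p = params.beta.shape[0]
    T_tot = n_periods + burn_in_periods

    X = rng.uniform(x_low, x_high, size=(N, T_tot, p))
    raw = dist.rvs((N, T_tot), rng)
    eps = center_errors(raw, tau, dist)
    if design == "homoscedastic":
        u = eps
    else:
        scale = 1.0 + 0.1 * X[:, :, 0]
        if np.any(scale <= 0):
            raise ValueError("heteroscedastic scale 1 + 0.1*X must stay positive")
        u = scale * eps

    rhs = np.einsum("ntp,p->nt", X, params.beta) + params.eta[:, None] + u
    A = np.eye(N) - params.rho * w.values
    try:
        y = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - |rho|<1 and valid W
        raise ValueError("I - rho*W is singular") from exc

    b = burn_in_periods
    return PanelData(
        y=y[:, b:],
        X=X[:, b:, :],
        y_burn=y[:, :b] if b else None,
    )


def compute_spatial_lag(panel: PanelData, w: SpatialWeightMatrix) -> np.ndarray:
    """Spatial lag D_it = sum_j w_ij y_jt, shape (N, T)."""
    if w.n_units != panel.n_units:
        raise ValueError(
            f"weight matrix has {w.n_units} units, panel has {panel.n_units}")
    return w.values @ panel.y


def make_instruments(panel: PanelData, w: SpatialWeightMatrix,
                     kind: Literal["lagged_response", "spatial_lag_X"]) -> InstrumentSet:
    """Build instruments for the endogenous spatial lag.

    ``lagged_response``
        omega_it = y_{i,t-1}.  If the panel carries a burn-in period the
        instrument covers all T periods (t_offset=0); otherwise the first
        period is dropped (t_offset=1).
    ``spatial_lag_X``
        omega_it = w_i' X_t, the spatial lag of each covariate (t_offset=0).
        This is the default instrument throughout the package: it is
        correlated with D_it through the reduced form in every period while
        remaining independent of the disturbances.
    """
    if kind == "lagged_response":
        if panel.y_burn is not None and panel.y_burn.shape[1] >= 1:
            omega = np.concatenate(
                [panel.y_burn[:, -1:], panel.y[:, :-1]], axis=1)
            return InstrumentSet(omega=omega, kind=kind, t_offset=0)
        if panel.n_periods < 2:
            raise ValueError("lagged_response requires T >= 2 or a burn-in period")
        return InstrumentSet(omega=panel.y[:, :-1], kind=kind, t_offset=1)
    if kind == "spatial_lag_X":
        if w.n_units != panel.n_units:
            raise ValueError("weight matrix and panel dimensions disagree")
        omega = np.einsum("ij,jtp->itp", w.values, panel.X)
        return InstrumentSet(omega=omega, kind=kind, t_offset=0)
    raise ValueError(f"unknown instrument kind {kind!r}")
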