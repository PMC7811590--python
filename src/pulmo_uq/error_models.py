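"""Error models: iid Gaussian noise and Gaussian-process model mismatch.

Two observation models for a pressure time series y(t) against a model
prediction m(theta, t):

* iid errors:  y = m + u,  u ~ N(0, sigma^2 I)
* GP mismatch: y = m + Gamma,  Gamma(t) = f(t) + u(t) with
  f ~ GP(0, K(w, b)) under a non-stationary neural-network (arcsine)
  covariance and u ~ N(0, sigma_n^2 I), so C = K + sigma_n^2 I.

The mismatch function Gamma absorbs both model discrepancy and noise-model
error; the two contributions are not separately identifiable and are
represented by the single GP.  Kernel inputs are times in seconds,
unscaled; pressures are in mmHg.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .exceptions import ContractError, DomainError, NumericalError

__all__ = [
    "TimeSeriesData",
    "IidErrorModel",
    "GPMismatchModel",
    "nn_kernel",
    "build_covariance",
    "loglik_iid",
    "loglik_correlated",
    "loglik_correlated_pointwise",
    "mismatch_predict",
]

logger = logging.getLogger(__name__)

_MAX_JITTER = 1e-10


@dataclass
class TimeSeriesData:
    """An observed pressure series in one vessel.

    ``t`` strictly increasing times (s), ``y`` pressures (mmHg).
    """

    t: np.ndarray
    y: np.ndarray
    vessel_id: int = 1

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.ndim != 1 or self.y.shape != self.t.shape:
            raise ContractError("t and y must be 1-D arrays of equal length")
        if self.t.size < 2:
            raise ContractError("a time series needs at least 2 points")
        if np.any(np.diff(self.t) <= 0):
            raise ContractError("times must be strictly increasing")

    @property
    def n(self) -> int:
        return self.t.size


@dataclass
class IidErrorModel:
    """iid Gaussian noise with variance ``sigma2`` and its IG(a, b) prior."""

    sigma2: float = 1.0
    prior_shape: float = 0.001
    prior_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise DomainError("sigma2 must be positive")


@dataclass
class GPMismatchModel:
    """Neural-network-kernel GP mismatch model.

    ``w`` (weight variance) and ``b`` (bias variance) are the kernel
    hyperparameters; ``sigma_n2`` is the residual noise variance (mmHg^2).
    ``amplitude2`` optionally scales the whole mismatch covariance
    (K + sigma_n2 I); the default of 1 matches the two-hyperparameter
    formulation, while the synthetic-data generator records the amplitude
    it used so the generating covariance is fully specified.
    """

    w: float = 5.0e4
    b: float = 140.0
    sigma_n2: float = 0.05
    amplitude2: float = 1.0
    w_range: tuple[float, float] = (1.0e4, 9.0e4)
    b_range: tuple[float, float] = (1.0, 500.0)

    def __post_init__(self) -> None:
        if self.w <= 0 or self.b <= 0:
            raise DomainError("kernel hyperparameters w, b must be positive")
        if self.sigma_n2 <= 0:
            raise DomainError("sigma_n2 must be positive")
        if self.amplitude2 <= 0:
            raise DomainError("amplitude2 must be positive")


def nn_kernel(t, tp, w: float, b: float):
    """Neural-network (arcsine) covariance between times ``t`` and ``tp``.

        k(t, t') = (2/pi) asin( 2 (b + w t t')
                   / sqrt((1 + 2(b + w t^2)) (1 + 2(b + w t'^2))) )

    The kernel is non-stationary, symmetric and bounded by |k| <= 1.
    Broadcasts over array inputs.
    """
    if w <= 0 or b <= 0:
        raise DomainError("w and b must be positive")
    t = np.asarray(t, dtype=float)
    tp = np.asarray(tp, dtype=float)
    num = 2.0 * (b + w * t * tp)
    den = np.sqrt((1.0 + 2.0 * (b + w * t * t)) * (1.0 + 2.0 * (b + w * tp * tp)))
    arg = np.clip(num / den, -1.0, 1.0)
    out = (2.0 / math.pi) * np.arcsin(arg)
    return float(out) if out.ndim == 0 else out


def build_covariance(t: np.ndarray, gp: GPMismatchModel) -> np.ndarray:
    """Covariance C = amplitude2 * (K(t, t) + sigma_n2 I) on the grid ``t``.

    Raises :class:`NumericalError` if C cannot be Cholesky-factorized even
    after a logged jitter of at most 1e-10 on the diagonal.
    """
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise ContractError("t must be a 1-D array with n >= 1")
    K = nn_kernel(t[:, None], t[None, :], gp.w, gp.b)
    C = gp.amplitude2 * (K + gp.sigma_n2 * np.eye(t.size))
    _chol(C)  # validate factorizability (with jitter) up front
    return C


def _chol(C: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor, adding a logged jitter of at most 1e-10."""
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        jitter = _MAX_JITTER * max(1.0, float(np.max(np.diag(C))))
        logger.warning("covariance not PD; retrying with jitter %.3g", jitter)
        try:
            return np.linalg.cholesky(C + jitter * np.eye(C.shape[0]))
        except np.linalg.LinAlgError as exc:
            raise NumericalError(
                "covariance Cholesky factorization failed after jitter"
            ) from exc


def loglik_iid(data: TimeSeriesData, m: np.ndarray, sigma2: float) -> float:
    """Gaussian iid log-likelihood -(n/2) log(2 pi sigma2) - SSR/(2 sigma2)."""
    m = np.asarray(m, dtype=float)
    if m.shape != data.y.shape:
        raise ContractError("model prediction length must match the data")
    if sigma2 <= 0:
        raise DomainError("sigma2 must be positive")
    r = data.y - m
    n = data.n
    return float(-0.5 * n * math.log(2.0 * math.pi * sigma2)
                 - 0.5 * np.dot(r, r) / sigma2)


def loglik_correlated(
    data: TimeSeriesData | list[TimeSeriesData],
    m: np.ndarray | list[np.ndarray],
    C: np.ndarray | list[np.ndarray],
) -> float:
    """Correlated Gaussian log-likelihood via Cholesky factorization.

        -1/2 log det(2 pi C) - 1/2 (y - m)^T C^{-1} (y - m)

    Multi-vessel data are passed as lists and treated as a block-diagonal
    covariance (independent blocks with shared error parameters); the result
    is then the sum of per-vessel log-likelihoods.
    """
    if isinstance(data, list):
        if not (isinstance(m, list) and isinstance(C, list)
                and len(data) == len(m) == len(C)):
            raise ContractError("multi-vessel inputs must be equal-length lists")
        return float(sum(loglik_correlated(d, mi, Ci)
                         for d, mi, Ci in zip(data, m, C)))
    return float(np.sum(loglik_correlated_pointwise(data, m, C)))


def loglik_correlated_pointwise(
    data: TimeSeriesData, m: np.ndarray, C: np.ndarray
) -> np.ndarray:
    """Per-observation conditional log densities summing to the joint.

    Decomposes the joint MVN log density through its Cholesky factor into n
    univariate conditionals  log p(y_i | y_1..y_{i-1}); their sum equals the
    correlated log-likelihood exactly, which gives WAIC an additive
    pointwise structure under a correlated likelihood.
    """
    m = np.asarray(m, dtype=float)
    if m.shape != data.y.shape:
        raise ContractError("model prediction length must match the data")
    if C.shape != (data.n, data.n):
        raise ContractError("covariance must be n x n")
    L = _chol(C)
    z = solve_triangular(L, data.y - m, lower=True)
    d = np.diag(L)
    return -0.5 * np.log(2.0 * math.pi * d ** 2) - 0.5 * z ** 2


def mismatch_predict(
    data: TimeSeriesData,
    m: np.ndarray,
    gp: GPMismatchModel,
    t_star: np.ndarray,
    include_noise: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """GP posterior of the mismatch Gamma(t*) given residuals y - m.

    Returns (mean, covariance) of the latent mismatch at ``t_star``:
    mean = K*^T C^{-1} (y - m), cov = K** - K*^T C^{-1} K*; with
    ``include_noise`` the residual noise variance is added to the diagonal,
    giving the predictive law of new observations' mismatch.
    """
    m = np.asarray(m, dtype=float)
    t_star = np.asarray(t_star, dtype=float)
    if m.shape != data.y.shape:
        raise ContractError("model prediction length must match the data")
    C = build_covariance(data.t, gp)
    a2 = gp.amplitude2
    Ks = a2 * nn_kernel(data.t[:, None], t_star[None, :], gp.w, gp.b)
    Kss = a2 * nn_kernel(t_star[:, None], t_star[None, :], gp.w, gp.b)
    cf = cho_factor(C, lower=True)
    alpha = cho_solve(cf, data.y - m)
    mean = Ks.T @ alpha
    V = cho_solve(cf, Ks)
    cov = Kss - Ks.T @ V
    if include_noise:
        cov = cov + a2 * gp.sigma_n2 * np.eye(t_star.size)
    return mean, cov
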