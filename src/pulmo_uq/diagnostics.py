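"""Model selection and MCMC diagnostics.

WAIC (Watanabe-Akaike information criterion) from the stored per-time-point
log predictive density matrix; relative sum of squared errors against known
truth parameters; Geweke mean-stationarity Z test with spectral standard
errors; Brooks-Gelman multivariate potential scale reduction factor; kernel
density estimates (univariate normal-optimal and multivariate diagonal
Silverman bandwidths); and 95% credible / prediction bands in output space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import welch
from scipy.special import logsumexp
from scipy.stats import norm

from .error_models import GPMismatchModel, TimeSeriesData, mismatch_predict
from .exceptions import ContractError, DiagnosticError, DomainError
from .inference import Chain

__all__ = [
    "WAICResult",
    "IntervalBand",
    "waic",
    "relative_sse",
    "geweke",
    "mpsrf",
    "kde_density",
    "interval_bands",
]


# ---------------------------------------------------------------------------
# WAIC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WAICResult:
    """WAIC decomposition; lower ``waic`` indicates better support."""

    lppd: float
    p_waic: float
    waic: float

    def __post_init__(self) -> None:
        if self.p_waic < 0:
            raise ContractError("p_waic must be nonnegative")


def waic(pointwise_loglik: np.ndarray) -> WAICResult:
    """WAIC from an (S draws x n points) log predictive density matrix.

    lppd = sum_i log mean_s exp(ll[s, i]) (log-sum-exp stabilized),
    p_waic = sum_i var_s ll[s, i] (sample variance, denominator S - 1),
    waic = -2 (lppd - p_waic).
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2 or ll.shape[1] < 1:
        raise ContractError("need an S x n matrix with S >= 2, n >= 1")
    if not np.all(np.isfinite(ll)):
        raise ContractError("pointwise log-likelihood contains non-finite values")
    S = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - math.log(S)))
    p_waic = float(np.sum(np.var(ll, axis=0, ddof=1)))
    return WAICResult(lppd=lppd, p_waic=p_waic, waic=-2.0 * (lppd - p_waic))


def relative_sse(theta_hat: np.ndarray, theta_true: np.ndarray) -> float:
    """Relative sum of squared errors sum_i ((theta_i - hat_i)/theta_i)^2."""
    theta_hat = np.asarray(theta_hat, dtype=float)
    theta_true = np.asarray(theta_true, dtype=float)
    if theta_hat.shape != theta_true.shape:
        raise ContractError("estimate and truth must have equal length")
    if np.any(theta_true == 0):
        raise DomainError("true parameter coordinates must be nonzero")
    return float(np.sum(((theta_true - theta_hat) / theta_true) ** 2))


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------

def _spectral_density_zero(v: np.ndarray) -> float:
    """Spectral density of ``v`` at frequency zero (Welch, 8 segments)."""
    n = v.size
    nperseg = max(n // 8, 8)
    freqs, psd = welch(v, nperseg=nperseg, detrend="constant",
                       scaling="density", fs=1.0)
    # psd[0] is suppressed by per-segment mean removal; use the lowest
    # resolved nonzero frequencies as the f -> 0 limit
    lo = psd[1:4]
    if lo.size == 0:
        return float(np.var(v))
    return float(np.mean(lo))


def geweke(
    chain_values: np.ndarray,
    first_frac: float = 0.1,
    last_frac: float = 0.5,
) -> tuple[float, float]:
    """Geweke mean-stationarity test on a single chain.

    Compares the means of the first ``first_frac`` and last ``last_frac``
    segments with spectral-density standard errors; returns (Z, p) with p
    from the two-sided standard normal test.
    """
    v = np.asarray(chain_values, dtype=float)
    if v.ndim != 1 or v.size < 100:
        raise ContractError("need a 1-D chain with at least 100 draws")
    if not (0 < first_frac < 1 and 0 < last_frac < 1
            and first_frac + last_frac <= 1):
        raise ContractError("segment fractions must partition the chain")
    a = v[: int(first_frac * v.size)]
    b = v[-int(last_frac * v.size):]
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return 0.0, 1.0
        raise DiagnosticError("degenerate (constant) chain segments")
    se2_a = _spectral_density_zero(a) / a.size
    se2_b = _spectral_density_zero(b) / b.size
    denom = math.sqrt(se2_a + se2_b)
    if denom == 0:
        raise DiagnosticError("zero spectral variance in both segments")
    z = float((a.mean() - b.mean()) / denom)
    p = float(2.0 * norm.sf(abs(z)))
    return z, p


def mpsrf(chains: np.ndarray) -> float:
    """Brooks-Gelman multivariate potential scale reduction factor.

    ``chains`` has shape (m chains, n draws, d parameters); convergence is
    commonly declared at MPSRF <= 1.1.
    """
    c = np.asarray(chains, dtype=float)
    if c.ndim == 2:
        c = c[:, :, None]
    if c.ndim != 3 or c.shape[0] < 2 or c.shape[1] < 2:
        raise ContractError("need (m >= 2, n >= 2, d) chain array")
    m, n, d = c.shape
    means = c.mean(axis=1)                        # (m, d)
    W = np.zeros((d, d))
    for j in range(m):
        dev = c[j] - means[j]
        W += dev.T @ dev / (n - 1)
    W /= m
    gdev = means - means.mean(axis=0)
    B_over_n = gdev.T @ gdev / (m - 1)            # = B/n
    try:
        lam = np.linalg.eigvals(np.linalg.solve(W, B_over_n))
    except np.linalg.LinAlgError as exc:
        raise DiagnosticError("singular within-chain covariance") from exc
    lam_max = float(np.max(lam.real))
    return (n - 1.0) / n + ((m + 1.0) / m) * lam_max


# ---------------------------------------------------------------------------
# Kernel density estimation
# ---------------------------------------------------------------------------

def kde_density(
    samples: np.ndarray,
    eval_points: np.ndarray,
    mode: str = "univariate",
) -> np.ndarray:
    """Gaussian-kernel density estimate.

    Univariate: normal-optimal bandwidth 1.06 sigma S^(-1/5).  Multivariate:
    product Gaussian kernel with per-coordinate Silverman bandwidths
    sigma_j (4 / ((d + 2) S))^(1/(d + 4)); samples should be pre-scaled to a
    common order of magnitude.
    """
    x = np.asarray(samples, dtype=float)
    pts = np.asarray(eval_points, dtype=float)
    if mode == "univariate":
        if x.ndim != 1 or x.size < 2:
            raise ContractError("univariate mode needs >= 2 scalar samples")
        sd = x.std(ddof=1)
        if sd == 0:
            raise DomainError("zero sample variance")
        h = 1.06 * sd * x.size ** (-0.2)
        z = (pts[..., None] - x[None, :]) / h
        return np.exp(-0.5 * z ** 2).sum(axis=-1) / (x.size * h * math.sqrt(2 * math.pi))
    if mode != "multivariate":
        raise ContractError(f"unknown mode {mode!r}")
    if x.ndim != 2 or x.shape[0] < 2:
        raise ContractError("multivariate mode needs an (S, d) sample array")
    S, d = x.shape
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise DomainError("zero sample variance in a coordinate")
    h = sd * (4.0 / ((d + 2.0) * S)) ** (1.0 / (d + 4.0))
    pts = np.atleast_2d(pts)
    z = (pts[:, None, :] - x[None, :, :]) / h[None, None, :]
    log_kern = -0.5 * np.sum(z ** 2, axis=-1) \
        - d / 2.0 * math.log(2 * math.pi) - np.sum(np.log(h))
    dens = np.exp(logsumexp(log_kern, axis=1) - math.log(S))
    return dens


# ---------------------------------------------------------------------------
# Output-space uncertainty bands
# ---------------------------------------------------------------------------

@dataclass
class IntervalBand:
    """Pointwise 95% credible and prediction bands for a pressure series."""

    t: np.ndarray
    median: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    pi_lo: np.ndarray
    pi_hi: np.ndarray
    n_failed: int = 0

    def __post_init__(self) -> None:
        if not (np.all(self.ci_lo <= self.median + 1e-12)
                and np.all(self.median <= self.ci_hi + 1e-12)):
            raise ContractError("band quantiles must be ordered")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t, "median": self.median,
            "ci_lo": self.ci_lo, "ci_hi": self.ci_hi,
            "pi_lo": self.pi_lo, "pi_hi": self.pi_hi,
        })

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def interval_bands(
    chain: Chain,
    simulator,
    t_star: np.ndarray,
    error_model: str = "iid",
    data: TimeSeriesData | None = None,
    n_draws: int = 200,
    seed: int = 0,
) -> IntervalBand:
    """95% credible and prediction bands at times ``t_star``.

    The credible (explanatory) band holds pointwise 2.5/50/97.5% quantiles
    of the noise-free model output m(theta, t*) over posterior draws.  The
    prediction band adds, per draw, a draw of the error process: iid noise
    for ``error_model='iid'``; for ``'gp_mismatch'`` a draw of the GP
    mismatch posterior (conditioned on ``data``) plus residual noise.

    ``simulator`` maps a parameter vector (chain order) to the model output
    at ``t_star``; draws on which it fails are skipped and counted.
    """
    t_star = np.asarray(t_star, dtype=float)
    post = chain.posterior
    if post.shape[0] < 100:
        raise ContractError("need at least 100 posterior draws")
    if error_model not in ("iid", "gp_mismatch"):
        raise ContractError(f"unknown error model {error_model!r}")
    if error_model == "gp_mismatch" and data is None:
        raise ContractError("gp_mismatch bands require the observed data")
    rng = np.random.default_rng(seed)
    idx = np.unique(
        np.floor(np.arange(min(n_draws, post.shape[0]))
                 * post.shape[0] / min(n_draws, post.shape[0])).astype(int)
    )
    curves, preds = [], []
    n_failed = 0
    names = chain.names
    for i in idx:
        x = post[i]
        try:
            m = np.asarray(simulator(x), dtype=float)
        except Exception:
            n_failed += 1
            continue
        curves.append(m)
        if error_model == "iid":
            s2 = x[names.index("sigma2")]
            preds.append(m + math.sqrt(max(s2, 0.0))
                         * rng.standard_normal(t_star.size))
        else:
            gp = GPMismatchModel(
                w=x[names.index("w")], b=x[names.index("b")],
                sigma_n2=x[names.index("sigma_n2")],
            )
            m_data = m if data.t.shape == t_star.shape and \
                np.allclose(data.t, t_star) else \
                np.interp(data.t, t_star, m)
            mean, cov = mismatch_predict(data, m_data, gp, t_star,
                                         include_noise=True)
            L = np.linalg.cholesky(cov + 1e-10 * np.eye(t_star.size))
            preds.append(m + mean + L @ rng.standard_normal(t_star.size))
    if not curves:
        raise DiagnosticError("simulator failed on every stored draw")
    curves = np.asarray(curves)
    preds = np.asarray(preds)
    qs = np.quantile(curves, [0.025, 0.5, 0.975], axis=0)
    qp = np.quantile(preds, [0.025, 0.975], axis=0)
    return IntervalBand(
        t=t_star, median=qs[1], ci_lo=qs[0], ci_hi=qs[2],
        pi_lo=np.minimum(qp[0], qs[0]), pi_hi=np.maximum(qp[1], qs[2]),
        n_failed=n_failed,
    )
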