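"""Priors and MCMC posterior sampling.

Biophysical parameters carry rescaled beta(1, 1) priors, i.e. uniform on a
physiological box [l, u]; variance parameters carry a weakly informative
conjugate inverse-gamma IG(0.001, 0.001) prior; GP kernel hyperparameters
(w, b) carry log-uniform priors on their printed ranges.

Sampling is adaptive random-walk Metropolis on transformed coordinates
(logit for box-bounded parameters, log for variances) with the exact
Jacobian correction, joint proposals with covariance adaptation, and - for
the iid noise model - a conjugate Gibbs update of sigma^2.  Chains are
deterministic given the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit

from .exceptions import ContractError, DiagnosticError, DomainError

__all__ = [
    "ParameterPrior",
    "PriorSpec",
    "MCMCSettings",
    "Chain",
    "log_prior",
    "run_mcmc",
    "sigma2_gibbs",
]


# ---------------------------------------------------------------------------
# Priors and transforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterPrior:
    """Prior for one scalar parameter.

    ``dist`` is one of ``uniform`` (rescaled beta(1,1) on [lower, upper]),
    ``log_uniform`` (uniform in log x on [lower, upper]) or
    ``inverse_gamma`` (IG(shape, rate), unbounded positive support).
    """

    name: str
    dist: str
    lower: float | None = None
    upper: float | None = None
    shape: float = 0.001
    rate: float = 0.001

    def __post_init__(self) -> None:
        if self.dist not in ("uniform", "log_uniform", "inverse_gamma"):
            raise ContractError(f"unknown prior {self.dist!r} for {self.name}")
        if self.dist in ("uniform", "log_uniform"):
            if self.lower is None or self.upper is None \
                    or not (self.lower < self.upper):
                raise ContractError(
                    f"{self.name}: bounded prior needs lower < upper"
                )
            if self.dist == "log_uniform" and self.lower <= 0:
                raise ContractError(f"{self.name}: log_uniform needs lower > 0")

    # -- log density in natural space ------------------------------------
    def log_density(self, x: float) -> float:
        if self.dist == "uniform":
            if not (self.lower <= x <= self.upper):
                return -math.inf
            return -math.log(self.upper - self.lower)
        if self.dist == "log_uniform":
            if not (self.lower <= x <= self.upper):
                return -math.inf
            return -math.log(x) - math.log(math.log(self.upper / self.lower))
        # inverse gamma
        if x <= 0:
            return -math.inf
        a, b = self.shape, self.rate
        return a * math.log(b) - gammaln(a) - (a + 1.0) * math.log(x) - b / x

    # -- unconstrained transform -----------------------------------------
    def to_unconstrained(self, x: float) -> float:
        if self.dist == "inverse_gamma":
            return math.log(x)
        if self.dist == "log_uniform":
            u = (math.log(x) - math.log(self.lower)) / \
                (math.log(self.upper) - math.log(self.lower))
        else:
            u = (x - self.lower) / (self.upper - self.lower)
        u = min(max(u, 1e-12), 1.0 - 1e-12)
        return float(logit(u))

    def from_unconstrained(self, z: float) -> float:
        if self.dist == "inverse_gamma":
            return math.exp(z)
        u = float(expit(z))
        if self.dist == "log_uniform":
            return math.exp(
                math.log(self.lower)
                + u * (math.log(self.upper) - math.log(self.lower))
            )
        return self.lower + u * (self.upper - self.lower)

    def log_jacobian(self, z: float) -> float:
        """log |dx/dz| of the inverse transform."""
        if self.dist == "inverse_gamma":
            return z
        # d expit / dz = s (1 - s); stable form log(s(1-s)) for large |z|
        lj = -abs(z) - 2.0 * math.log1p(math.exp(-abs(z)))
        if self.dist == "log_uniform":
            x = self.from_unconstrained(z)
            return lj + math.log(math.log(self.upper / self.lower)) + \
                math.log(x)
        return lj + math.log(self.upper - self.lower)


class PriorSpec:
    """Ordered prior specification: biophysical block then error block."""

    def __init__(self, theta: Sequence[ParameterPrior],
                 eta: Sequence[ParameterPrior]):
        self.theta = list(theta)
        self.eta = list(eta)
        self.params = self.theta + self.eta
        names = [p.name for p in self.params]
        if len(set(names)) != len(names):
            raise ContractError("duplicate parameter names")
        self.names = names
        self.k_theta = len(self.theta)

    @property
    def dim(self) -> int:
        return len(self.params)

    def __getitem__(self, name: str) -> ParameterPrior:
        for p in self.params:
            if p.name == name:
                return p
        raise ContractError(f"parameter {name!r} missing from the prior spec")

    def index(self, name: str) -> int:
        for i, p in enumerate(self.params):
            if p.name == name:
                return i
        raise ContractError(f"parameter {name!r} missing from the prior spec")

    def log_prior_vec(self, x: np.ndarray) -> float:
        if len(x) != self.dim:
            raise ContractError(
                f"expected {self.dim} parameters, got {len(x)}"
            )
        return float(sum(p.log_density(float(v))
                         for p, v in zip(self.params, x)))

    def to_unconstrained(self, x: np.ndarray) -> np.ndarray:
        return np.array([p.to_unconstrained(float(v))
                         for p, v in zip(self.params, x)])

    def from_unconstrained(self, z: np.ndarray) -> np.ndarray:
        return np.array([p.from_unconstrained(float(v))
                         for p, v in zip(self.params, z)])

    def log_jacobian(self, z: np.ndarray) -> float:
        return float(sum(p.log_jacobian(float(v))
                         for p, v in zip(self.params, z)))


def log_prior(theta: np.ndarray, eta: np.ndarray, spec: PriorSpec) -> float:
    """Joint log prior density of the biophysical and error parameters."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    if len(theta) != spec.k_theta or len(eta) != len(spec.eta):
        raise ContractError(
            f"expected {spec.k_theta} biophysical + {len(spec.eta)} error "
            f"parameters, got {len(theta)} + {len(eta)}"
        )
    return spec.log_prior_vec(np.concatenate([theta, eta]))


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MCMCSettings:
    """Adaptive random-walk Metropolis settings.

    Proposal covariance is re-estimated from the history every
    ``adapt_every`` iterations (Haario-style, scaled by 2.38^2/d), and the
    global scale is tuned toward ``target_accept``; adaptation freezes at
    burn-in.  ``n_pointwise`` caps the number of stored rows of the
    per-time-point log-likelihood matrix used by WAIC.
    """

    adapt_every: int = 100
    target_accept: float = 0.25
    burn_in_frac: float = 0.5
    n_pointwise: int = 1000
    init_scale: float = 0.05
    #: optional unconstrained-space proposal covariance to start from
    #: (e.g. from a pilot chain); adapted further during burn-in
    init_cov: np.ndarray | None = None


@dataclass
class Chain:
    """MCMC output: draws in natural parameter space plus WAIC inputs."""

    names: list[str]
    draws: np.ndarray            # (n_iter, d)
    log_post: np.ndarray         # (n_iter,)
    burn: int
    seed: int
    accept_rate: float
    pointwise_loglik: np.ndarray | None = None   # (S, n)
    pointwise_iters: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.log_post)):
            raise ContractError("chain contains non-finite log-posterior")
        if self.pointwise_loglik is not None \
                and self.pointwise_loglik.shape[0] != \
                (0 if self.pointwise_iters is None
                 else len(self.pointwise_iters)):
            raise ContractError("pointwise matrix rows must match iterations")

    @property
    def posterior(self) -> np.ndarray:
        """Post-burn-in draws."""
        return self.draws[self.burn:]

    def param(self, name: str, posterior_only: bool = True) -> np.ndarray:
        j = self.names.index(name)
        return (self.posterior if posterior_only else self.draws)[:, j]

    def median(self) -> np.ndarray:
        return np.median(self.posterior, axis=0)

    def quantiles(self, qs=(0.025, 0.5, 0.975)) -> pd.DataFrame:
        qa = np.quantile(self.posterior, qs, axis=0)
        return pd.DataFrame(qa.T, index=self.names,
                            columns=[f"q{100 * q:g}" for q in qs])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws, columns=self.names)

    def save(self, path: str | Path) -> None:
        """Write draws as CSV plus a JSON sidecar with sampling metadata."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if self.pointwise_loglik is not None:
            pd.DataFrame(self.pointwise_loglik).to_csv(
                path.with_name("pointwise_loglik.csv"), index=False)
        sidecar = path.with_suffix(".json")
        with open(sidecar, "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "burn": self.burn,
                    "accept_rate": self.accept_rate,
                    "names": self.names,
                    **{k: v for k, v in self.meta.items()
                       if isinstance(v, (int, float, str, bool, list))},
                },
                fh, indent=1,
            )


def sigma2_gibbs(residuals: np.ndarray, a: float, b: float,
                 rng: np.random.Generator) -> float:
    """Draw sigma^2 from its conjugate IG(a + n/2, b + SSR/2) conditional."""
    residuals = np.asarray(residuals, dtype=float)
    n = residuals.size
    if n < 1:
        raise ContractError("need at least one residual")
    shape = a + 0.5 * n
    rate = b + 0.5 * float(np.dot(residuals, residuals))
    # IG(shape, rate) draw = rate / Gamma(shape, 1)
    return rate / rng.gamma(shape, 1.0)


def run_mcmc(
    log_posterior: Callable,
    init: np.ndarray,
    n_iter: int,
    seed: int,
    spec: PriorSpec,
    settings: MCMCSettings | None = None,
    gibbs: Callable | None = None,
) -> Chain:
    """Sample the posterior with adaptive random-walk Metropolis.

    Parameters
    ----------
    log_posterior : callable
        Maps a natural-space parameter vector to either a float log
        posterior density or a tuple ``(log_post, pointwise_loglik)``;
        must be finite at ``init``.
    init : array
        Initial natural-space parameter vector (ordered as ``spec``).
    gibbs : callable, optional
        Conjugate update hook called once per iteration with
        ``(x, rng)``; returns ``(x_new, log_post_new, pointwise_new)``
        (used for the iid-noise sigma^2 step).

    Proposals act on unconstrained coordinates with the exact Jacobian
    correction; the first ``burn_in_frac`` of the chain is discarded as
    burn-in by downstream summaries.
    """
    settings = settings or MCMCSettings()
    rng = np.random.default_rng(seed)
    init = np.asarray(init, dtype=float)
    d = spec.dim
    if init.shape != (d,):
        raise ContractError(f"init must have length {d}")

    def evaluate(x: np.ndarray):
        out = log_posterior(x)
        if isinstance(out, tuple):
            return float(out[0]), out[1]
        return float(out), None

    z = spec.to_unconstrained(init)
    x = spec.from_unconstrained(z)
    lp, pw = evaluate(x)
    if not np.isfinite(lp):
        raise ContractError("log-posterior not finite at the initial point")
    lp_z = lp + spec.log_jacobian(z)

    burn = int(settings.burn_in_frac * n_iter)
    draws = np.empty((n_iter, d))
    log_post = np.empty(n_iter)
    n_keep = n_iter - burn
    pw_iters = np.unique(
        burn + np.floor(
            np.arange(min(settings.n_pointwise, n_keep))
            * n_keep / min(settings.n_pointwise, n_keep)
        ).astype(int)
    ) if n_keep > 0 else np.empty(0, dtype=int)
    pw_set = set(pw_iters.tolist())
    pw_rows: list[np.ndarray] = []
    pw_iters_kept: list[int] = []

    scale = settings.init_scale
    if settings.init_cov is not None:
        cov = np.asarray(settings.init_cov, dtype=float)
        scale = 1.0
    else:
        cov = np.eye(d)
    chol = np.linalg.cholesky(cov)
    cov_learned = settings.init_cov is not None
    z_hist = np.empty((n_iter, d))
    accepted = 0
    accepted_window = 0

    for it in range(n_iter):
        zprop = z + scale * (chol @ rng.standard_normal(d))
        xprop = spec.from_unconstrained(zprop)
        lprop_prior = spec.log_prior_vec(xprop)
        if not np.isfinite(lprop_prior):
            lp_prop_z = -math.inf
            pw_prop = None
        else:
            lp_prop, pw_prop = evaluate(xprop)
            lp_prop_z = lp_prop + spec.log_jacobian(zprop)
        if math.log(rng.random()) < lp_prop_z - lp_z:
            z, x, lp_z, pw = zprop, xprop, lp_prop_z, pw_prop
            lp = lp_prop
            accepted += 1
            accepted_window += 1
        if gibbs is not None:
            x_new, lp_new, pw_new = gibbs(x.copy(), rng)
            x = np.asarray(x_new, dtype=float)
            z = spec.to_unconstrained(x)
            lp = float(lp_new)
            lp_z = lp + spec.log_jacobian(z)
            pw = pw_new
        z_hist[it] = z
        draws[it] = x
        log_post[it] = lp
        if it in pw_set and pw is not None:
            pw_rows.append(np.asarray(pw, dtype=float))
            pw_iters_kept.append(it)
        # adaptation (frozen after burn-in)
        if it < burn and (it + 1) % settings.adapt_every == 0:
            rate = accepted_window / settings.adapt_every
            accepted_window = 0
            scale *= math.exp(rate - settings.target_accept)
            if it + 1 >= 2 * settings.adapt_every:
                # recent-half history: discards the early transient so the
                # proposal geometry tracks the stationary correlations
                emp = np.cov(z_hist[(it + 1) // 2: it + 1].T)
                emp = np.atleast_2d(emp) + 1e-8 * np.eye(d)
                try:
                    chol = np.linalg.cholesky((2.38 ** 2 / d) * emp)
                    if not cov_learned:
                        # leaving the isotropic start: re-anchor the scale
                        scale = 1.0
                        cov_learned = True
                except np.linalg.LinAlgError:
                    pass

    if accepted == 0:
        raise DiagnosticError(
            "sampler accepted no proposals; check the posterior scale"
        )
    pointwise = np.vstack(pw_rows) if pw_rows else None
    return Chain(
        names=list(spec.names),
        draws=draws,
        log_post=log_post,
        burn=burn,
        seed=seed,
        accept_rate=accepted / n_iter,
        pointwise_loglik=pointwise,
        pointwise_iters=np.array(pw_iters_kept) if pw_rows else None,
        meta={"n_iter": n_iter, "scale_final": scale},
    )
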