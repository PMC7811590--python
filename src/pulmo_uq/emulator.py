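"""GP surrogate (emulator) of the log-posterior to accelerate MCMC.

A space-filling Latin-hypercube design over the prior box is evaluated on
the true (PDE-backed) log-posterior; an anisotropic squared-exponential GP
with a nugget is fitted to the design by maximizing the marginal
likelihood, then refined by adding points where the emulator's predictive
standard deviation is largest among candidate draws.  MCMC then runs
against the emulator's predictive mean, which needs no further PDE solves.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.stats import qmc
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .exceptions import ConfigurationError, ContractError
from .inference import Chain, MCMCSettings, PriorSpec, run_mcmc

__all__ = [
    "EmulatorModel",
    "OutputEmulator",
    "train_emulator",
    "train_output_emulator",
    "emulated_mcmc",
    "bounds_from_spec",
]

#: default natural-space range assumed for unbounded positive variance
#: parameters when deriving an emulation box from a prior specification
_VARIANCE_BOX = (1e-3, 5.0)


def bounds_from_spec(spec: PriorSpec) -> list[tuple[float, float]]:
    """Natural-space emulation box implied by a prior specification."""
    out = []
    for p in spec.params:
        if p.dist == "inverse_gamma":
            out.append(_VARIANCE_BOX)
        elif p.dist == "log_uniform":
            out.append((p.lower, p.upper))
        else:
            out.append((p.lower, p.upper))
    return out


@dataclass
class EmulatorModel:
    """Trained log-posterior surrogate.

    ``X`` holds design points in natural space, ``y`` the log-posterior
    values; inputs are scaled to the unit box and log-uniform/variance
    coordinates to log scale internally before the GP sees them.
    """

    X: np.ndarray
    y: np.ndarray
    bounds: list[tuple[float, float]]
    log_dims: list[bool]
    gpr: GaussianProcessRegressor = field(repr=False)
    spec: PriorSpec | None = field(default=None, repr=False)
    seed: int = 0

    def _scale(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty_like(X)
        for j, (lo, hi) in enumerate(self.bounds):
            if self.log_dims[j]:
                out[:, j] = (np.log(X[:, j]) - math.log(lo)) / \
                    (math.log(hi) - math.log(lo))
            else:
                out[:, j] = (X[:, j] - lo) / (hi - lo)
        return out

    def predict(self, x: np.ndarray, return_std: bool = False):
        """Emulated log-posterior (and predictive sd) at natural-space x."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        if single:
            for j, (lo, hi) in enumerate(self.bounds):
                if not (lo <= x[j] <= hi):
                    return (-math.inf, 0.0) if return_std else -math.inf
        out = self.gpr.predict(self._scale(x), return_std=return_std)
        if return_std:
            mean, std = out
            return (float(mean[0]), float(std[0])) if single else (mean, std)
        return float(out[0]) if single else out

    def __call__(self, x: np.ndarray) -> float:
        return self.predict(x)

    def save(self, path: str | Path) -> None:
        """Portable JSON archive: design inputs/targets + hyperparameters."""
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(
                {
                    "X": self.X.tolist(),
                    "y": self.y.tolist(),
                    "bounds": [list(b) for b in self.bounds],
                    "log_dims": list(self.log_dims),
                    "kernel": str(self.gpr.kernel_),
                    "seed": self.seed,
                },
                fh,
            )


def _fit_gpr(Xs: np.ndarray, y: np.ndarray, seed: int) -> GaussianProcessRegressor:
    d = Xs.shape[1]
    kernel = ConstantKernel(1.0, (1e-3, 1e5)) * RBF(
        length_scale=np.full(d, 0.3), length_scale_bounds=(1e-2, 1e2)
    ) + WhiteKernel(1e-6, (1e-10, 1e-1))
    gpr = GaussianProcessRegressor(
        kernel=kernel, normalize_y=True, n_restarts_optimizer=2,
        random_state=seed,
    )
    gpr.fit(Xs, y)
    return gpr


def train_emulator(
    log_posterior: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    n_design: int | None = None,
    seed: int = 0,
    log_dims: Sequence[bool] | None = None,
    n_refine: int | None = None,
    n_candidates: int = 512,
    spec: PriorSpec | None = None,
    max_resample: int = 20,
    refit_every: int = 5,
    ucb_kappa: float = 2.0,
    clip_range: float = 50.0,
) -> EmulatorModel:
    """Two-stage design-and-fit of the log-posterior surrogate.

    Stage 1: seeded Latin-hypercube design of ``n_design`` points (default
    30 per dimension) over the box; points with non-finite log-posterior
    are discarded and resampled.  Stage 2: ``n_refine`` extra points chosen
    by an upper-confidence acquisition (predictive mean + ``ucb_kappa``
    standard deviations) over candidate draws - half uniform over the box,
    half jittered around the best design points - so the design concentrates
    where the posterior carries mass while the predictive-variance term
    keeps exploring; the GP is refitted every ``refit_every`` additions.

    Log-posterior values more than ``clip_range`` below the running maximum
    are clipped before fitting: the surrogate only needs to be accurate
    where the posterior mass lives, and the clipped tail (relative density
    below e^-clip_range) keeps the GP from chasing the enormous dynamic
    range of the far tails.
    """
    bounds = list(bounds)
    d = len(bounds)
    if n_design is None:
        n_design = 30 * d
    if n_design < 10 * d:
        raise ContractError("n_design must be at least 10 per dimension")
    if n_refine is None:
        n_refine = max(n_design // 4, 1)
    if log_dims is None:
        if spec is not None:
            log_dims = [p.dist in ("log_uniform", "inverse_gamma")
                        for p in spec.params]
        else:
            log_dims = [False] * d
    log_dims = list(log_dims)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def unscale(U: np.ndarray) -> np.ndarray:
        X = np.empty_like(U)
        for j in range(d):
            if log_dims[j]:
                X[:, j] = np.exp(
                    math.log(lo[j]) + U[:, j]
                    * (math.log(hi[j]) - math.log(lo[j]))
                )
            else:
                X[:, j] = lo[j] + U[:, j] * (hi[j] - lo[j])
        return X

    sampler = qmc.LatinHypercube(d=d, seed=seed)
    X_list: list[np.ndarray] = []
    y_list: list[float] = []
    for _round in range(max_resample):
        need = n_design - len(y_list)
        if need <= 0:
            break
        U = sampler.random(need)
        X = unscale(U)
        for xi in X:
            yi = float(log_posterior(xi))
            if np.isfinite(yi):
                X_list.append(xi)
                y_list.append(yi)
    if not y_list:
        raise ConfigurationError(
            "every design point had a non-finite log-posterior"
        )
    X = np.array(X_list)
    y = np.array(y_list)

    def clipped(v: np.ndarray) -> np.ndarray:
        return np.maximum(v, v.max() - clip_range)

    model = EmulatorModel(X=X, y=y, bounds=bounds, log_dims=log_dims,
                          gpr=None, spec=spec, seed=seed)
    model.gpr = _fit_gpr(model._scale(X), clipped(y), seed)

    rng = np.random.default_rng(seed + 1)
    added = 0
    for _r in range(n_refine):
        n_half = n_candidates // 2
        Uc = rng.random((n_half, d))
        # local candidates jittered (in scaled space) around the best points
        Us = model._scale(X)
        order = np.argsort(y)[::-1]
        top = Us[order[: max(5, len(order) // 10)]]
        picks = top[rng.integers(0, len(top), n_half)]
        # mixture of narrow and wide jitters: narrow refines the mode,
        # wide covers weakly identified (broad) posterior directions
        sds = np.where(rng.random((n_half, 1)) < 0.5, 0.05, 0.25)
        Ul = np.clip(picks + sds * rng.standard_normal((n_half, d)),
                     1e-9, 1 - 1e-9)
        Uc = np.vstack([Uc, Ul])
        Xc = unscale(Uc)
        mean, std = model.gpr.predict(model._scale(Xc), return_std=True)
        xi = Xc[int(np.argmax(mean + ucb_kappa * std))]
        yi = float(log_posterior(xi))
        if not np.isfinite(yi):
            continue
        X = np.vstack([X, xi])
        y = np.append(y, yi)
        model.X, model.y = X, y
        added += 1
        if added % refit_every == 0:
            model.gpr = _fit_gpr(model._scale(X), clipped(y), seed)
    model.gpr = _fit_gpr(model._scale(X), clipped(y), seed)
    return model


@dataclass
class OutputEmulator:
    """GP surrogate of the forward map theta -> pressure outputs.

    Emulates only the expensive PDE solve; the error-model likelihood is
    then evaluated analytically in the error parameters, which stay exact.
    ``Y`` holds one row of concatenated per-vessel pressure outputs per
    design point.
    """

    X: np.ndarray
    Y: np.ndarray
    bounds: list[tuple[float, float]]
    log_dims: list[bool]
    gpr: GaussianProcessRegressor = field(repr=False)
    seed: int = 0

    def _scale(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty_like(X)
        for j, (lo, hi) in enumerate(self.bounds):
            if self.log_dims[j]:
                out[:, j] = (np.log(X[:, j]) - math.log(lo)) / \
                    (math.log(hi) - math.log(lo))
            else:
                out[:, j] = (X[:, j] - lo) / (hi - lo)
        return out

    def predict(self, theta: np.ndarray, return_std: bool = False):
        """Emulated output vector at ``theta`` (optionally with GP sd)."""
        out = self.gpr.predict(self._scale(theta), return_std=return_std)
        if return_std:
            mean, std = out
            return mean[0], np.atleast_2d(std)[0]
        return out[0]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(
                {
                    "X": self.X.tolist(),
                    "Y": self.Y.tolist(),
                    "bounds": [list(b) for b in self.bounds],
                    "log_dims": list(self.log_dims),
                    "kernel": str(self.gpr.kernel_),
                    "seed": self.seed,
                },
                fh,
            )


def train_output_emulator(
    forward_fn: Callable[[np.ndarray], np.ndarray],
    bounds: Sequence[tuple[float, float]],
    n_design: int | None = None,
    seed: int = 0,
    log_dims: Sequence[bool] | None = None,
    n_refine: int | None = None,
    score_fn: Callable[[np.ndarray, np.ndarray], float] | None = None,
    n_candidates: int = 512,
    refit_every: int = 25,
    ucb_kappa: float = 2.0,
    sigma_ref: float = 0.3,
    max_resample: int = 20,
) -> OutputEmulator:
    """Design-and-fit of the forward-map surrogate.

    Stage 1 is a seeded Latin-hypercube design over the parameter box
    (default 40 points per dimension); stage 2 adds points chosen by an
    upper-confidence score: ``score_fn(theta, m_emulated)`` (typically a
    reference log-posterior computed from the emulated outputs) plus
    ``ucb_kappa`` times the GP output uncertainty in units of ``sigma_ref``
    (mmHg).  Without a ``score_fn`` refinement maximizes the predictive
    uncertainty alone.
    """
    bounds = list(bounds)
    d = len(bounds)
    if n_design is None:
        n_design = 40 * d
    if n_design < 10 * d:
        raise ContractError("n_design must be at least 10 per dimension")
    if n_refine is None:
        n_refine = max(n_design // 2, 1)
    if log_dims is None:
        log_dims = [False] * d
    log_dims = list(log_dims)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def unscale(U: np.ndarray) -> np.ndarray:
        X = np.empty_like(U)
        for j in range(d):
            if log_dims[j]:
                X[:, j] = np.exp(math.log(lo[j]) + U[:, j]
                                 * (math.log(hi[j]) - math.log(lo[j])))
            else:
                X[:, j] = lo[j] + U[:, j] * (hi[j] - lo[j])
        return X

    sampler = qmc.LatinHypercube(d=d, seed=seed)
    X_list: list[np.ndarray] = []
    Y_list: list[np.ndarray] = []
    for _round in range(max_resample):
        need = n_design - len(Y_list)
        if need <= 0:
            break
        for xi in unscale(sampler.random(need)):
            try:
                yi = np.asarray(forward_fn(xi), dtype=float)
            except Exception:
                continue
            if np.all(np.isfinite(yi)):
                X_list.append(xi)
                Y_list.append(yi)
    if not Y_list:
        raise ConfigurationError("every design point failed to evaluate")
    X = np.array(X_list)
    Y = np.array(Y_list)

    model = OutputEmulator(X=X, Y=Y, bounds=bounds, log_dims=log_dims,
                           gpr=None, seed=seed)
    model.gpr = _fit_gpr(model._scale(X), Y, seed)

    rng = np.random.default_rng(seed + 1)
    if score_fn is not None:
        scores = np.array([score_fn(x, y) for x, y in zip(X, Y)])
    added = 0
    for _r in range(n_refine):
        n_half = n_candidates // 2
        Uc = rng.random((n_half, d))
        if score_fn is not None:
            Us = model._scale(X)
            order = np.argsort(scores)[::-1]
            top = Us[order[: max(5, len(order) // 10)]]
            picks = top[rng.integers(0, len(top), n_half)]
            sds = np.where(rng.random((n_half, 1)) < 0.5, 0.05, 0.25)
            Ul = np.clip(picks + sds * rng.standard_normal((n_half, d)),
                         1e-9, 1 - 1e-9)
            Uc = np.vstack([Uc, Ul])
        Xc = unscale(Uc)
        M, S = model.gpr.predict(model._scale(Xc), return_std=True)
        S = np.atleast_2d(S)
        unc = np.sqrt(np.sum(S ** 2, axis=1)) / sigma_ref
        if score_fn is not None:
            acq = np.array([score_fn(x, m) for x, m in zip(Xc, M)]) \
                + ucb_kappa * unc
        else:
            acq = unc
        xi = Xc[int(np.argmax(acq))]
        try:
            yi = np.asarray(forward_fn(xi), dtype=float)
        except Exception:
            continue
        if not np.all(np.isfinite(yi)):
            continue
        X = np.vstack([X, xi])
        Y = np.vstack([Y, yi])
        model.X, model.Y = X, Y
        if score_fn is not None:
            scores = np.append(scores, score_fn(xi, yi))
        added += 1
        if added % refit_every == 0:
            model.gpr = _fit_gpr(model._scale(X), Y, seed)
    model.gpr = _fit_gpr(model._scale(X), Y, seed)
    return model


def emulated_mcmc(
    emulator: EmulatorModel,
    n_iter: int,
    seed: int,
    spec: PriorSpec | None = None,
    init: np.ndarray | None = None,
    settings: MCMCSettings | None = None,
) -> Chain:
    """Run MCMC against the emulator's predictive mean (no PDE solves).

    The chain is flagged ``emulated`` in its metadata.
    """
    spec = spec or emulator.spec
    if spec is None:
        raise ContractError("emulated_mcmc needs the prior specification")
    if init is None:
        init = emulator.X[int(np.argmax(emulator.y))]

    def logpost(x: np.ndarray) -> float:
        return emulator.predict(x)

    chain = run_mcmc(logpost, init, n_iter, seed, spec, settings=settings)
    chain.meta["emulated"] = True
    return chain
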