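"""Joint posterior of biophysical and error parameters.

Realizes p(theta, eta | y) ~ p(y | theta, eta) p(theta, eta): a
:class:`ForwardModel` maps a named parameter vector to pressure predictions
at the observation times, and posterior factories combine it with either the
iid or the GP-mismatch likelihood over one or several observed vessels.
The forward model warm-starts each solve from the previous converged state
and picks a CFL-safe time step per proposal, which keeps joint MCMC over
the PDE tractable at desk scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import PhysicalConstants
from .error_models import (
    GPMismatchModel,
    TimeSeriesData,
    build_covariance,
    loglik_correlated_pointwise,
)
from .exceptions import ContractError, SolverError
from .inference import (
    Chain,
    MCMCSettings,
    ParameterPrior,
    PriorSpec,
    run_mcmc,
    sigma2_gibbs,
)
from .network import ScalingFactors, VesselNetwork, apply_scalings, nominal_windkessel
from .pde import SimulationGrid, WallModel, simulate, stable_dt
from .synth import DEFAULT_NOMINAL_MEAN_PRESSURE, InflowSpec, synthetic_inflow

__all__ = [
    "ForwardModel",
    "CalibrationProblem",
    "default_theta_priors",
    "default_eta_priors",
]

#: Windkessel scaling-factor prior box shared by all models
SCALING_BOUNDS = (0.05, 2.50)


def default_theta_priors(
    wall_kind: str = "linear",
    stiffness_mode: str = "radius_dependent",
) -> list[ParameterPrior]:
    """Uniform (rescaled beta(1,1)) priors on the printed physiological boxes."""
    priors: list[ParameterPrior] = []
    if stiffness_mode == "radius_dependent":
        if wall_kind == "linear":
            priors += [
                ParameterPrior("f1", "uniform", 1.0e3, 1.0e7),
                ParameterPrior("f2", "uniform", -300.0, -50.0),
                ParameterPrior("f3", "uniform", 3.0e4, 6.0e4),
            ]
        else:
            priors += [
                ParameterPrior("f1", "uniform", 5.0e3, 1.0e5),
                ParameterPrior("f2", "uniform", -200.0, 0.0),
                ParameterPrior("f3", "uniform", 1.0e4, 50.0e4),
            ]
    elif stiffness_mode == "constant":
        if wall_kind == "linear":
            priors.append(ParameterPrior("f3", "uniform", 2.0e4, 10.0e4))
        else:
            priors.append(ParameterPrior("f3", "uniform", 3.0e4, 50.0e4))
    else:
        raise ContractError(
            "vessel_specific priors are built by the hierarchical sampler"
        )
    if wall_kind == "nonlinear":
        priors.append(ParameterPrior("gamma", "uniform", 1.0, 2.0 * math.pi))
    priors += [
        ParameterPrior("psi1", "uniform", *SCALING_BOUNDS),
        ParameterPrior("psi2", "uniform", *SCALING_BOUNDS),
        ParameterPrior("c", "uniform", *SCALING_BOUNDS),
    ]
    return priors


def default_eta_priors(error_model: str = "gp_mismatch") -> list[ParameterPrior]:
    """Error-parameter priors: IG(0.001, 0.001) variances, log-uniform (w, b)."""
    if error_model == "iid":
        return [ParameterPrior("sigma2", "inverse_gamma")]
    if error_model == "gp_mismatch":
        return [
            ParameterPrior("w", "log_uniform", 1.0e4, 9.0e4),
            ParameterPrior("b", "log_uniform", 1.0, 500.0),
            ParameterPrior("sigma_n2", "inverse_gamma"),
        ]
    raise ContractError(f"unknown error model {error_model!r}")


class ForwardModel:
    """Pressure predictions in observed vessels as a function of parameters.

    Parameters are passed as a name -> value mapping covering the wall model
    (``f1``/``f2``/``f3``, ``gamma``, or per-vessel ``chi_<id>``) and the
    Windkessel scaling factors (``psi1``, ``psi2``, ``c``).  Output is the
    mid-vessel pressure series of each observed vessel interpolated onto the
    requested observation times.
    """

    def __init__(
        self,
        network: VesselNetwork,
        vessels: Sequence[int],
        wall_kind: str = "linear",
        stiffness_mode: str = "radius_dependent",
        inflow: InflowSpec | None = None,
        constants: PhysicalConstants | None = None,
        dx: float = 0.05,
        n_cycles: int = 10,
        convergence_tol: float = 1e-3,
        n_store: int = 128,
        x_frac: float = 0.5,
        nominal_mean_pressure: float = DEFAULT_NOMINAL_MEAN_PRESSURE,
        cfl_safety: float = 0.35,
    ):
        self.network = network
        self.vessels = list(vessels)
        for vid in self.vessels:
            if vid not in network:
                raise ContractError(f"vessel {vid} not in the network")
        self.wall_kind = wall_kind
        self.stiffness_mode = stiffness_mode
        self.inflow = inflow or InflowSpec()
        self.constants = constants or PhysicalConstants(T=self.inflow.T)
        self.dx = dx
        self.n_cycles = n_cycles
        self.convergence_tol = convergence_tol
        self.n_store = n_store
        self.x_frac = x_frac
        self.cfl_safety = cfl_safety
        self._flow = synthetic_inflow(self.inflow)
        self._nominal = nominal_windkessel(
            network, self.inflow.mean_flow, nominal_mean_pressure,
            blood=self.constants,
        )
        self._state = None
        self.n_solves = 0
        self.n_cold_retries = 0

    # -- parameter handling ------------------------------------------------
    def wall_from_params(self, params: dict[str, float]) -> WallModel:
        gamma = params.get("gamma") if self.wall_kind == "nonlinear" else None
        if self.stiffness_mode == "vessel_specific":
            chi = {
                v.id: float(params[f"chi_{v.id}"])
                for v in self.network.vessels
            }
            return WallModel(
                kind=self.wall_kind, gamma=gamma,
                stiffness_mode="vessel_specific", chi_per_vessel=chi,
            )
        f1 = float(params.get("f1", 0.0))
        f2 = float(params.get("f2", 0.0))
        f3 = float(params["f3"])
        return WallModel(
            kind=self.wall_kind, f1=f1, f2=f2, f3=f3, gamma=gamma,
            stiffness_mode=self.stiffness_mode,
        )

    # -- prediction --------------------------------------------------------
    def predict(
        self, params: dict[str, float], t_obs: np.ndarray
    ) -> dict[int, np.ndarray]:
        """Per-vessel pressure (mmHg) at observation times ``t_obs``."""
        wall = self.wall_from_params(params)
        wk = apply_scalings(
            self._nominal,
            ScalingFactors(params["psi1"], params["psi2"], params["c"]),
        )
        dt = stable_dt(self.network, wall, self.dx, self.constants,
                       safety=self.cfl_safety)
        grid = SimulationGrid(dx=self.dx, dt=dt, n_cycles=self.n_cycles,
                              convergence_tol=self.convergence_tol)
        try:
            fields = simulate(
                self.network, wall, wk, self._flow, grid, self.constants,
                n_store=self.n_store, init_state=self._state,
            )
        except SolverError:
            # retry cold with a halved step before giving up
            self.n_cold_retries += 1
            grid2 = SimulationGrid(dx=self.dx, dt=0.5 * dt,
                                   n_cycles=self.n_cycles,
                                   convergence_tol=self.convergence_tol)
            fields = simulate(
                self.network, wall, wk, self._flow, grid2, self.constants,
                n_store=self.n_store,
            )
        self._state = fields.final_state
        self.n_solves += 1
        T = self.constants.T
        out: dict[int, np.ndarray] = {}
        tmod = np.mod(t_obs, T)
        for vid in self.vessels:
            series = fields.pressure_series(vid, self.x_frac)
            tper = np.concatenate([fields.t, [fields.t[0] + T]])
            yper = np.concatenate([series, [series[0]]])
            out[vid] = np.interp(tmod, tper, yper)
        return out


@dataclass
class CalibrationProblem:
    """A forward model + data + priors, ready for MCMC.

    ``error_model`` selects the iid likelihood (with conjugate Gibbs updates
    of sigma^2) or the GP-mismatch likelihood with the neural-network
    kernel.  Multi-vessel data enter as independent blocks sharing the same
    error parameters.
    """

    forward: ForwardModel
    data: list[TimeSeriesData]
    error_model: str = "gp_mismatch"
    spec: PriorSpec | None = None

    def __post_init__(self) -> None:
        if self.error_model not in ("iid", "gp_mismatch"):
            raise ContractError(f"unknown error model {self.error_model!r}")
        if not self.data:
            raise ContractError("need at least one observed vessel series")
        data_ids = [d.vessel_id for d in self.data]
        if sorted(data_ids) != sorted(self.forward.vessels):
            raise ContractError(
                "data vessels must match the forward model's observed vessels"
            )
        if self.spec is None:
            self.spec = PriorSpec(
                default_theta_priors(self.forward.wall_kind,
                                     self.forward.stiffness_mode),
                default_eta_priors(self.error_model),
            )
        self._t_obs = self.data[0].t
        for d in self.data:
            if d.t.shape != self._t_obs.shape or \
                    not np.allclose(d.t, self._t_obs):
                raise ContractError(
                    "all vessels must share one observation grid"
                )
        self._pred_cache: dict[tuple, dict[int, np.ndarray]] = {}

    # -- likelihood building blocks ---------------------------------------
    def _theta_names(self) -> list[str]:
        return [p.name for p in self.spec.theta]

    def _predictions(self, params: dict[str, float]) -> dict[int, np.ndarray]:
        key = tuple(params[n] for n in self._theta_names())
        if key in self._pred_cache:
            return self._pred_cache[key]
        preds = self.forward.predict(params, self._t_obs)
        if len(self._pred_cache) > 3:
            self._pred_cache.clear()
        self._pred_cache[key] = preds
        return preds

    def _pointwise_rows(
        self, preds: dict[int, np.ndarray], params: dict[str, float]
    ) -> np.ndarray:
        """Per-point log-likelihood terms for the chosen error model."""
        rows = []
        if self.error_model == "iid":
            s2 = params["sigma2"]
            for d in self.data:
                r = d.y - preds[d.vessel_id]
                rows.append(
                    -0.5 * np.log(2 * math.pi * s2) - 0.5 * r ** 2 / s2
                )
        else:
            gp = GPMismatchModel(
                w=params["w"], b=params["b"], sigma_n2=params["sigma_n2"]
            )
            C = build_covariance(self._t_obs, gp)
            for d in self.data:
                rows.append(
                    loglik_correlated_pointwise(d, preds[d.vessel_id], C)
                )
        return np.concatenate(rows)

    def log_posterior(self, x: np.ndarray):
        """Returns (log posterior, per-point log-likelihood vector)."""
        x = np.asarray(x, dtype=float)
        lp = self.spec.log_prior_vec(x)
        if not np.isfinite(lp):
            return -math.inf, None
        params = dict(zip(self.spec.names, x))
        try:
            preds = self._predictions(params)
        except SolverError:
            return -math.inf, None
        pointwise = self._pointwise_rows(preds, params)
        return lp + float(pointwise.sum()), pointwise

    def _gibbs_sigma2(self, x: np.ndarray, rng: np.random.Generator):
        """Conjugate sigma^2 update reusing the cached forward prediction."""
        params = dict(zip(self.spec.names, x))
        preds = self._predictions(params)
        resid = np.concatenate(
            [d.y - preds[d.vessel_id] for d in self.data]
        )
        prior = self.spec["sigma2"]
        s2 = sigma2_gibbs(resid, prior.shape, prior.rate, rng)
        x[self.spec.index("sigma2")] = s2
        lp, pw = self.log_posterior(x)
        return x, lp, pw

    def initial_point(self, jitter: float = 0.0,
                      rng: np.random.Generator | None = None) -> np.ndarray:
        """Prior-box midpoint (log-midpoint for positive parameters)."""
        vals = []
        for p in self.spec.params:
            if p.dist == "uniform":
                v = 0.5 * (p.lower + p.upper)
            elif p.dist == "log_uniform":
                v = math.exp(0.5 * (math.log(p.lower) + math.log(p.upper)))
            else:
                v = 0.25  # variance start, mmHg^2
            vals.append(v)
        x = np.array(vals)
        if jitter > 0 and rng is not None:
            for i, p in enumerate(self.spec.params):
                if p.dist == "uniform":
                    x[i] += jitter * (p.upper - p.lower) * \
                        (rng.random() - 0.5)
        return x

    # -- emulation ---------------------------------------------------------
    def _split_preds(self, m: np.ndarray) -> dict[int, np.ndarray]:
        n = self._t_obs.size
        return {
            d.vessel_id: m[i * n:(i + 1) * n]
            for i, d in enumerate(self.data)
        }

    def train_output_emulator(self, seed: int, n_design: int | None = None,
                              n_refine: int | None = None, **kw):
        """Fit a GP surrogate of theta -> concatenated pressure outputs.

        The error parameters are not emulated: the likelihood stays exact
        in them, so the surrogate only has to cover the biophysical box.
        Refinement is scored by a reference log-posterior computed from the
        emulated outputs at mid-prior error parameters.
        """
        from .emulator import train_output_emulator

        names = self._theta_names()
        bounds = [(p.lower, p.upper) for p in self.spec.theta]
        eta_ref = {
            p.name: (
                math.exp(0.5 * (math.log(p.lower) + math.log(p.upper)))
                if p.dist == "log_uniform" else 0.25
            )
            for p in self.spec.eta
        }

        def fwd(theta_vec: np.ndarray) -> np.ndarray:
            params = dict(zip(names, theta_vec))
            preds = self.forward.predict(params, self._t_obs)
            return np.concatenate([preds[d.vessel_id] for d in self.data])

        def score(theta_vec: np.ndarray, m: np.ndarray) -> float:
            params = dict(zip(names, theta_vec))
            params.update(eta_ref)
            return float(self._pointwise_rows(self._split_preds(m),
                                              params).sum())

        return train_output_emulator(
            fwd, bounds, n_design=n_design, seed=seed, n_refine=n_refine,
            score_fn=score, **kw,
        )

    def run_emulated(
        self,
        n_iter: int,
        seed: int,
        emulator=None,
        init: np.ndarray | None = None,
        settings: MCMCSettings | None = None,
        n_design: int | None = None,
    ) -> Chain:
        """MCMC against the output surrogate (no PDE solves per iteration).

        The biophysical block uses the emulated forward map; the error
        parameters enter the likelihood exactly.  The chain is flagged
        ``emulated``.
        """
        if emulator is None:
            emulator = self.train_output_emulator(seed=seed,
                                                  n_design=n_design)
        names = self._theta_names()
        k = len(names)

        def logpost(x: np.ndarray):
            lp = self.spec.log_prior_vec(x)
            if not np.isfinite(lp):
                return -math.inf, None
            params = dict(zip(self.spec.names, x))
            m = emulator.predict(np.asarray(x[:k], dtype=float))
            pointwise = self._pointwise_rows(self._split_preds(m), params)
            return lp + float(pointwise.sum()), pointwise

        init = self.initial_point() if init is None else np.asarray(init)
        chain = run_mcmc(logpost, init, n_iter, seed, self.spec,
                         settings=settings)
        chain.meta["emulated"] = True
        chain.meta["error_model"] = self.error_model
        chain.meta["n_design"] = int(emulator.X.shape[0])
        return chain

    def run(
        self,
        n_iter: int,
        seed: int,
        init: np.ndarray | None = None,
        settings: MCMCSettings | None = None,
    ) -> Chain:
        """Sample the joint posterior; Gibbs sigma^2 step in the iid case."""
        init = self.initial_point() if init is None else np.asarray(init)
        gibbs = self._gibbs_sigma2 if self.error_model == "iid" else None
        chain = run_mcmc(
            self.log_posterior, init, n_iter, seed, self.spec,
            settings=settings, gibbs=gibbs,
        )
        chain.meta["error_model"] = self.error_model
        chain.meta["vessels"] = [int(v) for v in self.forward.vessels]
        chain.meta["n_solves"] = self.forward.n_solves
        return chain
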