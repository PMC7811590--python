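"""Bayesian hierarchical model for vessel-specific wall stiffness.

Each vessel's stiffness chi_j is drawn from a common population law
N(m_chi, sigma_chi^2) truncated to chi_j > 0; the population mean and
variance carry a normal / inverse-gamma hyperprior pair calibrated so the
prior predictive places ~90% of its mass on the physiological stiffness
range (2, 10) x 10^4 g cm^-1 s^-2.  The model subsumes shared stiffness
(sigma_chi^2 -> 0) and independent per-vessel stiffness
(sigma_chi^2 -> infinity) as limiting cases.

Sampling is Gibbs-within-Metropolis: conjugate draws of m_chi and
sigma_chi^2, Metropolis updates of each chi_j (one forward PDE solve per
proposal), and a joint Metropolis block for the Windkessel scaling factors
and error parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .calibrate import ForwardModel, default_eta_priors
from .error_models import (
    GPMismatchModel,
    TimeSeriesData,
    build_covariance,
    loglik_correlated_pointwise,
)
from .exceptions import ContractError, SolverError
from .inference import Chain, ParameterPrior, PriorSpec, sigma2_gibbs
from .network import ScalingFactors

__all__ = ["HierarchicalHyperprior", "gibbs_hierarchical"]


@dataclass(frozen=True)
class HierarchicalHyperprior:
    """Hyperpriors of the stiffness population law.

    ``m_sd=None`` selects a flat prior on the population mean (used to test
    the conjugate conditional).  ``fix_sigma2_chi`` freezes the population
    variance (limiting-case studies) instead of sampling it.
    """

    m_mean: float = 6.0e4
    m_sd: float | None = 2.15e4
    s2_shape: float = 2.0
    s2_rate: float = 1.75e8
    fix_sigma2_chi: float | None = None


def _m_chi_conditional(
    chi: np.ndarray, s2_chi: float, hp: HierarchicalHyperprior
) -> tuple[float, float]:
    """Mean and variance of the conjugate normal conditional of m_chi."""
    k = chi.size
    if hp.m_sd is None:
        return float(chi.mean()), s2_chi / k
    prec = 1.0 / hp.m_sd ** 2 + k / s2_chi
    mean = (hp.m_mean / hp.m_sd ** 2 + chi.sum() / s2_chi) / prec
    return float(mean), 1.0 / prec


def gibbs_hierarchical(
    data: list[TimeSeriesData],
    forward: ForwardModel,
    n_iter: int,
    seed: int,
    hyperprior: HierarchicalHyperprior | None = None,
    error_model: str = "gp_mismatch",
    init: dict[str, float] | None = None,
    chi_init: float = 5.0e4,
    chi_prop_scale: float = 0.05,
    shared_prop_scale: float = 0.05,
    adapt_every: int = 50,
    burn_in_frac: float = 0.5,
    n_pointwise: int = 1000,
) -> Chain:
    """Sample the hierarchical vessel-specific stiffness posterior.

    ``forward`` must be built with ``stiffness_mode='vessel_specific'``.
    The returned chain has columns chi_<id> per vessel, psi1, psi2, c, the
    error parameters, and the hyperparameters m_chi and sigma2_chi.
    """
    hp = hyperprior or HierarchicalHyperprior()
    if forward.stiffness_mode != "vessel_specific":
        raise ContractError(
            "hierarchical sampling needs a vessel_specific forward model"
        )
    if error_model not in ("iid", "gp_mismatch"):
        raise ContractError(f"unknown error model {error_model!r}")
    rng = np.random.default_rng(seed)
    vessel_ids = [v.id for v in forward.network.vessels]
    k = len(vessel_ids)
    t_obs = data[0].t
    data_by_id = {d.vessel_id: d for d in data}
    if sorted(data_by_id) != sorted(forward.vessels):
        raise ContractError("data vessels must match the observed vessels")

    eta_priors = default_eta_priors(error_model)
    shared_priors = [
        ParameterPrior("psi1", "uniform", 0.05, 2.50),
        ParameterPrior("psi2", "uniform", 0.05, 2.50),
        ParameterPrior("c", "uniform", 0.05, 2.50),
    ] + eta_priors
    shared_spec = PriorSpec(shared_priors, [])
    n_shared = shared_spec.dim

    # state
    chi = np.full(k, chi_init, dtype=float)
    m_chi = hp.m_mean
    s2_chi = hp.fix_sigma2_chi if hp.fix_sigma2_chi is not None else \
        hp.s2_rate / (hp.s2_shape + 1.0)   # prior mode
    shared = np.array([
        0.5 * (p.lower + p.upper) if p.dist == "uniform"
        else (math.exp(0.5 * (math.log(p.lower) + math.log(p.upper)))
              if p.dist == "log_uniform" else 0.25)
        for p in shared_priors
    ])
    if init:
        for j, vid in enumerate(vessel_ids):
            if f"chi_{vid}" in init:
                chi[j] = init[f"chi_{vid}"]
        for j, p in enumerate(shared_priors):
            if p.name in init:
                shared[j] = init[p.name]

    def params_dict() -> dict[str, float]:
        d = {f"chi_{vid}": chi[j] for j, vid in enumerate(vessel_ids)}
        d.update(dict(zip(shared_spec.names, shared)))
        return d

    def loglik(pd: dict[str, float]):
        """(log-likelihood, pointwise rows, residuals) at parameters pd."""
        try:
            preds = forward.predict(pd, t_obs)
        except SolverError:
            return -math.inf, None, None
        rows = []
        resid = []
        if error_model == "iid":
            s2 = pd["sigma2"]
            for vid in forward.vessels:
                r = data_by_id[vid].y - preds[vid]
                resid.append(r)
                rows.append(-0.5 * np.log(2 * math.pi * s2)
                            - 0.5 * r ** 2 / s2)
        else:
            gp = GPMismatchModel(w=pd["w"], b=pd["b"],
                                 sigma_n2=pd["sigma_n2"])
            C = build_covariance(t_obs, gp)
            for vid in forward.vessels:
                r = data_by_id[vid].y - preds[vid]
                resid.append(r)
                rows.append(loglik_correlated_pointwise(
                    data_by_id[vid], preds[vid], C))
        pw = np.concatenate(rows)
        return float(pw.sum()), pw, np.concatenate(resid)

    def log_chi_prior(cj: float, m: float, s2: float) -> float:
        if cj <= 0:
            return -math.inf
        # truncated normal; the normalizer depends on (m, s2), which are
        # held fixed within each chi_j Metropolis step
        return -0.5 * (cj - m) ** 2 / s2

    ll, pw, resid = loglik(params_dict())
    if not np.isfinite(ll):
        raise ContractError("likelihood not finite at the initial state")

    names = [f"chi_{vid}" for vid in vessel_ids] + shared_spec.names + \
        ["m_chi", "sigma2_chi"]
    draws = np.empty((n_iter, len(names)))
    log_post = np.empty(n_iter)
    burn = int(burn_in_frac * n_iter)
    n_keep = max(n_iter - burn, 1)
    m_pw = min(n_pointwise, n_keep)
    pw_iters = np.unique(
        burn + np.floor(np.arange(m_pw) * n_keep / m_pw).astype(int))
    pw_set = set(pw_iters.tolist())
    pw_rows: list[np.ndarray] = []
    pw_kept: list[int] = []

    chi_scale = np.full(k, chi_prop_scale)
    sh_scale = shared_prop_scale
    chi_acc = np.zeros(k)
    sh_acc = 0
    acc_total = 0

    sigma2_idx = shared_spec.index("sigma2") if error_model == "iid" else -1

    for it in range(n_iter):
        # (i) conjugate m_chi update
        mean, var = _m_chi_conditional(chi, s2_chi, hp)
        m_chi = rng.normal(mean, math.sqrt(var))
        # (ii) conjugate sigma2_chi update
        if hp.fix_sigma2_chi is None:
            shape = hp.s2_shape + 0.5 * k
            rate = hp.s2_rate + 0.5 * float(np.sum((chi - m_chi) ** 2))
            s2_chi = rate / rng.gamma(shape, 1.0)
        # (iii) per-vessel chi Metropolis
        for j in range(k):
            prop = chi[j] * math.exp(chi_scale[j] * rng.standard_normal())
            pd = params_dict()
            pd[f"chi_{vessel_ids[j]}"] = prop
            lp_old = log_chi_prior(chi[j], m_chi, s2_chi)
            lp_new = log_chi_prior(prop, m_chi, s2_chi)
            if np.isfinite(lp_new):
                ll_new, pw_new, resid_new = loglik(pd)
            else:
                ll_new = -math.inf
            # log-scale proposal Jacobian: q(x->y)/q(y->x) = y/x
            ratio = (ll_new + lp_new) - (ll + lp_old) + \
                math.log(prop / chi[j])
            if math.log(rng.random()) < ratio:
                chi[j] = prop
                ll, pw, resid = ll_new, pw_new, resid_new
                chi_acc[j] += 1
                acc_total += 1
        # (iv) shared block Metropolis (+ conjugate sigma2 in the iid case)
        z = shared_spec.to_unconstrained(shared)
        zp = z + sh_scale * rng.standard_normal(n_shared)
        sh_prop = shared_spec.from_unconstrained(zp)
        lpr_new = shared_spec.log_prior_vec(sh_prop) + \
            shared_spec.log_jacobian(zp)
        lpr_old = shared_spec.log_prior_vec(shared) + \
            shared_spec.log_jacobian(z)
        pd = params_dict()
        pd.update(dict(zip(shared_spec.names, sh_prop)))
        ll_new, pw_new, resid_new = loglik(pd)
        if math.log(rng.random()) < (ll_new + lpr_new) - (ll + lpr_old):
            shared = sh_prop
            ll, pw, resid = ll_new, pw_new, resid_new
            sh_acc += 1
            acc_total += 1
        if error_model == "iid":
            pr = shared_spec["sigma2"]
            s2_draw = sigma2_gibbs(resid, pr.shape, pr.rate, rng)
            old = shared[sigma2_idx]
            shared[sigma2_idx] = s2_draw
            # rescale the cached iid log densities to the new variance
            n_all = resid.size
            ll = float(-0.5 * n_all * math.log(2 * math.pi * s2_draw)
                       - 0.5 * np.dot(resid, resid) / s2_draw)
            pw = -0.5 * np.log(2 * math.pi * s2_draw) - 0.5 * resid ** 2 / s2_draw
        # adaptation
        if it < burn and (it + 1) % adapt_every == 0:
            for j in range(k):
                rate_j = chi_acc[j] / adapt_every
                chi_scale[j] *= math.exp(0.5 * (rate_j - 0.44))
            sh_rate = sh_acc / adapt_every
            sh_scale *= math.exp(0.5 * (sh_rate - 0.25))
            chi_acc[:] = 0
            sh_acc = 0
        draws[it] = np.concatenate([chi, shared, [m_chi, s2_chi]])
        log_post[it] = ll
        if it in pw_set and pw is not None:
            pw_rows.append(pw.copy())
            pw_kept.append(it)

    return Chain(
        names=names,
        draws=draws,
        log_post=log_post,
        burn=burn,
        seed=seed,
        accept_rate=acc_total / (n_iter * (k + 1)),
        pointwise_loglik=np.vstack(pw_rows) if pw_rows else None,
        pointwise_iters=np.array(pw_kept) if pw_kept else None,
        meta={"n_iter": n_iter, "error_model": error_model,
              "hierarchical": True},
    )
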