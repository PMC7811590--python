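"""Experiment orchestration: the model catalogue A-I and end-to-end runs.

Each catalogue entry combines a wall law (linear/nonlinear), a stiffness
relation (constant, radius-dependent, or vessel-specific via the
hierarchical model) and an error model (iid or GP mismatch), mirroring the
models compared on the measured data.  ``run_experiment`` executes
inference, WAIC, convergence diagnostics and output-space bands, writing a
reproducible run directory; ``compare_models`` assembles the ranking table.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibrate import (
    CalibrationProblem,
    ForwardModel,
    default_eta_priors,
    default_theta_priors,
)
from .diagnostics import geweke, interval_bands, mpsrf, waic
from .error_models import TimeSeriesData
from .exceptions import ConfigurationError, ContractError
from .hierarchical import HierarchicalHyperprior, gibbs_hierarchical
from .inference import MCMCSettings, ParameterPrior, PriorSpec
from .network import VesselNetwork
from .synth import InflowSpec

__all__ = ["ModelSpec", "MODEL_CATALOGUE", "run_experiment", "compare_models"]

logger = logging.getLogger("pulmo_uq")


@dataclass(frozen=True)
class ModelSpec:
    """One entry of the model catalogue.

    ``abbreviation`` A-I selects wall kind, stiffness mode, mismatch flag
    and whether the emulator accelerates MCMC; custom combinations must be
    marked explicitly.  The nonlinear wall with vessel-specific stiffness
    is rejected (it would require vessel-specific (chi, gamma) pairs).
    """

    abbreviation: str
    wall_kind: str
    stiffness_mode: str
    mismatch: bool
    emulate: bool = False
    full_scale_iterations: int = 150_000
    custom: bool = False

    def __post_init__(self) -> None:
        if self.wall_kind == "nonlinear" and \
                self.stiffness_mode == "vessel_specific":
            raise ConfigurationError(
                "vessel-specific stiffness is not supported for the "
                "nonlinear wall (would need per-vessel (chi, gamma))"
            )
        if not self.custom:
            ref = MODEL_CATALOGUE.get(self.abbreviation)
            if ref is None or (
                ref.wall_kind, ref.stiffness_mode, ref.mismatch, ref.emulate
            ) != (self.wall_kind, self.stiffness_mode, self.mismatch,
                  self.emulate):
                raise ConfigurationError(
                    f"model {self.abbreviation!r} does not match the "
                    "catalogue; mark custom combinations with custom=True"
                )

    @property
    def error_model(self) -> str:
        return "gp_mismatch" if self.mismatch else "iid"


MODEL_CATALOGUE: dict[str, ModelSpec] = {}
for _ms in [
    ModelSpec("A", "linear", "constant", False, True, 5_000, custom=True),
    ModelSpec("B", "linear", "constant", True, True, 5_000, custom=True),
    ModelSpec("C", "linear", "constant", True, False, 150_000, custom=True),
    ModelSpec("D", "linear", "radius_dependent", False, False, 150_000,
              custom=True),
    ModelSpec("E", "linear", "radius_dependent", True, False, 150_000,
              custom=True),
    ModelSpec("F", "linear", "vessel_specific", False, False, 300_000,
              custom=True),
    ModelSpec("G", "linear", "vessel_specific", True, False, 300_000,
              custom=True),
    ModelSpec("H", "nonlinear", "constant", True, True, 5_000, custom=True),
    ModelSpec("I", "nonlinear", "radius_dependent", True, False, 150_000,
              custom=True),
]:
    MODEL_CATALOGUE[_ms.abbreviation] = _ms


def _spec_for(model: ModelSpec) -> PriorSpec | None:
    if model.stiffness_mode == "vessel_specific":
        return None
    return PriorSpec(
        default_theta_priors(model.wall_kind, model.stiffness_mode),
        default_eta_priors(model.error_model),
    )


def _data_hash(data: list[TimeSeriesData]) -> str:
    h = hashlib.sha256()
    for d in sorted(data, key=lambda s: s.vessel_id):
        h.update(np.int64(d.vessel_id).tobytes())
        h.update(np.ascontiguousarray(d.t).tobytes())
        h.update(np.ascontiguousarray(d.y).tobytes())
    return h.hexdigest()[:16]


def run_experiment(
    model: ModelSpec,
    network: VesselNetwork,
    data: list[TimeSeriesData],
    seed: int,
    out_dir: str | Path,
    n_iter: int | None = None,
    inflow: InflowSpec | None = None,
    dx: float = 0.05,
    n_emulator_design: int | None = None,
    settings: MCMCSettings | None = None,
) -> Path:
    """Run infer -> WAIC -> diagnostics -> bands for one catalogue model.

    Writes chain.csv(+json), waic.json, diagnostics.json, bands.csv and
    manifest.json into ``out_dir``; reruns with the same manifest inputs
    and seed are bit-reproducible.  A Geweke p <= 0.05 on any parameter or
    a split-chain MPSRF > 1.1 marks the run non-converged (outputs are
    still written).
    """
    t_start = time.time()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_iter = n_iter or model.full_scale_iterations
    vessels = sorted({d.vessel_id for d in data})
    fm = ForwardModel(
        network, vessels, wall_kind=model.wall_kind,
        stiffness_mode=model.stiffness_mode,
        inflow=inflow, dx=dx,
    )

    stage_times: dict[str, float] = {}
    t0 = time.time()
    if model.stiffness_mode == "vessel_specific":
        chain = gibbs_hierarchical(
            data, fm, n_iter, seed, HierarchicalHyperprior(),
            error_model=model.error_model,
        )
    else:
        prob = CalibrationProblem(fm, data, error_model=model.error_model,
                                  spec=_spec_for(model))
        if model.emulate:
            emu = prob.train_output_emulator(seed=seed,
                                             n_design=n_emulator_design)
            chain = prob.run_emulated(n_iter, seed, emulator=emu,
                                      settings=settings)
            # pointwise log-likelihood for WAIC from a posterior subsample
            post = chain.posterior
            idx = np.linspace(0, post.shape[0] - 1,
                              min(200, post.shape[0])).astype(int)
            rows = []
            for i in idx:
                _, pw = prob.log_posterior(post[i])
                if pw is not None:
                    rows.append(pw)
            chain.pointwise_loglik = np.vstack(rows) if rows else None
            chain.pointwise_iters = chain.burn + idx if rows else None
        else:
            chain = prob.run(n_iter, seed, settings=settings)
    stage_times["infer"] = time.time() - t0
    chain.save(out_dir / "chain.csv")

    t0 = time.time()
    if chain.pointwise_loglik is not None and \
            chain.pointwise_loglik.shape[0] >= 2:
        w = waic(chain.pointwise_loglik)
        waic_doc = {"lppd": w.lppd, "p_waic": w.p_waic, "waic": w.waic}
    else:
        waic_doc = {"lppd": None, "p_waic": None, "waic": None}
    with open(out_dir / "waic.json", "w") as fh:
        json.dump(waic_doc, fh, indent=1)
    stage_times["waic"] = time.time() - t0

    t0 = time.time()
    post = chain.posterior
    geweke_p = {}
    for j, name in enumerate(chain.names):
        try:
            _, p = geweke(post[:, j])
        except Exception:
            p = float("nan")
        geweke_p[name] = p
    half = post.shape[0] // 2
    keep = [j for j in range(post.shape[1])
            if np.std(post[:, j]) > 1e-12 * (1 + abs(np.mean(post[:, j])))]
    try:
        rhat = mpsrf(np.stack([post[:half, keep], post[half:2 * half, keep]]))
    except Exception:
        rhat = float("nan")
    converged = bool(
        all(not (p == p and p <= 0.05) for p in geweke_p.values())
        and (rhat == rhat and rhat <= 1.1)
    )
    diag_doc = {"geweke_p": geweke_p, "mpsrf_split": rhat,
                "converged": converged}
    with open(out_dir / "diagnostics.json", "w") as fh:
        json.dump(diag_doc, fh, indent=1)
    if not converged:
        logger.warning("run %s marked non-converged", out_dir)
    stage_times["diagnose"] = time.time() - t0

    t0 = time.time()
    mpa = min(vessels)
    mpa_data = next(d for d in data if d.vessel_id == mpa)
    t_star = mpa_data.t

    def simulator(x: np.ndarray) -> np.ndarray:
        params = dict(zip(chain.names, x))
        return fm.predict(params, t_star)[mpa]

    band = interval_bands(
        chain, simulator, t_star,
        error_model="gp_mismatch" if model.mismatch else "iid",
        data=mpa_data if model.mismatch else None,
        n_draws=100, seed=seed,
    )
    band.save(out_dir / "bands.csv")
    stage_times["bands"] = time.time() - t0

    # Euclidean distance (residual norm) at the posterior median
    med = chain.median()
    preds = fm.predict(dict(zip(chain.names, med)), t_star)
    euclid = float(sum(
        np.sum((d.y - preds[d.vessel_id]) ** 2) for d in data
    ))

    manifest = {
        "model": asdict(model),
        "seed": seed,
        "n_iter": n_iter,
        "vessels": vessels,
        "data_hash": _data_hash(data),
        "version": __version__,
        "accept_rate": chain.accept_rate,
        "waic": waic_doc["waic"],
        "euclidean_distance": euclid,
        "posterior_median": dict(zip(chain.names, map(float, med))),
        "converged": converged,
        "stage_seconds": {k: round(v, 3) for k, v in stage_times.items()},
        "total_seconds": round(time.time() - t_start, 3),
    }
    config_blob = json.dumps(
        {k: manifest[k] for k in ("model", "seed", "n_iter", "vessels",
                                  "data_hash", "version")},
        sort_keys=True,
    )
    manifest["config_hash"] = hashlib.sha256(
        config_blob.encode()).hexdigest()[:16]
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    logger.info("experiment %s finished in %.1fs",
                model.abbreviation, manifest["total_seconds"])
    return out_dir


def compare_models(run_dirs: list[str | Path]) -> pd.DataFrame:
    """Ranking table over completed runs on identical data.

    Sorted by WAIC (lower is better) with lexicographic tie-break on the
    model abbreviation; includes the Euclidean distance at the posterior
    median and parameter medians.
    """
    if not run_dirs:
        raise ContractError("need at least one run directory")
    rows = []
    hashes = set()
    for rd in run_dirs:
        rd = Path(rd)
        with open(rd / "manifest.json") as fh:
            man = json.load(fh)
        hashes.add(man["data_hash"])
        rows.append({
            "model": man["model"]["abbreviation"],
            "mismatch": man["model"]["mismatch"],
            "waic": man["waic"],
            "euclidean_distance": man["euclidean_distance"],
            "converged": man["converged"],
            "run_dir": str(rd),
            **{f"median_{k}": v for k, v in man["posterior_median"].items()},
        })
    if len(hashes) > 1:
        raise ContractError(
            "runs were made on different data; cannot rank them together"
        )
    frame = pd.DataFrame(rows)
    frame = frame.sort_values(
        ["waic", "model"], na_position="last"
    ).reset_index(drop=True)
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    return frame


def load_config(path: str | Path) -> dict:
    """Load a YAML experiment configuration."""
    with open(path) as fh:
        return yaml.safe_load(fh)
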