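"""Hierarchical vessel-specific stiffness: conjugate updates and limits."""

import math

import numpy as np
import pytest

from pulmo_uq.error_models import TimeSeriesData
from pulmo_uq.hierarchical import (
    HierarchicalHyperprior,
    _m_chi_conditional,
    gibbs_hierarchical,
)


class FakeVessel:
    def __init__(self, vid):
        self.id = vid


class FakeNetwork:
    def __init__(self, ids):
        self.vessels = [FakeVessel(i) for i in ids]


class FakeForward:
    """Frozen forward model: analytic map from stiffness to 'pressure'.

    ``gains[vid]`` scales how strongly vessel vid's data constrain its
    stiffness; gain 0 makes the likelihood flat in that stiffness.
    """

    stiffness_mode = "vessel_specific"

    def __init__(self, ids, t, gains=None, base=15.0):
        self.network = FakeNetwork(ids)
        self.vessels = list(ids)
        self.t = t
        self.gains = gains or {i: 0.0 for i in ids}
        self.base = base

    def predict(self, params, t_obs):
        out = {}
        for vid in self.vessels:
            chi = params[f"chi_{vid}"]
            out[vid] = np.full(
                t_obs.size,
                self.base + self.gains[vid] * (chi - 5.0e4) / 1.0e4,
            )
        return out


def _flat_data(ids, t, value=15.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    return [
        TimeSeriesData(t=t, y=value + noise * rng.standard_normal(t.size),
                       vessel_id=vid)
        for vid in ids
    ]


class TestConjugateConditionals:
    def test_flat_prior_population_mean(self):
        chi = np.array([4.0e4, 5.0e4, 6.6e4])
        s2 = 2.0e8
        hp = HierarchicalHyperprior(m_sd=None)
        mean, var = _m_chi_conditional(chi, s2, hp)
        assert mean == pytest.approx(chi.mean(), rel=1e-12)
        assert var == pytest.approx(s2 / 3, rel=1e-12)

    def test_informative_prior_shrinks_toward_hypermean(self):
        chi = np.full(4, 9.0e4)
        hp = HierarchicalHyperprior()
        mean, var = _m_chi_conditional(chi, 1.0e8, hp)
        assert hp.m_mean < mean < 9.0e4
        assert var < 1.0e8 / 4

    def test_prior_predictive_mass_on_printed_range(self):
        # ~90% prior probability on (2, 10) x 10^4 (Monte-Carlo check)
        hp = HierarchicalHyperprior()
        rng = np.random.default_rng(0)
        n = 400_000
        m = rng.normal(hp.m_mean, hp.m_sd, n)
        s2 = hp.s2_rate / rng.gamma(hp.s2_shape, 1.0, n)
        chi = rng.normal(m, np.sqrt(s2))
        chi = chi[chi > 0]
        mass = np.mean((chi > 2e4) & (chi < 1e5))
        assert mass == pytest.approx(0.90, abs=0.02)


class TestGibbsStationaryLaws:
    def test_flat_likelihood_recovers_prior_predictive(self):
        """With a likelihood flat in chi, the chi marginal must equal the
        population prior predictive (validates all conjugate updates plus
        the chi Metropolis step jointly)."""
        t = np.linspace(0, 0.1, 8)
        ids = [1, 2, 3]
        fm = FakeForward(ids, t)
        data = _flat_data(ids, t, noise=0.05, seed=1)
        chain = gibbs_hierarchical(data, fm, 6000, seed=2,
                                   error_model="iid")
        chi = np.concatenate([chain.param(f"chi_{i}") for i in ids])
        hp = HierarchicalHyperprior()
        rng = np.random.default_rng(3)
        m = rng.normal(hp.m_mean, hp.m_sd, chi.size)
        s2 = hp.s2_rate / rng.gamma(hp.s2_shape, 1.0, chi.size)
        ref = rng.normal(m, np.sqrt(s2))
        ref = ref[ref > 0]
        edges = np.linspace(0, 2e5, 41)
        a, _ = np.histogram(chi, bins=edges, density=False)
        b, _ = np.histogram(ref, bins=edges, density=False)
        tv = 0.5 * np.abs(a / a.sum() - b / b.sum()).sum()
        assert tv < 0.08

    def test_informative_likelihood_grid_oracle(self):
        """Single-vessel chi posterior against numeric-integration oracle.

        With the iid sigma^2 integrated out analytically the marginal is
        p(chi) ~ N(chi; m0, s2_0) (b + SSR(chi)/2)^-(a + n/2) on a grid.
        """
        t = np.linspace(0, 0.1, 16)
        gain = 3.0
        fm = FakeForward([1], t, gains={1: gain})
        truth_chi = 5.6e4
        rng = np.random.default_rng(4)
        y = 15.0 + gain * (truth_chi - 5.0e4) / 1.0e4 \
            + 0.3 * rng.standard_normal(t.size)
        data = [TimeSeriesData(t=t, y=y, vessel_id=1)]
        s2_0 = 1.0e8
        hp = HierarchicalHyperprior(m_sd=1e-6, fix_sigma2_chi=s2_0)
        chain = gibbs_hierarchical(data, fm, 20_000, seed=5,
                                   hyperprior=hp, error_model="iid",
                                   chi_prop_scale=0.1)
        chi = chain.param("chi_1")
        # oracle on a grid
        grid = np.linspace(1e4, 1.2e5, 800)
        a = b = 0.001
        n = t.size
        ssr = np.array([
            np.sum((y - (15.0 + gain * (g - 5.0e4) / 1.0e4)) ** 2)
            for g in grid
        ])
        logp = -0.5 * (grid - hp.m_mean) ** 2 / s2_0 \
            - (a + n / 2) * np.log(b + ssr / 2)
        p = np.exp(logp - logp.max())
        p /= p.sum()
        edges = np.linspace(1e4, 1.2e5, 41)
        emp, _ = np.histogram(chi, bins=edges)
        emp = emp / emp.sum()
        ref = np.array([
            p[(grid >= lo) & (grid < hi)].sum()
            for lo, hi in zip(edges[:-1], edges[1:])
        ])
        tv = 0.5 * np.abs(emp - ref).sum()
        assert tv < 0.05

    def test_vanishing_population_variance_collapses_chi(self):
        t = np.linspace(0, 0.1, 8)
        ids = [1, 2, 3]
        fm = FakeForward(ids, t)
        data = _flat_data(ids, t, noise=0.05, seed=6)
        hp = HierarchicalHyperprior(fix_sigma2_chi=1.0)   # ~delta population
        chain = gibbs_hierarchical(data, fm, 3000, seed=7,
                                   hyperprior=hp, error_model="iid")
        post = chain.posterior
        m = chain.param("m_chi")
        for vid in ids:
            spread = np.std(chain.param(f"chi_{vid}") - m)
            assert spread < 10.0   # vs population scale ~1e4

    def test_shrinkage_versus_decoupled_limit(self):
        """Common-truth data: the hierarchical posterior spread of the
        stiffness parameters is smaller than in the near-independent limit
        (huge fixed population variance)."""
        t = np.linspace(0, 0.1, 16)
        ids = [1, 2, 3]
        gains = {1: 2.0, 2: 2.0, 3: 2.0}
        fm1 = FakeForward(ids, t, gains=gains)
        fm2 = FakeForward(ids, t, gains=gains)
        rng = np.random.default_rng(8)
        data = [
            TimeSeriesData(t=t, y=15.0 + 0.4 * rng.standard_normal(t.size),
                           vessel_id=vid)
            for vid in ids
        ]
        hier = gibbs_hierarchical(data, fm1, 8000, seed=9,
                                  error_model="iid")
        indep = gibbs_hierarchical(
            data, fm2, 8000, seed=9,
            hyperprior=HierarchicalHyperprior(fix_sigma2_chi=1.0e12),
            error_model="iid",
        )
        spread_h = np.mean([np.std(hier.param(f"chi_{i}")) for i in ids])
        spread_i = np.mean([np.std(indep.param(f"chi_{i}")) for i in ids])
        assert spread_h < spread_i


class TestGibbsOnPDE:
    def test_desk_run_recovers_common_stiffness(self, tree3):
        """3-vessel PDE run with constant-stiffness data: posterior chi
        medians are approximately equal across vessels and physiological."""
        from pulmo_uq.calibrate import ForwardModel
        from pulmo_uq.network import ScalingFactors
        from pulmo_uq.pde import WallModel
        from pulmo_uq.synth import MODEL_E_TRUTH, generate_dataset

        wall = WallModel(kind="linear", stiffness_mode="constant",
                         f1=0.0, f3=5.0e4)
        ds = generate_dataset(
            network=tree3, wall=wall,
            scalings=ScalingFactors(0.29, 0.87, 1.34),
            vessels=[1, 2, 3], n_instantiations=1, seed=11, n_obs=48,
            truth={**MODEL_E_TRUTH, "f1": 0.0, "f2": 0.0, "f3": 5.0e4},
        )
        data = [ds.instantiations[0][v] for v in [1, 2, 3]]
        fm = ForwardModel(tree3, [1, 2, 3],
                          stiffness_mode="vessel_specific")
        init = {f"chi_{v}": 5.0e4 for v in [1, 2, 3]}
        init.update(psi1=0.29, psi2=0.87, c=1.34)
        chain = gibbs_hierarchical(data, fm, 500, seed=12,
                                   error_model="iid", init=init,
                                   chi_prop_scale=0.02)
        meds = [np.median(chain.param(f"chi_{v}")) for v in [1, 2, 3]]
        for m in meds:
            assert 2.0e4 < m < 1.0e5
        assert max(meds) / min(meds) < 2.0
        assert np.all(np.isfinite(chain.log_post))
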