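"""Shared fixtures: small vessel networks and inflow waveforms."""

import math

import numpy as np
import pytest

from pulmo_uq.constants import PhysicalConstants
from pulmo_uq.network import (
    ScalingFactors,
    Vessel,
    VesselNetwork,
    apply_scalings,
    generate_tree,
    nominal_windkessel,
)
from pulmo_uq.synth import DEFAULT_INFLOW, InflowSpec, synthetic_inflow


@pytest.fixture(scope="session")
def constants():
    return PhysicalConstants()


@pytest.fixture(scope="session")
def single_vessel():
    return VesselNetwork([Vessel(1, None, 1.0, 0.047, True)])


@pytest.fixture(scope="session")
def tree3():
    """Smallest bifurcation: MPA plus two daughters."""
    return generate_tree(2, root_radius=0.047, seed=1)


@pytest.fixture(scope="session")
def tree21():
    """Reference-scale 21-vessel stand-in tree (11 terminals)."""
    return generate_tree(11, root_radius=0.047, seed=1)


@pytest.fixture(scope="session")
def mouse_inflow():
    """Default parametric mouse inflow, one period on 256 points."""
    return synthetic_inflow(DEFAULT_INFLOW, 256)


@pytest.fixture(scope="session")
def smooth_inflow(constants):
    """Infinitely differentiable waveform for convergence studies."""
    T = constants.T
    t = np.linspace(0, T, 1024, endpoint=False)
    q = 0.24 * (1 + 0.8 * np.sin(2 * np.pi * t / T)
                + 0.3 * np.cos(4 * np.pi * t / T))
    return t, q


def scaled_windkessel(network, mean_flow, scalings=ScalingFactors(0.29, 0.87, 1.34)):
    return apply_scalings(
        nominal_windkessel(network, mean_flow, 17.0), scalings
    )


@pytest.fixture(scope="session")
def wk3(tree3):
    return scaled_windkessel(tree3, DEFAULT_INFLOW.mean_flow)


@pytest.fixture(scope="session")
def wk21(tree21):
    return scaled_windkessel(tree21, DEFAULT_INFLOW.mean_flow)
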