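"""Vessel network representation, I/O, synthesis and nominal Windkessels."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulmo_uq.constants import PhysicalConstants
from pulmo_uq.exceptions import (
    ConfigurationError,
    DomainError,
    NetworkParseError,
    NetworkValidationError,
)
from pulmo_uq.network import (
    NominalWindkessel,
    ScalingFactors,
    Vessel,
    VesselNetwork,
    apply_scalings,
    generate_tree,
    nominal_windkessel,
    poiseuille_resistance,
    read_network,
    write_network,
)


def test_vessel_area_identity():
    v = Vessel(1, None, 0.5, 0.047, True)
    assert v.A0 == pytest.approx(math.pi * 0.047 ** 2, rel=1e-12)


@pytest.mark.parametrize("bad", [
    dict(L=-1.0, r0=0.05),
    dict(L=0.5, r0=0.0),
])
def test_vessel_geometry_must_be_positive(bad):
    with pytest.raises(NetworkValidationError):
        Vessel(1, None, bad["L"], bad["r0"], True)


class TestTopologyValidation:
    def test_smallest_bifurcation(self):
        net = VesselNetwork([
            Vessel(1, None, 0.5, 0.05, False),
            Vessel(2, 1, 0.4, 0.04, True),
            Vessel(3, 1, 0.4, 0.04, True),
        ])
        assert len(net.junctions) == 1
        assert net.n_terminal == 2
        assert net.junctions[0] == (1, 2, 3)

    def test_nonexistent_parent_rejected(self):
        with pytest.raises(NetworkValidationError, match="nonexistent parent"):
            VesselNetwork([
                Vessel(1, None, 0.5, 0.05, False),
                Vessel(2, 1, 0.4, 0.04, True),
                Vessel(3, 9, 0.4, 0.04, True),
            ])

    def test_single_child_rejected(self):
        with pytest.raises(NetworkValidationError, match="exactly 2"):
            VesselNetwork([
                Vessel(1, None, 0.5, 0.05, False),
                Vessel(2, 1, 0.4, 0.04, True),
            ])

    def test_multiple_roots_rejected(self):
        with pytest.raises(NetworkValidationError, match="exactly one root"):
            VesselNetwork([
                Vessel(1, None, 0.5, 0.05, True),
                Vessel(2, None, 0.4, 0.04, True),
            ])

    def test_terminal_flag_consistency(self):
        with pytest.raises(NetworkValidationError, match="terminal"):
            VesselNetwork([
                Vessel(1, None, 0.5, 0.05, True),
                Vessel(2, 1, 0.4, 0.04, True),
                Vessel(3, 1, 0.4, 0.04, True),
            ])


class TestIO:
    @pytest.mark.parametrize("suffix", [".csv", ".json"])
    def test_round_trip_lossless(self, tmp_path, suffix):
        net = generate_tree(5, seed=3)
        path = tmp_path / f"net{suffix}"
        write_network(net, path)
        back = read_network(path)
        assert len(back) == len(net)
        for a, b in zip(net.vessels, back.vessels):
            assert a.id == b.id and a.parent_id == b.parent_id
            assert a.terminal == b.terminal
            assert b.L == pytest.approx(a.L, rel=1e-12)
            assert b.r0 == pytest.approx(a.r0, rel=1e-12)

    def test_reference_scale_network_counts(self, tmp_path, tree21):
        path = tmp_path / "net.csv"
        write_network(tree21, path)
        net = read_network(path)
        assert len(net) == 21
        assert net.n_terminal == 11
        assert len(net) - net.n_terminal == 10

    def test_bad_parent_in_file(self, tmp_path):
        path = tmp_path / "net.csv"
        path.write_text(
            "id,parent_id,length_cm,r0_cm,terminal\n"
            "1,,0.5,0.05,False\n2,1,0.4,0.04,True\n3,7,0.4,0.04,True\n"
        )
        with pytest.raises(NetworkValidationError):
            read_network(path)

    def test_malformed_record_names_location(self, tmp_path):
        path = tmp_path / "net.csv"
        path.write_text(
            "id,parent_id,length_cm,r0_cm,terminal\n"
            "1,,abc,0.05,False\n"
        )
        with pytest.raises(NetworkParseError, match="row 2"):
            read_network(path)

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            read_network("no_such_file.csv")


class TestGenerateTree:
    @settings(max_examples=20, deadline=None)
    @given(n=st.integers(min_value=2, max_value=24))
    def test_full_binary_tree_identity(self, n):
        net = generate_tree(n, seed=0)
        assert len(net) == 2 * n - 1
        assert net.n_terminal == n

    def test_deterministic_given_seed(self):
        a = generate_tree(11, seed=4)
        b = generate_tree(11, seed=4)
        assert a.vessels == b.vessels
        c = generate_tree(11, seed=5)
        assert a.vessels != c.vessels

    def test_daughters_smaller_than_parent(self):
        net = generate_tree(8, seed=2)
        for parent, child in net.edges():
            assert net[child].r0 < net[parent].r0

    @pytest.mark.parametrize("kwargs", [
        dict(n_terminal=1),
        dict(n_terminal=4, radius_ratio=1.5),
        dict(n_terminal=4, length_radius_ratio=-1.0),
    ])
    def test_domain_errors(self, kwargs):
        with pytest.raises(DomainError):
            generate_tree(**kwargs)


class TestNominalWindkessel:
    def test_single_outlet_limit(self):
        # one wide, short vessel: Poiseuille path resistance is negligible
        net = VesselNetwork([Vessel(1, None, 0.1, 0.2, True)])
        wk = nominal_windkessel(net, mean_flow=0.5, mean_pressure=15.0)
        R = 1333.22 * 15.0 / 0.5
        assert wk.R1[0] + wk.R2[0] == pytest.approx(R, rel=1e-3)
        # and exactly R minus the vessel's own Poiseuille resistance
        assert wk.R1[0] + wk.R2[0] == pytest.approx(
            R - poiseuille_resistance(0.1, 0.2, PhysicalConstants().mu),
            rel=1e-12)
        assert wk.R1[0] / (wk.R1[0] + wk.R2[0]) == pytest.approx(0.2)
        assert wk.C[0] == pytest.approx(0.025 / wk.R2[0])

    def test_symmetric_terminals_get_identical_triples(self):
        net = VesselNetwork([
            Vessel(1, None, 0.5, 0.05, False),
            Vessel(2, 1, 0.4, 0.04, True),
            Vessel(3, 1, 0.4, 0.04, True),
        ])
        wk = nominal_windkessel(net, 0.25, 14.0)
        assert wk.R1[0] == pytest.approx(wk.R1[1], rel=1e-12)
        assert wk.R2[0] == pytest.approx(wk.R2[1], rel=1e-12)
        assert wk.C[0] == pytest.approx(wk.C[1], rel=1e-12)

    def test_conductance_bookkeeping_oracle(self, tree21):
        """Independent path enumeration reproduces mean_flow/(P conv)."""
        blood = PhysicalConstants()
        Q, P = 0.24, 17.0
        wk = nominal_windkessel(tree21, Q, P, blood=blood)
        # brute-force series/parallel reduction over root-to-leaf branches
        total_conductance = 0.0
        for k, tid in enumerate(wk.terminal_ids):
            path = 0.0
            node = tree21[tid]
            while node is not None:
                path += poiseuille_resistance(node.L, node.r0, blood.mu)
                node = tree21[node.parent_id] \
                    if node.parent_id is not None else None
            total_conductance += 1.0 / (wk.R1[k] + wk.R2[k] + path)
        assert total_conductance == pytest.approx(
            Q / (P * blood.conv), rel=1e-8)

    def test_small_network_brute_force(self, tree3):
        wk = nominal_windkessel(tree3, 0.24, 17.0)
        blood = PhysicalConstants()
        g = 0.0
        for k, tid in enumerate(wk.terminal_ids):
            path = sum(
                poiseuille_resistance(tree3[i].L, tree3[i].r0, blood.mu)
                for i in tree3.path_to_root(tid)
            )
            g += 1.0 / (wk.R1[k] + wk.R2[k] + path)
        assert g == pytest.approx(0.24 / (17.0 * blood.conv), rel=1e-8)

    def test_infeasible_target_raises(self):
        # microscopic radius: the path resistance alone exceeds the target
        net = VesselNetwork([Vessel(1, None, 1.0, 0.003, True)])
        with pytest.raises(ConfigurationError, match="Poiseuille"):
            nominal_windkessel(net, mean_flow=5.0, mean_pressure=1.0)


class TestApplyScalings:
    def test_identity(self):
        nom = NominalWindkessel([1, 2], [1e4, 2e4], [4e4, 5e4], [1e-6, 2e-6])
        out = apply_scalings(nom, ScalingFactors(1.0, 1.0, 1.0))
        np.testing.assert_allclose(out.R1, nom.R1)
        np.testing.assert_allclose(out.R2, nom.R2)
        np.testing.assert_allclose(out.C, nom.C)

    def test_posterior_median_scalings_on_unit_nominal(self):
        nom = NominalWindkessel([1], [1.0], [1.0], [1.0])
        out = apply_scalings(nom, ScalingFactors(0.21, 0.88, 1.44))
        assert (out.R1[0], out.R2[0], out.C[0]) == (0.21, 0.88, 1.44)

    def test_linearity_in_each_factor(self):
        nom = NominalWindkessel([1, 2], [1e4, 2e4], [4e4, 5e4], [1e-6, 2e-6])
        a = apply_scalings(nom, ScalingFactors(0.5, 0.6, 0.7))
        b = apply_scalings(nom, ScalingFactors(0.5, 1.2, 0.7))
        np.testing.assert_allclose(b.R2, 2.0 * a.R2, rtol=1e-12)
        np.testing.assert_allclose(b.R1, a.R1, rtol=1e-12)

    def test_out_of_bounds_factor_rejected(self):
        with pytest.raises(DomainError):
            ScalingFactors(3.0, 1.0, 1.0)
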