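"""Darcy elements and the hydraulic-resistance network solver."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import organostack.darcy_network as dn
from organostack.synthetic_data import gen_circuit

from conftest import dense_solve_oracle


def element(**kw):
    base = dict(length=340e-6, area=1e-4, permeability=1e-12,
                fluid_viscosity=1e-3)
    base.update(kw)
    return dn.PorousElement(**base)


class TestElementResistance:
    def test_mu_l_over_k_a(self):
        assert dn.element_resistance(element()) == pytest.approx(3.4e9)

    def test_proportionalities(self):
        r = dn.element_resistance(element())
        assert dn.element_resistance(element(length=680e-6)) == pytest.approx(2 * r)
        assert dn.element_resistance(element(area=2e-4)) == pytest.approx(r / 2)

    def test_series_doubles_pressure_drop_at_equal_flow(self):
        r = dn.element_resistance(element())
        q = 1e-10
        assert 2 * r * q == pytest.approx(2 * (r * q))

    def test_invalid_element(self):
        with pytest.raises(dn.InvalidElementError):
            dn.element_resistance(element(permeability=-1.0))


class TestCombinators:
    def test_singletons(self):
        assert dn.combine_series([7.0]) == 7.0
        assert dn.combine_parallel([7.0]) == 7.0

    def test_two_equal_parallel_halves(self):
        assert dn.combine_parallel([4.0, 4.0]) == pytest.approx(2.0)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            dn.combine_series([])
        with pytest.raises(ValueError):
            dn.combine_parallel([])

    def test_mixed_ladder_matches_network_solve(self):
        # R1 in series with (R2 || R3): closed form vs Kirchhoff solve
        r1, r2, r3 = 2.0, 3.0, 6.0
        r_eq = dn.combine_series([r1, dn.combine_parallel([r2, r3])])
        net = dn.HydraulicNetwork(pressures={"in": 1.0, "out": 0.0})
        net.add_edge("in", "mid", r1)
        net.add_edge("mid", "out", r2)
        net.add_edge("mid", "out", r3)
        sol = dn.solve_network(net)
        assert sol.boundary_throughflow() == pytest.approx(1.0 / r_eq)


class TestSolveNetwork:
    def test_single_edge_ohm(self):
        net = dn.HydraulicNetwork(pressures={"a": 3.0, "b": 0.0})
        net.add_edge("a", "b", 1.5)
        sol = dn.solve_network(net)
        assert sol.edge_flows[0] == pytest.approx(2.0)

    def test_parallel_split_inverse_to_resistance(self):
        net = dn.HydraulicNetwork(pressures={"a": 1.0, "b": 0.0})
        net.add_edge("a", "b", 1.0)
        net.add_edge("a", "b", 4.0)
        sol = dn.solve_network(net)
        assert sol.edge_flows[0] == pytest.approx(4.0 * sol.edge_flows[1])

    def test_random_networks_match_dense_oracle(self):
        rng = np.random.default_rng(42)
        for trial in range(10):
            n_nodes = int(rng.integers(3, 9))
            nodes = [f"n{i}" for i in range(n_nodes)]
            edges = []
            # random spanning tree plus extra chords keeps it connected
            for i in range(1, n_nodes):
                j = int(rng.integers(0, i))
                edges.append((nodes[i], nodes[j],
                              float(rng.uniform(0.5, 5.0))))
            for _ in range(int(rng.integers(0, 6))):
                i, j = rng.choice(n_nodes, size=2, replace=False)
                edges.append((nodes[int(i)], nodes[int(j)],
                              float(rng.uniform(0.5, 5.0))))
            pressures = {nodes[0]: float(rng.uniform(1, 10)), nodes[-1]: 0.0}
            inflows = {}
            if n_nodes > 3:
                inflows[nodes[1]] = float(rng.uniform(0, 1))
            net = dn.HydraulicNetwork(
                edges=[dn.Edge(a, b, r) for a, b, r in edges],
                pressures=pressures, inflows=inflows)
            sol = dn.solve_network(net)
            p_oracle, q_oracle = dense_solve_oracle(edges, pressures, inflows)
            for node, p in sol.node_pressures.items():
                assert p == pytest.approx(p_oracle[node], abs=1e-9)
            np.testing.assert_allclose(sol.edge_flows, q_oracle, atol=1e-9)

    def test_no_fixed_pressure_rejected(self):
        net = dn.HydraulicNetwork(inflows={"a": 1.0})
        net.add_edge("a", "b", 1.0)
        with pytest.raises(dn.SingularNetworkError):
            dn.solve_network(net)

    def test_floating_component_named(self):
        net = dn.HydraulicNetwork(pressures={"a": 1.0})
        net.add_edge("a", "b", 1.0)
        net.add_edge("c", "d", 1.0)  # disconnected island
        with pytest.raises(dn.SingularNetworkError, match="c.*d"):
            dn.solve_network(net)

    def test_reciprocity_swapping_boundaries_negates_flows(self):
        edges = [("a", "m", 1.0), ("m", "b", 2.0), ("a", "b", 3.0)]
        net1 = dn.HydraulicNetwork(
            edges=[dn.Edge(*e) for e in edges],
            pressures={"a": 5.0, "b": 1.0})
        net2 = dn.HydraulicNetwork(
            edges=[dn.Edge(*e) for e in edges],
            pressures={"a": 1.0, "b": 5.0})
        q1 = dn.solve_network(net1).edge_flows
        q2 = dn.solve_network(net2).edge_flows
        np.testing.assert_allclose(q1, -q2, atol=1e-12)

    @given(n=st.integers(1, 10), seed=st.integers(0, 100))
    def test_chain_and_fan_agree_with_combinators(self, n, seed):
        rng = np.random.default_rng(seed)
        rs = rng.uniform(0.5, 4.0, n)
        # chain
        chain = dn.HydraulicNetwork(pressures={"n0": 1.0, f"n{n}": 0.0})
        for i, r in enumerate(rs):
            chain.add_edge(f"n{i}", f"n{i + 1}", float(r))
        q_chain = dn.solve_network(chain).boundary_throughflow()
        assert q_chain == pytest.approx(1.0 / dn.combine_series(rs))
        # fan
        fan = dn.HydraulicNetwork(pressures={"a": 1.0, "b": 0.0})
        for r in rs:
            fan.add_edge("a", "b", float(r))
        q_fan = dn.solve_network(fan).boundary_throughflow()
        assert q_fan == pytest.approx(1.0 / dn.combine_parallel(rs))

    @given(seed=st.integers(0, 50))
    def test_lowering_any_resistance_never_lowers_throughflow(self, seed):
        rng = np.random.default_rng(seed)
        edges = [("a", "m", float(rng.uniform(1, 5))),
                 ("m", "b", float(rng.uniform(1, 5))),
                 ("a", "b", float(rng.uniform(1, 5))),
                 ("m", "b", float(rng.uniform(1, 5)))]
        base = dn.HydraulicNetwork(
            edges=[dn.Edge(a, b, r, label=str(i))
                   for i, (a, b, r) in enumerate(edges)],
            pressures={"a": 1.0, "b": 0.0})
        q0 = dn.solve_network(base).boundary_throughflow()
        for i, (_, _, r) in enumerate(edges):
            faster = base.with_resistance(str(i), r / 2)
            assert dn.solve_network(faster).boundary_throughflow() >= q0 - 1e-12


class TestFlowPartition:
    def test_infinite_bypass_gives_all_wanted(self):
        net = dn.HydraulicNetwork(pressures={"a": 1.0, "b": 0.0})
        net.add_edge("a", "b", 1.0, "module", wanted=True)
        net.add_edge("a", "b", 1e15, "bypass")
        part = dn.flow_partition(dn.solve_network(net))
        assert part["wanted_fraction"] == pytest.approx(1.0, abs=1e-12)

    def test_equal_resistances_split_evenly(self):
        net = dn.HydraulicNetwork(pressures={"a": 1.0, "b": 0.0})
        net.add_edge("a", "b", 2.0, "module", wanted=True)
        net.add_edge("a", "b", 2.0, "bypass")
        part = dn.flow_partition(dn.solve_network(net))
        assert part["wanted_fraction"] == pytest.approx(0.5)
        assert part["wasteful_fraction"] == pytest.approx(0.5)

    def test_central_hole_carries_more_than_edges(self):
        # regulated inputs feed a stack over a spacer with a central hole:
        # the low-resistance center path dominates the edge bypass
        circuit = gen_circuit("fig7_cross")
        net = circuit.network
        net.pressures = {f"A{i}": 10.0 for i in range(1, 5)}
        net.pressures["B"] = 0.0
        sol = dn.solve_network(net)
        table = sol.edge_table.set_index("edge")
        assert (table.loc["center_hole", "Q_m3_per_s"]
                > table.loc["edge_bypass", "Q_m3_per_s"] > 0)
        part = dn.flow_partition(sol)
        assert part["wanted_fraction"] > 0.5

    def test_no_wanted_edge_warns(self):
        net = dn.HydraulicNetwork(pressures={"a": 1.0, "b": 0.0})
        net.add_edge("a", "b", 1.0)
        with pytest.warns(UserWarning, match="wanted"):
            part = dn.flow_partition(dn.solve_network(net))
        assert part["wanted_fraction"] == 0.0


class TestRegulatorSwap:
    def make_net(self, r_reg, r_rest):
        net = dn.HydraulicNetwork(pressures={"a": 1.0, "b": 0.0})
        net.add_edge("a", "m", r_reg, "regulator")
        net.add_edge("m", "b", r_rest, "stack")
        return net

    def test_identical_swap_is_unity(self):
        net = self.make_net(3.0, 1.0)
        assert dn.regulator_swap_ratio(net, "regulator", 3.0) == pytest.approx(1.0)

    def test_dominant_regulator_three_fold(self):
        # swapping a dominant regulator for one with a third the resistance
        # speeds flow ~3x
        net = self.make_net(3e6, 1.0)
        ratio = dn.regulator_swap_ratio(net, "regulator", 1e6)
        assert ratio == pytest.approx(3.0, rel=1e-4)

    def test_non_dominant_regulator_bounded(self):
        net = self.make_net(3.0, 2.0)
        ratio = dn.regulator_swap_ratio(net, "regulator", 1.0)
        assert 1.0 < ratio < 3.0
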