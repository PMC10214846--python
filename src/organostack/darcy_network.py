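"""Lumped hydraulic-resistance model of stacked-module circuits.

Flow through a porous module obeys Darcy's law, ``dP = Q * mu*L/(k*A)``, so
``R_hyd = mu*L/(k*A)`` plays the role of an electrical resistance and whole
circuits compose like resistor networks: modules in a stack add in series,
and seepage around modules or up stack sides appears as explicit parallel
bypass edges.  A circuit is solved by nodal analysis (Kirchhoff current law
at every free node), exactly as one solves a DC resistor network.

This is deliberately a lumped 1-D approximation: fluid walls morph during
flow and a rigorous treatment would need continuum Darcy boundary
conditions.  Bypass paths are user-declared edges with user resistances;
nothing is inferred from geometry.

Edge flow sign convention: positive flow runs from ``node_a`` to ``node_b``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "InvalidElementError",
    "SingularNetworkError",
    "PorousElement",
    "Edge",
    "HydraulicNetwork",
    "NetworkSolution",
    "element_resistance",
    "combine_series",
    "combine_parallel",
    "solve_network",
    "flow_partition",
    "regulator_swap_ratio",
]

#: interior-node mass balance must close to this relative tolerance
CONSERVATION_RTOL = 1e-9


class InvalidElementError(ValueError):
    """A porous element has a non-positive dimension or property."""


class SingularNetworkError(ValueError):
    """The network is disconnected or under-determined; names offending nodes."""


@dataclass(frozen=True)
class PorousElement:
    """A 1-D Darcy element: length L along the flow axis, cross-section A,
    permeability k, carrying a fluid of viscosity mu."""

    length: float  # m
    area: float  # m^2
    permeability: float  # m^2
    fluid_viscosity: float  # Pa*s
    label: str = ""
    wanted: bool = False  # True = flow through this element passes cells


@dataclass(frozen=True)
class Edge:
    node_a: str
    node_b: str
    resistance: float  # Pa*s/m^3
    label: str = ""
    wanted: bool = False

    def __post_init__(self) -> None:
        if self.resistance <= 0:
            raise InvalidElementError(
                f"edge {self.label or (self.node_a, self.node_b)}: "
                f"resistance must be positive, got {self.resistance}")
        if self.node_a == self.node_b:
            raise InvalidElementError(f"self-loop at node {self.node_a!r}")


@dataclass
class HydraulicNetwork:
    """Node/edge resistance graph with boundary conditions.

    ``pressures`` fixes node pressures (Pa, Dirichlet); ``inflows`` injects
    volumetric flow (m^3/s, positive into the node).  At least one pressure
    must be fixed to pin the datum.
    """

    edges: list[Edge] = field(default_factory=list)
    pressures: dict[str, float] = field(default_factory=dict)
    inflows: dict[str, float] = field(default_factory=dict)

    def add_edge(self, node_a: str, node_b: str, resistance: float,
                 label: str = "", wanted: bool = False) -> None:
        self.edges.append(Edge(node_a, node_b, resistance, label, wanted))

    @property
    def nodes(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.edges:
            seen.setdefault(e.node_a)
            seen.setdefault(e.node_b)
        for n in (*self.pressures, *self.inflows):
            seen.setdefault(n)
        return list(seen)

    def with_resistance(self, edge_label: str,
                        new_resistance: float) -> "HydraulicNetwork":
        """Copy of the network with one labelled edge's resistance replaced."""
        labels = [e.label for e in self.edges]
        if edge_label not in labels:
            raise KeyError(f"no edge labelled {edge_label!r}")
        new_edges = [
            Edge(e.node_a, e.node_b,
                 new_resistance if e.label == edge_label else e.resistance,
                 e.label, e.wanted)
            for e in self.edges
        ]
        return HydraulicNetwork(new_edges, dict(self.pressures), dict(self.inflows))


@dataclass(frozen=True)
class NetworkSolution:
    """Node pressures (Pa) and per-edge flows (m^3/s, positive a->b)."""

    network: HydraulicNetwork
    node_pressures: dict[str, float]
    edge_flows: np.ndarray  # aligned with network.edges

    @property
    def edge_table(self) -> pd.DataFrame:
        rows = []
        for e, q in zip(self.network.edges, self.edge_flows):
            dp = (self.node_pressures[e.node_a] - self.node_pressures[e.node_b])
            rows.append({"edge": e.label or f"{e.node_a}->{e.node_b}",
                         "node_a": e.node_a, "node_b": e.node_b,
                         "resistance_Pa_s_per_m3": e.resistance,
                         "delta_P_Pa": dp, "Q_m3_per_s": q,
                         "wanted": e.wanted})
        return pd.DataFrame(rows)

    def boundary_throughflow(self) -> float:
        """Total flow delivered by the boundary (sum of positive injections).

        Counts fixed inflows plus net flow out of fixed-pressure nodes, on
        the delivering side.
        """
        total = sum(q for q in self.network.inflows.values() if q > 0)
        for node in self.network.pressures:
            net_out = 0.0
            for e, q in zip(self.network.edges, self.edge_flows):
                if e.node_a == node:
                    net_out += q
                elif e.node_b == node:
                    net_out -= q
            if net_out > 0:
                total += net_out
        return total


# --- element and composition laws -------------------------------------------

def element_resistance(element: PorousElement) -> float:
    """Darcy hydraulic resistance ``mu*L/(k*A)`` in Pa*s/m^3."""
    bad = [name for name, v in (("length", element.length),
                                ("area", element.area),
                                ("permeability", element.permeability),
                                ("fluid_viscosity", element.fluid_viscosity))
           if v <= 0]
    if bad:
        raise InvalidElementError(
            f"element {element.label!r}: non-positive {', '.join(bad)}")
    return (element.fluid_viscosity * element.length
            / (element.permeability * element.area))


def _check_resistances(resistances: Sequence[float]) -> np.ndarray:
    r = np.asarray(list(resistances), dtype=float)
    if r.size == 0:
        raise ValueError("resistance list must be non-empty")
    if np.any(r <= 0):
        raise InvalidElementError("all resistances must be positive")
    return r


def combine_series(resistances: Iterable[float]) -> float:
    """Equivalent resistance of elements in series (sum)."""
    return float(_check_resistances(list(resistances)).sum())


def combine_parallel(resistances: Iterable[float]) -> float:
    """Equivalent resistance of elements in parallel (reciprocal sum)."""
    r = _check_resistances(list(resistances))
    return float(1.0 / np.sum(1.0 / r))


# --- network solve ------------------------------------------------------------

def solve_network(net: HydraulicNetwork) -> NetworkSolution:
    """Solve node pressures and edge flows by nodal analysis.

    Builds the conductance (weighted-Laplacian) system for free nodes with
    Dirichlet rows for fixed pressures, solves it sparsely, and verifies
    Kirchhoff's current law at every interior node to
    :data:`CONSERVATION_RTOL` (relative to the local flow scale).

    Raises :class:`SingularNetworkError` for networks with no fixed
    pressure, or with components not tied to any boundary pressure
    (under-determined), naming the offending nodes.
    """
    nodes = net.nodes
    if not nodes:
        raise SingularNetworkError("empty network")
    if not net.pressures:
        raise SingularNetworkError(
            "no fixed-pressure node; pressures are defined only up to a datum")
    # connectivity: every node must reach a fixed-pressure node through edges
    adj: dict[str, set[str]] = {n: set() for n in nodes}
    for e in net.edges:
        adj[e.node_a].add(e.node_b)
        adj[e.node_b].add(e.node_a)
    reached = set(net.pressures)
    frontier = list(reached)
    while frontier:
        n = frontier.pop()
        for m in adj[n]:
            if m not in reached:
                reached.add(m)
                frontier.append(m)
    floating = sorted(set(nodes) - reached)
    if floating:
        raise SingularNetworkError(
            f"nodes not connected to any fixed-pressure boundary: {floating}")

    fixed = set(net.pressures)
    free_nodes = [n for n in nodes if n not in fixed]
    node_pressures = {n: float(p) for n, p in net.pressures.items()}

    if free_nodes:
        idx = {n: i for i, n in enumerate(free_nodes)}
        n_free = len(free_nodes)
        rows, cols, vals = [], [], []
        rhs = np.zeros(n_free)
        for node, q in net.inflows.items():
            if node in idx:
                rhs[idx[node]] += q
        for e in net.edges:
            g = 1.0 / e.resistance
            fa, fb = e.node_a in idx, e.node_b in idx
            if fa:
                ia = idx[e.node_a]
                rows.append(ia), cols.append(ia), vals.append(g)
                if fb:
                    rows.append(ia), cols.append(idx[e.node_b]), vals.append(-g)
                else:
                    rhs[ia] += g * node_pressures[e.node_b]
            if fb:
                ib = idx[e.node_b]
                rows.append(ib), cols.append(ib), vals.append(g)
                if fa:
                    rows.append(ib), cols.append(idx[e.node_a]), vals.append(-g)
                else:
                    rhs[ib] += g * node_pressures[e.node_a]
        a = sp.csr_matrix((vals, (rows, cols)), shape=(n_free, n_free))
        p_free = spla.spsolve(a, rhs)
        if not np.all(np.isfinite(p_free)):
            raise SingularNetworkError(
                f"singular system; check nodes {sorted(free_nodes)}")
        node_pressures.update({n: float(p_free[idx[n]]) for n in free_nodes})
    flows = np.array([
        (node_pressures[e.node_a] - node_pressures[e.node_b]) / e.resistance
        for e in net.edges
    ])

    # mass balance at interior (free) nodes, relative to the global flow scale
    flow_scale = float(np.max(np.abs(flows))) if len(flows) else 0.0
    for node in nodes:
        if node in fixed:
            continue
        net_in = float(net.inflows.get(node, 0.0))
        for e, q in zip(net.edges, flows):
            if e.node_b == node:
                net_in += q
            elif e.node_a == node:
                net_in -= q
        if flow_scale > 0 and abs(net_in) > CONSERVATION_RTOL * flow_scale:
            raise SingularNetworkError(
                f"mass balance violated at node {node!r}: residual {net_in}")
    return NetworkSolution(net, node_pressures, flows)


# --- flow bookkeeping ---------------------------------------------------------

def flow_partition(solution: NetworkSolution) -> dict:
    """Partition boundary throughflow into wanted vs wasteful fractions.

    Edges flagged ``wanted`` carry flow past cells; everything else at the
    same tier (bypass gaps, seepage up stack sides) is wasteful.  The
    wanted fraction is the summed magnitude of wanted-edge flow over the
    total boundary throughflow; this equals the physical split whenever the
    wanted and bypass edges form a cut of the circuit (the usual
    module-plus-bypass topology).  Returns a dict with ``wanted_fraction``,
    ``wasteful_fraction`` and a ``per_edge`` table; if no edge is wanted a
    warning is recorded and the wanted fraction is 0.
    """
    import warnings

    table = solution.edge_table
    total = solution.boundary_throughflow()
    wanted_edges = table[table["wanted"]]
    if wanted_edges.empty:
        warnings.warn("no edge is flagged 'wanted'; wanted fraction is 0",
                      stacklevel=2)
        wanted_flow = 0.0
    else:
        wanted_flow = float(wanted_edges["Q_m3_per_s"].abs().sum())
    if total <= 0:
        frac = 0.0
    else:
        frac = min(wanted_flow / total, 1.0)
    return {
        "wanted_fraction": frac,
        "wasteful_fraction": 1.0 - frac,
        "total_throughflow_m3_per_s": total,
        "per_edge": table,
    }


def regulator_swap_ratio(net: HydraulicNetwork, regulator_edge: str,
                         new_resistance: float) -> float:
    """Throughflow ratio after/before swapping a regulator element.

    Replaces the labelled regulator edge's resistance, holding boundary
    pressures fixed, and returns ``Q_after / Q_before``.  When the
    regulator dominates the circuit the ratio approaches
    ``R_old / R_new`` (e.g. a 3x-lower-resistance regulator speeds flow
    ~3-fold); otherwise it lies strictly between 1 and that limit.
    """
    before = solve_network(net).boundary_throughflow()
    after = solve_network(net.with_resistance(regulator_edge,
                                              new_resistance)).boundary_throughflow()
    if before == 0:
        raise ZeroDivisionError("no throughflow in the reference network")
    return after / before
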