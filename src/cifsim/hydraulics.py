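"""Lumped-element hydraulic networks for multiplexed and pumpless operation.

Low-Reynolds channel flow is linear, so a device manifold or an
arteriovenous extracorporeal circuit reduces to a resistor network: channels
are edges with a hydraulic resistance, junctions are nodes, the arterial and
venous pressures are fixed-pressure boundaries, and a withdrawal syringe
pump is a fixed-flow edge.  Solving the network is nodal analysis (Kirchhoff
current law) — one linear solve.

Pressures may be supplied in any single consistent unit (mmHg at physiologic
boundaries is conventional; ``MMHG_PA`` converts).  Resistances returned by
:func:`rect_channel_resistance` are in Pa per (µL/min), so pressures in Pa
give flows in µL/min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "MMHG_PA",
    "BLOOD_VISCOSITY_MPA_S",
    "NetworkStructureError",
    "HydraulicNetwork",
    "NetworkSolution",
    "rect_channel_resistance",
    "invivo_circuit",
]

MMHG_PA = 133.322  # 1 mmHg in Pa
BLOOD_VISCOSITY_MPA_S = 4.0  # undiluted whole blood, Newtonian approximation


class NetworkStructureError(ValueError):
    """The network is disconnected from any pressure reference or otherwise
    cannot be solved."""


def rect_channel_resistance(
    w: float, h: float, length_mm: float, viscosity_mpa_s: float = BLOOD_VISCOSITY_MPA_S
) -> float:
    """Laminar hydraulic resistance of a rectangular channel, Pa/(µL/min).

    Uses the exact series solution for fully developed flow in a rectangular
    duct, truncated at 51 odd terms (the series converges as n⁻⁵; truncation
    error is far below 1e-6 relative).  Symmetric in ``w`` and ``h`` and
    linear in length and viscosity.

    Parameters
    ----------
    w, h : cross-section sides, µm.
    length_mm : channel length, mm.
    viscosity_mpa_s : dynamic viscosity, mPa·s (cP).
    """
    if w <= 0 or h <= 0 or length_mm <= 0 or viscosity_mpa_s <= 0:
        raise ValueError("channel dimensions and viscosity must be positive")
    a = min(w, h) * 1e-6  # short side, m
    b = max(w, h) * 1e-6
    series = 0.0
    for n in range(1, 102, 2):
        series += math.tanh(n * math.pi * b / (2.0 * a)) / n**5
    s = 1.0 - 192.0 * a / (math.pi**5 * b) * series
    mu = viscosity_mpa_s * 1e-3  # Pa·s
    length = length_mm * 1e-3  # m
    r_si = 12.0 * mu * length / (a**3 * b * s)  # Pa·s/m³
    return r_si * 1e-9 / 60.0  # Pa per (µL/min)


@dataclass(frozen=True)
class NetworkSolution:
    """Node pressures and signed edge flows (positive from u to v)."""

    pressures: dict
    flows: dict

    def node_imbalance(self, graph: nx.MultiDiGraph) -> dict:
        """Net inflow at every node (should vanish at interior nodes)."""
        net = {n: 0.0 for n in graph.nodes}
        for (u, v, key), q in self.flows.items():
            net[u] -= q
            net[v] += q
        return net


class HydraulicNetwork:
    """A resistor-network model of a microfluidic circuit.

    Edges are added with either explicit resistance (Pa per (µL/min)) or
    rectangular-channel geometry; ``add_flow_source`` adds a prescribed-flow
    edge (e.g. a withdrawal pump).  At least one node must have a fixed
    pressure.
    """

    def __init__(self):
        self.graph = nx.MultiDiGraph()
        self._fixed_pressure: dict = {}

    def add_node(self, name, pressure: float | None = None) -> None:
        self.graph.add_node(name)
        if pressure is not None:
            self._fixed_pressure[name] = float(pressure)

    def add_channel(
        self,
        u,
        v,
        resistance: float | None = None,
        w: float | None = None,
        h: float | None = None,
        length_mm: float | None = None,
        viscosity_mpa_s: float = BLOOD_VISCOSITY_MPA_S,
    ):
        """Add a resistive channel from ``u`` to ``v``; returns the edge key."""
        if resistance is None:
            if w is None or h is None or length_mm is None:
                raise ValueError("give either resistance or (w, h, length_mm)")
            resistance = rect_channel_resistance(w, h, length_mm, viscosity_mpa_s)
        if resistance <= 0:
            raise ValueError(f"resistance must be positive, got {resistance}")
        self.graph.add_node(u)
        self.graph.add_node(v)
        key = self.graph.add_edge(u, v, kind="channel", resistance=float(resistance))
        return (u, v, key)

    def add_flow_source(self, u, v, flow: float):
        """Add a fixed-flow edge carrying ``flow`` from ``u`` to ``v``."""
        self.graph.add_node(u)
        self.graph.add_node(v)
        key = self.graph.add_edge(u, v, kind="flow", flow=float(flow))
        return (u, v, key)

    def solve(self) -> NetworkSolution:
        """Nodal-analysis solution: pressures at free nodes, flows on edges."""
        g = self.graph
        if g.number_of_nodes() == 0:
            raise NetworkStructureError("empty network")
        if not self._fixed_pressure:
            raise NetworkStructureError("no fixed-pressure node")
        # every weakly connected component needs a pressure reference
        for comp in nx.weakly_connected_components(g):
            if not comp & self._fixed_pressure.keys():
                raise NetworkStructureError(
                    f"component {sorted(map(str, comp))} has no fixed-pressure node"
                )
        free = [n for n in g.nodes if n not in self._fixed_pressure]
        idx = {n: i for i, n in enumerate(free)}
        a = np.zeros((len(free), len(free)))
        b = np.zeros(len(free))
        for u, v, data in g.edges(data=True):
            if data["kind"] == "channel":
                gcond = 1.0 / data["resistance"]
                for node, other, sign in ((u, v, 1.0), (v, u, 1.0)):
                    if node in idx:
                        a[idx[node], idx[node]] += gcond
                        if other in idx:
                            a[idx[node], idx[other]] -= gcond
                        else:
                            b[idx[node]] += gcond * self._fixed_pressure[other]
            else:  # prescribed flow u -> v
                q = data["flow"]
                if u in idx:
                    b[idx[u]] -= q
                if v in idx:
                    b[idx[v]] += q
        if free:
            try:
                p_free = np.linalg.solve(a, b)
            except np.linalg.LinAlgError as exc:
                raise NetworkStructureError(
                    "singular nodal system (an interior node may connect only "
                    "to prescribed-flow edges)"
                ) from exc
        else:
            p_free = np.array([])
        pressures = dict(self._fixed_pressure)
        for n, i in idx.items():
            pressures[n] = float(p_free[i])
        flows = {}
        for u, v, key, data in g.edges(keys=True, data=True):
            if data["kind"] == "channel":
                flows[(u, v, key)] = (pressures[u] - pressures[v]) / data["resistance"]
            else:
                flows[(u, v, key)] = data["flow"]
        return NetworkSolution(pressures=pressures, flows=flows)


def invivo_circuit(
    arterial_pressure_mmhg: float,
    venous_pressure_mmhg: float,
    device_resistance: float,
    tubing_resistance: float,
    withdrawal_flow_ul_min: float,
) -> HydraulicNetwork:
    """Pumpless arteriovenous circuit: artery → tubing → device → tubing →
    vein, with a fixed-flow retentate withdrawal edge at the device outlet.

    The arteriovenous pressure difference drives the flow; the withdrawal
    pump draws the retentate at a prescribed rate.  Pressures are converted
    to Pa internally so flows come out in µL/min.
    """
    net = HydraulicNetwork()
    net.add_node("artery", pressure=arterial_pressure_mmhg * MMHG_PA)
    net.add_node("vein", pressure=venous_pressure_mmhg * MMHG_PA)
    net.add_channel("artery", "device_in", resistance=tubing_resistance / 2.0)
    net.add_channel("device_in", "device_out", resistance=device_resistance)
    net.add_channel("device_out", "vein", resistance=tubing_resistance / 2.0)
    net.add_flow_source("device_out", "retentate_syringe", withdrawal_flow_ul_min)
    net.add_node("retentate_syringe", pressure=venous_pressure_mmhg * MMHG_PA)
    return net
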