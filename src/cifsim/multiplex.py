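"""Multiplexing CIF elements into devices and devices into parallel arrays.

One device packs eight identical elements in parallel behind a bifurcating
inlet manifold; devices are further parallelised with Y-connectors.  Because
capture at a gap depends only on geometry (low-Reynolds flow), collection
efficiency is invariant under parallelisation — throughput scales with the
device count while per-element flow stays fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .blood import BloodSample
from .geometry import CIFElementDesign
from .hydraulics import HydraulicNetwork
from .separation import SeparationResult, _result_from_ce, separate

__all__ = ["DeviceArray", "array_throughput", "parallel_separation", "bifurcation_network"]

ELEMENTS_PER_DEVICE = 8


@dataclass(frozen=True)
class DeviceArray:
    """A bank of identical CIF devices run in parallel.

    ``per_device_flow`` in mL/min; dead volumes in µL.  Defaults: ~87 µL per
    device plus ~214 µL of connection tubing, i.e. ~301 µL for a single
    plumbed device.  ``tubing_dead_volume`` is an array-level term — larger
    manifolds (Y-connector trees) should pass their measured total.
    """

    n_devices: int
    per_device_flow: float = 1.2
    elements_per_device: int = ELEMENTS_PER_DEVICE
    dead_volume_per_device: float = 87.0
    tubing_dead_volume: float = 214.0

    def __post_init__(self):
        if self.n_devices < 1:
            raise ValueError(f"need at least one device, got {self.n_devices}")
        if self.per_device_flow <= 0:
            raise ValueError("per-device flow must be positive")

    @property
    def total_flow(self) -> float:
        """Array throughput, mL/min."""
        return self.n_devices * self.per_device_flow

    @property
    def per_element_flow(self) -> float:
        """Flow through one CIF element, mL/min."""
        return self.total_flow / (self.n_devices * self.elements_per_device)

    @property
    def total_dead_volume(self) -> float:
        """Total extracorporeal dead volume, µL (devices + tubing)."""
        return self.n_devices * self.dead_volume_per_device + self.tubing_dead_volume


def array_throughput(n_devices: int, per_device_flow: float = 1.2) -> float:
    """Total throughput of ``n_devices`` in parallel, mL/min."""
    return DeviceArray(n_devices, per_device_flow).total_flow


def parallel_separation(
    array: DeviceArray,
    design: CIFElementDesign,
    sample: BloodSample,
    seed: int | None = None,
    mode: str = "deterministic",
    n_cells: int = 10_000,
    element_design_flow: float | None = None,
) -> SeparationResult:
    """Separate a sample split equally across a device array and pool outputs.

    Each device processes ``sample.volume / n_devices``; retentate and
    filtrate are pooled across devices.  In the deterministic model the
    pooled CE equals the single-device CE exactly; in Monte-Carlo mode each
    device gets an independent sub-stream of the seed, so the pooled CE
    agrees within sampling error.  ``element_design_flow`` (mL/min), if
    given, is compared with the array's per-element flow and a mismatch is
    reported as a warning (capture itself is flow-rate-agnostic).
    """
    if element_design_flow is not None:
        import warnings

        if not np.isclose(array.per_element_flow, element_design_flow, rtol=1e-6):
            warnings.warn(
                f"per-element flow {array.per_element_flow:.4g} mL/min differs "
                f"from the element design flow {element_design_flow:.4g} mL/min",
                stacklevel=2,
            )
    if mode == "deterministic":
        return separate(design, sample, mode="deterministic")
    if seed is None:
        raise ValueError("Monte-Carlo mode requires a seed")
    rng = np.random.default_rng(seed)
    per_device = sample.with_volume(sample.volume / array.n_devices)
    retained_counts = {name: 0 for name in sample.names}
    totals = {name: 0 for name in sample.names}
    from .separation import transport_monte_carlo

    for _ in range(array.n_devices):
        cells = transport_monte_carlo(design, per_device, n_cells, rng)
        grp = cells.groupby("type", sort=False)["retained"]
        for name, s in grp.sum().items():
            retained_counts[name] += int(s)
        for name, c in grp.count().items():
            totals[name] += int(c)
    ce = {
        name: 100.0 * retained_counts[name] / totals[name] for name in sample.names
    }
    return _result_from_ce(sample, ce, design.flow_ratio)


def bifurcation_network(
    n_devices: int,
    device_resistance: float,
    branch_resistance: float,
    inlet_pressure: float,
    outlet_pressure: float = 0.0,
) -> HydraulicNetwork:
    """Symmetric binary bifurcation tree feeding ``n_devices`` (a power of 2)
    identical devices between two pressure rails.

    Used to verify that a balanced manifold delivers equal per-device flows.
    """
    if n_devices < 1 or (n_devices & (n_devices - 1)) != 0:
        raise ValueError(f"n_devices must be a power of 2, got {n_devices}")
    net = HydraulicNetwork()
    net.add_node("inlet", pressure=inlet_pressure)
    net.add_node("outlet", pressure=outlet_pressure)
    # build the tree level by level; leaves connect through a device edge
    frontier = ["inlet"]
    level = 0
    while len(frontier) < n_devices:
        nxt = []
        for node in frontier:
            for side in ("L", "R"):
                child = f"n{level}_{len(nxt)}{side}"
                net.add_channel(node, child, resistance=branch_resistance)
                nxt.append(child)
        frontier = nxt
        level += 1
    for i, leaf in enumerate(frontier):
        net.add_channel(leaf, "outlet", resistance=device_resistance)
    return net
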