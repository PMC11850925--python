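"""Gap-by-gap geometry of a controlled incremental filtration (CIF) element.

A CIF element is a central (retentate) channel flanked by two filtrate
channels, separated by arrays of identical filtration gaps.  At gap ``i`` a
small fraction ``f_gap(i)`` of the retentate flow ``Q_r(i)`` is extracted
through each side gap.  The fluid that leaves comes from a wall-adjacent
lamina of width ``w_l``; any cell whose center cannot enter that lamina
(radius >= ``w_l``) stays in the retentate.  Holding ``w_l`` constant along
the element therefore holds the cell-size cutoff constant, which requires
``f_gap(i)`` to grow as the retentate flow shrinks and the channel narrows.

This module computes the lamina/fraction relation for a chosen depth-averaged
velocity profile, generates complete element designs (per-gap fractions,
widths and flow schedules), and evaluates the flow-ratio theory limits
(small-cell loss ``1/(1+FR)``, maximum concentration ``1+FR``).

Units: lengths in µm, flows in µL/min.  Gap indices are 0-based.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "InfeasibleDesignError",
    "CIFElementDesign",
    "FlowSchedule",
    "FlowRatioTheory",
    "lamina_width_from_fraction",
    "fraction_from_lamina_width",
    "design_element",
    "flow_ratio_theory",
]


class InfeasibleDesignError(ValueError):
    """Raised when the design iteration cannot continue.

    Carries ``gap_index``, the 0-based gap at which the iteration failed.
    """

    def __init__(self, message: str, gap_index: int):
        super().__init__(message)
        self.gap_index = gap_index


# ---------------------------------------------------------------------------
# Velocity profiles: cumulative flow fraction carried by a wall lamina
# ---------------------------------------------------------------------------

def _parabolic_cum_fraction(d: float, w: float, depth: float | None = None) -> float:
    # Plane-Poiseuille profile across the width: u(x) ∝ x(1-x), x = y/w.
    # Fraction of total flow within distance d of one wall: 3x² − 2x³.
    x = d / w
    return 3.0 * x * x - 2.0 * x * x * x


def _uniform_cum_fraction(d: float, w: float, depth: float | None = None) -> float:
    return d / w


def _duct_cum_fraction(d: float, w: float, depth: float) -> float:
    # Full rectangular-duct laminar profile, averaged over the depth h.
    # Depth-averaged velocity at lateral position y (wall at y=0):
    #   ū(y) ∝ Σ_{n odd} n⁻⁴ [1 − cosh(k(y−w/2))/cosh(kw/2)],  k = nπ/h.
    # The cumulative integral of each term is analytic (sinh), so the lamina
    # flow fraction needs no quadrature.
    if d <= 0.0:
        return 0.0
    h = depth
    num = 0.0
    den = 0.0
    for n in range(1, 102, 2):
        k = math.pi * n / h
        c = math.cosh(k * w / 2.0)
        # ∫_0^d [1 − cosh(k(y−w/2))/cosh(kw/2)] dy
        term_d = d - (math.sinh(k * (d - w / 2.0)) + math.sinh(k * w / 2.0)) / (k * c)
        term_w = w - 2.0 * math.tanh(k * w / 2.0) / k
        num += term_d / n**4
        den += term_w / n**4
    return num / den


_PROFILES: dict[str, Callable[[float, float, float | None], float]] = {
    "parabolic": _parabolic_cum_fraction,
    "uniform": _uniform_cum_fraction,
    "duct": _duct_cum_fraction,
}


def fraction_from_lamina_width(
    d: float, w: float, profile: str = "parabolic", depth: float | None = None
) -> float:
    """Per-side flow fraction carried by a wall lamina of width ``d``.

    Parameters
    ----------
    d : lamina width, µm; must satisfy ``0 <= d <= w/2``.
    w : channel width, µm.
    profile : ``"parabolic"`` (depth-averaged plane Poiseuille, default),
        ``"duct"`` (full rectangular-duct profile; requires ``depth``), or
        ``"uniform"`` (plug flow).
    """
    if w <= 0:
        raise ValueError(f"channel width must be positive, got {w}")
    if d < 0 or d > w / 2.0 + 1e-12 * w:
        raise ValueError(f"lamina width must lie in [0, w/2]=[0, {w / 2}], got {d}")
    if profile == "duct" and depth is None:
        raise ValueError("the duct profile requires the channel depth")
    return float(_PROFILES[profile](min(d, w / 2.0), w, depth))


def lamina_width_from_fraction(
    f: float, w: float, profile: str = "parabolic", depth: float | None = None
) -> float:
    """Width of the wall lamina that carries a per-side flow fraction ``f``.

    Inverse of :func:`fraction_from_lamina_width`; strictly increasing in
    ``f`` on [0, 0.5].  Solved by bisection to a relative tolerance of 1e-12.
    """
    if w <= 0:
        raise ValueError(f"channel width must be positive, got {w}")
    if f < 0 or f > 0.5:
        raise ValueError(f"per-side flow fraction must lie in [0, 0.5], got {f}")
    if f == 0.0:
        return 0.0
    if f == 0.5:
        return w / 2.0
    cum = _PROFILES[profile]
    if profile == "duct" and depth is None:
        raise ValueError("the duct profile requires the channel depth")
    return float(
        brentq(lambda d: cum(d, w, depth) - f, 0.0, w / 2.0, xtol=1e-15 * w, rtol=1e-14)
    )


# ---------------------------------------------------------------------------
# Flow-ratio theory
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlowRatioTheory:
    """Theoretical limits set by the flow ratio FR = V_fil / V_ret."""

    flow_ratio: float
    small_cell_loss_percent: float  # fraction of sub-cutoff cells lost to retentate
    max_concentration_fold: float   # ceiling on retentate concentration gain


def flow_ratio_theory(flow_ratio: float) -> FlowRatioTheory:
    """Small-cell loss and maximum concentration set by the flow ratio.

    A neutrally-advected cell below the size cutoff distributes with the
    fluid, so ``100/(1+FR)`` percent end up in the retentate (a loss), and a
    fully retained cell type can be concentrated at most ``1+FR``-fold.
    """
    if flow_ratio < 0:
        raise ValueError(f"flow ratio must be non-negative, got {flow_ratio}")
    return FlowRatioTheory(
        flow_ratio=flow_ratio,
        small_cell_loss_percent=100.0 / (1.0 + flow_ratio),
        max_concentration_fold=1.0 + flow_ratio,
    )


# ---------------------------------------------------------------------------
# Element design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlowSchedule:
    """Flows along the element for a given inlet flow (µL/min).

    ``q_r[i]`` is the retentate flow entering gap pair ``i``; ``q_r[-1]`` is
    the retentate output.  ``q_gap[i]`` is the per-side gap flow and
    ``q_fil_cum[i]`` the total filtrate accumulated after gap pair ``i``.
    """

    q_in: float
    q_r: np.ndarray
    q_gap: np.ndarray
    q_fil_cum: np.ndarray


@dataclass(frozen=True)
class CIFElementDesign:
    """A complete CIF element: per-gap fractions, widths, and the size cutoff.

    ``f_gap[i]`` is the per-side filtration fraction at gap pair ``i`` (each
    of the two side gaps extracts ``f_gap[i] * Q_r(i)``), ``w_r[i]`` /
    ``w_f[i]`` the retentate/filtrate channel widths at that station, and
    ``w_l_target`` the extracted lamina width the schedule holds constant.
    """

    f_gap_star: float
    w_r_star: float
    gap_width: float
    depth: float
    n_gaps: int
    f_gap: np.ndarray
    w_r: np.ndarray
    w_f: np.ndarray
    w_l_target: float
    profile: str = "parabolic"
    width_rule: str = "velocity"
    min_width: float = field(default=0.0)

    @property
    def retentate_flow_fraction(self) -> float:
        """Fraction of the inlet flow leaving as retentate, Π(1 − 2 f_gap)."""
        if self.n_gaps == 0:
            return 1.0
        return float(np.prod(1.0 - 2.0 * self.f_gap))

    @property
    def flow_ratio(self) -> float:
        """FR = filtrate volume / retentate volume."""
        phi = self.retentate_flow_fraction
        return (1.0 - phi) / phi

    def flow_schedule(self, q_in: float = 1.0) -> FlowSchedule:
        """Per-gap flows for inlet flow ``q_in`` (µL/min)."""
        if q_in <= 0:
            raise ValueError(f"inlet flow must be positive, got {q_in}")
        q_r = np.empty(self.n_gaps + 1)
        q_r[0] = q_in
        q_gap = np.empty(self.n_gaps)
        for i in range(self.n_gaps):
            q_gap[i] = self.f_gap[i] * q_r[i]
            q_r[i + 1] = q_r[i] - 2.0 * q_gap[i]
        return FlowSchedule(q_in=q_in, q_r=q_r, q_gap=q_gap, q_fil_cum=q_in - q_r[1:])

    def realized_lamina_widths(self) -> np.ndarray:
        """Lamina width actually extracted at each gap (should all equal
        ``w_l_target`` to solver tolerance)."""
        return np.array(
            [
                lamina_width_from_fraction(f, w, self.profile, self.depth)
                for f, w in zip(self.f_gap, self.w_r)
            ]
        )

    # -- serialization ------------------------------------------------------

    def to_frame(self, q_in: float = 1.0) -> pd.DataFrame:
        """One row per gap: index, fraction, widths, flows, realized lamina."""
        sched = self.flow_schedule(q_in) if self.n_gaps else None
        return pd.DataFrame(
            {
                "i": np.arange(self.n_gaps, dtype=int),
                "f_gap": self.f_gap,
                "w_r_um": self.w_r,
                "w_f_um": self.w_f,
                "q_r_ul_min": sched.q_r[:-1] if sched else np.array([]),
                "q_gap_ul_min": sched.q_gap if sched else np.array([]),
                "w_l_um": self.realized_lamina_widths(),
            }
        )

    def header(self) -> dict:
        return {
            "f_gap_star": self.f_gap_star,
            "w_r_star": self.w_r_star,
            "gap_width": self.gap_width,
            "depth": self.depth,
            "n_gaps": self.n_gaps,
            "flow_ratio": self.flow_ratio,
            "w_l_target": self.w_l_target,
            "profile": self.profile,
            "width_rule": self.width_rule,
            "min_width": self.min_width,
        }

    def save(self, csv_path, json_path=None, q_in: float = 1.0) -> None:
        """Write the per-gap table as CSV and the header as JSON."""
        self.to_frame(q_in).to_csv(csv_path, index=False)
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump(self.header(), fh, indent=2)

    @classmethod
    def load(cls, csv_path, json_path) -> "CIFElementDesign":
        with open(json_path) as fh:
            hdr = json.load(fh)
        table = pd.read_csv(csv_path, float_precision="round_trip")
        return cls(
            f_gap_star=hdr["f_gap_star"],
            w_r_star=hdr["w_r_star"],
            gap_width=hdr["gap_width"],
            depth=hdr["depth"],
            n_gaps=int(hdr["n_gaps"]),
            f_gap=table["f_gap"].to_numpy(),
            w_r=table["w_r_um"].to_numpy(),
            w_f=table["w_f_um"].to_numpy(),
            w_l_target=hdr["w_l_target"],
            profile=hdr.get("profile", "parabolic"),
            width_rule=hdr.get("width_rule", "velocity"),
            min_width=hdr.get("min_width", 0.0),
        )


def design_element(
    f_gap_star: float,
    w_r_star: float = 230.0,
    gap_width: float = 20.0,
    depth: float = 150.0,
    n_gaps: int | None = None,
    target_fr: float | None = None,
    width_rule: str = "velocity",
    profile: str = "parabolic",
    min_width: float | None = None,
    strict_min_width: bool = False,
) -> CIFElementDesign:
    """Generate a CIF element that holds the extracted lamina width constant.

    The lamina width ``w_l`` is fixed by ``(f_gap_star, w_r_star)`` at gap 0;
    at every subsequent gap the filtration fraction is recomputed from the
    current retentate width so that the same lamina is extracted, keeping the
    size cutoff constant along the element.

    Parameters
    ----------
    f_gap_star : initial per-side filtration fraction (dimensionless, ~1e-3).
    w_r_star : initial retentate channel width, µm.  The default (230 µm,
        with ``f_gap_star = 1e-3``) puts the size cutoff ``2·w_l`` ≈ 8.5 µm,
        between typical lymphocyte and monocyte diameters.
    gap_width, depth : gap opening and channel depth, µm (geometry metadata;
        ``depth`` also feeds the ``"duct"`` profile).
    n_gaps, target_fr : stopping rule — exactly one must be given.  With
        ``target_fr``, the element gets the smallest gap count whose realized
        flow ratio reaches the target.
    width_rule : ``"velocity"`` shrinks the retentate width in proportion to
        its flow (constant mean velocity), clamped at ``min_width``;
        ``"fixed"`` keeps ``w_r`` constant, which makes ``f_gap`` constant
        (the constant-fraction reference mode).
    min_width : narrowest manufacturable retentate width, µm (default
        ``2 * gap_width`` so the gap posts stay separable).
    strict_min_width : if True, hitting ``min_width`` raises
        :class:`InfeasibleDesignError` instead of clamping.
    """
    if not 0.0 < f_gap_star <= 0.05:
        raise ValueError(f"f_gap_star must lie in (0, 0.05], got {f_gap_star}")
    if (n_gaps is None) == (target_fr is None):
        raise ValueError("give exactly one of n_gaps or target_fr")
    if target_fr is not None and target_fr <= 0:
        raise ValueError(f"target_fr must be positive, got {target_fr}")
    if n_gaps is not None and n_gaps < 0:
        raise ValueError(f"n_gaps must be >= 0, got {n_gaps}")
    if width_rule not in ("velocity", "fixed"):
        raise ValueError(f"unknown width rule {width_rule!r}")
    if min_width is None:
        min_width = 2.0 * gap_width

    w_l = lamina_width_from_fraction(f_gap_star, w_r_star, profile, depth)
    w_f_floor = gap_width

    f_list: list[float] = []
    w_r_list: list[float] = []
    w_f_list: list[float] = []
    q = 1.0  # retentate flow as a fraction of the inlet flow
    w = w_r_star
    i = 0
    while True:
        if n_gaps is not None and i >= n_gaps:
            break
        if w_l >= w / 2.0:
            raise InfeasibleDesignError(
                f"at gap {i} the retentate width {w:.3g} µm cannot supply a "
                f"{w_l:.3g} µm lamina per side (fraction would reach 0.5)",
                gap_index=i,
            )
        f_i = fraction_from_lamina_width(w_l, w, profile, depth)
        f_list.append(f_i)
        w_r_list.append(w)
        q_next = q * (1.0 - 2.0 * f_i)
        # filtrate width per side: constant mean velocity w.r.t. the inlet,
        # floored at the gap width
        w_f_list.append(max(w_f_floor, w_r_star * (1.0 - q_next) / 2.0))
        q = q_next
        i += 1
        if target_fr is not None and (1.0 - q) / q >= target_fr:
            break
        if width_rule == "velocity":
            w_prop = w_r_star * q
            if w_prop < min_width:
                if strict_min_width:
                    raise InfeasibleDesignError(
                        f"at gap {i} the velocity rule requires retentate width "
                        f"{w_prop:.3g} µm below the minimum {min_width:.3g} µm",
                        gap_index=i,
                    )
                w = min_width
            else:
                w = w_prop
        # "fixed": w stays at w_r_star

    return CIFElementDesign(
        f_gap_star=f_gap_star,
        w_r_star=w_r_star,
        gap_width=gap_width,
        depth=depth,
        n_gaps=len(f_list),
        f_gap=np.asarray(f_list),
        w_r=np.asarray(w_r_list),
        w_f=np.asarray(w_f_list),
        w_l_target=w_l,
        profile=profile,
        width_rule=width_rule,
        min_width=min_width,
    )
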