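"""In-vivo recirculating leukapheresis: a well-mixed compartment model.

Blood is drawn from an artery through the device at ``Q_proc`` and the
filtrate (``Q_fil``) returns to the vein while the retentate is withdrawn
continuously at ``Q_ret = retentate_fraction × Q_fil``.  Treating the
circulation as a single well-mixed pool of volume ``V(t)`` holding ``N_k``
cells of type ``k``:

    dN_k/dt = −Q_proc · (CE_k/100) · C_k + influx_k,    C_k = N_k / V
    dV/dt   = −Q_ret  (+ impulses from sampling and fluid administration)

where ``CE_k`` is the single-pass collection efficiency of the device for
type ``k``.  Serial CBC draws remove whole blood instantaneously (cells and
volume in proportion); by default the drawn volume is replaced 1:1 with
crystalloid, which is what makes serial sampling dilute the red-cell count.
Cumulative retentate and filtrate cell fluxes are co-integrated so the
30-minute retentate aliquots and the apheresis estimators (per-epoch
concentration ratio, whole-run collection efficiency, final percent of
baseline) can be evaluated exactly from the simulated ledgers.

Units: volumes mL, flows mL/min, concentrations cells/µL, time min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .blood import BloodSample
from .metrics import etbv

__all__ = [
    "Subject",
    "RecirculationProtocol",
    "RecirculationRun",
    "SimulationAbort",
    "simulate_recirculation",
    "cr_timepoint",
    "ce_invivo",
    "final_percent_and_ratios",
]

WBC_TYPES = ("LYM", "MON", "PMN", "NEU", "EOS", "BASO", "BLAST", "WBC")


class SimulationAbort(RuntimeError):
    """The circulating volume was driven to zero or below."""


@dataclass(frozen=True)
class Subject:
    """The connected animal or patient."""

    weight_kg: float
    baseline: BloodSample
    etbv_ml: float | None = None
    influx_per_min: dict = field(default_factory=dict)  # cells/min entering, per type

    def __post_init__(self):
        if self.weight_kg <= 0:
            raise ValueError("weight must be positive")
        if any(v < 0 for v in self.influx_per_min.values()):
            raise ValueError("influx rates must be >= 0")

    @property
    def blood_volume_ml(self) -> float:
        return self.etbv_ml if self.etbv_ml is not None else etbv(self.weight_kg)


@dataclass(frozen=True)
class RecirculationProtocol:
    """Timing and plumbing of one extracorporeal run.

    ``circuit_flow_ml_min`` is the measured filtrate flow returning to the
    subject; the retentate is withdrawn at ``retentate_fraction`` of it
    (device FR = 1/retentate_fraction).  ``sample_times_min`` are serial CBC
    draws of ``sample_volume_ml`` whole blood; with
    ``replace_sample_volume`` each draw is immediately compensated with an
    equal crystalloid bolus.  ``fluid_events`` are extra (time, volume_ml)
    boluses.  ``circuit_ecv_ml`` is sequestered from the circulating volume
    at connection.
    """

    duration_min: float = 180.0
    circuit_flow_ml_min: float = 0.45
    retentate_fraction: float = 0.05
    sample_times_min: tuple = ()
    sample_volume_ml: float = 0.3
    retentate_epoch_min: float = 30.0
    fluid_events: tuple = ()  # (time_min, volume_ml)
    replace_sample_volume: bool = True
    circuit_ecv_ml: float = 0.0
    measurement_noise_cv: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.duration_min <= 0:
            raise ValueError("duration must be positive")
        # 0 is allowed for sham circuits (no retentate channel to withdraw)
        if not 0.0 <= self.retentate_fraction < 0.5:
            raise ValueError(
                f"retentate fraction must lie in [0, 0.5), got {self.retentate_fraction}"
            )
        for t in self.sample_times_min:
            if not 0.0 <= t <= self.duration_min:
                raise ValueError(f"sample time {t} outside [0, {self.duration_min}]")
        for t, _v in self.fluid_events:
            if not 0.0 <= t <= self.duration_min:
                raise ValueError(f"fluid event at {t} outside the run")

    @property
    def retentate_flow_ml_min(self) -> float:
        return self.retentate_fraction * self.circuit_flow_ml_min

    @property
    def processed_flow_ml_min(self) -> float:
        """Blood flow drawn from the subject: filtrate return + retentate."""
        return self.circuit_flow_ml_min + self.retentate_flow_ml_min

    @property
    def flow_ratio(self) -> float:
        if self.retentate_fraction == 0.0:
            return math.inf
        return 1.0 / self.retentate_fraction


@dataclass(frozen=True)
class RecirculationRun:
    """Everything a run produces: time series, aliquots, and ledgers."""

    types: tuple
    times_min: np.ndarray
    concentrations: pd.DataFrame  # tidy: time_min, type, conc_per_ul, volume_ml
    volume_ml: np.ndarray
    retentate_aliquots: pd.DataFrame  # epoch_start, epoch_end, type, c_ret, v_ret_ml
    filtrate_mean_conc: dict  # per type, flow-weighted over the whole run
    c_pre: dict
    c_post: dict
    v_proc_ml: float
    etbv_ml: float
    device_ce: dict
    fluid_removed_ml: float
    fluid_given_ml: float
    cells_removed_retentate: dict
    cells_removed_sampling: dict
    cells_influx: dict
    cells_start: dict
    cells_end: dict

    @property
    def etbv_processed(self) -> float:
        return self.v_proc_ml / self.etbv_ml

    def cell_balance_error(self) -> dict:
        """Relative ledger imbalance per type:
        start + influx − retentate − sampling − end, over start + influx."""
        out = {}
        for k in self.types:
            supplied = self.cells_start[k] + self.cells_influx[k]
            spent = (
                self.cells_end[k]
                + self.cells_removed_retentate[k]
                + self.cells_removed_sampling[k]
            )
            out[k] = abs(supplied - spent) / supplied if supplied else 0.0
        return out

    def summary(self) -> dict:
        fin = final_percent_and_ratios(self)
        return {
            "etbv_processed": self.etbv_processed,
            "final_percent": fin["final_percent"],
            "ratios": fin["ratios"],
            "ce_percent": {k: ce_invivo(self, k) * 100.0 for k in self.types},
            "cr_fold": {
                k: cr_timepoint_mean(self, k, denominator="circulating")
                for k in self.types
            },
            "fluid_removed_ml": self.fluid_removed_ml,
            "fluid_given_ml": self.fluid_given_ml,
        }


def simulate_recirculation(
    subject: Subject,
    device_ce: dict,
    protocol: RecirculationProtocol,
) -> RecirculationRun:
    """Integrate the compartment model over the protocol.

    ``device_ce`` maps each population name in the subject's baseline CBC to
    a single-pass collection efficiency in percent.  The integrator runs
    piecewise between discrete events (CBC draws, fluid boluses, retentate
    epoch boundaries) with a relative tolerance of 1e-10; cumulative
    retentate and filtrate cell counts are part of the state, so the ledgers
    are integrals of the same solution, not post-hoc sums.
    """
    types = tuple(subject.baseline.names)
    for k in types:
        if k not in device_ce:
            raise ValueError(f"no device CE given for population {k!r}")
        if not 0.0 <= device_ce[k] <= 100.0:
            raise ValueError(f"CE for {k} must be in [0, 100], got {device_ce[k]}")

    q_fil = protocol.circuit_flow_ml_min
    q_ret = protocol.retentate_flow_ml_min
    q_proc = protocol.processed_flow_ml_min
    ce = np.array([device_ce[k] / 100.0 for k in types])
    influx = np.array([subject.influx_per_min.get(k, 0.0) for k in types])
    c0 = np.array([subject.baseline[k].concentration for k in types])

    v0 = subject.blood_volume_ml - protocol.circuit_ecv_ml
    if v0 <= 0:
        raise SimulationAbort("circuit ECV exceeds the subject's blood volume")
    # counts tracked as concentration(µL⁻¹) × volume(mL); all reported
    # quantities are ratios, so the 10³ scale factor cancels throughout
    n0 = c0 * v0

    n_types = len(types)

    def rhs(t, y):
        n = y[:n_types]
        v = y[n_types]
        c = n / v
        # the filtrate returns to the pool, so only captured cells leave
        removal = q_proc * ce * c
        dn = -removal + influx
        dv = -q_ret
        # cumulative: retentate cells, filtrate-stream cells, processed volume
        dret = removal
        dfil = q_proc * (1.0 - ce) * c
        return np.concatenate([dn, [dv], dret, dfil])

    # breakpoints: events + epoch boundaries + duration
    t_end = protocol.duration_min
    epoch_edges = np.arange(0.0, t_end + 1e-9, protocol.retentate_epoch_min)
    if epoch_edges[-1] < t_end - 1e-9:
        epoch_edges = np.append(epoch_edges, t_end)
    breaks = {0.0, t_end}
    breaks.update(float(t) for t in protocol.sample_times_min)
    breaks.update(float(t) for t, _ in protocol.fluid_events)
    breaks.update(float(t) for t in epoch_edges)
    breaks = sorted(breaks)

    sample_at = {round(float(t), 9) for t in protocol.sample_times_min}
    fluid_at: dict[float, float] = {}
    for t, v in protocol.fluid_events:
        key = round(float(t), 9)
        fluid_at[key] = fluid_at.get(key, 0.0) + float(v)

    y = np.concatenate([n0, [v0], np.zeros(n_types), np.zeros(n_types)])
    times = [0.0]
    conc_rows = [y[:n_types] / y[n_types]]
    vols = [y[n_types]]
    cum_at_break = {0.0: y.copy()}
    removed_sampling = np.zeros(n_types)
    fluid_removed = 0.0
    fluid_given = 0.0

    rng = np.random.default_rng(protocol.seed) if protocol.seed is not None else None

    if 0.0 in sample_at:
        c = y[:n_types] / y[n_types]
        vs = protocol.sample_volume_ml
        y[:n_types] -= c * vs
        removed_sampling += c * vs
        fluid_removed += vs
        if not protocol.replace_sample_volume:
            y[n_types] -= vs
        else:
            fluid_given += vs
        cum_at_break[0.0] = y.copy()

    for t0, t1 in zip(breaks[:-1], breaks[1:]):
        if t1 > t0:
            dense_t = np.linspace(t0, t1, max(2, int(math.ceil(t1 - t0)) + 1))
            sol = solve_ivp(
                rhs,
                (t0, t1),
                y,
                method="LSODA",
                t_eval=dense_t,
                rtol=1e-10,
                atol=1e-12 * max(1.0, float(np.max(n0))),
            )
            if not sol.success:
                raise SimulationAbort(f"integration failed on [{t0}, {t1}]: {sol.message}")
            y = sol.y[:, -1].copy()
            for j in range(1, sol.t.size):
                times.append(float(sol.t[j]))
                conc_rows.append(sol.y[:n_types, j] / sol.y[n_types, j])
                vols.append(float(sol.y[n_types, j]))
            if np.any(sol.y[n_types] <= 0):
                raise SimulationAbort(
                    f"circulating volume reached zero during [{t0}, {t1}]"
                )
        key = round(t1, 9)
        # discrete events at t1
        if key in sample_at:
            v = y[n_types]
            vs = protocol.sample_volume_ml
            if vs >= v:
                raise SimulationAbort(f"sampling at t={t1} would empty the pool")
            c = y[:n_types] / v
            y[:n_types] -= c * vs
            removed_sampling += c * vs
            fluid_removed += vs
            y[n_types] = v - vs
            if protocol.replace_sample_volume:
                y[n_types] += vs
                fluid_given += vs
            times.append(float(t1))
            conc_rows.append(y[:n_types] / y[n_types])
            vols.append(float(y[n_types]))
        if key in fluid_at:
            y[n_types] += fluid_at[key]
            fluid_given += fluid_at[key]
            times.append(float(t1))
            conc_rows.append(y[:n_types] / y[n_types])
            vols.append(float(y[n_types]))
        cum_at_break[round(t1, 9)] = y.copy()

    times = np.asarray(times)
    conc = np.vstack(conc_rows)
    vols = np.asarray(vols)

    # retentate aliquots per epoch from the co-integrated cumulative fluxes
    rows = []
    for e0, e1 in zip(epoch_edges[:-1], epoch_edges[1:]):
        y0 = cum_at_break[round(float(e0), 9)]
        y1 = cum_at_break[round(float(e1), 9)]
        dret = y1[n_types + 1 : 2 * n_types + 1] - y0[n_types + 1 : 2 * n_types + 1]
        v_ret = q_ret * (e1 - e0)
        for j, k in enumerate(types):
            c_ret = dret[j] / v_ret if v_ret > 0 else 0.0
            if rng is not None and protocol.measurement_noise_cv > 0:
                sigma = math.sqrt(math.log1p(protocol.measurement_noise_cv**2))
                c_ret *= math.exp(rng.normal(-sigma**2 / 2.0, sigma))
            rows.append(
                {
                    "epoch_start_min": e0,
                    "epoch_end_min": e1,
                    "type": k,
                    "c_ret_per_ul": c_ret,
                    "v_ret_ml": v_ret,
                }
            )
    aliquots = pd.DataFrame(rows)

    v_proc = q_proc * t_end
    cum_fil = y[2 * n_types + 1 :]
    fil_mean = {k: float(cum_fil[j] / (q_fil * t_end)) for j, k in enumerate(types)}
    fluid_removed += q_ret * t_end  # continuously withdrawn retentate volume

    c_post = {k: float(conc[-1, j]) for j, k in enumerate(types)}
    if rng is not None and protocol.measurement_noise_cv > 0:
        sigma = math.sqrt(math.log1p(protocol.measurement_noise_cv**2))
        c_post = {
            k: v * math.exp(rng.normal(-sigma**2 / 2.0, sigma))
            for k, v in c_post.items()
        }

    tidy = pd.DataFrame(
        {
            "time_min": np.repeat(times, n_types),
            "type": np.tile(np.array(types, dtype=object), times.size),
            "conc_per_ul": conc.ravel(),
            "volume_ml": np.repeat(vols, n_types),
        }
    )

    return RecirculationRun(
        types=types,
        times_min=times,
        concentrations=tidy,
        volume_ml=vols,
        retentate_aliquots=aliquots,
        filtrate_mean_conc=fil_mean,
        c_pre={k: float(c0[j]) for j, k in enumerate(types)},
        c_post=c_post,
        v_proc_ml=v_proc,
        etbv_ml=subject.blood_volume_ml,
        device_ce=dict(device_ce),
        fluid_removed_ml=fluid_removed,
        fluid_given_ml=fluid_given,
        cells_removed_retentate={
            k: float(y[n_types + 1 + j]) for j, k in enumerate(types)
        },
        cells_removed_sampling={k: float(removed_sampling[j]) for j, k in enumerate(types)},
        cells_influx={
            k: float(subject.influx_per_min.get(k, 0.0) * t_end) for k in types
        },
        cells_start={k: float(n0[j]) for j, k in enumerate(types)},
        cells_end={k: float(y[j]) for j, k in enumerate(types)},
    )


# ---------------------------------------------------------------------------
# Apheresis estimators on simulated (or measured) runs
# ---------------------------------------------------------------------------

def cr_timepoint(c_ret_t: float, mean_c_fil: float) -> float:
    """Concentration ratio of one retentate aliquot: C_ret_t over the mean
    filtrate concentration of the period."""
    if mean_c_fil <= 0:
        raise ValueError(f"mean filtrate concentration must be positive, got {mean_c_fil}")
    return c_ret_t / mean_c_fil


def cr_timepoint_mean(
    run: RecirculationRun, cell_type: str, denominator: str = "filtrate"
) -> float:
    """Run-level concentration ratio: mean over retentate epochs.

    ``denominator="filtrate"`` uses the run-mean filtrate concentration;
    ``denominator="circulating"`` uses the circulating concentration at each
    epoch midpoint (the contemporaneous-blood variant, which stays finite
    even at CE = 100% when the filtrate carries no cells).
    """
    sub = run.retentate_aliquots[run.retentate_aliquots["type"] == cell_type]
    if sub.empty:
        raise ValueError(f"no retentate aliquots for {cell_type!r}")
    if denominator == "filtrate":
        return float(
            np.mean([cr_timepoint(c, run.filtrate_mean_conc[cell_type]) for c in sub["c_ret_per_ul"]])
        )
    if denominator == "circulating":
        series = run.concentrations[run.concentrations["type"] == cell_type]
        ratios = []
        for _, row in sub.iterrows():
            mid = 0.5 * (row["epoch_start_min"] + row["epoch_end_min"])
            c_circ = float(np.interp(mid, series["time_min"], series["conc_per_ul"]))
            ratios.append(row["c_ret_per_ul"] / c_circ)
        return float(np.mean(ratios))
    raise ValueError(f"unknown denominator {denominator!r}")


def ce_invivo(run: RecirculationRun, cell_type: str) -> float:
    """Whole-run collection efficiency estimator (fraction, not percent):

        Σ(C_ret_t · V_ret_t) / ((C_pre + C_post)/2 · V_proc)

    The numerator is the cells recovered in the serial retentate aliquots;
    the denominator estimates the cells presented to the device from the
    trapezoid of the pre/post circulating concentrations and the processed
    volume.  Multiply by 100 for percent.
    """
    if run.v_proc_ml <= 0:
        raise ValueError("no blood processed")
    sub = run.retentate_aliquots[run.retentate_aliquots["type"] == cell_type]
    if sub.empty:
        raise ValueError(f"no retentate aliquots for {cell_type!r}")
    collected = float((sub["c_ret_per_ul"] * sub["v_ret_ml"]).sum())
    mean_c = 0.5 * (run.c_pre[cell_type] + run.c_post[cell_type])
    return collected / (mean_c * run.v_proc_ml)


def final_percent_and_ratios(run: RecirculationRun) -> dict:
    """Final counts as a percent of baseline, and the loss ratios
    WBC%:RBC% and PLT%:RBC% (a ratio < 1 means the numerator type lost
    proportionally more than RBC)."""
    final_pct = {}
    for k in run.types:
        if run.c_pre[k] <= 0:
            raise ValueError(f"zero baseline concentration for {k!r}")
        final_pct[k] = 100.0 * run.c_post[k] / run.c_pre[k]
    wbc_names = [k for k in run.types if k in WBC_TYPES]
    ratios = {}
    if "RBC" in run.types:
        rbc_pct = final_pct["RBC"]
        if wbc_names:
            wbc_pre = sum(run.c_pre[k] for k in wbc_names)
            wbc_post = sum(run.c_post[k] for k in wbc_names)
            ratios["WBC:RBC"] = (100.0 * wbc_post / wbc_pre) / rbc_pct
        if "PLT" in run.types:
            ratios["PLT:RBC"] = final_pct["PLT"] / rbc_pct
    return {"final_percent": final_pct, "ratios": ratios}
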