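"""Clinical apheresis bookkeeping: blood volumes, processing rates, ECV.

Estimated total blood volume (eTBV) uses the 70 mL/kg convention for every
species handled here (configurable).  Processed volume is expressed in eTBV
units — (inlet volume − anticoagulant volume) / eTBV — and the
extracorporeal volume (ECV) of a circuit as a percentage of eTBV, the number
that decides whether a small patient can be connected safely.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ETBV_ML_PER_KG",
    "ApheresisProcedure",
    "etbv",
    "etbv_processed",
    "processing_rate",
    "ecv_fraction",
]

ETBV_ML_PER_KG = 70.0


def etbv(weight_kg: float, ml_per_kg: float = ETBV_ML_PER_KG) -> float:
    """Estimated total blood volume, mL (70 mL per kg body weight)."""
    if weight_kg <= 0:
        raise ValueError(f"weight must be positive, got {weight_kg}")
    return ml_per_kg * weight_kg


@dataclass(frozen=True)
class ApheresisProcedure:
    """One procedure's volume ledger (mL, kg, min)."""

    inlet_flow_volume_ml: float
    anticoagulation_flow_volume_ml: float
    patient_weight_kg: float
    circuit_ecv_ml: float = 0.0
    duration_min: float | None = None

    def __post_init__(self):
        if self.anticoagulation_flow_volume_ml < 0:
            raise ValueError("anticoagulation volume must be >= 0")
        if self.inlet_flow_volume_ml < self.anticoagulation_flow_volume_ml:
            raise ValueError("inlet volume must be >= anticoagulation volume")
        if self.patient_weight_kg <= 0:
            raise ValueError("weight must be positive")


def etbv_processed(proc: ApheresisProcedure) -> float:
    """Blood volume processed, in eTBV units:
    (inlet volume − anticoagulant volume) / eTBV."""
    net = proc.inlet_flow_volume_ml - proc.anticoagulation_flow_volume_ml
    return net / etbv(proc.patient_weight_kg)


def processing_rate(proc: ApheresisProcedure) -> float:
    """Processing rate in eTBV per hour (requires ``duration_min``)."""
    if proc.duration_min is None or proc.duration_min <= 0:
        raise ValueError("procedure duration required for a rate")
    return etbv_processed(proc) / (proc.duration_min / 60.0)


def ecv_fraction(circuit_ecv_ml: float, weight_kg: float) -> float:
    """Circuit extracorporeal volume as a percent of the patient's eTBV."""
    if circuit_ecv_ml <= 0:
        raise ValueError(f"circuit ECV must be positive, got {circuit_ecv_ml}")
    return 100.0 * circuit_ecv_ml / etbv(weight_kg)
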