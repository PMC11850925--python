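"""Reproducible synthetic blood samples and ready-to-run protocol templates.

Everything here is generated, seeded data: CBC-style whole-blood samples for
healthy humans and rats, leukemic-blast-spiked blood (MV-4-11-like cells), a
hyperleukocytosis preset, and the protocol templates for the rat
extracorporeal runs and a hypothetical multiplexed pediatric procedure.

Concentration means and diameter distributions are literature-informed
package defaults chosen to be physiologically realistic; they are fixture
parameters, not measurements.  Diameters are log-normal per type; WBC
subtype concentrations are constructed to sum exactly to the drawn WBC
total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .blood import BloodSample, CellPopulation
from .multiplex import DeviceArray
from .recirculation import RecirculationProtocol

__all__ = [
    "FixtureSpec",
    "ProtocolTemplate",
    "make_blood",
    "human_blood",
    "rat_blood",
    "spiked_blood",
    "hyperleukocytosis_blood",
    "make_protocol_templates",
]

# mean diameters (µm); RBC uses an effective (sphered) diameter
_HUMAN_DIAMETERS = {
    "RBC": 5.5,
    "PLT": 2.5,
    "LYM": 7.5,
    "PMN": 8.5,
    "MON": 9.5,
    "EOS": 9.0,
    "BLAST": 10.5,
}
# in rats EOS and PMN are the two largest WBC subtypes
_RAT_DIAMETERS = {
    "RBC": 5.0,
    "PLT": 2.3,
    "LYM": 7.0,
    "MON": 8.5,
    "PMN": 9.5,
    "EOS": 10.0,
}

_HUMAN_MEANS = {"RBC": 5.0e6, "PLT": 2.5e5, "WBC": 7.0e3}
_HUMAN_DIFFERENTIAL = {"PMN": 0.60, "LYM": 0.30, "MON": 0.07, "EOS": 0.03}
# rats run a lymphocyte-dominant differential and higher platelet counts
_RAT_MEANS = {"RBC": 7.0e6, "PLT": 8.0e5, "WBC": 8.0e3}
_RAT_DIFFERENTIAL = {"LYM": 0.72, "PMN": 0.20, "MON": 0.05, "EOS": 0.03}

# sanity bounds (cells/µL) enforced on drawn concentrations
_BOUNDS = {"RBC": (1.0e6, 1.5e7), "PLT": (1.0e4, 3.0e6), "WBC": (5.0e2, 5.0e5)}

HYPERLEUKOCYTOSIS_WBC_PER_UL = 1.0e5  # definition: WBC above this count


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters for one synthetic blood sample.  ``seed`` is mandatory."""

    seed: int
    species: str = "human"
    volume_ul: float = 1000.0
    concentration_means: dict = field(default_factory=dict)  # RBC/PLT/WBC
    wbc_differential: dict = field(default_factory=dict)
    diameter_means: dict = field(default_factory=dict)
    diameter_cv: float = 0.10
    concentration_cv: float = 0.10  # log-normal donor-to-donor noise
    hematocrit: float = 0.45
    spike_blast_per_ul: float | None = None

    def resolved(self) -> tuple[dict, dict, dict]:
        if self.species == "human":
            means = {**_HUMAN_MEANS, **self.concentration_means}
            diff = self.wbc_differential or dict(_HUMAN_DIFFERENTIAL)
            diam = {**_HUMAN_DIAMETERS, **self.diameter_means}
        elif self.species == "rat":
            means = {**_RAT_MEANS, **self.concentration_means}
            diff = self.wbc_differential or dict(_RAT_DIFFERENTIAL)
            diam = {**_RAT_DIAMETERS, **self.diameter_means}
        else:
            raise ValueError(f"unknown species {self.species!r}")
        total = sum(diff.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"WBC differential must sum to 1, got {total}")
        return means, diff, diam


def make_blood(spec: FixtureSpec) -> BloodSample:
    """Draw one blood sample from a fixture spec; reproducible per seed."""
    means, diff, diam = spec.resolved()
    rng = np.random.default_rng(spec.seed)
    sigma = np.sqrt(np.log1p(spec.concentration_cv**2))
    drawn = {}
    for key in ("RBC", "PLT", "WBC"):
        c = means[key] * np.exp(rng.normal(-sigma**2 / 2.0, sigma))
        lo, hi = _BOUNDS[key]
        if not lo <= means[key] <= hi:
            raise ValueError(
                f"{key} mean {means[key]:g}/µL outside physiologic bounds [{lo:g}, {hi:g}]"
            )
        drawn[key] = float(np.clip(c, lo, hi))
    pops = [
        CellPopulation("RBC", drawn["RBC"], diam["RBC"], spec.diameter_cv),
        CellPopulation("PLT", drawn["PLT"], diam["PLT"], spec.diameter_cv),
    ]
    # subtypes partition the drawn WBC total exactly
    for name, frac in diff.items():
        pops.append(CellPopulation(name, drawn["WBC"] * frac, diam[name], spec.diameter_cv))
    if spec.spike_blast_per_ul is not None:
        if spec.spike_blast_per_ul < 0:
            raise ValueError("spike concentration must be >= 0")
        pops.append(
            CellPopulation(
                "BLAST",
                spec.spike_blast_per_ul,
                diam.get("BLAST", _HUMAN_DIAMETERS["BLAST"]),
                spec.diameter_cv,
            )
        )
    return BloodSample(populations=tuple(pops), volume=spec.volume_ul, species=spec.species)


def human_blood(seed: int, volume_ul: float = 1000.0, **kw) -> BloodSample:
    """Healthy human whole blood."""
    return make_blood(FixtureSpec(seed=seed, species="human", volume_ul=volume_ul, **kw))


def rat_blood(seed: int, volume_ul: float = 1000.0, **kw) -> BloodSample:
    """Healthy rat whole blood (lymphocyte-dominant differential; EOS and
    PMN are the two largest WBC)."""
    return make_blood(FixtureSpec(seed=seed, species="rat", volume_ul=volume_ul, **kw))


def spiked_blood(seed: int, blast_per_ul: float = 100.0, volume_ul: float = 1000.0) -> BloodSample:
    """Human whole blood spiked with cultured leukemic blasts (MV-4-11-like,
    ~10.5 µm).  The spiked concentration after mixing is a configurable
    fixture default; the culture stock itself is 1×10⁶ cells/mL in PBS."""
    return make_blood(
        FixtureSpec(seed=seed, species="human", volume_ul=volume_ul, spike_blast_per_ul=blast_per_ul)
    )


def hyperleukocytosis_blood(
    seed: int, wbc_per_ul: float = 2.0e5, blast_fraction: float = 0.9, volume_ul: float = 1000.0
) -> BloodSample:
    """Leukemic hyperleukocytosis: WBC above 1×10⁵/µL, dominated by blasts."""
    if wbc_per_ul <= HYPERLEUKOCYTOSIS_WBC_PER_UL:
        raise ValueError(
            f"hyperleukocytosis requires WBC > {HYPERLEUKOCYTOSIS_WBC_PER_UL:g}/µL"
        )
    normal = 1.0 - blast_fraction
    diff = {
        "BLAST": blast_fraction,
        "PMN": 0.60 * normal,
        "LYM": 0.30 * normal,
        "MON": 0.07 * normal,
        "EOS": 0.03 * normal,
    }
    return make_blood(
        FixtureSpec(
            seed=seed,
            species="human",
            volume_ul=volume_ul,
            concentration_means={"WBC": wbc_per_ul},
            wbc_differential=diff,
        )
    )


# ---------------------------------------------------------------------------
# Protocol templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProtocolTemplate:
    """A named, ready-to-run recirculation setup."""

    name: str
    subject_weight_kg: float
    species: str
    protocol: RecirculationProtocol
    device_array: DeviceArray | None = None
    demargination_influx: bool = False  # stress-demargination preset (PMN rise)

    @property
    def flow_ml_min(self) -> float:
        """Blood flow processed (device throughput for arrays)."""
        if self.device_array is not None:
            return self.device_array.total_flow
        return self.protocol.processed_flow_ml_min


def make_protocol_templates() -> dict[str, ProtocolTemplate]:
    """The three study setups: rat leukapheresis, rat sham, and a
    hypothetical 9 kg pediatric run on an eight-device array."""
    q15 = tuple(float(t) for t in range(15, 181, 15))
    rat_cif = ProtocolTemplate(
        name="rat_cif",
        subject_weight_kg=0.375,
        species="rat",
        protocol=RecirculationProtocol(
            duration_min=180.0,
            # filtrate return chosen so the total processed flow is ~0.448
            # mL/min (filtrate + 5% retentate withdrawal)
            circuit_flow_ml_min=0.427,
            retentate_fraction=0.05,
            sample_times_min=q15,
            sample_volume_ml=0.3,
            retentate_epoch_min=30.0,
            circuit_ecv_ml=0.736,
        ),
    )
    rat_sham = ProtocolTemplate(
        name="rat_sham",
        subject_weight_kg=0.267,
        species="rat",
        protocol=RecirculationProtocol(
            duration_min=180.0,
            circuit_flow_ml_min=0.319,
            retentate_fraction=0.0,  # resistance bridge: nothing withdrawn
            sample_times_min=q15,
            sample_volume_ml=0.3,
            retentate_epoch_min=30.0,
            circuit_ecv_ml=0.736,
        ),
        demargination_influx=True,
    )
    pediatric = ProtocolTemplate(
        name="pediatric_multiplex",
        subject_weight_kg=9.0,
        species="human",
        protocol=RecirculationProtocol(
            duration_min=60.0,
            # eight devices at 1.2 mL/min each; 9.6 mL/min total through the
            # array, of which 5% is withdrawn as retentate
            circuit_flow_ml_min=9.6 / 1.05,
            retentate_fraction=0.05,
            sample_times_min=(30.0, 60.0),
            sample_volume_ml=1.0,
            retentate_epoch_min=30.0,
            circuit_ecv_ml=4.2,
        ),
        device_array=DeviceArray(n_devices=8, per_device_flow=1.2),
    )
    return {"rat_cif": rat_cif, "rat_sham": rat_sham, "pediatric_multiplex": pediatric}
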