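"""Cell populations and CBC-style blood samples.

A :class:`BloodSample` is a small, CBC-like table: named cell types (RBC,
PLT, LYM, MON, PMN, EOS, BLAST, ...) with concentrations in cells/µL and a
diameter distribution per type.  Diameters are log-normal by default
(parameterised by the mean diameter in µm and a coefficient of variation);
``spread=0`` gives monodisperse cells, which is also the point-particle
limit used in closed-form checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["CellPopulation", "BloodSample"]


@dataclass(frozen=True)
class CellPopulation:
    """One cell type: concentration (cells/µL) and diameter distribution.

    ``diameter_mean_um`` is the arithmetic mean diameter; ``diameter_cv`` the
    coefficient of variation of the log-normal diameter distribution (0 for
    monodisperse cells).
    """

    name: str
    concentration: float
    diameter_mean_um: float
    diameter_cv: float = 0.10

    def __post_init__(self):
        if self.concentration < 0:
            raise ValueError(f"{self.name}: concentration must be >= 0")
        if self.diameter_mean_um <= 0:
            raise ValueError(f"{self.name}: mean diameter must be > 0")
        if self.diameter_cv < 0:
            raise ValueError(f"{self.name}: diameter spread must be >= 0")

    def _lognormal_params(self) -> tuple[float, float]:
        sigma2 = math.log1p(self.diameter_cv**2)
        mu = math.log(self.diameter_mean_um) - sigma2 / 2.0
        return mu, math.sqrt(sigma2)

    def sample_diameters(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw ``n`` diameters (µm)."""
        if self.diameter_cv == 0.0:
            return np.full(n, self.diameter_mean_um)
        mu, sigma = self._lognormal_params()
        return np.exp(rng.normal(mu, sigma, size=n))

    def diameter_quadrature(self, n_nodes: int = 64) -> tuple[np.ndarray, np.ndarray]:
        """Gauss–Hermite nodes/weights for integrating over the diameter
        distribution; returns (diameters µm, weights summing to 1)."""
        if self.diameter_cv == 0.0:
            return np.array([self.diameter_mean_um]), np.array([1.0])
        x, w = np.polynomial.hermite.hermgauss(n_nodes)
        mu, sigma = self._lognormal_params()
        return np.exp(mu + math.sqrt(2.0) * sigma * x), w / math.sqrt(math.pi)


@dataclass(frozen=True)
class BloodSample:
    """A blood aliquot: unique named populations, volume (µL), species tag."""

    populations: tuple[CellPopulation, ...]
    volume: float
    species: str = "human"

    def __post_init__(self):
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError(f"population names must be unique, got {names}")
        if self.volume <= 0:
            raise ValueError(f"sample volume must be positive, got {self.volume}")

    def __getitem__(self, name: str) -> CellPopulation:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.populations]

    def concentrations(self) -> dict[str, float]:
        return {p.name: p.concentration for p in self.populations}

    def with_volume(self, volume: float) -> "BloodSample":
        return replace(self, volume=volume)

    # -- CSV dialect: one row per type ---------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "type": self.names,
                "concentration_per_ul": [p.concentration for p in self.populations],
                "diameter_mean_um": [p.diameter_mean_um for p in self.populations],
                "diameter_cv": [p.diameter_cv for p in self.populations],
            }
        )

    def save(self, path, include_meta: bool = True) -> None:
        frame = self.to_frame()
        frame.attrs = {}
        with open(path, "w") as fh:
            if include_meta:
                fh.write(f"# volume_ul={self.volume} species={self.species}\n")
            frame.to_csv(fh, index=False, float_format="%.17g")

    @classmethod
    def load(cls, path) -> "BloodSample":
        volume, species = 1000.0, "human"
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                for tok in first[1:].split():
                    key, _, val = tok.partition("=")
                    if key == "volume_ul":
                        volume = float(val)
                    elif key == "species":
                        species = val
                table = pd.read_csv(fh, float_precision="round_trip")
            else:
                fh.seek(0)
                table = pd.read_csv(fh, float_precision="round_trip")
        pops = tuple(
            CellPopulation(
                name=row["type"],
                concentration=row["concentration_per_ul"],
                diameter_mean_um=row["diameter_mean_um"],
                diameter_cv=row["diameter_cv"],
            )
            for _, row in table.iterrows()
        )
        return cls(populations=pops, volume=volume, species=species)
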