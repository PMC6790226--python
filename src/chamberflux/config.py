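"""Shared domain types and run configuration for the chamber-flux pipeline.

The pipeline converts 60-second closed-chamber CO2 closure records into net
ecosystem exchange (NEE), partitions NEE into gross ecosystem exchange (GEE)
and ecosystem respiration (Reco) via light- and temperature-response models,
accounts soil/vegetation carbon and nitrogen stocks, and runs the
chronosequence statistics linking stocks to fluxes.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: Universal gas constant, J mol-1 K-1.
R_GAS = 8.314
#: Molar mass of carbon, g mol-1.
CARBON_MOLAR_MASS = 12.011
#: Zero Celsius in Kelvin.
T_ZERO_K = 273.15


@dataclass(frozen=True)
class ChamberGeometry:
    """Chamber/collar geometry used to convert concentration slopes to fluxes.

    The collar is the fixed ring delimiting the measured ecosystem patch;
    its area normalises all fluxes.  The system volume is the enclosed air
    volume of chamber plus collar headspace.
    """

    collar_diameter: float = 0.20      # m
    system_volume: float = 0.004       # m3 (chamber bowl + collar headspace)
    pressure_default: float = 76000.0  # Pa (barometric at ~2400 m a.s.l.)

    def __post_init__(self) -> None:
        for name in ("collar_diameter", "system_volume", "pressure_default"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def collar_area(self) -> float:
        """Collar area in m2, pi*(d/2)^2."""
        return math.pi * (self.collar_diameter / 2.0) ** 2


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Attributes
    ----------
    geometry : ChamberGeometry
    dead_band : float
        Seconds after chamber closure discarded while the headspace mixes.
    fit_window : float
        Seconds of data after the dead band used for the closure fit.
    co2_dilution_correction : bool
        Whether to water-correct the CO2 mole fraction before fitting.
    reference_ppfd : float
        PPFD at which NEE2000/GEE2000 are evaluated (umol m-2 s-1).
    reference_temp : float
        Reference temperature for R10 (deg C).
    carbon_molar_mass : float
        g mol-1; converts umol CO2 to g C.
    seed : int
        Recorded in every output table for provenance.
    """

    geometry: ChamberGeometry = field(default_factory=ChamberGeometry)
    dead_band: float = 20.0
    fit_window: float = 40.0
    co2_dilution_correction: bool = True
    reference_ppfd: float = 2000.0
    reference_temp: float = 10.0
    carbon_molar_mass: float = CARBON_MOLAR_MASS
    seed: int = 0
    # header mapping: canonical column name -> name used in the input file
    header_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.reference_ppfd <= 0 or self.carbon_molar_mass <= 0:
            raise ValueError("reference values must be positive")
        if self.dead_band < 0 or self.fit_window <= 0:
            raise ValueError("dead_band must be >= 0 and fit_window > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        geom = ChamberGeometry(**raw.pop("geometry", {}))
        return cls(geometry=geom, **raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        raw["geometry"] = asdict(self.geometry)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)
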