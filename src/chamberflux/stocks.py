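"""Soil and vegetation carbon/nitrogen stock accounting.

Soil cores are taken in three 5-cm layers ([0,5), [5,10), [10,15) cm,
0-based top-down).  Sample volume is measured by backfilling the hole with
plastic balls whose volume is a calibrated function of their mass.  Bulk
density is total dry mass (fine earth + stones) over sampled volume; a
component's stock (g m-2) is its dry mass times its C or N mass fraction
over the collar area, additive across components and layers.  Transect
summaries report across-plot means and n-1 sample SDs, the topsoil share
of the 0-15 cm stock held in the top layer, and the chronosequence carbon
accumulation rate between a young and an old site.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LAYERS = ((0.0, 5.0), (5.0, 10.0), (10.0, 15.0))   # cm, half-open top-down
LAYER_MIDPOINTS = (-2.5, -7.5, -12.5)              # cm, for profile plots
#: LIA glacial maximum (1860) to the 2014 sampling season.
DEFAULT_CHRONOSEQUENCE_YEARS = 154.0

#: canonical soil-core table columns
CORE_COLUMNS = [
    "plot_id", "transect_id", "layer_top", "layer_bottom",
    "wet_mass", "dry_fine_mass", "stone_dry_mass", "root_dry_mass",
    "ball_mass",
    "c_frac_fine", "c_frac_stone", "c_frac_root",
    "n_frac_fine", "n_frac_stone", "n_frac_root",
    "d13c",
]
AG_COLUMNS = ["plot_id", "transect_id", "dry_mass", "c_frac", "n_frac",
              "collar_area"]


def ball_volume(ball_mass, calibration_density: float):
    """Sample volume (cm3) from backfill-ball mass via calibration density."""
    if calibration_density <= 0:
        raise ValueError("calibration density must be positive")
    ball_mass = np.asarray(ball_mass, dtype=float)
    if np.any(ball_mass < 0):
        raise ValueError("ball mass must be non-negative")
    out = ball_mass / calibration_density
    return out.item() if out.ndim == 0 else out


def bulk_density(dry_mass, volume_cm3):
    """Dry mass (g) over volume (cm3); numerically equals kg dm-3."""
    dry_mass = np.asarray(dry_mass, dtype=float)
    volume_cm3 = np.asarray(volume_cm3, dtype=float)
    if np.any(volume_cm3 <= 0):
        raise ValueError("sample volume must be positive")
    out = dry_mass / volume_cm3
    return out.item() if out.ndim == 0 else out


def component_stock(dry_mass, frac, area):
    """Areal stock (g m-2) = dry mass (g) * mass fraction / area (m2)."""
    area = np.asarray(area, dtype=float)
    if np.any(area <= 0):
        raise ValueError("area must be positive")
    out = np.asarray(dry_mass, dtype=float) * np.asarray(frac, dtype=float) / area
    return out.item() if out.ndim == 0 else out


@dataclass(frozen=True)
class StockSummary:
    """Per-transect stock summary (means and n-1 SDs over plots, g m-2)."""

    transect_id: str
    n_plots: int
    ag_biomass: float
    ag_biomass_sd: float
    ag_c: float
    ag_c_sd: float
    ag_n: float
    ag_n_sd: float
    bg_biomass: float
    bg_biomass_sd: float
    bg_c: float
    bg_c_sd: float
    bg_n: float
    bg_n_sd: float
    soil_c: float
    soil_c_sd: float
    soil_n: float
    soil_n_sd: float
    bulk_density_by_layer: tuple      # kg dm-3, one per layer top-down
    topsoil_share_c: float            # % of 0-15 cm soil C in [0,5) cm
    topsoil_share_n: float


def plot_stocks(cores: pd.DataFrame, collar_area: float,
                calibration_density: float = 0.57,
                include_stones_in_soil: bool = True) -> pd.DataFrame:
    """Per-plot, per-layer stocks from a soil-core table.

    Soil C/N stock covers fine earth (plus stones unless excluded); roots
    are accounted separately as below-ground (BG) vegetation.
    """
    df = cores.copy()
    vol = ball_volume(df["ball_mass"].to_numpy(), calibration_density)
    total_dry = df["dry_fine_mass"].to_numpy() + df["stone_dry_mass"].to_numpy()
    df["bulk_density"] = bulk_density(total_dry, vol)
    soil_c = component_stock(df["dry_fine_mass"], df["c_frac_fine"], collar_area)
    soil_n = component_stock(df["dry_fine_mass"], df["n_frac_fine"], collar_area)
    if include_stones_in_soil:
        soil_c = soil_c + component_stock(df["stone_dry_mass"],
                                          df["c_frac_stone"], collar_area)
        soil_n = soil_n + component_stock(df["stone_dry_mass"],
                                          df["n_frac_stone"], collar_area)
    df["soil_c"] = soil_c
    df["soil_n"] = soil_n
    df["bg_biomass"] = df["root_dry_mass"] / collar_area
    df["bg_c"] = component_stock(df["root_dry_mass"], df["c_frac_root"],
                                 collar_area)
    df["bg_n"] = component_stock(df["root_dry_mass"], df["n_frac_root"],
                                 collar_area)
    return df


def transect_summary(cores: pd.DataFrame, ag: pd.DataFrame,
                     collar_area: float,
                     calibration_density: float = 0.57,
                     include_stones_in_soil: bool = True,
                     ) -> list[StockSummary]:
    """Aggregate per-plot stocks to per-transect means and sample SDs."""
    if cores.empty:
        raise ValueError("no soil cores supplied")
    per_layer = plot_stocks(cores, collar_area, calibration_density,
                            include_stones_in_soil)
    summaries = []
    for tid, g in per_layer.groupby("transect_id", sort=True):
        per_plot = g.groupby("plot_id")[
            ["soil_c", "soil_n", "bg_biomass", "bg_c", "bg_n"]].sum()
        if per_plot.empty:
            raise ValueError(f"transect {tid} has no plots")
        ag_t = ag[ag["transect_id"] == tid]
        ag_stocks = pd.DataFrame({
            "ag_biomass": ag_t["dry_mass"] / ag_t["collar_area"],
            "ag_c": component_stock(ag_t["dry_mass"], ag_t["c_frac"],
                                    ag_t["collar_area"]),
            "ag_n": component_stock(ag_t["dry_mass"], ag_t["n_frac"],
                                    ag_t["collar_area"]),
        })
        bd_by_layer = tuple(
            float(g[g["layer_top"] == top]["bulk_density"].mean())
            for top, _ in LAYERS)
        top = g[g["layer_top"] == 0.0]
        total_c = float(g["soil_c"].sum())
        total_n = float(g["soil_n"].sum())
        share_c = 100.0 * float(top["soil_c"].sum()) / total_c if total_c else float("nan")
        share_n = 100.0 * float(top["soil_n"].sum()) / total_n if total_n else float("nan")

        def ms(series):
            arr = np.asarray(series, dtype=float)
            sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
            return float(np.mean(arr)), sd

        ag_b, ag_b_sd = ms(ag_stocks["ag_biomass"]) if len(ag_stocks) else (float("nan"), float("nan"))
        ag_c, ag_c_sd = ms(ag_stocks["ag_c"]) if len(ag_stocks) else (float("nan"), float("nan"))
        ag_n, ag_n_sd = ms(ag_stocks["ag_n"]) if len(ag_stocks) else (float("nan"), float("nan"))
        summaries.append(StockSummary(
            transect_id=str(tid), n_plots=len(per_plot),
            ag_biomass=ag_b, ag_biomass_sd=ag_b_sd,
            ag_c=ag_c, ag_c_sd=ag_c_sd, ag_n=ag_n, ag_n_sd=ag_n_sd,
            bg_biomass=ms(per_plot["bg_biomass"])[0],
            bg_biomass_sd=ms(per_plot["bg_biomass"])[1],
            bg_c=ms(per_plot["bg_c"])[0], bg_c_sd=ms(per_plot["bg_c"])[1],
            bg_n=ms(per_plot["bg_n"])[0], bg_n_sd=ms(per_plot["bg_n"])[1],
            soil_c=ms(per_plot["soil_c"])[0], soil_c_sd=ms(per_plot["soil_c"])[1],
            soil_n=ms(per_plot["soil_n"])[0], soil_n_sd=ms(per_plot["soil_n"])[1],
            bulk_density_by_layer=bd_by_layer,
            topsoil_share_c=share_c, topsoil_share_n=share_n))
    return summaries


def summaries_to_frame(summaries: list[StockSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {k: v for k, v in s.__dict__.items()
               if k != "bulk_density_by_layer"}
        for (top, _), bd in zip(LAYERS, s.bulk_density_by_layer):
            row[f"bulk_density_{int(top)}_{int(top)+5}cm"] = bd
        rows.append(row)
    return pd.DataFrame(rows)


def accumulation_rate(total_c_young: float, total_c_old: float,
                      years: float = DEFAULT_CHRONOSEQUENCE_YEARS) -> float:
    """Chronosequence carbon accumulation rate, g C m-2 yr-1.

    ``total_c_*`` are configurable component sums (e.g. soil + BG, or
    soil + BG + AG) at the young and old end of the space-for-time series.
    """
    if years <= 0:
        raise ValueError("chronosequence age gap must be positive")
    return (total_c_old - total_c_young) / years
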