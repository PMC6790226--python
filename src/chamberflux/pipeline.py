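"""Stage orchestration: closure table -> fluxes -> response fits -> indices
-> daily budgets, as plain DataFrame-in/DataFrame-out functions.

These are the functions the numbered analysis drivers and the CLI call;
each stage's heavy lifting lives in the per-topic modules.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .closure import fluxes_from_series
from .config import RunConfig
from .io import ClosureSeries
from .responses import (LightResponseParams, TemperatureResponseParams,
                        daily_course, fit_light_response,
                        fit_temperature_response, indices,
                        sinusoidal_drivers)

logger = logging.getLogger("chamberflux")


def flux_table(series: list[ClosureSeries], config: RunConfig | None = None,
               ) -> pd.DataFrame:
    """Fit every closure and tabulate one flux row per closure with
    fit diagnostics (curvature, rmse, linear-fallback flag)."""
    config = config or RunConfig()
    obs, fits, kept = fluxes_from_series(series, config)
    rows = []
    for o, f, s in zip(obs, fits, kept):
        rows.append({
            "transect_id": o.transect_id, "plot_id": o.plot_id,
            "campaign": o.campaign, "filter_count": o.filter_count,
            "closure_index": s.closure_index,
            "nee": o.nee, "ppfd": o.ppfd, "tair": o.tair,
            "kappa": f.kappa, "rmse": f.rmse, "n_points": f.n_points,
            "fallback_linear": f.fallback_linear, "seed": config.seed,
        })
    return pd.DataFrame(rows)


def zero_filter_drift(fluxes: pd.DataFrame) -> pd.DataFrame:
    """Drift diagnostic: NEE change between the opening and the repeated
    closing zero-filter closure of each plot x campaign sequence.

    The repeat is measured at the same light level after the filter cycle,
    so the difference reflects chamber-induced warming or physiological
    drift, not light.
    """
    zeros = fluxes[fluxes["filter_count"] == 0]
    rows = []
    for (plot, campaign), g in zeros.groupby(["plot_id", "campaign"]):
        if g["closure_index"].nunique() < 2:
            continue
        g = g.sort_values("closure_index")
        rows.append({"plot_id": plot, "campaign": campaign,
                     "nee_first": g["nee"].iloc[0],
                     "nee_repeat": g["nee"].iloc[-1],
                     "drift": g["nee"].iloc[-1] - g["nee"].iloc[0]})
    return pd.DataFrame(rows)


def light_response_table(fluxes: pd.DataFrame,
                         group_cols: tuple = ("plot_id", "campaign"),
                         ) -> pd.DataFrame:
    """Fit the sigmoid light response per group; unidentifiable groups are
    logged and skipped."""
    rows = []
    for key, g in fluxes.groupby(list(group_cols), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        try:
            lr = fit_light_response(g)
        except ValueError as exc:
            logger.warning("light-response group %s skipped: %s", key, exc)
            continue
        row = dict(zip(group_cols, key))
        row.update({"transect_id": g["transect_id"].iloc[0],
                    "alpha_qy": lr.alpha_qy, "f_inf": lr.f_inf, "rd": lr.rd,
                    "lr_rmse": lr.rmse, "n_obs": lr.n,
                    "tair": float(g["tair"].mean()),
                    "respiration_only": lr.respiration_only})
        rows.append(row)
    return pd.DataFrame(rows)


def temperature_response_table(lr_table: pd.DataFrame,
                               group_col: str = "transect_id",
                               ) -> pd.DataFrame:
    """Fit the Arrhenius-type model per transect from the per-fit daytime
    respiration values paired with mean campaign air temperature."""
    rows = []
    for key, g in lr_table.groupby(group_col, sort=True):
        try:
            tr = fit_temperature_response(g["rd"].to_numpy(),
                                          g["tair"].to_numpy())
        except ValueError as exc:
            logger.warning("temperature-response group %s skipped: %s",
                           key, exc)
            continue
        rows.append({group_col: key, "rref": tr.rref, "e0": tr.e0,
                     "tr_rmse": tr.rmse, "n_obs": tr.n})
    return pd.DataFrame(rows)


def indices_table(lr_table: pd.DataFrame, tr_table: pd.DataFrame,
                  reference_ppfd: float = 2000.0) -> pd.DataFrame:
    """NEE2000 / GEE2000 / R10 / alpha per light-response group."""
    tr_map = tr_table.set_index("transect_id")
    rows = []
    for _, r in lr_table.iterrows():
        lr = LightResponseParams(r["alpha_qy"], r["f_inf"], r["rd"])
        tr = TemperatureResponseParams(
            float(tr_map.loc[r["transect_id"], "rref"]),
            float(tr_map.loc[r["transect_id"], "e0"]))
        ix = indices(lr, tr, reference_ppfd)
        rows.append({
            "transect_id": r["transect_id"], "plot_id": r.get("plot_id", ""),
            "campaign": r.get("campaign", ""),
            "nee2000": ix.nee2000, "gee2000": ix.gee2000,
            "r10": ix.r10, "alpha_qy": ix.alpha_qy,
        })
    return pd.DataFrame(rows)


def daily_budget_table(lr_table: pd.DataFrame, tr_table: pd.DataFrame,
                       steps_per_day: int = 48,
                       peak_ppfd: float = 1800.0) -> pd.DataFrame:
    """Mean daily NEE/GEE/Reco budgets (g C m-2 day-1).

    Light-response groups are averaged to transect x campaign parameter
    sets, driven through one idealised sinusoidal diurnal cycle whose
    temperature is centred on the group's mean campaign air temperature.
    """
    tr_map = tr_table.set_index("transect_id")
    rows = []
    grouped = lr_table.groupby(["transect_id", "campaign"], sort=True)
    for (tid, campaign), g in grouped:
        lr = LightResponseParams(float(g["alpha_qy"].mean()),
                                 float(g["f_inf"].mean()),
                                 float(g["rd"].mean()))
        tr = TemperatureResponseParams(float(tr_map.loc[tid, "rref"]),
                                       float(tr_map.loc[tid, "e0"]))
        ppfd, tair = sinusoidal_drivers(steps_per_day, peak_ppfd=peak_ppfd,
                                        t_mean=float(g["tair"].mean()))
        d = daily_course(lr, tr, ppfd, tair, transect_id=tid,
                         campaign=campaign)
        rows.append({"transect_id": tid, "campaign": campaign,
                     "nee_daily": d.nee, "gee_daily": d.gee,
                     "reco_daily": d.reco})
    return pd.DataFrame(rows)


def transect_daily_means(daily: pd.DataFrame) -> pd.DataFrame:
    """Across-campaign mean and n-1 SD of the daily budgets per transect."""
    out = daily.groupby("transect_id")[
        ["nee_daily", "gee_daily", "reco_daily"]].agg(["mean", "std"])
    out.columns = ["_".join(c) for c in out.columns]
    return out.reset_index()
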