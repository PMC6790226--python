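"""Seeded generators for every input the pipeline consumes.

The generators emulate the field design of a glacier-forefield
chronosequence study: three transects (T1 young/glacier, T2 intermediate/
LIA moraine, T3 old/conoid), five collared plots per transect, three
monthly campaigns, and per plot a shading-filter sequence of 11 light
levels plus a repeated zero-filter closure (12 closures).  Every generator
is a pure function of (spec, seed), and each output table has a truth
sidecar so downstream estimates can be scored without re-deriving truth.

Default parameter magnitudes are centred on values typical of sparsely to
fully vegetated alpine forefield sites (daily NEE of -1 to -8 g C m-2
day-1, soil C stocks of tens to hundreds of g m-2); they are defaults, not
ground truth about any particular site.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import ChamberGeometry, RunConfig, R_GAS, T_ZERO_K
from .responses import (LightResponseParams, TemperatureResponseParams,
                        nee_model, reco_model)

CAMPAIGNS = ("July", "August", "September")
FILTER_SEQUENCE = (0, 1, 2, 3, 4, 5, 6, 7, 9, 11, 0)   # final 0 = drift check
N_PLOTS = 5
LAYER_TOPS = (0.0, 5.0, 10.0)
LAYER_THICKNESS_CM = 5.0


@dataclass(frozen=True)
class TransectTruth:
    """True parameters of one transect."""

    transect_id: str
    # light response per campaign: campaign -> (alpha_qy, f_inf)
    light: dict
    # temperature response
    rref: float
    e0: float
    # campaign mean air temperature, deg C
    tair: dict
    # ambient (outside-filter) PPFD per campaign, umol m-2 s-1
    ppfd_ambient: dict
    # soil profile
    soil_c: float                  # g m-2, 0-15 cm target
    soil_n: float                  # g m-2
    c_shares: tuple                # per-layer share of soil C, sums to 1
    n_shares: tuple
    bulk_density: tuple            # kg dm-3 per layer, top-down increasing
    stone_share: float             # of total dry mass
    # vegetation
    root_biomass: float            # g m-2
    root_depth_shares: tuple
    root_c_frac: float
    root_n_frac: float
    ag_biomass: float              # g m-2
    ag_c_frac: float
    ag_n_frac: float


def _default_transects() -> tuple:
    return (
        TransectTruth(
            transect_id="T1",
            light={"July": (0.004, -2.0), "August": (0.006, -3.0),
                   "September": (0.008, -5.0)},
            rref=0.9, e0=250.0,
            tair={"July": 11.5, "August": 13.6, "September": 6.2},
            ppfd_ambient={"July": 1650.0, "August": 1550.0, "September": 1250.0},
            soil_c=40.0, soil_n=22.0,
            c_shares=(0.700, 0.19, 0.11), n_shares=(0.546, 0.28, 0.174),
            bulk_density=(1.42, 1.70, 1.99), stone_share=0.30,
            root_biomass=58.0, root_depth_shares=(0.6, 0.3, 0.1),
            root_c_frac=0.41, root_n_frac=0.006,
            ag_biomass=207.0, ag_c_frac=0.32, ag_n_frac=0.0072),
        TransectTruth(
            transect_id="T2",
            light={"July": (0.030, -11.5), "August": (0.028, -11.0),
                   "September": (0.033, -12.0)},
            rref=3.6, e0=310.0,
            tair={"July": 12.5, "August": 13.0, "September": 9.9},
            ppfd_ambient={"July": 1700.0, "August": 1550.0, "September": 1300.0},
            soil_c=557.0, soil_n=58.0,
            c_shares=(0.446, 0.33, 0.224), n_shares=(0.445, 0.33, 0.225),
            bulk_density=(0.66, 1.30, 1.84), stone_share=0.10,
            root_biomass=1774.0, root_depth_shares=(0.6, 0.3, 0.1),
            root_c_frac=0.425, root_n_frac=0.0113,
            ag_biomass=1753.0, ag_c_frac=0.43, ag_n_frac=0.0137),
        TransectTruth(
            transect_id="T3",
            light={"July": (0.026, -10.0), "August": (0.024, -10.0),
                   "September": (0.028, -9.5)},
            rref=3.5, e0=330.0,
            tair={"July": 13.5, "August": 16.8, "September": 10.4},
            ppfd_ambient={"July": 1700.0, "August": 1550.0, "September": 1300.0},
            soil_c=384.0, soil_n=59.0,
            c_shares=(0.613, 0.25, 0.137), n_shares=(0.550, 0.28, 0.170),
            bulk_density=(0.63, 1.30, 1.94), stone_share=0.10,
            root_biomass=2062.0, root_depth_shares=(0.6, 0.3, 0.1),
            root_c_frac=0.465, root_n_frac=0.0099,
            ag_biomass=1095.0, ag_c_frac=0.51, ag_n_frac=0.010),
    )


@dataclass(frozen=True)
class ScenarioSpec:
    """Study-design scenario with true parameters and noise levels."""

    transects: tuple = field(default_factory=_default_transects)
    geometry: ChamberGeometry = field(default_factory=ChamberGeometry)
    n_plots: int = N_PLOTS
    filter_transmission: float = 0.7     # per-filter PPFD fraction
    plot_cv: float = 0.15                # between-plot lognormal CV on params
    closure_noise: float = 0.3           # sigma_c, umol mol-1 on CO2 samples
    flux_noise: float = 0.5              # sigma_f, umol m-2 s-1 on NEE
    assay_cv: float = 0.10               # CV of C/N concentration assays
    kappa_range: tuple = (0.005, 0.02)   # s-1, closure curvature draw
    h2o_mean: float = 8.0                # mmol mol-1 water vapour
    ambient_co2: float = 415.0           # umol mol-1 dry
    calibration_density: float = 0.57    # g cm-3, backfill-ball calibration
    seed: int = 0

    def noise_free(self) -> "ScenarioSpec":
        return replace(self, closure_noise=0.0, flux_noise=0.0, assay_cv=0.0)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv <= 0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size)


def _plot_params(spec: ScenarioSpec, rng: np.random.Generator):
    """Draw per-plot true parameters once (between-plot heterogeneity)."""
    out = {}
    for tr in spec.transects:
        for i in range(spec.n_plots):
            plot_id = f"{tr.transect_id}-C{i + 1}"
            f_alpha = _lognormal_factor(rng, spec.plot_cv)
            f_finf = _lognormal_factor(rng, spec.plot_cv)
            f_resp = _lognormal_factor(rng, spec.plot_cv)
            light = {c: (a * f_alpha, f * f_finf)
                     for c, (a, f) in tr.light.items()}
            out[plot_id] = {
                "transect": tr,
                "light": light,
                "rref": tr.rref * f_resp,
                "e0": tr.e0,
            }
    return out


def _true_flux(plot: dict, campaign: str, ppfd_in: float, tair: float):
    """True NEE and its components at the given drivers.

    Respiration follows the plot's temperature response (the light-model
    Rd is tied to it, so the two models are mutually consistent).
    """
    tr_params = TemperatureResponseParams(plot["rref"], plot["e0"])
    rd = reco_model(tr_params, tair)
    alpha, f_inf = plot["light"][campaign]
    lr = LightResponseParams(alpha, f_inf, rd)
    return float(nee_model(lr, ppfd_in)), lr, tr_params


def gen_closures(spec: ScenarioSpec, seed: int | None = None,
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the long-format closure table and its truth sidecar.

    Each closure is a 61-sample 1-Hz record.  The underlying flux is the
    sigmoid light response (with temperature-consistent respiration) at the
    transmitted PPFD, inverted through the chamber ideal-gas mass balance
    to a concentration slope at the start of the fit window, then bent into
    an exponential closure curve with curvature drawn from ``kappa_range``
    and Gaussian sample noise ``closure_noise`` added on the wet mole
    fraction.  Filter transmission is geometric: PPFD_in = PPFD_out * tau^k.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    plots = _plot_params(spec, rng)
    geom = spec.geometry
    dead_band = 20.0
    t = np.arange(61.0)
    rows, truth_rows = [], []
    for plot_id, plot in plots.items():
        tr = plot["transect"]
        for campaign in CAMPAIGNS:
            tair = tr.tair[campaign]
            ppfd_out = tr.ppfd_ambient[campaign]
            for seq, n_filters in enumerate(FILTER_SEQUENCE):
                ppfd_in = ppfd_out * spec.filter_transmission ** n_filters
                nee, lr, tr_params = _true_flux(plot, campaign, ppfd_in, tair)
                kappa = rng.uniform(*spec.kappa_range)
                n_air = (geom.pressure_default * geom.system_volume
                         / (R_GAS * (tair + T_ZERO_K)))
                slope0 = nee * geom.collar_area / n_air   # umol mol-1 s-1
                c_at_t0 = spec.ambient_co2 + rng.normal(0.0, 2.0)
                cx = c_at_t0 + slope0 / kappa
                co2_dry = cx + (c_at_t0 - cx) * np.exp(-kappa * (t - dead_band))
                h2o = spec.h2o_mean
                co2_wet = co2_dry * (1.0 - h2o / 1000.0)
                co2_wet = co2_wet + rng.normal(0.0, spec.closure_noise, t.size)
                rows.append(pd.DataFrame({
                    "plot_id": plot_id, "transect_id": tr.transect_id,
                    "campaign": campaign, "filter_count": n_filters,
                    "t": t, "co2_wet": co2_wet, "h2o": h2o,
                    "ppfd_in": ppfd_in, "ppfd_out": ppfd_out, "tair": tair,
                    "pressure": geom.pressure_default,
                }))
                truth_rows.append({
                    "plot_id": plot_id, "transect_id": tr.transect_id,
                    "campaign": campaign, "filter_count": n_filters,
                    "sequence_index": seq, "true_nee": nee,
                    "true_kappa": kappa, "true_slope": slope0,
                    "true_alpha": lr.alpha_qy, "true_f_inf": lr.f_inf,
                    "true_rd": lr.rd, "true_rref": tr_params.rref,
                    "true_e0": tr_params.e0, "ppfd_in": ppfd_in, "tair": tair,
                })
    return pd.concat(rows, ignore_index=True), pd.DataFrame(truth_rows)


def gen_flux_observations(spec: ScenarioSpec, seed: int | None = None,
                          ) -> pd.DataFrame:
    """Fast path: NEE observations from the response models directly.

    One row per plot x campaign x filter level with Gaussian ``flux_noise``
    on NEE; true parameters and the true (noise-free) NEE travel alongside
    in ``true_*`` columns.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    plots = _plot_params(spec, rng)
    rows = []
    for plot_id, plot in plots.items():
        tr = plot["transect"]
        for campaign in CAMPAIGNS:
            tair = tr.tair[campaign]
            ppfd_out = tr.ppfd_ambient[campaign]
            for seq, n_filters in enumerate(FILTER_SEQUENCE):
                ppfd_in = ppfd_out * spec.filter_transmission ** n_filters
                nee, lr, tr_params = _true_flux(plot, campaign, ppfd_in, tair)
                rows.append({
                    "plot_id": plot_id, "transect_id": tr.transect_id,
                    "campaign": campaign, "filter_count": n_filters,
                    "sequence_index": seq,
                    "nee": nee + rng.normal(0.0, spec.flux_noise),
                    "ppfd": ppfd_in, "tair": tair,
                    "true_nee": nee, "true_alpha": lr.alpha_qy,
                    "true_f_inf": lr.f_inf, "true_rd": lr.rd,
                    "true_rref": tr_params.rref, "true_e0": tr_params.e0,
                })
    return pd.DataFrame(rows)


def gen_soil_cores(spec: ScenarioSpec, seed: int | None = None,
                   ) -> pd.DataFrame:
    """Layered soil-core samples: C/N decaying and bulk density increasing
    with depth; multiplicative lognormal assay noise on concentrations."""
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    area_cm2 = spec.geometry.collar_area * 1e4
    vol = area_cm2 * LAYER_THICKNESS_CM            # cm3 per layer
    rows = []
    for tr in spec.transects:
        for i in range(spec.n_plots):
            plot_id = f"{tr.transect_id}-C{i + 1}"
            for li, top in enumerate(LAYER_TOPS):
                dry_total = tr.bulk_density[li] * vol   # g (kg dm-3 == g cm-3)
                stone = tr.stone_share * dry_total
                fine = dry_total - stone
                c_layer = tr.soil_c * tr.c_shares[li] * spec.geometry.collar_area
                n_layer = tr.soil_n * tr.n_shares[li] * spec.geometry.collar_area
                c_frac = (c_layer / fine) * _lognormal_factor(rng, spec.assay_cv)
                n_frac = (n_layer / fine) * _lognormal_factor(rng, spec.assay_cv)
                root = (tr.root_biomass * tr.root_depth_shares[li]
                        * spec.geometry.collar_area)
                rows.append({
                    "plot_id": plot_id, "transect_id": tr.transect_id,
                    "layer_top": top, "layer_bottom": top + LAYER_THICKNESS_CM,
                    "wet_mass": dry_total * 1.18, "dry_fine_mass": fine,
                    "stone_dry_mass": stone, "root_dry_mass": root,
                    "ball_mass": vol * spec.calibration_density,
                    "c_frac_fine": float(c_frac), "c_frac_stone": 0.0,
                    "c_frac_root": tr.root_c_frac
                    * float(_lognormal_factor(rng, spec.assay_cv)),
                    "n_frac_fine": float(n_frac), "n_frac_stone": 0.0,
                    "n_frac_root": tr.root_n_frac
                    * float(_lognormal_factor(rng, spec.assay_cv)),
                    "d13c": -26.0 + rng.normal(0.0, 0.5),
                })
    return pd.DataFrame(rows)


def gen_aboveground(spec: ScenarioSpec, seed: int | None = None,
                    ) -> pd.DataFrame:
    """Above-ground biomass harvested per collar, with assay noise."""
    rng = np.random.default_rng(spec.seed + 2 if seed is None else seed)
    area = spec.geometry.collar_area
    rows = []
    for tr in spec.transects:
        for i in range(spec.n_plots):
            rows.append({
                "plot_id": f"{tr.transect_id}-C{i + 1}",
                "transect_id": tr.transect_id,
                "dry_mass": tr.ag_biomass * area
                * float(_lognormal_factor(rng, spec.assay_cv)),
                "c_frac": tr.ag_c_frac
                * float(_lognormal_factor(rng, spec.assay_cv)),
                "n_frac": tr.ag_n_frac
                * float(_lognormal_factor(rng, spec.assay_cv)),
                "collar_area": area,
            })
    return pd.DataFrame(rows)


def light_recovery_study(n_replicates: int = 500, sigma_f: float = 0.5,
                         alpha: float = 0.03, f_inf: float = -11.0,
                         rd: float = 4.0, ppfd_ambient: float = 1600.0,
                         tau: float = 0.7, seed: int = 0) -> dict:
    """Median relative recovery errors of (alpha, Finf, Rd) over seeded
    replicates of the 11-closure shading-filter design with Gaussian flux
    noise ``sigma_f``."""
    from .responses import fit_light_response
    rng = np.random.default_rng(seed)
    truth = LightResponseParams(alpha, f_inf, rd)
    ppfd = ppfd_ambient * tau ** np.array(FILTER_SEQUENCE, dtype=float)
    nee_true = nee_model(truth, ppfd)
    errs = {"alpha_qy": [], "f_inf": [], "rd": []}
    for _ in range(n_replicates):
        obs = pd.DataFrame({"nee": nee_true + rng.normal(0, sigma_f, ppfd.size),
                            "ppfd": ppfd})
        fit = fit_light_response(obs)
        errs["alpha_qy"].append(abs(fit.alpha_qy - alpha) / abs(alpha))
        errs["f_inf"].append(abs(fit.f_inf - f_inf) / abs(f_inf))
        errs["rd"].append(abs(fit.rd - rd) / abs(rd))
    return {k: float(np.median(v)) for k, v in errs.items()}


def temperature_recovery_study(n_replicates: int = 500, sigma_f: float = 0.5,
                               rref: float = 3.6, e0: float = 310.0,
                               t_range: tuple = (5.0, 17.0), n_obs: int = 15,
                               seed: int = 0) -> dict:
    """Median relative recovery errors of (Rref, E0) over seeded replicates
    of an ``n_obs``-point respiration series spanning ``t_range`` degC."""
    from .responses import fit_temperature_response
    rng = np.random.default_rng(seed)
    truth = TemperatureResponseParams(rref, e0)
    tair = np.linspace(*t_range, n_obs)
    reco_true = reco_model(truth, tair)
    errs = {"rref": [], "e0": []}
    for _ in range(n_replicates):
        reco = reco_true + rng.normal(0, sigma_f, tair.size)
        reco = np.clip(reco, 1e-3, None)
        fit = fit_temperature_response(reco, tair)
        errs["rref"].append(abs(fit.rref - rref) / rref)
        errs["e0"].append(abs(fit.e0 - e0) / e0)
    return {k: float(np.median(v)) for k, v in errs.items()}


def closure_recovery_study(n_closures: int = 1000, sigma_c: float = 0.3,
                           seed: int = 0) -> dict:
    """Closure-fit recovery under sample noise: median relative curvature
    error and median relative flux (initial-slope) error over synthetic
    exponential closures with curvature and slope drawn from the scenario
    defaults."""
    from .closure import fit_closure, initial_slope
    from .io import ClosureSeries
    rng = np.random.default_rng(seed)
    spec = ScenarioSpec()
    geom = spec.geometry
    n_air = (geom.pressure_default * geom.system_volume
             / (R_GAS * (10.0 + T_ZERO_K)))
    t = np.arange(61.0)
    kappa_errs, flux_errs = [], []
    for i in range(n_closures):
        kappa = rng.uniform(*spec.kappa_range)
        # drawdown slope of a 1-12 umol m-2 s-1 uptake flux in this chamber
        nee = rng.uniform(-12.0, -1.0)
        slope0 = nee * geom.collar_area / n_air   # umol mol-1 s-1
        c0 = spec.ambient_co2 + rng.normal(0, 2)
        cx = c0 + slope0 / kappa
        co2 = cx + (c0 - cx) * np.exp(-kappa * (t - 20.0))
        co2 += rng.normal(0, sigma_c, t.size)
        s = ClosureSeries(plot_id=f"P{i}", transect_id="T", campaign="July",
                          filter_count=0, closure_index=0, t=t, co2_wet=co2,
                          h2o=np.zeros_like(t), tair=np.full_like(t, 10.0),
                          ppfd_in=np.zeros_like(t), ppfd_out=np.zeros_like(t))
        fit = fit_closure(s)
        if not fit.fallback_linear:
            kappa_errs.append(abs(fit.kappa - kappa) / kappa)
        flux_errs.append((initial_slope(fit) - slope0) / abs(slope0))
    return {"kappa_median_rel_err": float(np.median(kappa_errs)),
            "flux_median_rel_err": float(np.median(np.abs(flux_errs))),
            "flux_bias": float(np.mean(flux_errs)),
            "n_fallback": n_closures - len(kappa_errs)}


def gen_statistics_table(spec: ScenarioSpec, seed: int | None = None,
                         ) -> pd.DataFrame:
    """Merged per-plot x campaign table for the statistical layer.

    Response columns (nee2000, gee2000, r10) come from the per-plot true
    response models plus flux noise; stock predictors come from the soil
    and vegetation generators aggregated per plot.  This is the synthetic
    counterpart of the merged fluxes-plus-stocks analysis table.
    """
    base = spec.seed + 3 if seed is None else seed
    rng = np.random.default_rng(base)
    plots = _plot_params(spec, rng)
    cores = gen_soil_cores(spec, base + 1)
    ag = gen_aboveground(spec, base + 2)
    from .stocks import plot_stocks
    per_layer = plot_stocks(cores, spec.geometry.collar_area,
                            spec.calibration_density)
    per_plot = per_layer.groupby("plot_id")[
        ["soil_c", "soil_n", "bg_biomass", "bg_c", "bg_n"]].sum()
    ag = ag.set_index("plot_id")
    rows = []
    for plot_id, plot in plots.items():
        tr = plot["transect"]
        for campaign in CAMPAIGNS:
            tair = tr.tair[campaign]
            nee, lr, tr_params = _true_flux(plot, campaign, 2000.0, tair)
            nee2000 = nee + rng.normal(0.0, spec.flux_noise)
            rows.append({
                "plot_id": plot_id, "transect_id": tr.transect_id,
                "campaign": campaign,
                "nee2000": nee2000, "gee2000": nee2000 - lr.rd,
                "r10": plot["rref"]
                * float(_lognormal_factor(rng, spec.assay_cv)),
                "tair": tair,
                "ag_biomass": float(ag.loc[plot_id, "dry_mass"]
                                    / ag.loc[plot_id, "collar_area"]),
                "ag_c": float(ag.loc[plot_id, "dry_mass"]
                              * ag.loc[plot_id, "c_frac"]
                              / ag.loc[plot_id, "collar_area"]),
                "ag_n": float(ag.loc[plot_id, "dry_mass"]
                              * ag.loc[plot_id, "n_frac"]
                              / ag.loc[plot_id, "collar_area"]),
                "bg_biomass": float(per_plot.loc[plot_id, "bg_biomass"]),
                "bg_c": float(per_plot.loc[plot_id, "bg_c"]),
                "bg_n": float(per_plot.loc[plot_id, "bg_n"]),
                "soil_c": float(per_plot.loc[plot_id, "soil_c"]),
                "soil_n": float(per_plot.loc[plot_id, "soil_n"]),
            })
    return pd.DataFrame(rows)
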