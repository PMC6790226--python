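"""Exponential closure-curve fitting and conversion to areal CO2 flux.

During a chamber closure the headspace CO2 mole fraction relaxes towards an
asymptote.  Residual analyses in the chamber literature show a plain linear
regression is frequently inadequate even for short closures, so the dry
mole fraction C'(t) is fitted with the saturating exponential

    C'(t) = Cx' + (C0' - Cx') * exp(-kappa * (t - t0))

where C0' is the value at the start of the fit window t0, Cx' the asymptote
and kappa (s-1) the curvature.  The flux is taken from the initial slope
dC'/dt|_{t0} = kappa * (Cx' - C0') and converted to an areal molar flux via
the ideal-gas mass balance of the chamber volume.  The curvature parameter
is called kappa here to avoid a clash with the quantum yield alpha of the
light-response model.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .config import ChamberGeometry, RunConfig, R_GAS, T_ZERO_K
from .io import ClosureSeries

logger = logging.getLogger("chamberflux")

KAPPA_MIN = 1e-6   # s-1, below this the closure is treated as linear
KAPPA_MAX = 1.0    # s-1
MIN_POINTS = 10


@dataclass(frozen=True)
class ClosureFit:
    """Least-squares fit of one closure curve.

    ``fallback_linear`` marks closures where the exponential model was
    degenerate (flat closure or curvature at the identifiability bound) and
    an ordinary linear slope was used instead; ``c0_prime`` then holds the
    intercept at t0 and ``cx_prime``/``kappa`` are NaN.
    """

    c0_prime: float      # umol mol-1 at t0
    cx_prime: float      # umol mol-1, asymptote
    kappa: float         # s-1
    t0: float            # s, start of fit window (series-relative)
    rmse: float          # umol mol-1
    n_points: int
    fallback_linear: bool = False
    linear_slope: float = float("nan")   # umol mol-1 s-1, fallback only


@dataclass(frozen=True)
class FluxObservation:
    """One NEE observation (uptake negative) with its drivers."""

    nee: float        # umol CO2 m-2 s-1
    ppfd: float       # umol photons m-2 s-1, inside-filter sensor
    tair: float       # deg C
    plot_id: str
    transect_id: str
    campaign: str
    filter_count: int


def dilution_correct(co2_wet, h2o):
    """Water-dilution correction: wet to dry CO2 mole fraction.

    co2_dry = co2_wet / (1 - h2o/1000) with h2o in mmol mol-1.  Monotone
    increasing in h2o; identity for dry air.
    """
    co2_wet = np.asarray(co2_wet, dtype=float)
    h2o = np.asarray(h2o, dtype=float)
    if np.any(h2o < 0) or np.any(h2o >= 1000):
        raise ValueError("h2o mole fraction must be in [0, 1000) mmol mol-1")
    out = co2_wet / (1.0 - h2o / 1000.0)
    return out.item() if out.ndim == 0 else out


def _exp_model(t, c0, cx, kappa, t0):
    return cx + (c0 - cx) * np.exp(-kappa * (t - t0))


def fit_closure(series: ClosureSeries, config: RunConfig | None = None) -> ClosureFit:
    """Fit the exponential closure model over the post-dead-band window.

    Falls back to an ordinary linear slope when the exponential model is
    degenerate (flat closure, failed convergence, or curvature pinned at
    the identifiability bound).  Raises ValueError for series with fewer
    than 10 usable points or non-finite values.
    """
    config = config or RunConfig()
    mask = series.fit_mask()
    t = series.t[mask]
    y = series.co2_wet[mask]
    if config.co2_dilution_correction:
        y = dilution_correct(y, series.h2o[mask])
    if len(t) < MIN_POINTS:
        raise ValueError(
            f"closure {series.key()}: only {len(t)} usable points (< {MIN_POINTS})")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValueError(f"closure {series.key()}: non-finite input")

    t0 = float(t[0])
    n = len(t)

    def _linear() -> ClosureFit:
        slope, intercept = np.polyfit(t - t0, y, 1)
        resid = y - (intercept + slope * (t - t0))
        return ClosureFit(
            c0_prime=float(intercept), cx_prime=float("nan"),
            kappa=float("nan"), t0=t0,
            rmse=float(np.sqrt(np.mean(resid ** 2))), n_points=n,
            fallback_linear=True, linear_slope=float(slope))

    if np.ptp(y) == 0.0:
        return _linear()

    # initial guesses: endpoints for C0'/Cx', log-linearised two-point kappa
    c0_0, cx_0 = float(y[0]), float(y[-1])
    mid = y[n // 2]
    kappa_0 = 0.01
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (mid - cx_0) / (c0_0 - cx_0) if c0_0 != cx_0 else np.nan
        if np.isfinite(num) and 0 < num < 1:
            kappa_0 = -np.log(num) / (float(t[n // 2]) - t0)
    kappa_0 = float(np.clip(kappa_0, 10 * KAPPA_MIN, KAPPA_MAX / 10))

    try:
        popt, _ = curve_fit(
            lambda tt, c0, cx, k: _exp_model(tt, c0, cx, k, t0),
            t, y, p0=[c0_0, cx_0, kappa_0],
            bounds=([-np.inf, -np.inf, KAPPA_MIN], [np.inf, np.inf, KAPPA_MAX]),
            maxfev=10000)
    except RuntimeError:
        logger.debug("closure %s: exponential fit failed, linear fallback",
                     series.key())
        return _linear()
    c0, cx, kappa = map(float, popt)
    if kappa <= 2 * KAPPA_MIN:      # pinned at the bound: effectively linear
        return _linear()
    resid = y - _exp_model(t, c0, cx, kappa, t0)
    return ClosureFit(c0_prime=c0, cx_prime=cx, kappa=kappa, t0=t0,
                      rmse=float(np.sqrt(np.mean(resid ** 2))), n_points=n)


def initial_slope(fit: ClosureFit) -> float:
    """dC'/dt at t0: kappa*(Cx'-C0') for exponential fits, else the linear slope."""
    if fit.fallback_linear:
        return fit.linear_slope
    return fit.kappa * (fit.cx_prime - fit.c0_prime)


def slope_to_flux(slope: float, geometry: ChamberGeometry, tair: float,
                  pressure: float | None = None) -> float:
    """Convert a mole-fraction slope to an areal molar flux.

    nee = slope * n_air / S with n_air = P*V/(R*T) moles of air in the
    chamber system; slope in umol mol-1 s-1 gives nee in umol m-2 s-1.
    The sign of the flux equals the sign of the slope (drawdown inside the
    chamber means uptake, negative NEE).
    """
    pressure = geometry.pressure_default if pressure is None else pressure
    if pressure <= 0:
        raise ValueError("pressure must be positive")
    t_kelvin = tair + T_ZERO_K
    if t_kelvin <= 0:
        raise ValueError("temperature below absolute zero")
    n_air = pressure * geometry.system_volume / (R_GAS * t_kelvin)
    return slope * n_air / geometry.collar_area


def fluxes_from_series(series: list[ClosureSeries],
                       config: RunConfig | None = None,
                       ) -> tuple[list[FluxObservation], list[ClosureFit],
                                  list[ClosureSeries]]:
    """Fit every closure and convert each to a FluxObservation.

    Drivers attached to the flux are the within-window means of the
    inside-filter PPFD and air temperature.  Rejected closures are logged
    and skipped; the accepted series are returned alongside, index-aligned
    with the observations and fits.
    """
    config = config or RunConfig()
    obs, fits, kept = [], [], []
    for s in series:
        try:
            fit = fit_closure(s, config)
        except ValueError as exc:
            logger.warning("skipping closure: %s", exc)
            continue
        mask = s.fit_mask()
        tair = float(np.mean(s.tair[mask]))
        nee = slope_to_flux(initial_slope(fit), config.geometry, tair, s.pressure)
        obs.append(FluxObservation(
            nee=nee, ppfd=float(np.mean(s.ppfd_in[mask])), tair=tair,
            plot_id=s.plot_id, transect_id=s.transect_id,
            campaign=s.campaign, filter_count=s.filter_count))
        fits.append(fit)
        kept.append(s)
    return obs, fits, kept
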