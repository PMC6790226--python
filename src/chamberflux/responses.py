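"""Light- and temperature-response models, flux partitioning and daily budgets.

NEE partitioning follows the light-response-curve approach adapted to
closed-chamber measurements over small ecosystem patches.  Per plot-or-
transect x campaign group, the NEE-PPFD relation is fitted with a logistic
sigmoid

    NEE(PPFD) = 2*Finf * (0.5 - 1/(1 + exp(-2*alpha*PPFD/Finf))) + Rd

with quantum yield alpha >= 0 (CO2 per photon, the initial slope magnitude),
maximum NEE at full light Finf <= 0, and daytime ecosystem respiration
Rd >= 0; uptake is negative throughout.  Ecosystem respiration is modelled
with an Arrhenius-type exponential on a degC-shifted scale

    Reco(T) = Rref * exp(E0 * (0.0178507 - 1/(T + 46.02)))

whose exponent vanishes at the 10 degC reference (1/(10+46.02) = 0.0178507),
so Reco(10) = Rref = R10 identically.  Standardised indices NEE2000 and
GEE2000 evaluate the sigmoid at PPFD = 2000 umol m-2 s-1; GEE = NEE - Reco.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import expit

from .closure import FluxObservation
from .config import CARBON_MOLAR_MASS

# Arrhenius-type model constants (degC-shifted scale).  K_REF is stored as
# the exact quotient so the 10-degC reference identity Reco(10) = Rref holds
# to machine precision; it prints as 0.0178507 degC-1.
T_SHIFT = 46.02                     # deg C
K_REF = 1.0 / (10.0 + T_SHIFT)      # degC-1


@dataclass(frozen=True)
class LightResponseParams:
    """Logistic-sigmoid light-response parameters for one group."""

    alpha_qy: float    # umol CO2 (umol photon)-1, >= 0
    f_inf: float       # umol m-2 s-1, <= 0 (maximum NEE at full light)
    rd: float          # umol m-2 s-1, >= 0 (daytime ecosystem respiration)
    rmse: float = float("nan")
    n: int = 0
    respiration_only: bool = False   # set for all-dark groups


@dataclass(frozen=True)
class TemperatureResponseParams:
    """Arrhenius-type respiration parameters: Rref = R10, sensitivity E0."""

    rref: float        # umol m-2 s-1, > 0
    e0: float          # dimensionless, >= 0
    rmse: float = float("nan")
    n: int = 0


@dataclass(frozen=True)
class DerivedIndices:
    nee2000: float     # umol m-2 s-1
    gee2000: float     # umol m-2 s-1
    r10: float         # umol m-2 s-1
    alpha_qy: float


@dataclass(frozen=True)
class DailyFlux:
    """Daily carbon budget, g C m-2 day-1; NEE = GEE + Reco exactly."""

    nee: float
    gee: float
    reco: float
    transect_id: str = ""
    campaign: str = ""


def nee_model(params: LightResponseParams, ppfd):
    """Evaluate the logistic sigmoid NEE(PPFD).

    NEE(0) = Rd, NEE(inf) = Finf + Rd, dNEE/dPPFD|0 = -alpha.
    """
    ppfd = np.asarray(ppfd, dtype=float)
    if params.f_inf == 0.0:
        if params.alpha_qy != 0.0:
            raise ValueError("degenerate model: f_inf = 0 with alpha_qy > 0")
        out = np.full_like(ppfd, params.rd, dtype=float)
        return out.item() if out.ndim == 0 else out
    # 1/(1+exp(u)) written as expit(-u) to avoid overflow at high PPFD
    u = -2.0 * params.alpha_qy * ppfd / params.f_inf
    out = 2.0 * params.f_inf * (0.5 - expit(-u)) + params.rd
    return out.item() if out.ndim == 0 else out


def reco_model(params: TemperatureResponseParams, tair):
    """Evaluate the Arrhenius-type Reco(T); strictly increasing for e0 > 0."""
    tair = np.asarray(tair, dtype=float)
    if np.any(tair <= -T_SHIFT):
        raise ValueError(f"temperature must exceed {-T_SHIFT} degC")
    out = params.rref * np.exp(params.e0 * (K_REF - 1.0 / (tair + T_SHIFT)))
    return out.item() if out.ndim == 0 else out


def fit_light_response(obs: list[FluxObservation] | pd.DataFrame,
                       ) -> LightResponseParams:
    """Least-squares (alpha, Finf, Rd) for one group of flux observations.

    Requires >= 5 points spanning >= 3 distinct PPFD levels.  An all-dark
    group (every PPFD ~ 0) returns a flagged respiration-only fit with
    alpha = Finf = 0 and Rd the mean flux.
    """
    nee, ppfd = _extract(obs, "nee", "ppfd")
    n = len(nee)
    if n < 5:
        raise ValueError(f"light-response fit needs >= 5 points, got {n}")
    if np.all(ppfd < 1e-9):
        rd = float(np.mean(nee))
        resid = nee - rd
        return LightResponseParams(0.0, 0.0, max(rd, 0.0),
                                   rmse=float(np.sqrt(np.mean(resid ** 2))),
                                   n=n, respiration_only=True)
    levels = np.unique(np.round(ppfd, 6))
    if len(levels) < 3:
        raise ValueError(
            f"light-response fit unidentifiable: {len(levels)} distinct "
            "PPFD levels (< 3)")

    rd0 = float(np.clip(nee[np.argmin(ppfd)], 0.0, None))
    finf0 = min(float(np.min(nee) - rd0), -1e-3)
    # initial slope from the two lowest light levels
    order = np.argsort(ppfd)
    d_ppfd = ppfd[order[-1]] - ppfd[order[0]]
    alpha0 = float(np.clip(-(nee[order[-1]] - nee[order[0]]) / d_ppfd,
                           1e-5, 1.0))

    def model(p, alpha, finf, rd):
        return nee_model(LightResponseParams(alpha, finf, rd), p)

    popt, _ = curve_fit(
        model, ppfd, nee, p0=[alpha0, finf0, rd0],
        bounds=([0.0, -np.inf, 0.0], [np.inf, -1e-9, np.inf]),
        maxfev=10000)
    alpha, finf, rd = map(float, popt)
    resid = nee - model(ppfd, alpha, finf, rd)
    return LightResponseParams(alpha, finf, rd,
                               rmse=float(np.sqrt(np.mean(resid ** 2))), n=n)


def fit_temperature_response(reco, tair) -> TemperatureResponseParams:
    """Least-squares (Rref, E0) of the Arrhenius-type model.

    Requires >= 5 positive respiration observations spanning >= 3 degC.
    """
    reco = np.asarray(reco, dtype=float)
    tair = np.asarray(tair, dtype=float)
    if len(reco) < 5:
        raise ValueError(f"temperature-response fit needs >= 5 points, got {len(reco)}")
    if np.ptp(tair) < 3.0:
        raise ValueError(
            f"temperature-response fit unidentifiable: {np.ptp(tair):.2f} degC "
            "span (< 3)")
    if np.any(reco <= 0):
        raise ValueError("respiration observations must be positive")

    # log-linear solution as the starting point: ln Reco = ln Rref + E0*x
    x = K_REF - 1.0 / (tair + T_SHIFT)
    b, a = np.polyfit(x, np.log(reco), 1)
    p0 = [float(np.exp(a)), float(np.clip(b, 0.0, None))]

    def model(t, rref, e0):
        return reco_model(TemperatureResponseParams(rref, e0), t)

    popt, _ = curve_fit(model, tair, reco, p0=p0,
                        bounds=([1e-12, 0.0], [np.inf, np.inf]), maxfev=10000)
    rref, e0 = map(float, popt)
    resid = reco - model(tair, rref, e0)
    return TemperatureResponseParams(rref, e0,
                                     rmse=float(np.sqrt(np.mean(resid ** 2))),
                                     n=len(reco))


def fit_temperature_response_loglinear(reco, tair) -> TemperatureResponseParams:
    """Ordinary least squares on ln(Reco); cross-check for the direct fit."""
    reco = np.asarray(reco, dtype=float)
    tair = np.asarray(tair, dtype=float)
    x = K_REF - 1.0 / (tair + T_SHIFT)
    b, a = np.polyfit(x, np.log(reco), 1)
    rref, e0 = float(np.exp(a)), float(max(b, 0.0))
    resid = reco - reco_model(TemperatureResponseParams(rref, e0), tair)
    return TemperatureResponseParams(rref, e0,
                                     rmse=float(np.sqrt(np.mean(resid ** 2))),
                                     n=len(reco))


def indices(lr: LightResponseParams, tr: TemperatureResponseParams,
            reference_ppfd: float = 2000.0) -> DerivedIndices:
    """NEE2000, GEE2000 (= NEE2000 - Rd) and R10 (= Rref) for one group."""
    nee2000 = nee_model(lr, reference_ppfd)
    return DerivedIndices(nee2000=nee2000, gee2000=nee2000 - lr.rd,
                          r10=tr.rref, alpha_qy=lr.alpha_qy)


def partition(nee, reco):
    """GEE = NEE - Reco; the identity NEE = GEE + Reco is restored exactly."""
    return np.subtract(nee, reco)


def daily_course(lr: LightResponseParams, tr: TemperatureResponseParams,
                 ppfd: np.ndarray, tair: np.ndarray,
                 transect_id: str = "", campaign: str = "",
                 carbon_molar_mass: float = CARBON_MOLAR_MASS) -> DailyFlux:
    """Integrate the mean daily course of NEE, GEE and Reco over 24 h.

    ``ppfd``/``tair`` sample one diurnal cycle at a uniform step <= 1 h.
    Per step: Reco from the temperature model, GEE = NEE(PPFD) - Rd from the
    light model, NEE = GEE + Reco; each mean flux (umol m-2 s-1) converts to
    g C m-2 day-1 by * M_C * 86400 * 1e-6.
    """
    ppfd = np.asarray(ppfd, dtype=float)
    tair = np.asarray(tair, dtype=float)
    if ppfd.shape != tair.shape or ppfd.ndim != 1:
        raise ValueError("ppfd and tair must be 1-D and equal length")
    missing = np.flatnonzero(~(np.isfinite(ppfd) & np.isfinite(tair)))
    if missing.size:
        raise ValueError(f"gaps in drivers at step(s) {missing.tolist()}")
    if len(ppfd) < 24:
        raise ValueError("drivers must cover 24 h at a step <= 1 h")
    reco_t = reco_model(tr, tair)
    gee_t = nee_model(lr, ppfd) - lr.rd
    nee_t = gee_t + reco_t
    scale = carbon_molar_mass * 86400.0 * 1e-6
    return DailyFlux(
        nee=float(np.mean(nee_t)) * scale,
        gee=float(np.mean(gee_t)) * scale,
        reco=float(np.mean(reco_t)) * scale,
        transect_id=transect_id, campaign=campaign)


def sinusoidal_drivers(steps_per_day: int = 48, peak_ppfd: float = 1800.0,
                       t_mean: float = 10.0, t_amplitude: float = 5.0,
                       sunrise_h: float = 6.0, sunset_h: float = 20.0,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Idealised diurnal drivers: half-sine PPFD between sunrise and sunset,
    sinusoidal air temperature peaking mid-afternoon."""
    h = np.arange(steps_per_day) * 24.0 / steps_per_day
    day = (h >= sunrise_h) & (h <= sunset_h)
    ppfd = np.zeros(steps_per_day)
    ppfd[day] = peak_ppfd * np.sin(
        np.pi * (h[day] - sunrise_h) / (sunset_h - sunrise_h))
    tair = t_mean + t_amplitude * np.sin(2 * np.pi * (h - 9.0) / 24.0)
    return ppfd, tair


def _extract(obs, *names):
    if isinstance(obs, pd.DataFrame):
        return tuple(obs[n].to_numpy(dtype=float) for n in names)
    return tuple(np.array([getattr(o, n) for o in obs], dtype=float)
                 for n in names)
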