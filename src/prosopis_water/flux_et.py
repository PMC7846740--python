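"""Eddy-covariance fluxes, FAO-56 reference evapotranspiration and Kc.

High-frequency processing follows the conventional open-path chain: despiking
(median/MAD), double coordinate rotation, scalar time-lag optimisation,
covariance fluxes with a WPL-type density adjustment, and conversion of LE to
an evapotranspiration depth.  Reference ET uses the FAO-56 Penman-Monteith
hourly and daily forms for clipped grass; the crop coefficient is the
least-squares slope through the origin of daily ETa on daily ETo.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _met

__all__ = [
    "KcEstimate",
    "despike",
    "double_rotation",
    "lag_correct",
    "ec_fluxes",
    "half_hourly_eta",
    "soil_heat_flux",
    "soil_heat_capacity",
    "penman_monteith_eto",
    "daily_eto",
    "daily_eta",
    "kc_estimate",
]


# ---------------------------------------------------------------------------
# high-frequency window processing
# ---------------------------------------------------------------------------

def despike(window: pd.DataFrame, mad_threshold: float = 6.0,
            columns: tuple[str, ...] = ("u", "v", "w", "t_sonic", "h2o_g_m3"),
            ) -> tuple[pd.DataFrame, dict[str, int], bool]:
    """Replace median/MAD outliers by linear interpolation.

    Returns (cleaned window, per-column replacement counts, low_quality flag);
    the flag is raised when more than 10% of any column was replaced.
    """
    if window.empty:
        raise ValueError("empty window")
    out = window.copy()
    counts: dict[str, int] = {}
    low_quality = False
    for col in columns:
        if col not in out.columns:
            continue
        x = out[col].astype(float)
        med = x.median()
        mad = (x - med).abs().median()
        scale = 1.4826 * mad
        if scale == 0:
            counts[col] = 0
            continue
        bad = (x - med).abs() > mad_threshold * scale
        counts[col] = int(bad.sum())
        if counts[col]:
            x[bad] = np.nan
            out[col] = x.interpolate(limit_direction="both")
        if counts[col] > 0.10 * len(x):
            low_quality = True
    return out, counts, low_quality


def double_rotation(window: pd.DataFrame) -> pd.DataFrame:
    """Rotate wind into the mean streamline frame (mean v = mean w = 0).

    Two successive rotations: yaw into the mean horizontal wind, then pitch to
    null the mean vertical wind.  The per-sample wind-speed magnitude is
    preserved exactly.
    """
    u = window["u"].to_numpy(dtype=float)
    v = window["v"].to_numpy(dtype=float)
    w = window["w"].to_numpy(dtype=float)
    if np.hypot(u.mean(), v.mean()) == 0:
        raise ValueError("zero mean horizontal wind: rotation undefined")
    theta = np.arctan2(v.mean(), u.mean())
    u1 = u * np.cos(theta) + v * np.sin(theta)
    v1 = -u * np.sin(theta) + v * np.cos(theta)
    phi = np.arctan2(w.mean(), u1.mean())
    u2 = u1 * np.cos(phi) + w * np.sin(phi)
    w2 = -u1 * np.sin(phi) + w * np.cos(phi)
    out = window.copy()
    out["u"], out["v"], out["w"] = u2, v1, w2
    return out


def lag_correct(window: pd.DataFrame, scalar: str, max_lag_s: float,
                sampling_hz: float) -> tuple[pd.DataFrame, int, bool]:
    """Shift a scalar series to the lag maximising |cross-covariance| with w.

    Returns (window with shifted scalar, lag in samples, low_correlation
    flag).  The flag is raised when the peak |correlation| is below 3 / sqrt(n)
    (sampling noise level for an uncorrelated scalar).
    """
    w = window["w"].to_numpy(dtype=float)
    s = window[scalar].to_numpy(dtype=float)
    n = len(w)
    max_lag = int(round(max_lag_s * sampling_hz))
    if max_lag >= n:
        raise ValueError("max lag exceeds window length")
    wd = w - w.mean()
    best_lag, best_cov = 0, -np.inf
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            a, b = wd[lag:] if lag else wd, s[: n - lag] if lag else s
        else:
            a, b = wd[:n + lag], s[-lag:]
        cov = abs(np.mean(a * (b - b.mean())))
        if cov > best_cov:
            best_cov, best_lag = cov, lag
    shifted = np.roll(s, best_lag)
    out = window.copy()
    out[scalar] = shifted
    corr = best_cov / (w.std() * s.std()) if w.std() > 0 and s.std() > 0 else 0.0
    return out, best_lag, bool(corr < 3.0 / np.sqrt(n))


def _cov(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean((a - a.mean()) * (b - b.mean())))


def _cov_se(a: np.ndarray, b: np.ndarray) -> float:
    """Standard error of the covariance estimator (mean of products)."""
    prod = (a - a.mean()) * (b - b.mean())
    return float(prod.std(ddof=1) / np.sqrt(len(prod)))


def ec_fluxes(window: pd.DataFrame, pressure_kpa: float = 91.0) -> dict[str, float]:
    """Sensible and latent heat flux from a rotated, lag-corrected window.

    H = rho_a * cp * cov(w', T'); the water-vapour flux carries a WPL-type
    density adjustment, E = (1 + mu*sigma) * (cov(w', rho_v') +
    (rho_v/T) * cov(w', T')), and LE = lambda(T) * E.  Sonic temperature is
    taken as air temperature (single-unit IRGA/sonic, no separation).
    Returns fluxes in W/m^2 plus estimator standard errors.
    """
    w = window["w"].to_numpy(dtype=float)
    t = window["t_sonic"].to_numpy(dtype=float)
    q = window["h2o_g_m3"].to_numpy(dtype=float)  # absolute humidity
    t_mean = t.mean()
    t_k = t_mean + 273.15
    rho_v = q.mean()  # g/m^3
    e_kpa = _met.vapour_pressure_from_density(rho_v, t_mean)
    rho_a = _met.moist_air_density(t_mean, pressure_kpa, e_kpa)  # kg/m^3
    rho_d = rho_a - rho_v * 1e-3
    cp = _met.CP_DRY * (1.0 + 0.84 * (rho_v * 1e-3) / rho_a)
    lam_j_g = _met.latent_heat_mj_kg(t_mean) * 1e3  # J per g of water

    cov_wt = _cov(w, t)
    cov_wq = _cov(w, q)  # (m/s)(g/m^3) = g/m^2/s
    h = rho_a * cp * cov_wt
    sigma = (rho_v * 1e-3) / rho_d
    e_flux = (1.0 + _met.MU_WPL * sigma) * (cov_wq + (rho_v / t_k) * cov_wt)
    le = lam_j_g * e_flux
    return {
        "H_wm2": h,
        "LE_wm2": le,
        "cov_wT": cov_wt,
        "cov_wq": cov_wq,
        "H_se_wm2": rho_a * cp * _cov_se(w, t),
        "LE_se_wm2": lam_j_g * (1.0 + _met.MU_WPL * sigma) * _cov_se(w, q),
        "air_temperature_c": t_mean,
    }


def half_hourly_eta(le_wm2, t_c, interval_s: float = 1800.0,
                    clamp_negative: bool = True):
    """ET depth (mm per interval) from latent heat flux.

    ETa = LE * dt / (lambda * rho_w); 1 kg/m^2 of water = 1 mm.  Nocturnal
    negative LE is clamped to zero by default (water-budget semantics); pass
    ``clamp_negative=False`` to keep the signed flux.
    """
    le = np.asarray(le_wm2, dtype=float)
    if clamp_negative:
        le = np.maximum(le, 0.0)
    lam = _met.latent_heat_mj_kg(t_c) * 1e6  # J/kg
    return le * interval_s / lam  # kg/m^2 == mm


# ---------------------------------------------------------------------------
# soil heat flux
# ---------------------------------------------------------------------------

def soil_heat_capacity(soil_moisture_frac, mineral_fraction: float = 0.5):
    """Volumetric heat capacity of soil, J/m^3/K (de Vries mixing)."""
    theta = np.asarray(soil_moisture_frac, dtype=float)
    return 1.942e6 * mineral_fraction + 4.186e6 * theta


def soil_heat_flux(plate_wm2: pd.Series, soil_t_c: pd.Series | None,
                   soil_moisture_frac=0.15, depth_m: float = 0.08,
                   mineral_fraction: float = 0.5,
                   heat_capacity_j_m3_k=None) -> pd.Series:
    """Surface soil heat flux: plate reading plus storage above the plate.

    G = G_plate + Cs * dT/dt * depth.  With no soil-temperature series the
    storage term is omitted and the result flagged via
    ``result.attrs['storage_omitted']``.
    """
    if soil_t_c is None:
        out = plate_wm2.copy()
        out.attrs["storage_omitted"] = True
        return out
    cs = (np.asarray(heat_capacity_j_m3_k, dtype=float)
          if heat_capacity_j_m3_k is not None
          else soil_heat_capacity(soil_moisture_frac, mineral_fraction))
    dt_s = soil_t_c.index.to_series().diff().dt.total_seconds()
    dtemp = soil_t_c.diff()
    storage = cs * (dtemp / dt_s) * depth_m
    out = plate_wm2 + storage.fillna(0.0)
    out.attrs["storage_omitted"] = False
    return out


# ---------------------------------------------------------------------------
# FAO-56 reference evapotranspiration
# ---------------------------------------------------------------------------

def penman_monteith_eto(inputs: pd.DataFrame, freq: str = "hourly") -> pd.Series:
    """FAO-56 Penman-Monteith reference ET for clipped grass, mm per interval.

    ``inputs`` columns: rn_mj (net radiation, MJ/m^2 per interval), g_mj
    (soil heat flux, MJ/m^2 per interval), t_c, rh_pct, u2_ms, p_kpa.
    ``freq`` selects the hourly (Cn = 37) or daily (Cn = 900) coefficient.

    ETo = [0.408 D (Rn - G) + g Cn/(T+273) u2 (es - ea)] / [D + g (1 + 0.34 u2)]
    """
    t = inputs["t_c"].to_numpy(dtype=float)
    rh = inputs["rh_pct"].to_numpy(dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("relative humidity must be within [0, 100] %")
    u2 = inputs["u2_ms"].to_numpy(dtype=float)
    rn = inputs["rn_mj"].to_numpy(dtype=float)
    g = inputs["g_mj"].to_numpy(dtype=float)
    p = inputs["p_kpa"].to_numpy(dtype=float)
    cn = {"hourly": 37.0, "daily": 900.0}[freq]
    delta = _met.svp_slope(t)
    gamma = _met.psychrometric_constant(p)
    es = _met.saturation_vapour_pressure(t)
    ea = es * rh / 100.0
    num = 0.408 * delta * (rn - g) + gamma * (cn / (t + 273.0)) * u2 * (es - ea)
    den = delta + gamma * (1.0 + 0.34 * u2)
    eto = num / den
    return pd.Series(np.maximum(eto, 0.0), index=inputs.index, name="eto_mm")


def eto_inputs_from_weather(weather: pd.DataFrame,
                            albedo_slope: float = 0.65,
                            longwave_offset_wm2: float = 35.0) -> pd.DataFrame:
    """Hourly FAO-56 ETo inputs from a half-hourly weather table.

    Net radiation is approximated from solar irradiance as
    ``albedo_slope * Rs - longwave_offset`` (clipped at zero for the grass
    reference), G is taken as zero at the hourly grain, and wind is assumed
    measured at 2 m.
    """
    hourly = weather.set_index("timestamp")[
        ["solar_wm2", "t_c", "rh_pct", "u_ms", "p_kpa"]
    ].resample("1h", closed="right", label="right").mean()
    return pd.DataFrame({
        "rn_mj": (albedo_slope * hourly["solar_wm2"] - longwave_offset_wm2)
        .clip(lower=0) * 3600.0 / 1e6,
        "g_mj": 0.0,
        "t_c": hourly["t_c"],
        "rh_pct": hourly["rh_pct"].clip(0, 100),
        "u2_ms": hourly["u_ms"],
        "p_kpa": hourly["p_kpa"],
    }, index=hourly.index)


def daily_eto(hourly: pd.Series) -> pd.Series:
    """Daily ETo, mm/day, as the sum of hourly values (interval-ending stamps)."""
    day = (hourly.index - pd.Timedelta(seconds=1)).date
    return hourly.groupby(day).sum().rename("eto_mm_day")


def daily_eta(eta_interval: pd.Series) -> pd.Series:
    """Daily ETa, mm/day, summed from per-interval depths."""
    day = (eta_interval.index - pd.Timedelta(seconds=1)).date
    return eta_interval.groupby(day).sum().rename("eta_mm_day")


# ---------------------------------------------------------------------------
# crop coefficient
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KcEstimate:
    """Crop coefficient as the through-origin slope of daily ETa on ETo."""

    slope: float
    n_days: int
    slope_se: float
    r_squared: float


def kc_estimate(eta_daily: pd.Series, eto_daily: pd.Series,
                min_days: int = 10) -> KcEstimate:
    """Least-squares slope through the origin of ETa on ETo (paired days)."""
    paired = pd.concat([eta_daily.rename("eta"), eto_daily.rename("eto")],
                       axis=1, join="inner").dropna()
    if len(paired) < min_days:
        raise ValueError(f"need at least {min_days} paired days, got {len(paired)}")
    x = paired["eto"].to_numpy(dtype=float)
    y = paired["eta"].to_numpy(dtype=float)
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("all-zero ETo: slope undefined")
    slope = float(np.sum(x * y) / sxx)
    resid = y - slope * x
    dof = max(len(x) - 1, 1)
    se = float(np.sqrt(np.sum(resid**2) / dof / sxx))
    ss_tot = float(np.sum(y**2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return KcEstimate(slope=slope, n_days=len(x), slope_se=se, r_squared=r2)
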