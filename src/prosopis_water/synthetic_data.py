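"""Synthetic field campaign with known ground truth.

Emulates every input of the pipeline for a semi-arid Rift-Valley lowland
site: half-hourly weather with a bimodal rainy season, heat-pulse logger
tables whose temperature-rise ratios encode prescribed sap velocities,
high-frequency eddy-covariance windows with prescribed fluxes, half-hourly
energy-balance series tied to a prescribed crop coefficient, a fractional-
cover raster, and a tree inventory with a known sapwood allometry.  Every
generator is a deterministic function of its seed, and each output fed to
its consuming stage with zero noise returns the prescribed truth.
"""
from __future__ import annotations

import calendar
from dataclasses import dataclass, field, replace
from datetime import date

import numpy as np
import pandas as pd

from . import _met, flux_et
from .sapflow_hrm import ProbeGeometry, invert_wound_correction
from .upscaling import CoverRaster

__all__ = [
    "ClimateSpec",
    "TrueSapVelocityCurve",
    "TurbulenceSpec",
    "generate_weather",
    "expected_rain_total_sd",
    "generate_soil_moisture",
    "generate_heat_pulse_series",
    "generate_turbulence",
    "generate_halfhourly_fluxes",
    "generate_cover_raster",
    "generate_tree_inventory",
    "instrumented_tree_daily_means",
    "default_study_curves",
    "DEFAULT_ALLOMETRY",
    "DEFAULT_SEASONAL_MULTIPLIERS",
]

#: Generating sapwood-area allometry A = intercept + slope * D (cm^2, cm).
DEFAULT_ALLOMETRY = (-15.0, 4.2)

#: Monthly sap-velocity multipliers: higher in the dry season (Jan-Mar) than
#: the main rains (Jul-Sep), normalized to an annual mean of one.  The 1.25
#: dry/rainy contrast matches the observed seasonal water-use ratio.
_RAW_SEASONAL = {1: 1.104, 2: 1.104, 3: 1.104, 7: 0.883, 8: 0.883, 9: 0.883}
_MEAN_SEASONAL = (sum(_RAW_SEASONAL.values()) + 6 * 1.0) / 12.0
DEFAULT_SEASONAL_MULTIPLIERS = {
    m: _RAW_SEASONAL.get(m, 1.0) / _MEAN_SEASONAL for m in range(1, 13)
}


# ---------------------------------------------------------------------------
# weather
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClimateSpec:
    """Afar-like lowland climate: hot, ~91 kPa, bimodal rains, ~560 mm/yr."""

    annual_rainfall_mm: float = 560.0
    mean_temp_c: float = 31.0
    temp_amplitude_diurnal_c: float = 12.0
    temp_amplitude_seasonal_c: float = 5.0
    mean_pressure_kpa: float = 91.0
    peak_solar_wm2: float = 1000.0
    mean_wind_ms: float = 1.3
    mean_rh_pct: float = 58.0
    rainy_season_months: tuple[int, ...] = (3, 4, 7, 8, 9)
    wet_day_probability: float = 0.35
    rain_gamma_shape: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.annual_rainfall_mm < 0:
            raise ValueError("annual rainfall must be >= 0")
        if not (0 < self.peak_solar_wm2 <= 1400):
            raise ValueError("peak solar must lie in (0, 1400] W/m^2")
        if not (80 < self.mean_pressure_kpa < 105):
            raise ValueError("pressure must lie in (80, 105) kPa")

    @property
    def rainy_days_per_year(self) -> int:
        return sum(calendar.monthrange(2017, m)[1] for m in self.rainy_season_months)

    @property
    def mean_wet_amount_mm(self) -> float:
        if self.annual_rainfall_mm == 0:
            return 0.0
        return self.annual_rainfall_mm / (self.rainy_days_per_year *
                                          self.wet_day_probability)


def generate_weather(spec: ClimateSpec, start: date, days: int) -> pd.DataFrame:
    """Half-hourly weather table with interval-ending timestamps.

    Columns: timestamp, solar_wm2, t_c, rh_pct, u_ms, rain_mm, p_kpa.  Solar
    radiation is zero at night and peaks near noon; RH is inversely coupled
    to temperature; rain falls only in rainy-season months, with daily
    Bernoulli occurrence and gamma amounts whose 365-day expectation equals
    the annual total.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    rng = np.random.default_rng(spec.seed)
    idx = pd.date_range(pd.Timestamp(start) + pd.Timedelta(minutes=30),
                        periods=days * 48, freq="30min")
    hour = idx.hour + idx.minute / 60.0
    doy = idx.dayofyear.to_numpy()
    month = idx.month.to_numpy()
    day_ix = np.repeat(np.arange(days), 48)

    rainy = np.isin(month, spec.rainy_season_months)
    # classify days by their own calendar month (noon stamp), not the
    # interval-ending midnight stamp that belongs to the next day
    rainy_day = rainy.reshape(days, 48)[:, 23]

    # per-day atmospheric clearness: lower during the rains
    clear = np.where(rainy_day,
                     rng.uniform(0.35, 0.95, days),
                     rng.uniform(0.65, 1.00, days))
    elev = np.sin(np.pi * (hour - 6.0) / 12.0)
    solar = spec.peak_solar_wm2 * clear[day_ix] * np.clip(elev, 0.0, None)

    seas = spec.temp_amplitude_seasonal_c * np.cos(2 * np.pi * (doy - 172) / 365.0)
    diur = 0.5 * spec.temp_amplitude_diurnal_c * np.cos(2 * np.pi * (hour - 14.0) / 24.0)
    t_c = spec.mean_temp_c + seas + diur + rng.normal(0.0, 0.6, len(idx))

    rh_base = spec.mean_rh_pct + np.where(rainy, 12.0, -3.0)
    rh = rh_base - 1.8 * (diur + rng.normal(0.0, 0.5, len(idx)))
    rh = np.clip(rh + rng.normal(0.0, 3.0, len(idx)), 5.0, 100.0)

    u = spec.mean_wind_ms * (0.65 + 0.7 * np.clip(elev, 0.0, None)) \
        + np.abs(rng.normal(0.0, 0.4, len(idx)))

    p = spec.mean_pressure_kpa + 0.05 * np.sin(2 * np.pi * hour / 24.0) \
        + rng.normal(0.0, 0.03, len(idx))

    rain = np.zeros(len(idx))
    if spec.annual_rainfall_mm > 0:
        wet = rainy_day & (rng.random(days) < spec.wet_day_probability)
        amounts = rng.gamma(spec.rain_gamma_shape,
                            spec.mean_wet_amount_mm / spec.rain_gamma_shape,
                            days) * wet
        # dump the daily total into the 17:00-17:30 interval (convective rains)
        rain = rain.reshape(days, 48)
        rain[:, 34] = amounts
        rain = rain.ravel()

    return pd.DataFrame({
        "timestamp": idx,
        "solar_wm2": solar,
        "t_c": t_c,
        "rh_pct": rh,
        "u_ms": u,
        "rain_mm": rain,
        "p_kpa": p,
    })


def expected_rain_total_sd(spec: ClimateSpec, days_in_rainy_months: int) -> float:
    """Sampling SD of the simulated rain total over n rainy-season days."""
    p = spec.wet_day_probability
    k = spec.rain_gamma_shape
    theta = spec.mean_wet_amount_mm / k if k > 0 else 0.0
    mean_wet = k * theta
    second_moment_wet = k * theta**2 + mean_wet**2
    var_day = p * second_moment_wet - (p * mean_wet) ** 2
    return float(np.sqrt(days_in_rainy_months * var_day))


def generate_soil_moisture(weather: pd.DataFrame, theta_init: float = 12.0,
                           uptake_rate: float = 0.08,
                           infiltration: float = 0.5,
                           theta_residual: float = 8.0) -> pd.Series:
    """Daily volumetric soil moisture (%) as a leaky bucket over rainfall.

    theta_{d+1} = theta_d + infiltration * rain_d - uptake * (theta_d - residual),
    clipped to [4, 45] %.  Gives the driver regression a predictor that is
    realistically autocorrelated with rainfall.
    """
    day = (weather["timestamp"] - pd.Timedelta(seconds=1)).dt.date
    rain_daily = weather.groupby(day)["rain_mm"].sum()
    theta = np.empty(len(rain_daily))
    cur = theta_init
    for i, r in enumerate(rain_daily.to_numpy()):
        cur = cur + infiltration * r - uptake_rate * (cur - theta_residual)
        cur = float(np.clip(cur, 4.0, 45.0))
        theta[i] = cur
    return pd.Series(theta, index=rain_daily.index, name="soil_moisture_pct")


# ---------------------------------------------------------------------------
# heat-pulse logger
# ---------------------------------------------------------------------------

def _default_diurnal_shape() -> np.ndarray:
    """48 half-hour weights, mean one: solar-tracking with a small night base."""
    hour = (np.arange(48) + 1) * 0.5
    shape = np.clip(np.sin(np.pi * (hour - 6.5) / 12.0), 0.0, None) + 0.05
    return shape / shape.mean()


@dataclass(frozen=True)
class TrueSapVelocityCurve:
    """Prescribed sap velocity for one tree (the recovery target).

    ``base_velocity_cm_h`` is the daily-mean (wound-corrected) velocity;
    ``diurnal_shape`` holds 48 nonnegative half-hourly weights with mean one;
    ``seasonal_multiplier`` maps month -> factor; noise is additive on the
    raw heat-pulse velocity in cm/h.
    """

    tree_id: str
    base_velocity_cm_h: float
    diurnal_shape: tuple[float, ...] = tuple(_default_diurnal_shape())
    seasonal_multiplier: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SEASONAL_MULTIPLIERS))
    noise_sd_cm_h: float = 0.5

    def __post_init__(self) -> None:
        if self.base_velocity_cm_h < 0:
            raise ValueError("base velocity must be >= 0")
        shape = np.asarray(self.diurnal_shape, dtype=float)
        if shape.size != 48 or np.any(shape < 0):
            raise ValueError("diurnal shape needs 48 nonnegative weights")

    def true_velocity(self, timestamps: pd.DatetimeIndex) -> np.ndarray:
        """Prescribed wound-corrected velocity (cm/h) at interval-ending stamps."""
        shape = np.asarray(self.diurnal_shape, dtype=float)
        slot = ((timestamps.hour * 60 + timestamps.minute) // 30 - 1) % 48
        seas = np.array([self.seasonal_multiplier.get(m, 1.0)
                         for m in timestamps.month])
        return self.base_velocity_cm_h * shape[slot] * seas


def generate_heat_pulse_series(curve: TrueSapVelocityCurve, probe: ProbeGeometry,
                               start: date, days: int, seed: int = 0,
                               ) -> pd.DataFrame:
    """Half-hourly heat-pulse logger table for one tree.

    The emitted temperature-rise ratio v1/v2 encodes the raw heat-pulse
    velocity whose wound correction equals the prescribed velocity, so the
    full analysis chain (log-ratio, wound correction) round-trips exactly at
    zero noise.  Noise is additive on the raw velocity before encoding.
    Columns: tree_id, timestamp, depth_cm, v1_C, v2_C.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    rng = np.random.default_rng(seed)
    idx = pd.date_range(pd.Timestamp(start) + pd.Timedelta(minutes=30),
                        periods=days * 48, freq="30min")
    v_true = curve.true_velocity(idx)
    vh_raw = invert_wound_correction(v_true, probe.wound_width)
    frames = []
    for depth in probe.depths:
        noise = rng.normal(0.0, curve.noise_sd_cm_h, len(idx)) \
            if curve.noise_sd_cm_h > 0 else 0.0
        vh = vh_raw + noise
        ratio = np.exp(vh * probe.x / (probe.k * 3600.0))
        v2 = np.full(len(idx), 0.4)  # deg C, typical post-pulse rise
        frames.append(pd.DataFrame({
            "tree_id": curve.tree_id,
            "timestamp": idx,
            "depth_cm": depth,
            "v1_C": ratio * v2,
            "v2_C": v2,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# eddy covariance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TurbulenceSpec:
    """Prescribed fluxes and sampling for one high-frequency EC window."""

    target_le_wm2: float = 200.0
    target_h_wm2: float = 100.0
    sampling_hz: float = 10.0
    window_minutes: float = 30.0
    mean_wind_ms: float = 2.0
    tilt_deg: float = 0.0
    mean_temp_c: float = 31.0
    mean_h2o_g_m3: float = 15.0
    pressure_kpa: float = 91.0
    scalar_lag_s: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_hz <= 0:
            raise ValueError("sampling rate must be > 0")
        if self.window_minutes < 1:
            raise ValueError("window must be >= 1 minute")

    def state(self) -> dict[str, float]:
        """Mean thermodynamic state implied by the spec."""
        e = _met.vapour_pressure_from_density(self.mean_h2o_g_m3, self.mean_temp_c)
        rho_a = float(_met.moist_air_density(self.mean_temp_c, self.pressure_kpa, e))
        rho_d = rho_a - self.mean_h2o_g_m3 * 1e-3
        cp = _met.CP_DRY * (1.0 + 0.84 * (self.mean_h2o_g_m3 * 1e-3) / rho_a)
        lam_j_g = float(_met.latent_heat_mj_kg(self.mean_temp_c)) * 1e3
        sigma = (self.mean_h2o_g_m3 * 1e-3) / rho_d
        return {"rho_a": rho_a, "cp": cp, "lam_j_g": lam_j_g, "sigma": sigma,
                "t_k": self.mean_temp_c + 273.15}

    def target_covariances(self) -> tuple[float, float]:
        """(cov_wT, cov_wq) such that the flux chain returns the targets.

        The WPL adjustment is inverted so that analysed H and LE equal
        ``target_h_wm2`` and ``target_le_wm2`` in expectation.
        """
        st = self.state()
        cov_wt = self.target_h_wm2 / (st["rho_a"] * st["cp"])
        e_flux = self.target_le_wm2 / st["lam_j_g"]
        cov_wq = e_flux / (1.0 + _met.MU_WPL * st["sigma"]) \
            - (self.mean_h2o_g_m3 / st["t_k"]) * cov_wt
        return cov_wt, cov_wq


def generate_turbulence(spec: TurbulenceSpec) -> pd.DataFrame:
    """High-frequency EC window with prescribed covariances.

    Fluctuations are independent Gaussians mixed by a Cholesky-style factor
    so the (w, T) and (w, q) covariances equal the inverted-WPL targets in
    expectation.  An optional pitch tilt is applied so double rotation is
    exercised; an optional scalar lag shifts the humidity channel.
    Columns: u, v, w, t_sonic, h2o_g_m3.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.sampling_hz * spec.window_minutes * 60.0))
    cov_wt, cov_wq = spec.target_covariances()
    sd_w = 0.4
    sd_t = max(0.4, abs(cov_wt) / (0.8 * sd_w))
    sd_q = max(0.4, abs(cov_wq) / (0.8 * sd_w))
    z = rng.standard_normal((4, n))
    w = sd_w * z[0]
    a_t = cov_wt / sd_w
    t = a_t * z[0] + np.sqrt(max(sd_t**2 - a_t**2, 1e-12)) * z[1]
    a_q = cov_wq / sd_w
    q = a_q * z[0] + np.sqrt(max(sd_q**2 - a_q**2, 1e-12)) * z[2]
    u = spec.mean_wind_ms + 0.5 * rng.standard_normal(n)
    v = 0.4 * rng.standard_normal(n)
    if spec.scalar_lag_s:
        q = np.roll(q, int(round(spec.scalar_lag_s * spec.sampling_hz)))
    if spec.tilt_deg:
        phi = np.deg2rad(spec.tilt_deg)
        u_t = u * np.cos(phi) - w * np.sin(phi)
        w_t = u * np.sin(phi) + w * np.cos(phi)
        u, w = u_t, w_t
    return pd.DataFrame({
        "u": u, "v": v, "w": w,
        "t_sonic": spec.mean_temp_c + t,
        "h2o_g_m3": spec.mean_h2o_g_m3 + q,
    })


def generate_halfhourly_fluxes(weather: pd.DataFrame, kc_true: float = 0.77,
                               daily_noise_sd: float = 0.12,
                               seed: int = 0) -> pd.DataFrame:
    """Half-hourly energy-balance series consistent with Kc * ETo water use.

    Daily ETa is prescribed as ``kc_true`` times the FAO-56 daily ETo of the
    supplied weather, with multiplicative lognormal day-to-day noise, then
    distributed over daylight half hours in proportion to solar radiation.
    Net radiation is a linear function of solar irradiance, soil heat flux a
    fixed daytime/nighttime fraction of Rn, and H closes the energy balance.
    Columns: timestamp, rn_wm2, g_wm2, le_wm2, h_wm2, t_c.
    """
    rng = np.random.default_rng(seed)
    ts = weather["timestamp"]
    solar = weather["solar_wm2"].to_numpy(dtype=float)
    t_c = weather["t_c"].to_numpy(dtype=float)
    rn = 0.65 * solar - 35.0
    g = np.where(solar > 0, 0.1, 0.5) * rn

    eto_in = flux_et.eto_inputs_from_weather(weather)
    eto_d = flux_et.daily_eto(flux_et.penman_monteith_eto(eto_in, freq="hourly"))

    day = (ts - pd.Timedelta(seconds=1)).dt.date
    noise = np.exp(rng.normal(0.0, daily_noise_sd, len(eto_d)))
    eta_d = pd.Series(kc_true * eto_d.to_numpy() * noise, index=eto_d.index)

    frame = pd.DataFrame({"day": day, "solar": np.clip(solar, 0.0, None), "t_c": t_c})
    day_solar_sum = frame.groupby("day")["solar"].transform("sum")
    share = np.where(day_solar_sum > 0, frame["solar"] / day_solar_sum, 0.0)
    eta_mm = share * frame["day"].map(eta_d).to_numpy()
    lam = _met.latent_heat_mj_kg(t_c) * 1e6
    le = eta_mm * lam / 1800.0
    h = (rn - g) - le
    return pd.DataFrame({
        "timestamp": ts,
        "rn_wm2": rn,
        "g_wm2": g,
        "le_wm2": le,
        "h_wm2": h,
        "t_c": t_c,
    })


# ---------------------------------------------------------------------------
# cover raster and inventory
# ---------------------------------------------------------------------------

def generate_cover_raster(rows: int, cols: int, invaded_fraction: float = 1.0,
                          mean_cover: float = 0.21, seed: int = 0,
                          pixel_area_m2: float = 225.0) -> CoverRaster:
    """Fractional-cover raster: Bernoulli invasion mask, beta-distributed cover.

    ``mean_cover`` is the mean fractional cover of invaded pixels; the default
    reflects the sparse-to-dense mosaic of the mapped invasion.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    if not (0.0 <= invaded_fraction <= 1.0):
        raise ValueError("invaded fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = rows * cols
    invaded = rng.random(n) < invaded_fraction
    kappa = 2.0
    a = mean_cover * kappa
    b = (1.0 - mean_cover) * kappa
    values = np.zeros(n, dtype=np.float32)
    n_inv = int(invaded.sum())
    if n_inv:
        values[invaded] = rng.beta(a, b, n_inv).astype(np.float32)
    return CoverRaster(values.reshape(rows, cols), pixel_area_m2=pixel_area_m2)


def generate_tree_inventory(n: int, habitat_mix: dict[str, float] | None = None,
                            diameter_range: tuple[float, float] = (6.0, 30.0),
                            seed: int = 0,
                            allometry: tuple[float, float] = DEFAULT_ALLOMETRY,
                            noise_sd_cm2: float = 0.0) -> pd.DataFrame:
    """Tree inventory with sapwood areas from a known linear allometry.

    Diameters are uniform within ``diameter_range``; habitats follow
    ``habitat_mix`` (default 50/50 floodplain/dryland, floodplain trees on
    sites 1-2 and dryland trees on sites 3-4); sapwood areas are
    intercept + slope * D plus optional Gaussian noise, so the allometry fit
    is testable by round trip.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = diameter_range
    if not hi > lo:
        raise ValueError("diameter range must be non-empty")
    habitat_mix = habitat_mix or {"floodplain": 0.5, "dryland": 0.5}
    rng = np.random.default_rng(seed)
    diam = rng.uniform(lo, hi, n)
    habitats = rng.choice(list(habitat_mix), size=n,
                          p=np.array(list(habitat_mix.values()), dtype=float)
                          / sum(habitat_mix.values()))
    intercept, slope = allometry
    area = intercept + slope * diam
    if noise_sd_cm2 > 0:
        area = area + rng.normal(0.0, noise_sd_cm2, n)
    area = np.maximum(area, 1.0)
    bark = 0.5
    r_cambium = diam / 2.0 - bark
    # sapwood depth consistent with the annulus geometry of the assigned area
    disc = np.maximum(r_cambium**2 - area / np.pi, 0.0)
    sw_depth = r_cambium - np.sqrt(disc)
    site = np.where(habitats == "floodplain",
                    np.where(np.arange(n) % 2 == 0, "site1", "site2"),
                    np.where(np.arange(n) % 2 == 0, "site3", "site4"))
    return pd.DataFrame({
        "tree_id": [f"tree{i + 1:02d}" for i in range(n)],
        "site": site,
        "habitat": habitats,
        "stem_diameter_cm": diam,
        "bark_depth_cm": bark,
        "sapwood_depth_cm": sw_depth,
        "sapwood_area_cm2": area,
        "canopy_area_m2": 2.0,
    })


def instrumented_tree_daily_means() -> pd.DataFrame:
    """Default study conditions: per-tree mean daily water use (L/tree/day).

    Twelve instrumented trees, three per site, floodplain sites 1-2 and
    dryland sites 3-4; habitat means 5.1 and 8.5 and an overall mean of
    6.8 L/tree/day.
    """
    rows = [
        ("site1", "floodplain", 2.6), ("site1", "floodplain", 6.2),
        ("site1", "floodplain", 11.4),
        ("site2", "floodplain", 1.9), ("site2", "floodplain", 4.17),
        ("site2", "floodplain", 4.5),
        ("site3", "dryland", 2.4), ("site3", "dryland", 5.1),
        ("site3", "dryland", 19.2),
        ("site4", "dryland", 6.5), ("site4", "dryland", 9.5),
        ("site4", "dryland", 8.1),
    ]
    return pd.DataFrame(
        [{"tree_id": f"tree{i + 1:02d}", "site": s, "habitat": h,
          "mean_daily_l": v} for i, (s, h, v) in enumerate(rows)]
    )


def default_study_inventory(seed: int = 0) -> pd.DataFrame:
    """Inventory matching the twelve instrumented trees' habitats and sites."""
    ref = instrumented_tree_daily_means()
    rng = np.random.default_rng(seed)
    diam = rng.uniform(8.0, 28.0, len(ref))
    intercept, slope = DEFAULT_ALLOMETRY
    area = np.maximum(intercept + slope * diam, 1.0)
    bark = 0.5
    r_cambium = diam / 2.0 - bark
    disc = np.maximum(r_cambium**2 - area / np.pi, 0.0)
    inv = ref[["tree_id", "site", "habitat"]].copy()
    inv["stem_diameter_cm"] = diam
    inv["bark_depth_cm"] = bark
    inv["sapwood_depth_cm"] = r_cambium - np.sqrt(disc)
    inv["sapwood_area_cm2"] = area
    inv["canopy_area_m2"] = 2.0
    return inv


def default_study_curves(inventory: pd.DataFrame,
                         targets: pd.DataFrame | None = None,
                         noise_sd_cm_h: float = 0.5,
                         ) -> list[TrueSapVelocityCurve]:
    """Velocity curves whose daily volumes hit the per-tree target flows.

    The daily-mean velocity is target volume / (sapwood area * 24 h * 1e-3),
    so a noiseless round trip through the full sap-flow chain recovers each
    tree's prescribed L/day.
    """
    targets = targets if targets is not None else instrumented_tree_daily_means()
    tmap = targets.set_index("tree_id")["mean_daily_l"]
    curves = []
    for _, row in inventory.iterrows():
        base = tmap[row["tree_id"]] / (row["sapwood_area_cm2"] * 24.0 * 1e-3)
        curves.append(TrueSapVelocityCurve(
            tree_id=row["tree_id"],
            base_velocity_cm_h=float(base),
            noise_sd_cm_h=noise_sd_cm_h,
        ))
    return curves
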