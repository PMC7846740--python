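"""End-to-end pipeline: synthetic campaign -> water-use, ET, regression,
upscaling and valuation outputs.

Every stage writes its tidy CSV/JSON products under the configured output
directory; all randomness flows from the single config seed.
"""
from __future__ import annotations

import json
import logging
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from . import drivers_regression, economics, flux_et, sapflow_hrm, synthetic_data
from .upscaling import WaterUseRate, depth_vs_precipitation, regional_totals

log = logging.getLogger(__name__)

REPORT_SECTIONS = ("WEATHER", "SAP FLOW", "EVAPOTRANSPIRATION", "DRIVERS",
                   "UPSCALING", "ECONOMICS")


def _subseeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def run_pipeline(config) -> dict:
    """Run simulate -> sapflow -> ET/ETo -> drivers -> upscale -> econ.

    Returns the summary dictionary; writes stage outputs plus ``summary.json``
    and ``report.txt`` under ``config.out_dir``.
    """
    from .cli_io import PipelineConfig, tree_records_from_inventory, write_ascii_grid

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    start = date.fromisoformat(config.start)
    seeds = _subseeds(config.seed, 6)

    # --- simulate -----------------------------------------------------------
    climate = synthetic_data.ClimateSpec(seed=seeds[0])
    weather = synthetic_data.generate_weather(climate, start, config.days)
    soil = synthetic_data.generate_soil_moisture(weather)
    inventory = synthetic_data.default_study_inventory(seed=seeds[1])
    if config.n_trees != len(inventory):
        inventory = synthetic_data.generate_tree_inventory(config.n_trees,
                                                           seed=seeds[1])
        targets = inventory[["tree_id", "site", "habitat"]].copy()
        rng = np.random.default_rng(seeds[1])
        targets["mean_daily_l"] = rng.uniform(2.0, 12.0, len(inventory))
        curves = synthetic_data.default_study_curves(
            inventory, targets, noise_sd_cm_h=config.sap_noise_sd_cm_h)
    else:
        curves = synthetic_data.default_study_curves(
            inventory, noise_sd_cm_h=config.sap_noise_sd_cm_h)
    weather.to_csv(out / "weather.csv", index=False)
    inventory.to_csv(out / "inventory.csv", index=False)

    logger_tables = [
        synthetic_data.generate_heat_pulse_series(
            c, config.probe, start, config.days, seed=seeds[2] + i)
        for i, c in enumerate(curves)
    ]
    heat_pulse = pd.concat(logger_tables, ignore_index=True)

    # --- sap flow -----------------------------------------------------------
    velocities = sapflow_hrm.process_logger_table(heat_pulse, config.probe)
    trees = tree_records_from_inventory(inventory)
    daily_frames = []
    for tree in trees:
        sub = velocities[velocities["tree_id"] == tree.tree_id]
        wide = sub.pivot(index="timestamp", columns="depth_cm",
                         values="velocity_cm_h")
        flow = sapflow_hrm.tree_sap_flow(wide, tree, config.probe)
        daily_frames.append(sapflow_hrm.daily_aggregate(
            flow, tree, max_gap=config.gap_fill_max,
            qc_threshold=config.qc_threshold))
    daily = pd.concat(daily_frames, ignore_index=True)
    daily.to_csv(out / "daily_tree_flow.csv", index=False)

    habitat = sapflow_hrm.habitat_summary(daily, inventory)
    seasonal = sapflow_hrm.seasonal_summary(daily, inventory, config.seasons)
    habitat.to_csv(out / "habitat_summary.csv", index=False)
    seasonal.to_csv(out / "seasonal_summary.csv", index=False)
    classes = sapflow_hrm.size_class_table(daily, inventory)
    stand_mm_day = sapflow_hrm.stand_transpiration(
        classes, canopy_area_m2=float(inventory["canopy_area_m2"].mean()))

    # --- ET / ETo / Kc ------------------------------------------------------
    eto_hourly = flux_et.penman_monteith_eto(
        flux_et.eto_inputs_from_weather(weather), freq="hourly")
    eto_daily = flux_et.daily_eto(eto_hourly)
    fluxes = synthetic_data.generate_halfhourly_fluxes(
        weather, kc_true=config.kc_true, seed=seeds[3])
    fluxes.to_csv(out / "halfhour_fluxes.csv", index=False)
    eta_interval = pd.Series(
        flux_et.half_hourly_eta(fluxes["le_wm2"], fluxes["t_c"]),
        index=pd.DatetimeIndex(fluxes["timestamp"]))
    eta_daily = flux_et.daily_eta(eta_interval)
    kc = flux_et.kc_estimate(eta_daily, eto_daily)
    et_out = pd.DataFrame({"eta_mm_day": eta_daily, "eto_mm_day": eto_daily})
    et_out.to_csv(out / "daily_et.csv", index_label="date")

    # --- drivers regression --------------------------------------------------
    ts = weather["timestamp"]
    day = (ts - pd.Timedelta(seconds=1)).dt.date
    vpd_series = drivers_regression.compute_vpd(weather["t_c"],
                                                weather["rh_pct"])
    met_daily = pd.DataFrame({
        "solar_radiation": weather.groupby(day)["solar_wm2"].mean() * 0.0864,
        "wind_speed": weather.groupby(day)["u_ms"].mean(),
        "vpd": pd.Series(np.asarray(vpd_series), index=weather.index)
        .groupby(day).mean(),
    })
    matrix = met_daily.join(soil.rename("soil_moisture"))
    matrix = matrix.join(eto_daily.rename("eto"))
    matrix = matrix.join(eta_daily.rename("eta_mm_day"))
    sap_daily_mean = daily.groupby("date")["volume_l"].mean()
    matrix = matrix.join(sap_daily_mean.rename("sap_l_tree_day"))
    matrix.to_csv(out / "driver_matrix.csv", index_label="date")
    fits = {}
    for response in ("eta_mm_day", "sap_l_tree_day"):
        fit = drivers_regression.fit_drivers(matrix, response)
        fit.to_csv(out / f"drivers_{response}.csv")
        fits[response] = fit

    # --- upscaling ----------------------------------------------------------
    raster = synthetic_data.generate_cover_raster(
        config.raster_rows, config.raster_cols,
        invaded_fraction=config.invaded_fraction,
        mean_cover=config.mean_cover, seed=seeds[4])
    if raster.values.size <= 1_000_000:
        write_ascii_grid(raster, out / "cover.asc")
    rate_sap = WaterUseRate(mm_per_day=max(stand_mm_day, 0.0), source="sapflow")
    rate_et = WaterUseRate(mm_per_day=float(eta_daily.mean()), source="et")
    regional = {r.source: r for r in (regional_totals(raster, rate_sap),
                                      regional_totals(raster, rate_et))}

    # --- economics ----------------------------------------------------------
    volumes = sorted(r.annual_volume_m3 for r in regional.values())
    tariff_lo = economics.tariff_value(volumes[0], config.econ.tariff_usd_per_m3)
    tariff_hi = economics.tariff_value(volumes[1], config.econ.tariff_usd_per_m3)
    mid_volume = float(np.mean(volumes))
    crop_eq = {
        crop.name: economics.crop_equivalent(
            mid_volume, crop, formula=config.econ.net_benefit_formula,
            area_rounding_ha=config.econ.area_rounding_ha)
        for crop in config.econ.crops
    }

    # --- summary ------------------------------------------------------------
    summary = {
        "seed": config.seed,
        "days": config.days,
        "n_trees": len(trees),
        "weather": {
            "rain_total_mm": round(float(weather["rain_mm"].sum()), 3),
            "mean_t_c": round(float(weather["t_c"].mean()), 3),
            "mean_p_kpa": round(float(weather["p_kpa"].mean()), 3),
        },
        "sapflow": {
            "mean_tree_l_day": round(float(
                habitat.loc[habitat["habitat"] == "all", "mean_l_day"].iloc[0]), 3),
            "habitat_means_l_day": {
                row["habitat"]: round(row["mean_l_day"], 3)
                for _, row in habitat.iterrows() if row["habitat"] != "all"},
            "seasonal_means_l_day": {
                row["season"]: round(row["mean_l_day"], 3)
                for _, row in seasonal.iterrows()
                if row["habitat"] == "all" and not row.get("empty", False)},
            "stand_transpiration_mm_day": round(stand_mm_day, 3),
            "annual_stand_transpiration_mm": round(stand_mm_day * 365.0, 1),
        },
        "et": {
            "mean_eta_mm_day": round(float(eta_daily.mean()), 3),
            "mean_eto_mm_day": round(float(eto_daily.mean()), 3),
            "kc_slope": round(kc.slope, 4),
            "kc_n_days": kc.n_days,
        },
        "drivers": {
            resp: {"r_squared": round(f.r_squared, 4),
                   "f_statistic": round(f.f_statistic, 3),
                   "df_resid": f.df_resid}
            for resp, f in fits.items()
        },
        "upscaling": {
            src: {
                "daily_volume_m3": round(r.daily_volume_m3, 1),
                "annual_volume_m3": round(r.annual_volume_m3, 1),
                "invaded_area_ha": round(r.invaded_area_ha, 2),
                "cover_weighted_area_ha": round(r.cover_weighted_area_ha, 2),
                "mean_annual_depth_mm": round(r.mean_annual_depth_mm, 2),
                "depth_vs_precip_pct": round(
                    depth_vs_precipitation(r, config.annual_precip_mm), 2),
            } for src, r in regional.items()
        },
        "economics": {
            "tariff_usd_per_yr_lo": round(tariff_lo, 1),
            "tariff_usd_per_yr_hi": round(tariff_hi, 1),
            "crops": {
                name: {
                    "area_ha": eq.area_ha,
                    "tonnage_t": round(eq.tonnage_t, 1),
                    "market_value_usd_lo": round(eq.market_value_usd_lo, 1),
                    "market_value_usd_hi": round(eq.market_value_usd_hi, 1),
                    "net_benefit_usd_lo": round(eq.net_benefit_usd_lo, 1),
                    "net_benefit_usd_hi": round(eq.net_benefit_usd_hi, 1),
                    "net_benefit_formula": eq.net_benefit_formula,
                } for name, eq in crop_eq.items()
            },
        },
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    _write_report(out / "report.txt", summary)
    return summary


def _write_report(path, s: dict) -> None:
    lines = ["Prosopis water-use pipeline report", "=" * 40, ""]
    lines += ["== WEATHER ==",
              f"rain total {s['weather']['rain_total_mm']:.1f} mm, "
              f"mean T {s['weather']['mean_t_c']:.1f} C, "
              f"mean P {s['weather']['mean_p_kpa']:.1f} kPa", ""]
    sf = s["sapflow"]
    lines += ["== SAP FLOW ==",
              f"mean tree water use {sf['mean_tree_l_day']:.1f} L/tree/day",
              "habitat means (L/tree/day): " + ", ".join(
                  f"{k}={v:.1f}" for k, v in sf["habitat_means_l_day"].items()),
              "seasonal means (L/tree/day): " + ", ".join(
                  f"{k}={v:.1f}" for k, v in sf["seasonal_means_l_day"].items()),
              f"stand transpiration {sf['stand_transpiration_mm_day']:.2f} mm/day "
              f"({sf['annual_stand_transpiration_mm']:.0f} mm/yr)", ""]
    et = s["et"]
    lines += ["== EVAPOTRANSPIRATION ==",
              f"ETa {et['mean_eta_mm_day']:.2f} mm/day, "
              f"ETo {et['mean_eto_mm_day']:.2f} mm/day, "
              f"Kc {et['kc_slope']:.2f} (n={et['kc_n_days']} days)", ""]
    lines += ["== DRIVERS =="]
    for resp, f in s["drivers"].items():
        lines.append(f"{resp}: R^2={f['r_squared']:.3f}, "
                     f"F={f['f_statistic']:.1f}, df={f['df_resid']}")
    lines.append("")
    lines += ["== UPSCALING =="]
    for src, r in s["upscaling"].items():
        lines.append(
            f"{src}: {r['annual_volume_m3']:.3e} m^3/yr over "
            f"{r['invaded_area_ha']:.0f} ha invaded "
            f"({r['mean_annual_depth_mm']:.0f} mm/yr, "
            f"{r['depth_vs_precip_pct']:.0f}% of precipitation)")
    lines.append("")
    ec = s["economics"]
    lines += ["== ECONOMICS ==",
              f"tariff value ${ec['tariff_usd_per_yr_lo']:,.0f} - "
              f"${ec['tariff_usd_per_yr_hi']:,.0f} per year"]
    for name, eq in ec["crops"].items():
        lines.append(
            f"{name}: {eq['area_ha']:,.0f} ha, {eq['tonnage_t']:,.0f} t, "
            f"market ${eq['market_value_usd_lo']:,.0f}-${eq['market_value_usd_hi']:,.0f}, "
            f"net benefit ${eq['net_benefit_usd_lo']:,.0f}-"
            f"${eq['net_benefit_usd_hi']:,.0f} ({eq['net_benefit_formula']})")
    lines.append("")
    lines.append("note: crop tonnage and value follow from the rounded area and "
                 "the configured yield/price table; independently published "
                 "tonnage or value figures for the same area need not match.")
    Path(path).write_text("\n".join(lines))
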