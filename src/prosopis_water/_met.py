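"""Shared psychrometric and physical helpers (FAO-56 forms).

All temperatures in deg C, pressures in kPa, vapour pressures in kPa unless
stated otherwise.
"""
from __future__ import annotations

import numpy as np

#: Specific gas constant of dry air, J/kg/K.
R_DRY = 287.04
#: Specific gas constant of water vapour, J/kg/K.
R_VAPOUR = 461.5
#: Molar-mass ratio dry air / water vapour (WPL mu).
MU_WPL = R_VAPOUR / R_DRY  # 1.6077
#: Specific heat of dry air at constant pressure, J/kg/K.
CP_DRY = 1004.67
#: Density of liquid water, kg/m^3.
RHO_WATER = 1000.0


def saturation_vapour_pressure(t_c):
    """Saturation vapour pressure es(T), kPa (FAO-56 Tetens form)."""
    t_c = np.asarray(t_c, dtype=float)
    return 0.6108 * np.exp(17.27 * t_c / (t_c + 237.3))


def svp_slope(t_c):
    """Slope of the saturation vapour pressure curve, kPa/degC."""
    t_c = np.asarray(t_c, dtype=float)
    return 4098.0 * saturation_vapour_pressure(t_c) / (t_c + 237.3) ** 2


def psychrometric_constant(p_kpa):
    """Psychrometric constant gamma, kPa/degC (FAO-56, lambda fixed at 2.45)."""
    return 0.000665 * np.asarray(p_kpa, dtype=float)


def latent_heat_mj_kg(t_c):
    """Latent heat of vaporization, MJ/kg, linear in air temperature."""
    return 2.501 - 2.361e-3 * np.asarray(t_c, dtype=float)


def vapour_pressure_from_density(rho_v_g_m3, t_c):
    """Actual vapour pressure (kPa) from absolute humidity (g/m^3)."""
    t_k = np.asarray(t_c, dtype=float) + 273.15
    return np.asarray(rho_v_g_m3, dtype=float) * 1e-3 * R_VAPOUR * t_k * 1e-3


def vapour_density_from_pressure(e_kpa, t_c):
    """Absolute humidity (g/m^3) from vapour pressure (kPa)."""
    t_k = np.asarray(t_c, dtype=float) + 273.15
    return np.asarray(e_kpa, dtype=float) * 1e3 / (R_VAPOUR * t_k) * 1e3


def moist_air_density(t_c, p_kpa, e_kpa=0.0):
    """Density of moist air, kg/m^3, from the ideal-gas law."""
    t_k = np.asarray(t_c, dtype=float) + 273.15
    p_pa = np.asarray(p_kpa, dtype=float) * 1e3
    e_pa = np.asarray(e_kpa, dtype=float) * 1e3
    return (p_pa - e_pa) / (R_DRY * t_k) + e_pa / (R_VAPOUR * t_k)


def vpd(t_c, rh_pct):
    """Vapour pressure deficit, kPa. RH must lie in [0, 100]."""
    rh = np.asarray(rh_pct, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("relative humidity must be within [0, 100] %")
    return saturation_vapour_pressure(t_c) * (1.0 - rh / 100.0)
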