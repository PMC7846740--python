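"""Monetary valuation of regional water use.

Two complementary valuations: the basin water tariff (a payment-for-ecosystem
-services charge per m^3), and crop-production equivalents -- the irrigated
area, tonnage, market value and net benefit of the main local crops that the
same volume of water could support.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "CropParams",
    "EconParams",
    "CropEquivalent",
    "DEFAULT_ECON",
    "tariff_value",
    "crop_equivalent",
]


@dataclass(frozen=True)
class CropParams:
    """Water requirement, yield and market parameters for one crop."""

    name: str
    water_requirement_m3_per_ha: float
    yield_t_per_ha: float
    price_usd_per_t_lo: float
    price_usd_per_t_hi: float
    benefit_cost_ratio: float

    def __post_init__(self) -> None:
        vals = (self.water_requirement_m3_per_ha, self.yield_t_per_ha,
                self.price_usd_per_t_lo, self.price_usd_per_t_hi,
                self.benefit_cost_ratio)
        if any(v <= 0 for v in vals):
            raise ValueError("crop parameters must all be positive")
        if self.price_usd_per_t_lo > self.price_usd_per_t_hi:
            raise ValueError("price range lo must not exceed hi")


@dataclass(frozen=True)
class EconParams:
    """Tariff, crops and reporting conventions for the valuation."""

    tariff_usd_per_m3: float = 0.00015
    crops: tuple[CropParams, ...] = ()
    net_benefit_formula: str = "margin"  # "margin": V*(1-1/BCR); "markup": V*(BCR-1)
    area_rounding_ha: float = 10_000.0

    def __post_init__(self) -> None:
        if self.tariff_usd_per_m3 <= 0:
            raise ValueError("tariff must be positive")
        if self.net_benefit_formula not in ("margin", "markup"):
            raise ValueError("net_benefit_formula must be 'margin' or 'markup'")


DEFAULT_ECON = EconParams(
    crops=(
        CropParams("cotton", water_requirement_m3_per_ha=7_000.0,
                   yield_t_per_ha=2.1, price_usd_per_t_lo=500.0,
                   price_usd_per_t_hi=600.0, benefit_cost_ratio=1.49),
        CropParams("sugarcane", water_requirement_m3_per_ha=15_000.0,
                   yield_t_per_ha=37.0, price_usd_per_t_lo=536.0,
                   price_usd_per_t_hi=536.0, benefit_cost_ratio=1.12),
    ),
)


@dataclass(frozen=True)
class CropEquivalent:
    """Crop-production equivalent of an annual water volume."""

    crop: str
    area_ha: float                # rounded per reporting rule
    area_ha_raw: float
    tonnage_t: float              # from the rounded area
    market_value_usd_lo: float
    market_value_usd_hi: float
    net_benefit_usd_lo: float
    net_benefit_usd_hi: float
    net_benefit_formula: str


def tariff_value(volume_m3_per_yr: float, tariff_usd_per_m3: float = 0.00015) -> float:
    """Annual tariff value of a water volume, US$/yr (unrounded)."""
    if volume_m3_per_yr < 0:
        raise ValueError("volume must be >= 0")
    return volume_m3_per_yr * tariff_usd_per_m3


def _net_factor(bcr: float, formula: str) -> float:
    return (1.0 - 1.0 / bcr) if formula == "margin" else (bcr - 1.0)


def crop_equivalent(volume_m3_per_yr: float, crop: CropParams,
                    formula: str = "margin",
                    area_rounding_ha: float = 10_000.0) -> CropEquivalent:
    """Area, tonnage and value of ``crop`` supportable by an annual volume.

    area = volume / water requirement (reported both raw and rounded to the
    nearest ``area_rounding_ha``); tonnage and values follow from the rounded
    area.  The net benefit uses the configured benefit-cost-ratio formula.
    """
    if volume_m3_per_yr < 0:
        raise ValueError("volume must be >= 0")
    area_raw = volume_m3_per_yr / crop.water_requirement_m3_per_ha
    area = (round(area_raw / area_rounding_ha) * area_rounding_ha
            if area_rounding_ha > 0 else area_raw)
    tonnage = area * crop.yield_t_per_ha
    mv_lo = tonnage * crop.price_usd_per_t_lo
    mv_hi = tonnage * crop.price_usd_per_t_hi
    f = _net_factor(crop.benefit_cost_ratio, formula)
    return CropEquivalent(
        crop=crop.name,
        area_ha=area,
        area_ha_raw=area_raw,
        tonnage_t=tonnage,
        market_value_usd_lo=mv_lo,
        market_value_usd_hi=mv_hi,
        net_benefit_usd_lo=mv_lo * f,
        net_benefit_usd_hi=mv_hi * f,
        net_benefit_formula=formula,
    )
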