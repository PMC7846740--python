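"""Heat-ratio-method (HRM) sap-flow processing.

Converts raw heat-pulse temperature rises to heat-pulse velocities, applies a
wound correction, scales velocities to whole-tree volumetric flow through
sapwood annuli, and aggregates to daily, habitat, seasonal and stand-level
water use.

The core HRM relation is

    Vh = (k / x) * ln(v1 / v2) * 3600        [cm/h]

with k the thermal diffusivity of fresh wood (cm^2/s), x the heater-to-probe
spacing (cm) and v1/v2 the ratio of the downstream to upstream temperature
rises after a heat pulse.  The log-ratio form makes the method sensitive to
low and reverse flows, which is why it suits desert-adapted trees.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "ProbeGeometry",
    "TreeRecord",
    "AllometryModel",
    "WOUND_COEFFICIENTS",
    "heat_pulse_velocity",
    "wound_correct",
    "invert_wound_correction",
    "fit_allometry",
    "annulus_areas",
    "tree_sap_flow",
    "process_logger_table",
    "daily_aggregate",
    "habitat_summary",
    "seasonal_summary",
    "size_class_table",
    "stand_transpiration",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeGeometry:
    """Geometry and thermal constants of one HRM probe set.

    Parameters
    ----------
    k : thermal diffusivity of fresh sapwood, cm^2/s.
    x : heater-to-thermocouple spacing, cm.
    depths : thermocouple depths below the cambium, cm, strictly increasing.
    wound_width : drill-wound width, cm, used to look up the wound
        correction; ``None`` disables the correction.
    """

    k: float = 2.5e-3
    x: float = 0.5
    depths: tuple[float, ...] = (0.8, 1.1)
    wound_width: float | None = 0.20

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("thermal diffusivity k must be > 0")
        if self.x <= 0:
            raise ValueError("probe spacing x must be > 0")
        d = np.asarray(self.depths, dtype=float)
        if d.size == 0 or np.any(d <= 0) or np.any(np.diff(d) <= 0):
            raise ValueError("depths must be positive and strictly increasing")


@dataclass(frozen=True)
class TreeRecord:
    """One instrumented tree: geometry, habitat and canopy footprint."""

    tree_id: str
    site: str
    habitat: str  # "floodplain" | "dryland"
    stem_diameter_cm: float  # at ~60 cm height, below branching
    bark_depth_cm: float = 0.5
    sapwood_depth_cm: float = 2.0
    sapwood_area_cm2: float | None = None
    canopy_area_m2: float = 2.0

    def __post_init__(self) -> None:
        if self.stem_diameter_cm <= 0:
            raise ValueError("stem diameter must be > 0")
        if self.canopy_area_m2 <= 0:
            raise ValueError("canopy area must be > 0")
        if self.sapwood_area_cm2 is not None and self.sapwood_area_cm2 <= 0:
            raise ValueError("sapwood area must be > 0")


@dataclass(frozen=True)
class AllometryModel:
    """Linear sapwood-area vs stem-diameter model, A = intercept + slope * D."""

    intercept: float  # cm^2
    slope: float  # cm^2 per cm diameter
    r_squared: float

    def predict(self, stem_diameter_cm):
        """Predicted sapwood area, cm^2, clamped at a small positive floor."""
        a = self.intercept + self.slope * np.asarray(stem_diameter_cm, dtype=float)
        return np.maximum(a, 1e-6)


# ---------------------------------------------------------------------------
# heat-pulse velocity and wound correction
# ---------------------------------------------------------------------------

def heat_pulse_velocity(v1, v2, probe: ProbeGeometry) -> np.ndarray:
    """Raw heat-pulse velocity Vh (cm/h) from the temperature-rise ratio.

    Non-positive temperature rises leave the log-ratio undefined; those
    samples come back as NaN and the count is logged.  The sign of Vh is
    preserved (negative = reverse flow).
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    valid = (v1 > 0) & (v2 > 0)
    n_bad = int(np.size(valid) - np.count_nonzero(valid))
    if n_bad:
        log.info("heat_pulse_velocity: %d invalid samples (non-positive rise)", n_bad)
    with np.errstate(invalid="ignore", divide="ignore"):
        vh = np.where(valid, (probe.k / probe.x) * np.log(np.where(valid, v1, 1.0) /
                                                          np.where(valid, v2, 1.0)) * 3600.0,
                      np.nan)
    return vh


#: Quadratic wound-correction coefficients (a, b, c) for Vc = a + b*Vh + c*Vh^2,
#: keyed by wound width in cm.  Defaults for ~2 mm drill holes; widths between
#: table keys are linearly interpolated.  Override via `coefficients=`.
WOUND_COEFFICIENTS: dict[float, tuple[float, float, float]] = {
    0.17: (0.0, 1.6821, 0.0015),
    0.20: (0.0, 1.7304, 0.0018),
    0.22: (0.0, 1.7961, 0.0021),
    0.24: (0.0, 1.8558, 0.0024),
    0.26: (0.0, 1.9181, 0.0029),
    0.30: (0.0, 2.0671, 0.0038),
}


def _wound_coeffs(wound_width: float,
                  coefficients: dict[float, tuple[float, float, float]] | None = None,
                  ) -> tuple[float, float, float]:
    table = coefficients if coefficients is not None else WOUND_COEFFICIENTS
    widths = np.array(sorted(table))
    if not (widths[0] <= wound_width <= widths[-1]):
        raise ValueError(
            f"wound width {wound_width} cm outside the supported range "
            f"[{widths[0]}, {widths[-1]}] cm"
        )
    coeff = np.array([table[w] for w in sorted(table)])
    return tuple(np.interp(wound_width, widths, coeff[:, i]) for i in range(3))


def wound_correct(vh, wound_width: float | None,
                  coefficients: dict | None = None):
    """Wound-corrected velocity Vc = a + b*Vh + c*Vh^2.

    The polynomial is applied to |Vh| and the sign restored, so reverse flow
    is corrected symmetrically.  ``wound_width=None`` returns Vh unchanged.
    """
    vh = np.asarray(vh, dtype=float)
    if wound_width is None:
        return vh
    a, b, c = _wound_coeffs(wound_width, coefficients)
    mag = np.abs(vh)
    return np.sign(vh) * (a + b * mag + c * mag**2) * np.where(mag > 0, 1.0, 0.0) \
        + np.where(mag > 0, 0.0, a)


def invert_wound_correction(vc, wound_width: float | None,
                            coefficients: dict | None = None):
    """Raw Vh whose wound correction equals ``vc`` (used by the simulator)."""
    vc = np.asarray(vc, dtype=float)
    if wound_width is None:
        return vc
    a, b, c = _wound_coeffs(wound_width, coefficients)
    mag = np.maximum(np.abs(vc) - a, 0.0)
    if c == 0:
        raw = mag / b
    else:
        raw = (-b + np.sqrt(b * b + 4.0 * c * mag)) / (2.0 * c)
    return np.sign(vc) * raw


# ---------------------------------------------------------------------------
# allometry and radial integration
# ---------------------------------------------------------------------------

def fit_allometry(pairs) -> AllometryModel:
    """Ordinary least-squares fit of sapwood area (cm^2) on stem diameter (cm).

    ``pairs`` is an iterable of (stem_diameter, sapwood_area).  Requires at
    least three pairs and non-degenerate diameters.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("allometry fit needs at least 3 (diameter, area) pairs")
    d, a = arr[:, 0], arr[:, 1]
    if np.ptp(d) == 0:
        raise ValueError("allometry fit degenerate: all stem diameters identical")
    slope, intercept = np.polyfit(d, a, 1)
    pred = intercept + slope * d
    ss_res = float(np.sum((a - pred) ** 2))
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return AllometryModel(float(intercept), float(slope), float(max(min(r2, 1.0), 0.0)))


def annulus_areas(tree: TreeRecord, probe: ProbeGeometry) -> np.ndarray:
    """Sapwood annulus area (cm^2) carried by each thermocouple depth.

    The sapwood band (cambium to sapwood depth) is split at the midpoints
    between successive probe depths into concentric annuli, outermost annulus
    bounded by the cambium and innermost by the sapwood depth.  If the tree
    carries an explicit sapwood area the annuli are rescaled to sum to it.
    """
    r_cambium = tree.stem_diameter_cm / 2.0 - tree.bark_depth_cm
    if r_cambium <= 0:
        raise ValueError("bark depth exceeds stem radius")
    depth_in = min(tree.sapwood_depth_cm, r_cambium)
    depths = np.asarray(probe.depths, dtype=float)
    # annulus boundaries as depths below cambium: 0, midpoints, sapwood depth
    mids = (depths[:-1] + depths[1:]) / 2.0
    bounds = np.concatenate(([0.0], mids, [depth_in]))
    bounds = np.clip(bounds, 0.0, depth_in)
    r_out = r_cambium - bounds[:-1]
    r_in = np.maximum(r_cambium - bounds[1:], 0.0)
    areas = np.pi * (r_out**2 - r_in**2)
    areas = np.maximum(areas, 0.0)
    if tree.sapwood_area_cm2 is not None and areas.sum() > 0:
        areas *= tree.sapwood_area_cm2 / areas.sum()
    return areas


def tree_sap_flow(velocities: pd.DataFrame, tree: TreeRecord,
                  probe: ProbeGeometry) -> pd.Series:
    """Whole-tree volumetric sap flow, L/h.

    ``velocities`` has one column per probe depth (cm/h, wound-corrected) on a
    timestamp index.  Each depth's velocity is multiplied by its annulus area;
    1 cm^3 = 1e-3 L.  Timestamps where every depth is NaN yield NaN (a gap);
    partially valid timestamps use the valid depths with their annulus areas.
    """
    areas = annulus_areas(tree, probe)
    if velocities.shape[1] != areas.size:
        raise ValueError("velocity columns must match probe depths")
    contrib = velocities.to_numpy(dtype=float) * areas[None, :] * 1e-3
    all_nan = np.all(np.isnan(contrib), axis=1)
    flow = np.nansum(contrib, axis=1)
    flow[all_nan] = np.nan
    return pd.Series(flow, index=velocities.index, name=tree.tree_id)


def process_logger_table(samples: pd.DataFrame, probe: ProbeGeometry) -> pd.DataFrame:
    """Long logger table -> wound-corrected velocities.

    Input columns: tree_id, timestamp, depth_cm, v1_C, v2_C.  Output is a long
    frame (tree_id, timestamp, depth_cm, velocity_cm_h) with invalid samples
    as NaN.
    """
    required = {"tree_id", "timestamp", "depth_cm", "v1_C", "v2_C"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"logger table missing columns: {sorted(missing)}")
    vh = heat_pulse_velocity(samples["v1_C"], samples["v2_C"], probe)
    vc = wound_correct(vh, probe.wound_width)
    out = samples[["tree_id", "timestamp", "depth_cm"]].copy()
    out["velocity_cm_h"] = vc
    return out


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def daily_aggregate(flow: pd.Series, tree: TreeRecord,
                    max_gap: str = "2h", qc_threshold: float = 0.8) -> pd.DataFrame:
    """Daily water use per tree from an (half-)hourly flow series in L/h.

    Gaps up to ``max_gap`` are linearly interpolated; days whose fraction of
    valid (pre-fill) intervals falls below ``qc_threshold`` are dropped and
    counted in the ``n_dropped_days`` attribute of the result.  Timestamps are
    interval-ending local time; volumes are trapezoid-free sums of
    flow * step.  ``depth_mm`` is volume / canopy area (L/m^2 == mm).
    """
    if flow.empty:
        out = pd.DataFrame(columns=["tree_id", "date", "volume_l", "depth_mm", "qc"])
        out.attrs["n_dropped_days"] = 0
        return out
    flow = flow.sort_index()
    step_h = (flow.index[1] - flow.index[0]).total_seconds() / 3600.0 if len(flow) > 1 else 1.0
    limit = max(int(round(pd.Timedelta(max_gap) / pd.Timedelta(hours=step_h))), 1)
    valid = flow.notna()
    filled = flow.interpolate(method="time", limit=limit, limit_area="inside")
    # interval-ending stamps: midnight belongs to the previous day
    day = (filled.index - pd.Timedelta(seconds=1)).date
    frame = pd.DataFrame({"flow": filled, "valid": valid.astype(float), "day": day})
    grouped = frame.groupby("day")
    volume = grouped["flow"].sum() * step_h
    qc = grouped["valid"].mean()
    keep = qc >= qc_threshold
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("daily_aggregate(%s): dropped %d low-QC days", tree.tree_id, n_dropped)
    out = pd.DataFrame({
        "tree_id": tree.tree_id,
        "date": volume.index[keep],
        "volume_l": volume[keep].to_numpy(),
        "qc": qc[keep].to_numpy(),
    })
    out["depth_mm"] = out["volume_l"] / tree.canopy_area_m2
    out = out[["tree_id", "date", "volume_l", "depth_mm", "qc"]].reset_index(drop=True)
    out.attrs["n_dropped_days"] = n_dropped
    return out


def _per_tree_means(daily: pd.DataFrame) -> pd.Series:
    return daily.groupby("tree_id")["volume_l"].mean()


def habitat_summary(daily: pd.DataFrame, trees: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD water use (L/tree/day) per habitat and overall.

    Per-tree period means are computed first; habitat statistics are
    unweighted across trees.  A habitat with a single tree reports SD 0 with
    ``sd_defined = False``.
    """
    known = {"floodplain", "dryland"}
    bad = set(trees["habitat"]) - known
    if bad:
        raise ValueError(f"unknown habitat labels: {sorted(bad)}")
    means = _per_tree_means(daily)
    merged = trees.set_index("tree_id").loc[means.index, "habitat"]
    rows = []
    for habitat, vals in means.groupby(merged):
        rows.append({
            "habitat": habitat,
            "mean_l_day": float(vals.mean()),
            "sd_l_day": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            "n_trees": int(len(vals)),
            "sd_defined": len(vals) > 1,
        })
    rows.append({
        "habitat": "all",
        "mean_l_day": float(means.mean()),
        "sd_l_day": float(means.std(ddof=1)) if len(means) > 1 else 0.0,
        "n_trees": int(len(means)),
        "sd_defined": len(means) > 1,
    })
    return pd.DataFrame(rows)


def seasonal_summary(daily: pd.DataFrame, trees: pd.DataFrame,
                     seasons: dict[str, tuple[int, ...]] | None = None) -> pd.DataFrame:
    """Habitat summary restricted to each season's month window.

    Default windows follow the local climatology: dry = Jan-Mar, rainy =
    Jul-Sep.  Empty windows are flagged, not errors.
    """
    seasons = seasons or {"dry": (1, 2, 3), "rainy": (7, 8, 9)}
    months = pd.to_datetime(daily["date"]).dt.month
    frames = []
    for name, window in seasons.items():
        if not window:
            raise ValueError(f"season {name!r} has an empty month window")
        sub = daily[months.isin(window)]
        if sub.empty:
            frames.append(pd.DataFrame([{"season": name, "habitat": "all",
                                         "mean_l_day": np.nan, "sd_l_day": np.nan,
                                         "n_trees": 0, "sd_defined": False,
                                         "empty": True}]))
            continue
        block = habitat_summary(sub, trees)
        block.insert(0, "season", name)
        block["empty"] = False
        frames.append(block)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# stand scaling
# ---------------------------------------------------------------------------

def size_class_table(daily: pd.DataFrame, trees: pd.DataFrame,
                     bounds: list[float] | None = None,
                     proportions: list[float] | None = None,
                     allometry: AllometryModel | None = None) -> pd.DataFrame:
    """Stem size classes with representative flows (L/day).

    Classes are diameter intervals ``bounds[i], bounds[i+1]``; default bounds
    are terciles of the instrumented diameters.  ``proportions`` is the share
    of stand trees per class (default: share of instrumented trees).  The
    representative flow per class defaults to the mean daily volume of the
    instrumented trees in the class; if ``allometry`` is given, a
    regression-mode representative flow proportional to predicted sapwood
    area at the class mid-diameter is used instead.
    """
    means = _per_tree_means(daily)
    diam = trees.set_index("tree_id").loc[means.index, "stem_diameter_cm"]
    if bounds is None:
        qs = np.quantile(diam, [0.0, 1 / 3, 2 / 3, 1.0])
        bounds = list(qs)
        bounds[0] -= 1e-9
        bounds[-1] += 1e-9
    bounds = list(map(float, bounds))
    labels = np.searchsorted(bounds, diam, side="right") - 1
    labels = np.clip(labels, 0, len(bounds) - 2)
    rows = []
    n_classes = len(bounds) - 1
    if proportions is None:
        proportions = [float(np.mean(labels == c)) for c in range(n_classes)]
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    if allometry is not None:
        mean_area = allometry.predict(diam).mean()
        flux_per_area = means.mean() / mean_area  # L/day per cm^2 sapwood
    for c in range(n_classes):
        in_class = means[labels == c]
        if allometry is not None:
            mid = (bounds[c] + bounds[c + 1]) / 2.0
            rep = float(allometry.predict(mid) * flux_per_area)
        else:
            rep = float(in_class.mean()) if len(in_class) else 0.0
        rows.append({"diameter_lo": bounds[c], "diameter_hi": bounds[c + 1],
                     "proportion": proportions[c], "representative_flow_l_day": rep})
    return pd.DataFrame(rows)


def stand_transpiration(classes: pd.DataFrame, canopy_area_m2: float = 2.0,
                        stand_density: float | None = None) -> float:
    """Stand transpiration, mm/day, as a size-class weighted mean tree flow.

    Q_bar = sum_c p_c * Q_c (L/day).  Canopy-normalized mode (default) divides
    by the mean canopy area (L/m^2 == mm); density mode multiplies by stand
    density in trees/m^2.
    """
    p = classes["proportion"].to_numpy(dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("size-class proportions must sum to 1")
    q_bar = float(np.sum(p * classes["representative_flow_l_day"].to_numpy(dtype=float)))
    if stand_density is not None:
        return q_bar * stand_density
    if canopy_area_m2 <= 0:
        raise ValueError("canopy area must be > 0")
    return q_bar / canopy_area_m2
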