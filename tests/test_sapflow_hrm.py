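"""Heat-ratio-method processing: velocities, wound correction, allometry,
radial integration, daily/habitat/seasonal aggregation and stand scaling."""
from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prosopis_water import synthetic_data as sd
from prosopis_water.sapflow_hrm import (AllometryModel, ProbeGeometry,
                                        TreeRecord, annulus_areas,
                                        daily_aggregate, fit_allometry,
                                        habitat_summary, heat_pulse_velocity,
                                        invert_wound_correction,
                                        seasonal_summary, size_class_table,
                                        stand_transpiration, tree_sap_flow,
                                        wound_correct)


def _tree(**kw) -> TreeRecord:
    base = dict(tree_id="t1", site="site1", habitat="dryland",
                stem_diameter_cm=15.0, sapwood_depth_cm=2.0,
                sapwood_area_cm2=50.0, canopy_area_m2=2.0)
    base.update(kw)
    return TreeRecord(**base)


class TestHeatPulseVelocity:
    def test_equal_rises_give_zero_flow(self, probe):
        assert heat_pulse_velocity(0.4, 0.4, probe) == pytest.approx(0.0)

    def test_ratio_e_gives_18_cm_per_hour(self):
        # (k/x) * ln(e) * 3600 = (2.5e-3 / 0.5) * 3600 = 18
        probe = ProbeGeometry(k=2.5e-3, x=0.5)
        assert heat_pulse_velocity(np.e, 1.0, probe) == pytest.approx(18.0, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(v1=st.floats(0.01, 5.0), v2=st.floats(0.01, 5.0))
    def test_antisymmetric_in_swapped_rises(self, v1, v2):
        probe = ProbeGeometry()
        assert heat_pulse_velocity(v1, v2, probe) == pytest.approx(
            -heat_pulse_velocity(v2, v1, probe), rel=1e-12, abs=1e-12)

    def test_nonpositive_rise_marked_invalid(self, probe):
        vh = heat_pulse_velocity([0.4, -0.1, 0.0], [0.4, 0.4, 0.4], probe)
        assert np.isfinite(vh[0])
        assert np.isnan(vh[1]) and np.isnan(vh[2])


class TestWoundCorrection:
    def test_identity_coefficients(self):
        table = {0.2: (0.0, 1.0, 0.0)}
        v = np.linspace(-30, 30, 13)
        np.testing.assert_allclose(wound_correct(v, 0.2, table), v)

    def test_zero_velocity_stays_zero(self):
        assert wound_correct(0.0, 0.20) == pytest.approx(0.0)

    @pytest.mark.parametrize("width", [0.17, 0.20, 0.24, 0.30])
    def test_correction_inflates_velocity(self, width):
        vh = np.linspace(0.1, 60.0, 200)
        vc = wound_correct(vh, width)
        assert np.all(vc >= vh)
        assert np.all(np.diff(vc) > 0)  # monotone over the valid range

    def test_out_of_range_width_names_supported_range(self):
        with pytest.raises(ValueError, match=r"0\.17.*0\.3"):
            wound_correct(10.0, 0.5)

    def test_inversion_round_trips(self):
        v = np.linspace(-40, 40, 81)
        raw = invert_wound_correction(v, 0.22)
        np.testing.assert_allclose(wound_correct(raw, 0.22), v, atol=1e-10)


class TestAllometry:
    def test_exact_line_recovered(self):
        d = np.array([5.0, 10.0, 20.0, 30.0])
        model = fit_allometry(zip(d, 3.0 * d - 4.0))
        assert model.slope == pytest.approx(3.0)
        assert model.intercept == pytest.approx(-4.0)
        assert model.r_squared == pytest.approx(1.0)

    def test_degenerate_designs_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            fit_allometry([(10, 20), (10, 25), (10, 30)])
        with pytest.raises(ValueError, match="3"):
            fit_allometry([(10, 20), (12, 25)])

    def test_noiseless_inventory_round_trip(self):
        inv = sd.generate_tree_inventory(20, seed=7, noise_sd_cm2=0.0)
        model = fit_allometry(zip(inv["stem_diameter_cm"], inv["sapwood_area_cm2"]))
        a0, b0 = sd.DEFAULT_ALLOMETRY
        assert model.slope == pytest.approx(b0, rel=1e-6)
        assert model.intercept == pytest.approx(a0, rel=1e-6)

    def test_prediction_clamped_positive(self):
        model = AllometryModel(intercept=-100.0, slope=1.0, r_squared=0.9)
        assert model.predict(1.0) > 0


class TestTreeSapFlow:
    def test_zero_velocity_zero_flow(self, probe):
        idx = pd.date_range("2017-01-01 00:30", periods=4, freq="30min")
        vel = pd.DataFrame(0.0, index=idx, columns=list(probe.depths))
        assert tree_sap_flow(vel, _tree(), probe).abs().sum() == 0.0

    def test_unit_identity_single_depth(self):
        # 10 cm/h through 50 cm^2 = 500 cm^3/h = 0.5 L/h
        probe = ProbeGeometry(depths=(1.0,))
        idx = pd.date_range("2017-01-01 00:30", periods=2, freq="30min")
        vel = pd.DataFrame(10.0, index=idx, columns=[1.0])
        flow = tree_sap_flow(vel, _tree(), probe)
        assert flow.iloc[0] == pytest.approx(0.5)

    def test_linear_in_each_annulus(self, probe):
        """Flow with (v, 0) plus flow with (0, v) equals flow with (v, v)."""
        tree = _tree()
        idx = pd.date_range("2017-01-01 00:30", periods=1, freq="30min")
        def flow(vals):
            vel = pd.DataFrame([vals], index=idx, columns=list(probe.depths))
            return tree_sap_flow(vel, tree, probe).iloc[0]
        areas = annulus_areas(tree, probe)
        brute = sum(12.0 * a * 1e-3 for a in areas)
        assert flow([12.0, 0.0]) + flow([0.0, 12.0]) == pytest.approx(flow([12.0, 12.0]))
        assert flow([12.0, 12.0]) == pytest.approx(brute)

    def test_annuli_rescaled_to_sapwood_area(self, probe):
        assert annulus_areas(_tree(), probe).sum() == pytest.approx(50.0)

    def test_all_depths_invalid_is_gap(self, probe):
        idx = pd.date_range("2017-01-01 00:30", periods=2, freq="30min")
        vel = pd.DataFrame([[np.nan, np.nan], [5.0, np.nan]],
                           index=idx, columns=list(probe.depths))
        flow = tree_sap_flow(vel, _tree(), probe)
        assert np.isnan(flow.iloc[0]) and np.isfinite(flow.iloc[1])


class TestDailyAggregate:
    def _series(self, values, periods, start="2017-01-01 00:30"):
        idx = pd.date_range(start, periods=periods, freq="30min")
        return pd.Series(values, index=idx)

    def test_constant_half_litre_per_hour_sums_to_12(self):
        daily = daily_aggregate(self._series(0.5, 48), _tree())
        assert daily["volume_l"].iloc[0] == pytest.approx(12.0)

    def test_depth_equivalent_over_canopy(self):
        # 6.8 L over a 2 m^2 canopy is 3.4 mm
        daily = daily_aggregate(self._series(6.8 / 24.0, 48), _tree())
        assert daily["depth_mm"].iloc[0] == pytest.approx(3.4)

    def test_interpolating_constant_series_preserves_total(self):
        full = self._series(1.0, 48)
        gappy = full.copy()
        gappy.iloc[4:6] = np.nan   # two separate <=2 h gaps
        gappy.iloc[20:23] = np.nan
        a = daily_aggregate(full, _tree(), qc_threshold=0.0)
        b = daily_aggregate(gappy, _tree(), qc_threshold=0.0)
        assert b["volume_l"].iloc[0] == pytest.approx(a["volume_l"].iloc[0])

    def test_low_qc_days_dropped_and_counted(self):
        flow = self._series(1.0, 96)
        flow.iloc[10:34] = np.nan  # half of day one missing
        daily = daily_aggregate(flow, _tree(), qc_threshold=0.8)
        assert len(daily) == 1
        assert daily.attrs["n_dropped_days"] == 1

    def test_empty_series_empty_output(self):
        daily = daily_aggregate(pd.Series(dtype=float), _tree())
        assert daily.empty


def _daily_from_means(means: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for _, r in means.iterrows():
        for d in range(3):
            rows.append({"tree_id": r["tree_id"], "date": date(2017, 1, d + 1),
                         "volume_l": r["mean_daily_l"],
                         "depth_mm": r["mean_daily_l"] / 2.0, "qc": 1.0})
    return pd.DataFrame(rows)


class TestSummaries:
    def test_habitat_means_match_field_campaign_arithmetic(self):
        means = sd.instrumented_tree_daily_means()
        trees = means.rename(columns={"mean_daily_l": "x"})
        out = habitat_summary(_daily_from_means(means), trees)
        get = lambda h: out.loc[out["habitat"] == h, "mean_l_day"].iloc[0]
        assert round(get("dryland"), 1) == 8.5
        assert round(get("floodplain"), 1) == 5.1
        assert round(get("all"), 1) == 6.8

    def test_single_tree_sd_zero_flagged(self):
        means = sd.instrumented_tree_daily_means().iloc[:1]
        out = habitat_summary(_daily_from_means(means), means)
        row = out[out["habitat"] == "floodplain"].iloc[0]
        assert row["sd_l_day"] == 0.0 and not row["sd_defined"]

    def test_unknown_habitat_rejected(self):
        means = sd.instrumented_tree_daily_means().copy()
        means.loc[0, "habitat"] = "swamp"
        with pytest.raises(ValueError, match="swamp"):
            habitat_summary(_daily_from_means(means), means)

    def test_uniform_flow_gives_equal_seasons(self):
        means = sd.instrumented_tree_daily_means()
        rows = []
        for _, r in means.iterrows():
            for month in (1, 8):
                rows.append({"tree_id": r["tree_id"], "date": date(2017, month, 5),
                             "volume_l": 5.0, "depth_mm": 2.5, "qc": 1.0})
        out = seasonal_summary(pd.DataFrame(rows), means)
        dry = out[(out["season"] == "dry") & (out["habitat"] == "all")]
        rainy = out[(out["season"] == "rainy") & (out["habitat"] == "all")]
        assert dry["mean_l_day"].iloc[0] == rainy["mean_l_day"].iloc[0]

    def test_empty_window_flagged_not_error(self):
        means = sd.instrumented_tree_daily_means()
        out = seasonal_summary(_daily_from_means(means), means)  # Jan data only
        rainy = out[out["season"] == "rainy"]
        assert rainy["empty"].all() and rainy["n_trees"].iloc[0] == 0


class TestStandTranspiration:
    def test_single_class_normalized(self):
        classes = pd.DataFrame([{"diameter_lo": 0, "diameter_hi": 99,
                                 "proportion": 1.0,
                                 "representative_flow_l_day": 6.8}])
        assert stand_transpiration(classes, canopy_area_m2=2.0) == pytest.approx(3.4)

    def test_weighted_sum_of_two_classes(self):
        classes = pd.DataFrame([
            {"diameter_lo": 0, "diameter_hi": 10, "proportion": 0.5,
             "representative_flow_l_day": 4.0},
            {"diameter_lo": 10, "diameter_hi": 99, "proportion": 0.5,
             "representative_flow_l_day": 8.0}])
        assert stand_transpiration(classes, canopy_area_m2=2.0) == pytest.approx(3.0)

    def test_proportions_must_sum_to_one(self):
        classes = pd.DataFrame([{"diameter_lo": 0, "diameter_hi": 99,
                                 "proportion": 0.7,
                                 "representative_flow_l_day": 5.0}])
        with pytest.raises(ValueError, match="sum to 1"):
            stand_transpiration(classes)

    def test_density_mode_units(self):
        classes = pd.DataFrame([{"diameter_lo": 0, "diameter_hi": 99,
                                 "proportion": 1.0,
                                 "representative_flow_l_day": 6.8}])
        # 6.8 L/tree/day * 0.5 trees/m^2 = 3.4 L/m^2/day = 3.4 mm/day
        assert stand_transpiration(classes, stand_density=0.5) == pytest.approx(3.4)

    def test_size_class_table_from_inventory(self):
        means = sd.instrumented_tree_daily_means()
        inv = sd.default_study_inventory(seed=0)
        classes = size_class_table(_daily_from_means(means), inv)
        assert classes["proportion"].sum() == pytest.approx(1.0)
        q_bar = (classes["proportion"] * classes["representative_flow_l_day"]).sum()
        assert q_bar == pytest.approx(means["mean_daily_l"].mean(), rel=0.15)
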