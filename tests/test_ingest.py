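"""Survey-record filters, corrections and biomass standardization."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from krillspot.ingest import (
    CoefficientTable,
    apply_net_avoidance_correction,
    assign_ecosection,
    assign_stage_group,
    filter_depth_disparity,
    filter_season_daylight,
    ingest,
    read_haul_table,
    standardize_biomass,
)


def _haul(hid, bottom, sampling, year=2005, month=6, daylight=True):
    return {
        "haul_id": hid, "station_id": hid, "year": year, "month": month,
        "x_km": 1.0, "y_km": 1.0, "bottom_depth_m": bottom,
        "sampling_depth_m": sampling, "volume_m3": 100.0,
        "daylight": daylight, "species": "E_pacifica", "stage": "S4",
        "sex": "female", "count_per_haul": 1.0, "subsample_fraction": 1.0,
    }


class TestDepthDisparity:
    @pytest.mark.parametrize("bottom,sampling,kept", [
        (80.0, 45.0, False),   # gap 35 > 30 at shallow bottom
        (80.0, 80.0, True),    # zero gap
        (80.0, 52.0, True),    # gap 28 <= 30
        (200.0, 140.0, False),  # gap 60 > 50 at mid bottom
        (200.0, 160.0, True),   # gap 40 <= 50
        (400.0, 250.0, True),   # deep station, net capped at 250 m
        (400.0, 100.0, True),   # deep stations always kept
    ])
    def test_rules(self, bottom, sampling, kept):
        df = pd.DataFrame([_haul("H0", bottom, sampling)])
        out, excl = filter_depth_disparity(df)
        assert (len(out) == 1) is kept

    def test_missing_depth_rejected_with_warning(self):
        df = pd.DataFrame([_haul("H0", np.nan, 50.0)])
        with pytest.warns(UserWarning, match="missing depth"):
            out, excl = filter_depth_disparity(df)
        assert len(out) == 0
        assert excl["exclusion_reason"].iloc[0] == "missing depth"

    def test_idempotent(self):
        df = pd.DataFrame([_haul(f"H{i}", b, s) for i, (b, s) in
                           enumerate([(80, 45), (80, 80), (200, 160)])])
        once, _ = filter_depth_disparity(df)
        twice, _ = filter_depth_disparity(once)
        pd.testing.assert_frame_equal(once, twice)


class TestSeasonDaylight:
    @pytest.mark.parametrize("year,month,day,kept", [
        (1991, 6, True, False),   # pre-1993 truncated
        (2005, 3, True, False),   # outside Apr-Sep
        (2005, 7, False, False),  # night haul
        (2005, 7, True, True),
        (1993, 4, True, True),
        (2019, 9, True, True),
    ])
    def test_rules(self, year, month, day, kept):
        df = pd.DataFrame([_haul("H0", 100, 95, year, month, day)])
        out, _ = filter_season_daylight(df)
        assert (len(out) == 1) is kept

    def test_idempotent(self):
        df = pd.DataFrame([_haul(f"H{i}", 100, 95, y, m, d) for i, (y, m, d) in
                           enumerate([(1991, 6, True), (2005, 7, True),
                                      (2005, 7, False)])])
        once, _ = filter_season_daylight(df)
        twice, _ = filter_season_daylight(once)
        pd.testing.assert_frame_equal(once, twice)


class TestAvoidanceCorrection:
    def test_multiplication_and_conservation(self):
        rows = [_haul("H0", 100, 95)]
        rows.append({**_haul("H0", 100, 95), "stage": "s1", "sex": ""})
        df = pd.DataFrame(rows)
        df["count_per_haul"] = [10.0, 8.0]
        out = apply_net_avoidance_correction(df, 3.0)
        assert out["count_corrected"].tolist() == [30.0, 8.0]  # larvae uncorrected
        out2 = apply_net_avoidance_correction(df, 3.0, correct_larvae=True)
        assert out2["count_corrected"].tolist() == [30.0, 24.0]
        # factor 1 is the identity
        out3 = apply_net_avoidance_correction(df, 1.0)
        assert out3["count_corrected"].tolist() == [10.0, 8.0]

    def test_subsample_scaling_before_correction(self):
        df = pd.DataFrame([{**_haul("H0", 100, 95),
                            "subsample_fraction": 0.25}])
        out = apply_net_avoidance_correction(df, 2.0)
        assert out["count_corrected"].iloc[0] == pytest.approx(8.0)

    def test_invalid_factor(self):
        df = pd.DataFrame([_haul("H0", 100, 95)])
        with pytest.raises(ValueError):
            apply_net_avoidance_correction(df, 0.0)


class TestStageGroups:
    @pytest.mark.parametrize("length,egg,sex,expected", [
        (2.9, True, None, "eggs"),
        (4.9, False, None, "s1"),
        (5.0, False, None, "s2"),
        (9.99, False, None, "s2"),
        (10.0, False, "female", "S4_female"),
        (12.0, False, "male", "S4_male"),
        (11.0, False, None, "S4_unknown"),
    ])
    def test_boundaries(self, length, egg, sex, expected):
        assert assign_stage_group(length, egg, sex) == expected

    def test_unknown_sex_coefficient_falls_back_to_mean(self):
        tbl = CoefficientTable()
        tbl.set("E_pacifica", "S4", 6.0, sex="female")
        tbl.set("E_pacifica", "S4", 4.0, sex="male")
        assert tbl.lookup("E_pacifica", "S4", "unknown") == pytest.approx(5.0)
        with pytest.raises(KeyError):
            tbl.lookup("X_species", "S4", "female")


class TestStandardize:
    def _coeffs(self):
        tbl = CoefficientTable()
        tbl.set("E_pacifica", "S4", 5.0, sex="female")
        tbl.set("T_spinifera", "S4", 7.0, sex="male")
        tbl.set("E_pacifica", "eggs", 0.1)
        tbl.set("E_pacifica", "s1", 0.5)
        return tbl

    def test_arithmetic_chain(self):
        # 20 ind x 5 mg / 100 m3 * 200 m depth = 200 mg/m2
        df = pd.DataFrame([{**_haul("H0", 210, 200), "count_per_haul": 20.0}])
        df = apply_net_avoidance_correction(df, 1.0)
        obs, excl = standardize_biomass(df, self._coeffs())
        ep = obs[obs["group"] == "EP_adult"]["biomass_mg_m2"].iloc[0]
        assert ep == pytest.approx(200.0)
        assert len(obs) == 3  # always three groups per haul
        assert set(obs["group"]) == {"EP_adult", "TS_adult", "larvae"}

    def test_larval_pooling(self):
        # eggs 10 x 0.1 + s1 10 x 0.5 = 6 mg / 50 m3 * 100 m = 12 mg/m2
        base = _haul("H0", 110, 100)
        base["volume_m3"] = 50.0
        rows = [
            {**base, "stage": "eggs", "sex": "", "count_per_haul": 10.0},
            {**base, "stage": "s1", "sex": "", "count_per_haul": 10.0},
        ]
        df = apply_net_avoidance_correction(pd.DataFrame(rows), 1.0)
        obs, _ = standardize_biomass(df, self._coeffs())
        larv = obs[obs["group"] == "larvae"]["biomass_mg_m2"].iloc[0]
        assert larv == pytest.approx(12.0)

    def test_zero_counts_give_zero_observations(self):
        df = pd.DataFrame([{**_haul("H0", 110, 100), "count_per_haul": 0.0}])
        df = apply_net_avoidance_correction(df, 2.0)
        obs, _ = standardize_biomass(df, self._coeffs())
        assert (obs["biomass_mg_m2"] == 0).all()

    def test_missing_volume_excludes_haul(self):
        df = pd.DataFrame([{**_haul("H0", 110, 100), "volume_m3": np.nan}])
        df = apply_net_avoidance_correction(df, 1.0)
        obs, excl = standardize_biomass(df, self._coeffs())
        assert len(obs) == 0
        assert excl["exclusion_reason"].iloc[0] == "no volume"

    def test_volume_fallback_from_wire_out(self):
        df = pd.DataFrame([{**_haul("H0", 110, 100), "volume_m3": np.nan,
                            "wire_out_m": 100.0, "count_per_haul": 10.0}])
        df = apply_net_avoidance_correction(df, 1.0)
        obs, excl = standardize_biomass(
            df, self._coeffs(),
            volume_fallback={"mouth_area_m2": 0.25, "tow_angle_deg": 0.0})
        assert len(obs) == 3
        ep = obs[obs["group"] == "EP_adult"]["biomass_mg_m2"].iloc[0]
        assert ep == pytest.approx(10 * 5.0 / 25.0 * 100.0)

    def test_unit_chain_matches_scalar_recomputation(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(20):
            h = _haul(f"H{i}", 260, rng.uniform(50, 250))
            h["volume_m3"] = rng.uniform(20, 200)
            h["subsample_fraction"] = rng.choice([0.25, 1.0])
            h["count_per_haul"] = rng.uniform(0, 50)
            rows.append(h)
        df = apply_net_avoidance_correction(pd.DataFrame(rows), 2.5)
        obs, _ = standardize_biomass(df, self._coeffs())
        for _, h in pd.DataFrame(rows).iterrows():
            expected = (h["count_per_haul"] / h["subsample_fraction"] * 2.5
                        * 5.0 / h["volume_m3"] * h["sampling_depth_m"])
            got = obs[(obs["haul_id"] == h["haul_id"])
                      & (obs["group"] == "EP_adult")]["biomass_mg_m2"].iloc[0]
            assert got == pytest.approx(expected, rel=1e-12)


class TestEcosections:
    POLYS = [("A", box(0, 0, 10, 10)), ("B", box(10, 0, 20, 10))]

    def test_point_in_polygon(self):
        assert assign_ecosection(5, 5, self.POLYS) == "A"
        assert assign_ecosection(15, 5, self.POLYS) == "B"

    def test_shared_edge_goes_to_first_listed(self):
        assert assign_ecosection(10, 5, self.POLYS) == "A"

    def test_outside(self):
        assert assign_ecosection(50, 50, self.POLYS) == "outside"


class TestReadHaulTable:
    def test_wide_dialect_melts(self, tmp_path):
        wide = pd.DataFrame([{
            "haul_id": "H0", "station_id": "S0", "year": 2005, "month": 6,
            "x_km": 1.0, "y_km": 2.0, "bottom_depth_m": 100.0,
            "sampling_depth_m": 95.0, "volume_m3": 80.0, "daylight": True,
            "count_E_pacifica_S4_female": 5.0,
            "count_E_pacifica_s2": 7.0,
            "count_T_spinifera_S4_male": 3.0,
        }])
        path = tmp_path / "wide.csv"
        wide.to_csv(path, index=False)
        long = read_haul_table(path)
        assert len(long) == 3
        row = long[long["stage"] == "s2"].iloc[0]
        assert row["species"] == "E_pacifica"
        assert row["count_per_haul"] == 7.0
        s4 = long[long["sex"] == "female"].iloc[0]
        assert s4["species"] == "E_pacifica" and s4["stage"] == "S4"


def test_ingest_chain(haul_frame):
    tbl = CoefficientTable()
    tbl.set("E_pacifica", "S4", 5.0, sex="female")
    tbl.set("T_spinifera", "S4", 7.0, sex="male")
    tbl.set("E_pacifica", "s1", 0.5)
    with pytest.warns(UserWarning):
        obs, log = ingest(haul_frame, tbl, avoidance_factor=1.0)
    # H2 has gap 50 at bottom 300 -> kept (deep station)
    assert obs["haul_id"].nunique() == 3
    assert len(obs) == 9
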