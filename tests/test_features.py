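"""Vegetation indices, thermal time, accumulations and the element space."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenofcm.features import (
    FEATURE_VOCABULARY,
    START_DOY,
    accumulate_weather,
    assemble_element_space,
    compute_vi,
    cumulative_integral_vi,
    daily_accumulation_basis,
    doy_encoding,
    gdd,
    interpolate_gaps,
)


def band_record(**values):
    base = {"B02": 0.1, "B03": 0.1, "B04": 0.1, "B06": 0.1, "B08": 0.1, "B11": 0.1, "B12": 0.1}
    base.update(values)
    return base


class TestVegetationIndices:
    @pytest.mark.parametrize(
        "vi,bands,expected",
        [
            ("NDVI", dict(B08=0.5, B04=0.1), (0.5 - 0.1) / (0.5 + 0.1)),
            ("NDVI", dict(B08=0.3, B04=0.3), 0.0),
            ("SIPI", dict(B08=0.5, B02=0.1, B04=0.3), 2.0),
            ("NDWI", dict(B03=0.2, B08=0.6), (0.2 - 0.6) / (0.6 + 0.2)),
            ("NDMI", dict(B08=0.5, B11=0.25), (0.5 - 0.25) / (0.5 + 0.25)),
            ("PSRI", dict(B04=0.3, B02=0.1, B06=0.4), 0.5),
            ("SAVI", dict(B08=0.5, B04=0.1), (0.4 / (0.6 + 0.428)) * 1.428),
            ("EVI", dict(B08=0.5, B04=0.1, B02=0.05), 2.5 * 0.4 / (0.5 + 0.6 - 0.375 + 1.0)),
            ("WDRVI", dict(B08=0.5, B04=0.05), (0.1 - 0.05) / (0.1 + 0.05)),
            ("GVMI", dict(B08=0.5, B12=0.2), (0.6 - 0.22) / (0.6 + 0.22)),
        ],
    )
    def test_printed_formulas(self, vi, bands, expected):
        assert compute_vi(band_record(**bands), vi) == pytest.approx(expected)

    def test_zero_denominator_yields_nan(self):
        val = compute_vi(band_record(B08=0.0, B04=0.0), "NDVI")
        assert np.isnan(val)

    def test_unknown_index_rejected(self):
        with pytest.raises(ValueError):
            compute_vi(band_record(), "NDXI")

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.001, 1.0), min_size=7, max_size=7))
    def test_normalized_difference_indices_bounded(self, refl):
        b = dict(zip(("B02", "B03", "B04", "B06", "B08", "B11", "B12"), refl))
        for vi in ("NDVI", "NDWI", "NDMI", "GVMI"):
            v = compute_vi(b, vi)
            assert -1.0 - 1e-12 <= v <= 1.0 + 1e-12


class TestGdd:
    def test_warm_day(self):
        assert gdd(30.0, 21.2) == pytest.approx(10.0)

    def test_mean_at_base_is_zero(self):
        assert gdd(15.6, 15.6) == 0.0

    def test_cool_day_clipped_at_zero(self):
        assert gdd(16.0, 10.0) == 0.0

    def test_inverted_minmax_rejected(self):
        with pytest.raises(ValueError):
            gdd(10.0, 20.0)


class TestDoyEncoding:
    def test_quarter_period_hits_unit_sine(self):
        s, c = doy_encoding(365.25 / 4.0)
        assert s == pytest.approx(1.0)
        assert c == pytest.approx(0.0, abs=1e-12)

    def test_doy_100(self):
        s, c = doy_encoding(100)
        assert s == pytest.approx(np.sin(2 * np.pi * 100 / 365.25))
        assert c == pytest.approx(np.cos(2 * np.pi * 100 / 365.25))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(1, 366))
    def test_unit_circle_identity(self, doy):
        s, c = doy_encoding(doy)
        assert s * s + c * c == pytest.approx(1.0)

    @pytest.mark.parametrize("doy", [0, 367, -5])
    def test_out_of_range_rejected(self, doy):
        with pytest.raises(ValueError):
            doy_encoding(doy)


class TestInterpolation:
    def test_midpoint_gap(self):
        s = pd.Series([0.2, np.nan, 0.4], index=[100, 105, 110])
        assert interpolate_gaps(s).loc[105] == pytest.approx(0.3)

    def test_no_gaps_is_identity(self):
        s = pd.Series([0.1, 0.2, 0.3], index=[100, 105, 110])
        pd.testing.assert_series_equal(interpolate_gaps(s), s.astype(float))

    def test_leading_gap_takes_nearest_value(self):
        s = pd.Series([np.nan, 0.2, 0.4], index=[95, 100, 110])
        assert interpolate_gaps(s).loc[95] == pytest.approx(0.2)

    def test_single_defined_point_rejected(self):
        s = pd.Series([np.nan, 0.2, np.nan], index=[95, 100, 110])
        with pytest.raises(ValueError):
            interpolate_gaps(s)


class TestAccumulation:
    def test_constant_gdd_sums(self, tiny_weather):
        w = tiny_weather[tiny_weather.field_id == "a"]
        # 10 degC above base each day: (25.6 + 15.6)/2 - 15.6 = 5
        assert accumulate_weather(w, "gdd", 100, 109) == pytest.approx(50.0)

    def test_degenerate_single_day_window(self, tiny_weather):
        w = tiny_weather[tiny_weather.field_id == "a"]
        assert accumulate_weather(w, "gdd", 100, 100) == pytest.approx(5.0)

    def test_sequence_matches_direct_summation(self):
        # daily gdd values 0, 2.2, 7.0 via mean temperatures
        rows = []
        for doy, g in ((100, 0.0), (101, 2.2), (102, 7.0)):
            mean = 15.6 + g
            rows.append(
                {"field_id": "a", "doy": doy, "t2m_min": mean - 5, "t2m_max": mean + 5}
            )
        w = pd.DataFrame(rows)
        assert accumulate_weather(w, "gdd", 100, 102) == pytest.approx(9.2)

    def test_missing_day_reported(self, tiny_weather):
        w = tiny_weather[(tiny_weather.field_id == "a") & (tiny_weather.doy != 105)]
        with pytest.raises(ValueError, match="105"):
            accumulate_weather(w, "gdd", 100, 110)

    def test_soil_moisture_uses_daily_mean(self, tiny_weather):
        w = tiny_weather[tiny_weather.field_id == "a"]
        daily = daily_accumulation_basis(w, "soilmoist")
        assert daily.loc[100] == pytest.approx(0.20)


class TestCumulativeIntegral:
    def test_constant_rectangle(self):
        s = pd.Series(0.5, index=np.arange(100, 121, 5))
        assert cumulative_integral_vi(s, 100, 120) == pytest.approx(10.0)

    def test_single_point_is_zero_width(self):
        s = pd.Series([0.7], index=[100])
        assert cumulative_integral_vi(s, 100, 100) == 0.0

    def test_two_point_trapezoid(self):
        s = pd.Series([0.2, 0.6], index=[100, 110])
        assert cumulative_integral_vi(s, 100, 110) == pytest.approx(4.0)

    def test_reversed_window_rejected(self):
        s = pd.Series([0.2, 0.6], index=[100, 110])
        with pytest.raises(ValueError):
            cumulative_integral_vi(s, 110, upto_doy=100)


class TestElementSpace:
    FEATURES = ["sin_doy", "cos_doy", "NDVI", "I_NDVI", "acc_gdd"]

    def test_shape_is_fields_by_acquisitions(self, tiny_bands, tiny_weather):
        X = assemble_element_space(tiny_bands, tiny_weather, self.FEATURES)
        assert X.shape == (6, 5)  # 2 fields x 3 acquisitions
        assert list(X.columns) == self.FEATURES
        assert not X.isna().any().any()

    def test_doy_features_forced_in(self, tiny_bands, tiny_weather):
        X = assemble_element_space(tiny_bands, tiny_weather, ["NDVI"])
        assert {"sin_doy", "cos_doy"} <= set(X.columns)

    def test_unknown_feature_rejected(self, tiny_bands, tiny_weather):
        with pytest.raises(ValueError):
            assemble_element_space(tiny_bands, tiny_weather, ["NDVI", "bogus"])

    def test_row_matches_per_feature_recomputation(self, tiny_bands, tiny_weather):
        X = assemble_element_space(tiny_bands, tiny_weather, self.FEATURES)
        fb = tiny_bands[tiny_bands.field_id == "a"].sort_values("doy")
        ndvi = pd.Series(compute_vi(fb.set_index("doy"), "NDVI"), index=fb["doy"])
        row = X.loc[("a", 110)]
        assert row["NDVI"] == pytest.approx(ndvi.loc[110])
        assert row["I_NDVI"] == pytest.approx(cumulative_integral_vi(ndvi, 100, 110))
        w = tiny_weather[tiny_weather.field_id == "a"]
        assert row["acc_gdd"] == pytest.approx(accumulate_weather(w, "gdd", 100, 110))
        s, c = doy_encoding(110)
        assert row["sin_doy"] == pytest.approx(s)
        assert row["cos_doy"] == pytest.approx(c)

    def test_accumulations_monotone_in_doy(self, small_season):
        X = assemble_element_space(
            small_season.bands, small_season.weather, ["acc_gdd", "acc_precip", "acc_swrad"]
        )
        for _, grp in X.groupby(level="field_id"):
            grp = grp.sort_index(level="doy")
            for col in ("acc_gdd", "acc_precip", "acc_swrad"):
                assert (np.diff(grp[col].to_numpy()) >= -1e-9).all()

    def test_within_season_rows_match_after_season(self, small_season):
        """Feature rows at observed acquisitions never use future data."""
        full = assemble_element_space(small_season.bands, small_season.weather, self.FEATURES)
        cutoff = 200
        truncated_bands = small_season.bands[small_season.bands.doy <= cutoff]
        part = assemble_element_space(truncated_bands, small_season.weather, self.FEATURES)
        observed = set(
            map(tuple, small_season.bands[["field_id", "doy"]].itertuples(index=False))
        )
        shared = [ix for ix in part.index if ix in observed]
        assert len(shared) > 10
        pd.testing.assert_frame_equal(full.loc[shared], part.loc[shared])

    def test_vocabulary_has_32_features(self):
        assert len(FEATURE_VOCABULARY) == 32
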