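"""Fix regularization, step geometry, filtering, covariates and standardization."""
import numpy as np
import pandas as pd
import pytest

import telemove as tm


def fixes_at(minutes, xy, ids="a"):
    t0 = pd.Timestamp("2018-06-01 00:00:00")
    return pd.DataFrame(
        {
            "id": ids,
            "timestamp": [t0 + pd.Timedelta(minutes=m) for m in minutes],
            "x_km": [p[0] for p in xy],
            "y_km": [p[1] for p in xy],
        }
    )


class TestRegularize:
    def test_exact_grid_is_identity(self):
        fx = fixes_at([0, 80, 160], [(0, 0), (1, 0), (2, 0)])
        out = tm.regularize(fx, 80)
        assert np.allclose(out[["x_km", "y_km"]], fx[["x_km", "y_km"]])
        assert (out["timestamp"] == fx["timestamp"]).all()

    def test_gap_inserts_missing_slot(self):
        fx = fixes_at([0, 160], [(0, 0), (2, 0)])
        out = tm.regularize(fx, 80)
        assert len(out) == 3
        assert out["x_km"].isna().tolist() == [False, True, False]

    def test_nearest_within_tolerance(self):
        fx = fixes_at([0, 78, 161], [(0, 0), (1, 0), (2, 0)])
        out = tm.regularize(fx, 80, tolerance_minutes=5)
        assert len(out) == 3
        assert out["x_km"].tolist() == [0, 1, 2]

    def test_fix_outside_tolerance_dropped(self):
        fx = fixes_at([0, 70, 160], [(0, 0), (1, 0), (2, 0)])
        out = tm.regularize(fx, 80, tolerance_minutes=5)
        assert out["x_km"].isna().tolist() == [False, True, False]

    def test_duplicate_timestamps_rejected(self):
        fx = fixes_at([0, 0, 80], [(0, 0), (1, 0), (2, 0)])
        with pytest.raises(ValueError, match="duplicate"):
            tm.regularize(fx, 80)


class TestStepsAndAngles:
    def test_collinear_steps(self):
        out = tm.steps_and_angles(fixes_at([0, 80, 160], [(0, 0), (1, 0), (2, 0)]))
        assert np.allclose(out["step_km"], [1.0, 1.0])
        assert np.isnan(out["angle_rad"].iloc[0])
        assert out["angle_rad"].iloc[1] == pytest.approx(0.0, abs=1e-12)

    def test_left_turn_is_positive(self):
        out = tm.steps_and_angles(fixes_at([0, 80, 160], [(0, 0), (1, 0), (1, 1)]))
        assert out["angle_rad"].iloc[1] == pytest.approx(np.pi / 2)

    def test_two_fixes_single_record_missing_angle(self):
        out = tm.steps_and_angles(fixes_at([0, 80], [(0, 0), (3, 4)]))
        assert len(out) == 1
        assert out["step_km"].iloc[0] == pytest.approx(5.0)
        assert np.isnan(out["angle_rad"].iloc[0])

    def test_missing_position_propagates(self):
        fx = fixes_at([0, 160, 240], [(0, 0), (2, 0), (3, 0)])
        out = tm.steps_and_angles(tm.regularize(fx, 80))
        # slots: 0, missing, 160, 240 -> steps: nan, nan, 1.0
        assert np.isnan(out["step_km"].iloc[0]) and np.isnan(out["step_km"].iloc[1])
        assert out["step_km"].iloc[2] == pytest.approx(1.0)
        assert out["angle_rad"].isna().all()


class TestFilterMinStep:
    def test_zero_threshold_is_noop(self):
        recs = tm.steps_and_angles(fixes_at([0, 80, 160], [(0, 0), (0.05, 0), (1, 0)]))
        out = tm.filter_min_step(recs, 0.0)
        pd.testing.assert_frame_equal(out, recs)

    def test_counts_preserved_and_adjacent_angles_dropped(self):
        rng = np.random.default_rng(0)
        xy = np.cumsum(rng.uniform(0.3, 1.0, (11, 2)), axis=0)
        xy[4] = xy[3] + 0.05  # one short step at index 3
        recs = tm.steps_and_angles(fixes_at(np.arange(11) * 80, xy))
        out = tm.filter_min_step(recs, 0.2)
        assert len(out) == len(recs) == 10
        assert out["step_km"].isna().sum() >= 1
        short = recs["step_km"] < 0.2
        assert out.loc[short, "step_km"].isna().all()
        idx = np.flatnonzero(short)
        assert np.isnan(out["angle_rad"].iloc[idx + 1]).all()

    def test_all_below_threshold_degenerate(self):
        xy = [(0, 0), (0.01, 0), (0.02, 0), (0.03, 0)]
        recs = tm.steps_and_angles(fixes_at([0, 80, 160, 240], xy))
        out = tm.filter_min_step(recs, 0.2)
        assert len(out) == 3 and out["step_km"].isna().all()


class TestCovariates:
    def test_cell_center_lookup_and_mask(self, landscape):
        recs = tm.steps_and_angles(
            fixes_at([0, 80, 160], [(10.5, 20.5), (11.5, 20.5), (12.5, 20.5)])
        )
        out = tm.extract_covariates(recs, landscape)
        assert out["hfi_raw"].iloc[0] == landscape.footprint[20, 10]
        assert out["in_park"].iloc[0] == float(landscape.park_mask[20, 10])

    def test_denning_window_boundaries(self, landscape):
        t0 = pd.Timestamp("2018-01-01")  # 2018 is not a leap year
        days = [160, 220, 159, 221]
        recs = tm.steps_and_angles(fixes_at([0, 80], [(5, 5), (6, 5)]))
        recs = pd.concat([recs.assign(t=t0 + pd.Timedelta(days=d - 1)) for d in days],
                         ignore_index=True)
        out = tm.extract_covariates(recs, landscape)
        assert out["denning"].tolist() == [1, 1, 0, 0]

    def test_outside_extent_raises(self, landscape):
        recs = tm.steps_and_angles(fixes_at([0, 80, 160], [(5, 5), (500, 5), (6, 5)]))
        with pytest.raises(ValueError, match="outside"):
            tm.extract_covariates(recs, landscape)


class TestStandardize:
    def test_two_point_population_convention(self):
        recs = tm.steps_and_angles(fixes_at([0, 80, 160], [(0, 0), (1, 0), (2, 0)]))
        recs["hfi_raw"] = [2.0, 16.0]
        out, stats = tm.standardize(recs)
        assert stats.mean == 9.0 and stats.sd == 7.0
        assert np.allclose(out["hfi_std"].dropna(), [-1.0, 1.0])

    def test_centered_and_unit_scale(self, landscape, ref_spec_nocov):
        recs = tm.synthetic_step_table(ref_spec_nocov, landscape, 2, 80, seed=1)
        recs["hfi_std"] = np.nan
        out, stats = tm.standardize(recs)
        z = out["hfi_std"].dropna()
        assert abs(z.mean()) < 1e-12 and abs(z.std(ddof=0) - 1) < 1e-12
        assert stats.apply(stats.mean) == 0.0

    def test_zero_variance_rejected(self):
        recs = tm.steps_and_angles(fixes_at([0, 80, 160], [(0, 0), (1, 0), (2, 0)]))
        recs["hfi_raw"] = 4.0
        with pytest.raises(ValueError):
            tm.standardize(recs)


class TestPressureScore:
    def test_anchor_values(self):
        assert tm.pressure_score(0) == 0.0
        assert tm.pressure_score(9) == pytest.approx(3.333, abs=1e-12)

    def test_saturation_cap(self):
        assert tm.pressure_score(5000) == tm.pressure_score(1000) == pytest.approx(10.0, abs=0.01)

    def test_vectorized_and_validated(self):
        out = tm.pressure_score([0, 9, 99])
        assert np.allclose(out, [0.0, 3.333, 6.666])
        with pytest.raises(ValueError):
            tm.pressure_score(-1)
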