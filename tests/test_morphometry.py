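"""Morphometry and dynamics tests: measurement, percent change, steady state, CV."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octapipe.morphometry import (
    detect_steady_state,
    group_statistics,
    measure_lesion,
    percent_change_trace,
    pooled_cv_from_reference,
    trace_from_values,
)
from octapipe.synthetic_oct.reference import reference_means

DAYS = [1.0, 3.0, 7.0, 14.0, 21.0]

# printed group means, re-typed here as independent constants for arithmetic
ACUTE = {
    "onl": [128.31, 110.90, 87.86, 94.38, 94.50],
    "rpe": [136.59, 196.09, 156.98, 146.75, 137.17],
    "height": [121.39, 131.55, 125.08, 123.95, 121.55],
    "pr": [129.71, 78.07, 60.96, 64.52, 69.13],
}
CNV = {
    "onl": [408.75, 418.96, 566.08, 457.69, 433.87],
    "rpe": [345.66, 428.85, 566.49, 520.06, 528.33],
    "height": [170.38, 204.83, 246.35, 197.74, 178.06],
    "pr": [276.72, 278.93, 401.73, 314.71, 342.27],
}


class TestDynamicsArithmetic:
    def test_percent_change_matches_spreadsheet_recomputation(self):
        tr = trace_from_values(DAYS, ACUTE["onl"])
        expected_p3 = 100.0 * (110.90 - 128.31) / 128.31
        assert tr.percent_change[1] == pytest.approx(expected_p3, rel=1e-10)
        # every point, against a direct recomputation
        m0 = ACUTE["onl"][0]
        exp = [100.0 * (v - m0) / m0 for v in ACUTE["onl"]]
        np.testing.assert_allclose(tr.percent_change, exp, rtol=1e-10)

    def test_first_diff_normalized_by_baseline(self):
        tr = trace_from_values(DAYS, ACUTE["rpe"])
        assert tr.first_diff[0] == pytest.approx(100.0 * (196.09 - 136.59) / 136.59, rel=1e-10)

    def test_second_diff_length_and_values(self):
        tr = trace_from_values(DAYS, CNV["height"])
        assert len(tr.second_diff) == len(tr.first_diff) - 1
        np.testing.assert_allclose(tr.second_diff, np.diff(tr.first_diff), rtol=1e-12)

    def test_constant_series_is_steady_from_the_start(self):
        tr = trace_from_values(DAYS, [100.0] * 5)
        assert np.all(tr.percent_change == 0)
        assert np.all(tr.first_diff == 0)
        assert tr.steady_onset == 1.0

    def test_preconditions(self):
        with pytest.raises(ValueError):
            trace_from_values([1.0], [5.0])
        with pytest.raises(ValueError):
            trace_from_values([1.0, 1.0], [5.0, 6.0])
        with pytest.raises(ValueError):
            trace_from_values([1.0, 3.0], [0.0, 6.0])

    def test_accepts_dataframe_input(self):
        df = pd.DataFrame({"day": DAYS, "pr_um": ACUTE["pr"]})
        tr = percent_change_trace(df, "pr")
        assert tr.baseline == 129.71

    @settings(deadline=None, max_examples=50)
    @given(scale=st.floats(min_value=1e-3, max_value=1e4))
    def test_scale_invariance(self, scale):
        # the self-normalization that lets lesions of different sexes pool
        base = trace_from_values(DAYS, ACUTE["pr"])
        scaled = trace_from_values(DAYS, [v * scale for v in ACUTE["pr"]])
        np.testing.assert_allclose(scaled.percent_change, base.percent_change, rtol=1e-9)
        np.testing.assert_allclose(scaled.first_diff, base.first_diff, rtol=1e-9)
        assert scaled.steady_onset == base.steady_onset


class TestSteadyState:
    def test_acute_pr_reaches_steady_state_at_day_seven(self):
        tr = trace_from_values(DAYS, ACUTE["pr"])
        onset, phases = detect_steady_state(tr)
        assert onset == 7.0
        assert phases[1.0] == "early" and phases[21.0] == "late"

    @pytest.mark.parametrize("dim", ["onl", "rpe", "height", "pr"])
    def test_cnv_never_converges_through_day_21(self, dim):
        tr = trace_from_values(DAYS, CNV[dim])
        onset, _ = detect_steady_state(tr)
        assert onset is None

    def test_monotone_large_changes_never_converge(self):
        tr = trace_from_values(DAYS, [100, 120, 144, 173, 208])
        onset, _ = detect_steady_state(tr)
        assert onset is None

    def test_needs_three_timepoints(self):
        tr = trace_from_values([1.0, 3.0], [10.0, 11.0])
        with pytest.raises(ValueError):
            detect_steady_state(tr)


class TestGroupStatistics:
    def test_pooled_cv_from_reference_cells(self):
        assert round(pooled_cv_from_reference("acute"), 2) == 0.19
        assert round(pooled_cv_from_reference("cnv"), 2) == 0.33
        assert pooled_cv_from_reference("acute") == pytest.approx(0.194)
        assert pooled_cv_from_reference("cnv"), pytest.approx(0.335)

    def test_identical_lesions_have_zero_cv(self):
        rows = [
            dict(lesion_id=i, day=d, onl_um=100.0, rpe_um=120.0, height_um=110.0, pr_um=90.0)
            for i in range(4)
            for d in DAYS
        ]
        gs = group_statistics(pd.DataFrame(rows))
        assert (gs.cells["cv"] == 0).all()
        assert gs.pooled_cv == 0.0

    def test_population_sd_convention(self, rng):
        vals = rng.normal(100, 10, size=8)
        rows = [
            dict(lesion_id=i, day=1.0, onl_um=v, rpe_um=v, height_um=v, pr_um=v)
            for i, v in enumerate(vals)
        ]
        gs = group_statistics(pd.DataFrame(rows))
        cell = gs.cells[(gs.cells.dimension == "onl")].iloc[0]
        assert cell["std"] == pytest.approx(vals.std(ddof=0))

    def test_zero_mean_cell_excluded_and_flagged(self):
        rows = [
            dict(lesion_id=i, day=1.0, onl_um=0.0, rpe_um=100.0, height_um=90.0, pr_um=80.0)
            for i in range(3)
        ]
        gs = group_statistics(pd.DataFrame(rows))
        assert ("onl", 1.0) in gs.excluded
        assert not np.isnan(gs.pooled_cv)

    def test_single_lesion_cell_rejected(self):
        df = pd.DataFrame([dict(lesion_id=0, day=1.0, onl_um=1, rpe_um=1, height_um=1, pr_um=1)])
        with pytest.raises(ValueError):
            group_statistics(df)


class TestMeasurement:
    def test_acute_day1_dimensions_within_three_voxels(
        self, acute_scene, acute_day1, acute_day1_surfaces
    ):
        vol, _ = acute_day1
        geo = vol.geometry
        si = geo.n_slow // 2
        m = measure_lesion(
            vol.intensities[:, si, :], acute_day1_surfaces, si,
            acute_scene.lesion_specs[0].center_um[1], day=1.0,
        )
        meas = np.array([m.onl_um, m.rpe_um, m.height_um, m.pr_um])
        true = acute_scene.lesion_specs[0].dims_at(1.0)  # 128.31, 136.59, 121.39, 129.71
        assert abs(meas[0] - true[0]) <= 3 * 1.4
        assert abs(meas[1] - true[1]) <= 3 * 1.4
        assert abs(meas[2] - true[2]) <= 3 * 1.9
        assert abs(meas[3] - true[3]) <= 3 * 1.4

    def test_control_bscan_flags_no_lesion(self, control_volume):
        from octapipe.volume_core import register_bscans, segment_surfaces

        _, vol, _ = control_volume
        reg, _ = register_bscans(vol)
        surf = segment_surfaces(reg)
        si = vol.geometry.n_slow // 2
        m = measure_lesion(reg.intensities[:, si, :], surf, si, vol.geometry.field_um[1] / 2)
        assert m.no_lesion
        assert (m.onl_um, m.rpe_um, m.height_um, m.pr_um) == (0, 0, 0, 0)

    def test_cnv_day7_height_recovered(self, cnv_scene_wide):
        from octapipe.synthetic_oct import NoiseModel, render_volume
        from octapipe.volume_core import segment_surfaces

        vol = render_volume(cnv_scene_wide, 7.0, NoiseModel(motion_jitter_um=(0, 0), seed=3))
        surf = segment_surfaces(vol)
        si = vol.geometry.n_slow // 2
        m = measure_lesion(
            vol.intensities[:, si, :], surf, si, cnv_scene_wide.lesion_specs[0].center_um[1], day=7.0
        )
        assert m.height_um == pytest.approx(246.35, abs=3 * 1.9)
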