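"""Generator tests: calibration, dispersion, determinism, lesion schedules."""

import numpy as np
import pytest

from octapipe.synthetic_oct import (
    DimensionError,
    NoiseModel,
    PlacementError,
    render_volume,
    simulate_scene,
    simulate_timecourse,
)
from octapipe.synthetic_oct.reference import reference_cvs, reference_means
from octapipe.volume_core import VolumeGeometry

WIDE = VolumeGeometry(288, 288, 64, dx_um=8.4)


class TestCalibration:
    def test_dispersion_off_reproduces_reference_means_exactly(self):
        scene = simulate_scene(WIDE, "acute", 16, seed=3, dispersion=False)
        means = reference_means("acute")
        for spec in scene.lesion_specs:
            for ti, day in enumerate(spec.timepoint_days):
                np.testing.assert_allclose(
                    spec.true_dims[ti], means.loc[day].to_numpy(), rtol=0, atol=1e-9
                )
        # the printed day-1 ONL width, for every lesion
        assert all(s.dims_at(1.0)[0] == 128.31 for s in scene.lesion_specs)

    def test_cnv_day7_height_matches_reference(self):
        geo = VolumeGeometry(448, 48, 64, dx_um=2.8)
        scene = simulate_scene(geo, "cnv", 1, seed=7, dispersion=False)
        assert scene.lesion_specs[0].dims_at(7.0)[2] == pytest.approx(246.35)

    def test_timecourse_table_is_the_reference_series_with_dispersion_off(self):
        geo = VolumeGeometry(448, 48, 352, dx_um=2.8)
        _, table = simulate_timecourse(
            "cnv", 1, geo, NoiseModel(motion_jitter_um=(0, 0)), seed=7, dispersion=False
        )
        heights = table.sort_values("day")["height_um"].to_numpy()
        np.testing.assert_allclose(heights, [170.38, 204.83, 246.35, 197.74, 178.06])

    def test_one_hour_point_equals_day_one(self):
        scene = simulate_scene(WIDE, "acute", 2, seed=5, include_1h=True)
        for spec in scene.lesion_specs:
            assert spec.timepoint_days[0] == pytest.approx(1 / 24)
            np.testing.assert_allclose(spec.true_dims[0], spec.dims_at(1.0))

    def test_dispersion_recovers_requested_cv(self):
        # scene construction only; no rendering needed at n = 200
        geo = VolumeGeometry(256, 256, 64, dx_um=80.0)
        scene = simulate_scene(geo, "acute", 200, seed=9)
        dims = np.stack([s.true_dims for s in scene.lesion_specs])  # (n, days, 4)
        cvs = reference_cvs("acute").to_numpy()
        emp = dims.std(axis=0) / dims.mean(axis=0)
        rel_err = np.abs(emp - cvs) / cvs
        assert (rel_err < 0.15).all()


class TestLesionRules:
    def test_control_scene_has_no_lesions_and_disjoint_plexuses(self):
        geo = VolumeGeometry(96, 96, 256)
        scene = simulate_scene(geo, "control", 0, seed=1)
        assert scene.lesion_specs == []
        masks = scene.vessel_masks()
        names = list(masks)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                assert not (masks[a] & masks[b]).any()

    def test_acute_scenes_never_lose_vessels(self):
        geo = VolumeGeometry(352, 96, 320, dx_um=4.2)
        scene = simulate_scene(geo, "acute", 1, seed=2, dispersion=False)
        base = scene.vessel_mask("DVP", None).sum()
        for day in scene.timepoint_days:
            # lesion swelling displaces vessels (re-rasterized per day) but
            # must never delete them
            assert scene.vessel_mask("DVP", day).sum() >= 0.97 * base

    def test_cnv_default_schedule_follows_the_height_rule(self):
        # reference heights cross 200 um only on days 3 and 7
        geo = VolumeGeometry(352, 96, 320, dx_um=4.2)
        scene = simulate_scene(geo, "cnv", 1, seed=2, dispersion=False)
        sched = scene.lesion_specs[0].nonperfusion_schedule
        heights = scene.lesion_specs[0].true_dims[:, 2]
        np.testing.assert_array_equal(sched > 0, heights >= 200.0)
        base = scene.vessel_mask("DVP", None).sum()
        for day, f in zip(scene.timepoint_days, sched):
            removed_frac = 1 - scene.vessel_mask("DVP", day).sum() / base
            assert (removed_frac > 0.1) == (f > 0)

    def test_acute_lesions_cannot_rupture(self):
        geo = VolumeGeometry(352, 96, 64, dx_um=4.2)
        scene = simulate_scene(geo, "acute", 1, seed=2)
        assert scene.rpe_rupture == [False]

    def test_placement_errors(self):
        with pytest.raises(DimensionError):
            simulate_scene(VolumeGeometry(64, 64, 64), "cnv", 1, seed=0)
        with pytest.raises(PlacementError):
            simulate_scene(VolumeGeometry(256, 256, 64, dx_um=12.0), "cnv", 4, seed=0)
        with pytest.raises(ValueError):
            simulate_scene(VolumeGeometry(96, 96, 64), "control", 2, seed=0)


class TestRendering:
    def test_determinism_bit_identical(self):
        geo = VolumeGeometry(64, 32, 160)
        a = render_volume(simulate_scene(geo, "control", 0, seed=4), 1.0, NoiseModel(seed=2))
        b = render_volume(simulate_scene(geo, "control", 0, seed=4), 1.0, NoiseModel(seed=2))
        assert np.array_equal(a.intensities, b.intensities)
        assert np.array_equal(a.metadata["applied_offsets"], b.metadata["applied_offsets"])

    def test_zero_jitter_metadata(self, acute_day1):
        vol, _ = acute_day1
        assert not np.any(vol.metadata["applied_offsets"])

    def test_offgrid_timepoint_rejected(self, acute_scene):
        with pytest.raises(KeyError):
            render_volume(acute_scene, 2.5, NoiseModel())

    def test_vessels_are_hyperreflective(self, control_volume):
        # oracle: compare means under the ground-truth mask
        _, vol, truth = control_volume
        allv = np.zeros(vol.intensities.shape, bool)
        for m in truth.vessel_masks.values():
            allv |= m
        inner = (truth.surfaces["ilm"][None] / 1.9 < np.arange(vol.geometry.n_axial)[:, None, None]) & (
            np.arange(vol.geometry.n_axial)[:, None, None] < truth.surfaces["rpe"][None] / 1.9
        )
        inside = vol.intensities[allv & inner].mean()
        outside = vol.intensities[~allv & inner].mean()
        assert inside > outside

    def test_rupture_renders_a_choroidal_void(self, cnv_day1_wide, cnv_scene_wide):
        vol, truth = cnv_day1_wide
        fp = truth.rupture_footprint
        assert fp.any()
        geo = vol.geometry
        z = np.arange(geo.n_axial)[:, None, None] * geo.dz_um
        choroid = (z >= truth.surfaces["rpe"][None] + 15) & (
            z <= truth.surfaces["rpe"][None] + 65
        )
        inside = vol.intensities[choroid & fp[None]].mean()
        outside = vol.intensities[choroid & ~fp[None]].mean()
        assert inside < 0.5 * outside
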