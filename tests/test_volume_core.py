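"""Volume core tests: registration, reslicing, segmentation, slabs."""

import numpy as np
import pytest

from octapipe.synthetic_oct import NoiseModel, render_volume, simulate_scene
from octapipe.volume_core import (
    OCTVolume,
    SegmentationError,
    VolumeGeometry,
    extract_slab,
    flatten_to_surface,
    register_bscans,
    reslice,
    segment_surfaces,
    unflatten,
)


def _shift2(img, dz, dx):
    out = np.zeros_like(img)
    zs = slice(max(dz, 0), img.shape[0] + min(dz, 0))
    xs = slice(max(dx, 0), img.shape[1] + min(dx, 0))
    zsrc = slice(max(-dz, 0), img.shape[0] + min(-dz, 0))
    xsrc = slice(max(-dx, 0), img.shape[1] + min(-dx, 0))
    out[zs, xs] = img[zsrc, xsrc]
    return out


class TestRegistration:
    def test_known_shift_recovered_exactly(self, rng):
        # identical B-scans, last one displaced by (3, -2)
        geo = VolumeGeometry(64, 16, 64)
        b = rng.random((64, 64)).astype(np.float32)
        vol = np.repeat(b[:, None, :], 16, axis=1)
        vol[:, -1, :] = _shift2(b, 3, -2)
        _, table = register_bscans(OCTVolume(vol, geo))
        assert (table.dz_vox.to_numpy()[:-1] == 0).all()
        assert (table.dz_vox.iloc[-1], table.dx_vox.iloc[-1]) == (-3, 2)

    def test_zero_jitter_gives_zero_offsets(self, acute_day1):
        vol, _ = acute_day1
        _, table = register_bscans(vol)
        assert (table.dz_vox == 0).all() and (table.dx_vox == 0).all()

    def test_recovers_injected_jitter(self, control_volume):
        # oracle: the renderer's applied offsets from the volume sidecar
        _, vol, _ = control_volume
        applied = vol.metadata["applied_offsets"]
        _, table = register_bscans(vol)
        est = np.stack([table.dz_vox.to_numpy(), table.dx_vox.to_numpy()], axis=1)
        resid = est + applied
        resid = resid - np.median(resid, axis=0)
        assert (np.abs(resid) <= 1).all(axis=1).mean() >= 0.95

    def test_idempotence(self, control_volume):
        _, vol, _ = control_volume
        reg, _ = register_bscans(vol)
        _, table2 = register_bscans(reg)
        assert np.abs(table2[["dz_vox", "dx_vox"]].to_numpy()).max() <= 1

    def test_featureless_bscan_flagged(self, rng):
        geo = VolumeGeometry(32, 16, 32)
        vol = rng.random(geo.shape).astype(np.float32)
        vol[:, 5, :] = 0.5
        _, table = register_bscans(OCTVolume(vol, geo))
        assert bool(table.flagged.iloc[5])

    def test_agrees_with_phase_correlation(self, rng):
        # independent cross-check of the pair estimator
        from skimage.registration import phase_cross_correlation

        a = rng.random((96, 96)).astype(np.float32)
        b = _shift2(a, 4, -3)
        geo = VolumeGeometry(96, 16, 96)
        vol = np.repeat(a[:, None, :], 16, axis=1)
        vol[:, -1, :] = b
        _, table = register_bscans(OCTVolume(vol, geo))
        sh, _, _ = phase_cross_correlation(a, b, normalization=None)
        assert (table.dz_vox.iloc[-1], table.dx_vox.iloc[-1]) == (
            int(sh[0]),
            int(sh[1]),
        )


class TestReslice:
    @pytest.fixture()
    def volume(self, rng):
        geo = VolumeGeometry(20, 18, 24)
        return OCTVolume(rng.random(geo.shape).astype(np.float32), geo)

    @pytest.mark.parametrize(
        "plane,axis", [("bscan", 1), ("cscan", 0), ("ascan-line", 2)]
    )
    def test_round_trip_is_lossless(self, volume, plane, axis):
        n = volume.intensities.shape[axis]
        slices = [reslice(volume, plane, k) for k in range(n)]
        stacked = np.stack(slices, axis=1 if plane == "bscan" else 0)
        if plane == "ascan-line":
            stacked = np.stack(slices, axis=2)
        assert np.array_equal(stacked, volume.intensities)

    def test_cscan_shape(self, volume):
        assert reslice(volume, "cscan", 3).shape == (18, 20)

    def test_bounds_and_plane_errors(self, volume):
        with pytest.raises(IndexError):
            reslice(volume, "bscan", 99)
        with pytest.raises(ValueError):
            reslice(volume, "diagonal", 0)

    def test_lesion_centered_bscan_has_maximal_cross_section(
        self, acute_scene, acute_day1
    ):
        # oracle: argmax of lesion footprint area per B-scan
        _, truth = acute_day1
        areas = truth.core_footprint.sum(axis=1)
        plateau = np.nonzero(areas >= 0.99 * areas.max())[0]
        center_idx = int(round(acute_scene.lesion_specs[0].center_um[0] / 1.4 - 0.5))
        assert plateau.min() - 2 <= center_idx <= plateau.max() + 2


class TestSegmentation:
    def test_surfaces_accurate_on_synthetic_volume(self, acute_day1, acute_day1_surfaces):
        _, truth = acute_day1
        surf = acute_day1_surfaces
        outside = ~truth.core_footprint
        for name in ("ilm", "rpe"):
            err = np.abs(surf[name] - truth.surfaces[name])[outside]
            assert np.percentile(err, 95) <= 5.7

    def test_ordering_enforced(self, acute_day1_surfaces):
        assert acute_day1_surfaces.check_ordering()

    def test_flat_volume_raises(self):
        geo = VolumeGeometry(32, 16, 64)
        with pytest.raises(SegmentationError):
            segment_surfaces(OCTVolume(np.full(geo.shape, 0.3, np.float32), geo))

    def test_planar_two_layer_phantom_recovered(self):
        geo = VolumeGeometry(48, 32, 256)
        vol = np.full(geo.shape, 0.05, np.float32)
        vol[100:, :, :] = 0.35  # retina top
        vol[190:198, :, :] = 0.95  # bright outer band
        surf = segment_surfaces(OCTVolume(vol, geo))
        assert np.abs(surf["ilm"] - 100 * 1.9).max() <= 2.1 * 1.9
        assert np.abs(surf["rpe"] - 194 * 1.9).max() <= 2.1 * 1.9

    def test_validity_false_inside_rupture(self, cnv_day1_wide):
        # oracle: the renderer's rupture footprint
        vol, truth = cnv_day1_wide
        surf = segment_surfaces(vol)
        fp = truth.rupture_footprint
        assert (~surf.validity[fp]).mean() > 0.5
        assert (~surf.validity[~fp]).mean() < 0.25


class TestSlabs:
    def test_band_height_at_default_geometry(self, acute_day1, acute_day1_surfaces):
        vol, _ = acute_day1
        slab = extract_slab(vol, acute_day1_surfaces, "ilm", 0.0, 60.0)
        assert slab.band_voxels == round(60.0 / 1.9) == 32

    def test_zero_thickness_rejected(self, acute_day1, acute_day1_surfaces):
        vol, _ = acute_day1
        with pytest.raises(ValueError):
            extract_slab(vol, acute_day1_surfaces, "ilm", 0.0, 0.0)

    def test_ilm_slab_captures_svp_not_choroid(self, control_volume):
        # oracle: the scene's plexus masks
        _, vol, truth = control_volume
        surf = segment_surfaces(vol)
        reg, _ = register_bscans(vol)
        surf = segment_surfaces(reg)
        svp = extract_slab(truth.vessel_masks["SVP"].astype(np.uint8), surf, "ilm", -6.0, 52.0)
        cho = extract_slab(truth.vessel_masks["choroid"].astype(np.uint8), surf, "ilm", -6.0, 52.0)
        svp_frac = svp.voxels.sum() / max(truth.vessel_masks["SVP"].sum(), 1)
        cho_frac = cho.voxels.sum() / max(truth.vessel_masks["choroid"].sum(), 1)
        assert svp_frac >= 0.99
        assert cho_frac <= 0.01

    def test_clipping_flagged(self, acute_day1, acute_day1_surfaces):
        vol, _ = acute_day1
        with pytest.warns(UserWarning):
            slab = extract_slab(vol, acute_day1_surfaces, "rpe", 500.0, 400.0)
        assert slab.clipped

    def test_flatten_unflatten_round_trip(self, acute_day1, acute_day1_surfaces):
        vol, _ = acute_day1
        flat, shift = flatten_to_surface(vol.intensities, acute_day1_surfaces, "ilm")
        back = unflatten(flat, shift, fill=-1.0)
        ok = back != -1.0
        assert np.array_equal(back[ok], vol.intensities[ok])
        assert ok.mean() > 0.8
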