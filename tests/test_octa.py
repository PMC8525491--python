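"""Angiography tests: enhancement, segmentation, shadow rejection, projection."""

import numpy as np
import pytest
import scipy.signal

from octapipe.octa import (
    decode_depth,
    depth_project,
    enhance_vessels,
    segment_angiogram,
    suppress_projection_artifacts,
)
from octapipe.synthetic_oct import make_tube_phantom
from octapipe.synthetic_oct.render import _speckle_field
from octapipe.volume_core import LayerSurfaces, OCTVolume, VolumeGeometry


@pytest.fixture(scope="module")
def tube():
    vol, mask = make_tube_phantom(diameter_um=5.0, seed=9, speckle_contrast=0.3)
    return vol, mask, enhance_vessels(vol)


@pytest.fixture(scope="module")
def shadow_phantom():
    """One superficial vessel casting a decorrelation tail onto a deep band
    holding three capillaries; ground-truth masks kept for the oracle."""
    rng = np.random.default_rng(5)
    geo = VolumeGeometry(96, 96, 160)
    refl = np.full(geo.shape, 0.30, np.float32)
    zz = np.arange(geo.n_axial)[:, None, None] * geo.dz_um
    yy = (np.arange(geo.n_slow) + 0.5)[None, :, None] * geo.dx_um
    svp = np.broadcast_to(((zz - 40) / 8) ** 2 + ((yy - 67) / 8) ** 2 <= 1.0, geo.shape)
    dvp = np.zeros(geo.shape, bool)
    for yc in (30.0, 67.0, 104.0):
        dvp |= np.broadcast_to(((zz - 160) / 4) ** 2 + ((yy - yc) / 4) ** 2 <= 1.0, geo.shape)
    tail = np.broadcast_to((np.abs(zz - 160) <= 8) & (np.abs(yy - 67) <= 8), geo.shape) & ~dvp
    refl = refl.copy()
    refl[svp] *= 1.6
    refl[dvp] *= 1.6
    refl[tail] *= 1.25
    refl *= _speckle_field(rng, geo, 0.3, flow_mask=svp | dvp)
    refl += 0.02
    flat = np.zeros((geo.n_slow, geo.n_fast), np.float32)
    surf = LayerSurfaces(
        {"ilm": flat + 10, "opl_onl": flat + 190, "elm": flat + 220, "isos": flat + 230, "rpe": flat + 250},
        np.ones((geo.n_slow, geo.n_fast), bool),
        geo,
    )
    vv = enhance_vessels(OCTVolume(refl, geo, {}))
    ang = segment_angiogram(vv)
    return dict(svp=svp, dvp=dvp, tail=tail, surf=surf, vv=vv, ang=ang)


class TestEnhancement:
    def test_five_micron_tube_ratio(self, tube):
        # the resolving-limit probe: in-mask score vs background score
        vol, mask, vv = tube
        s = vv.scores
        assert s[mask].mean() / s[~mask].mean() >= 3.0

    def test_two_tubes_ten_microns_apart_resolved(self):
        vol, _ = make_tube_phantom(diameter_um=5.0, n_tubes=2, separation_um=10.0, seed=9)
        vv = enhance_vessels(vol)
        zc = vol.geometry.n_axial // 2
        prof = vv.scores[zc - 2 : zc + 3, 6:-6, vol.geometry.n_fast // 2].max(axis=0)
        peaks, _ = scipy.signal.find_peaks(prof, height=0.4 * prof.max())
        # two distinct ridge maxima at the tube centers (~y = 37 and 52 um)
        centers = (peaks + 6) * vol.geometry.dx_um
        assert any(abs(c - 37.3) < 5 for c in centers)
        assert any(abs(c - 52.3) < 5 for c in centers)

    def test_all_zero_volume_gives_zero_scores(self):
        geo = VolumeGeometry(32, 16, 32)
        vv = enhance_vessels(OCTVolume(np.zeros(geo.shape, np.float32), geo))
        assert vv.scores.max() == 0.0
        assert any("warning" in st for st in vv.iterator_log)

    def test_intensity_shift_invariance(self, tube):
        vol, _, vv = tube
        shifted = vol.copy_with(vol.intensities + 0.37)
        vs = enhance_vessels(shifted)
        rms = np.sqrt(((vs.scores - vv.scores) ** 2).mean())
        ref = np.sqrt((vv.scores**2).mean())
        assert rms < 0.01 * max(ref, 1e-9)

    def test_iterator_log_records_stages(self, tube):
        _, _, vv = tube
        stages = [st["stage"] for st in vv.iterator_log]
        assert "background-median" in stages
        assert "tubular-enhance" in stages


class TestSegmentation:
    def test_empty_vesselness_gives_empty_mask(self, tube):
        vol, _, _ = tube
        geo = vol.geometry
        vv = enhance_vessels(OCTVolume(np.zeros(geo.shape, np.float32), geo))
        assert not segment_angiogram(vv).mask.any()

    def test_equal_thresholds_degenerate_to_single_threshold(self, tube):
        _, _, vv = tube
        q = 0.97
        ang = segment_angiogram(
            vv, high_quantile=q, low_quantile=q, min_component_voxels=1,
            lumen_grow=0, wash_factor=None, intensity_factor=None, min_absolute=0.03,
        )
        s = vv.scores
        flat = s.reshape(s.shape[0], -1)
        hi = np.maximum(np.quantile(flat, q, axis=1), 0.03)[:, None, None]
        assert np.array_equal(ang.mask, s >= hi)

    def test_raising_high_threshold_never_grows_mask(self, tube):
        _, _, vv = tube
        kw = dict(lumen_grow=0, wash_factor=None)
        a = segment_angiogram(vv, high_quantile=0.97, **kw).mask
        b = segment_angiogram(vv, high_quantile=0.995, **kw).mask
        assert not (b & ~a).any()


class TestShadowRejection:
    def test_tail_mostly_removed(self, shadow_phantom):
        p = shadow_phantom
        post = suppress_projection_artifacts(p["ang"], p["vv"], p["surf"])
        pre_t = (p["ang"].mask & p["tail"]).sum()
        assert pre_t > 100
        assert 1 - (post.mask & p["tail"]).sum() / pre_t >= 0.8

    def test_deep_vessels_away_from_the_superficial_vessel_untouched(self, shadow_phantom):
        p = shadow_phantom
        post = suppress_projection_artifacts(p["ang"], p["vv"], p["surf"])
        # capillaries not under the superficial vessel's column footprint
        svp_fp = p["svp"].any(axis=0)
        side = p["dvp"] & ~np.broadcast_to(svp_fp[None], p["dvp"].shape)
        pre = (p["ang"].mask & side).sum()
        assert pre > 100
        assert (post.mask & side).sum() >= 0.99 * pre

    def test_output_is_subset_and_svp_band_untouched(self, shadow_phantom):
        p = shadow_phantom
        post = suppress_projection_artifacts(p["ang"], p["vv"], p["surf"])
        assert not (post.mask & ~p["ang"].mask).any()
        in_svp_band = np.zeros(p["ang"].mask.shape, bool)
        in_svp_band[: int((10 + 34) / 1.9) + 1] = True
        assert np.array_equal(post.mask & in_svp_band, p["ang"].mask & in_svp_band)

    def test_empty_superficial_band_is_identity(self, tube):
        from octapipe.octa import VesselnessVolume

        vol, _, vv = tube
        geo = vol.geometry
        flat = np.zeros((geo.n_slow, geo.n_fast), np.float32)
        surf = LayerSurfaces(
            {"ilm": flat + 1.9, "opl_onl": flat + 20, "elm": flat + 30, "isos": flat + 40, "rpe": flat + 50},
            np.ones((geo.n_slow, geo.n_fast), bool),
            geo,
        )
        scores = vv.scores.copy()
        scores[:4] = 0.0  # no superficial detections at all
        vv2 = VesselnessVolume(scores, geo, vv.iterator_log, vv.normalized, vv.speckle_contrast)
        ang = segment_angiogram(vv2)
        post = suppress_projection_artifacts(ang, vv2, surf, svp_band_um=(0.0, 2.0))
        assert np.array_equal(post.mask, ang.mask)


class TestDepthProjection:
    def test_hue_decodes_depth_within_one_pitch(self):
        mask = np.zeros((100, 24, 48), np.float32)
        mask[40, 8:16, :] = 1.0
        proj = depth_project(mask, band=(20, 80), mode="depth_color", dz_um=1.9)
        dec = decode_depth(proj)
        fg = ~np.isnan(dec)
        assert fg.sum() == 8 * 48
        assert np.nanmax(np.abs(dec[fg] - 40.5 * 1.9)) <= 1.9

    def test_max_intensity_equals_exhaustive_scan(self, rng):
        vol = rng.random((60, 16, 20)).astype(np.float32)
        proj = depth_project(vol, band=(0, 60), mode="max_intensity")
        assert np.array_equal(proj.image, vol.max(axis=0))

    def test_empty_angiogram_projects_to_background(self):
        proj = depth_project(np.zeros((30, 8, 16)), mode="depth_color")
        assert proj.image.sum() == 0.0
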