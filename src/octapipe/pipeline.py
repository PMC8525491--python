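"""End-to-end orchestration: volume -> registration -> OCTA -> per-lesion evidence.

Convenience layer gluing the core modules together the way an analysis of
a longitudinal laser-injury experiment uses them: register the volume,
segment surfaces, enhance and segment the angiogram over the inner-retina
band, extract plexus slabs, quantify per-lesion vessel density against a
surround-annulus baseline, and assemble the evidence channels for
acute-vs-CNV classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .morphometry import measure_lesion
from .octa import (
    Angiogram,
    VesselnessVolume,
    enhance_vessels,
    segment_angiogram,
    suppress_projection_artifacts,
)
from .perfusion import (
    LesionClassification,
    LesionEvidence,
    classify_lesion,
    detect_nonperfusion,
    vessel_density,
)
from .volume_core import (
    LayerSurfaces,
    OCTVolume,
    extract_slab,
    flatten_to_surface,
    register_bscans,
    segment_surfaces,
    unflatten,
)

__all__ = [
    "PLEXUS_BANDS",
    "band_range",
    "band_mask",
    "run_octa",
    "lesion_roi",
    "annulus_roi",
    "choroid_void_evidence",
    "rupture_evidence",
    "analyze_eye",
]

# surface-referenced plexus bands: (reference surface, start um, stop um)
PLEXUS_BANDS = {
    "SVP": ("ilm", -6.0, 38.0),
    "IVP": ("ilm", 46.0, 84.0),
    "DVP": ("opl_onl", -30.0, 8.0),
    "choroid": ("rpe", 10.0, 70.0),
}


def band_range(surfaces: LayerSurfaces, pad_um: float = 15.0) -> tuple[int, int]:
    """Axial voxel range covering the inner retina (ILM to ONL/OPL boundary)."""
    geo = surfaces.geometry
    lo = (surfaces["ilm"].min() - pad_um) / geo.dz_um
    hi = (surfaces["opl_onl"].max() + pad_um) / geo.dz_um
    return max(int(np.floor(lo)), 0), min(int(np.ceil(hi)) + 1, geo.n_axial)


def band_mask(
    surfaces: LayerSurfaces, reference: str, start_um: float, stop_um: float
) -> np.ndarray:
    """Boolean 3D mask of a surface-referenced depth band."""
    geo = surfaces.geometry
    z = np.arange(geo.n_axial)[:, None, None] * geo.dz_um
    ref = surfaces[reference][None]
    return (z >= ref + start_um) & (z <= ref + stop_um)


def run_octa(
    volume: OCTVolume,
    register: bool = True,
    shadow_rejection: bool = True,
    restrict_to_inner: bool = True,
    segment_kwargs: "dict | None" = None,
    **enhance_kwargs,
) -> tuple[OCTVolume, LayerSurfaces, VesselnessVolume, Angiogram]:
    """Registration, surface segmentation, enhancement and segmentation.

    With ``restrict_to_inner`` the enhancement runs only over the
    inner-retina band (where the three capillary plexuses live), which is
    where the angiogram is quantified.
    """
    if register:
        volume, _ = register_bscans(volume)
    surfaces = segment_surfaces(volume)
    # flatten to the ILM before en-face processing: C-scan slices then stay
    # within layers instead of grazing curved boundaries, whose en-face
    # contours would otherwise masquerade as vessels
    flat, shift = flatten_to_surface(volume.intensities, surfaces, "ilm")
    flat_vol = OCTVolume(flat, volume.geometry, dict(volume.metadata))
    if restrict_to_inner:
        geo = volume.geometry
        ilm_row = int(np.rint(np.percentile(surfaces["ilm"], 2) / geo.dz_um))
        inner_um = float(np.percentile(surfaces["opl_onl"] - surfaces["ilm"], 98))
        # generous pad below the boundary: the deep plexus band reaches
        # past it and lesion swelling moves it
        z_range = (
            max(ilm_row - int(15.0 / geo.dz_um), 0),
            min(ilm_row + int((inner_um + 50.0) / geo.dz_um), geo.n_axial),
        )
    else:
        z_range = None
    vesselness = enhance_vessels(flat_vol, z_range=z_range, **enhance_kwargs)
    angiogram = segment_angiogram(vesselness, **(segment_kwargs or {}))
    # back to volume coordinates for surface-referenced quantification
    vesselness = VesselnessVolume(
        unflatten(vesselness.scores, shift, 0.0),
        vesselness.geometry,
        vesselness.iterator_log,
        normalized=unflatten(vesselness.normalized, shift, 0.0)
        if vesselness.normalized is not None
        else None,
        speckle_contrast=unflatten(vesselness.speckle_contrast, shift, 1.0)
        if vesselness.speckle_contrast is not None
        else None,
    )
    angiogram = Angiogram(unflatten(angiogram.mask, shift, False), angiogram.provenance)
    if shadow_rejection:
        angiogram = suppress_projection_artifacts(angiogram, vesselness, surfaces)
    return volume, surfaces, vesselness, angiogram


def lesion_roi(
    geometry, center_um: tuple[float, float], radius_um: float
) -> np.ndarray:
    """Lateral disc ROI around a lesion center."""
    y = (np.arange(geometry.n_slow) + 0.5) * geometry.dx_um - center_um[0]
    x = (np.arange(geometry.n_fast) + 0.5) * geometry.dx_um - center_um[1]
    return np.hypot(y[:, None], x[None, :]) <= radius_um


def annulus_roi(
    geometry, center_um: tuple[float, float], inner_um: float, outer_um: float
) -> np.ndarray:
    """Lateral annulus ROI (baseline surround) around a lesion center."""
    y = (np.arange(geometry.n_slow) + 0.5) * geometry.dx_um - center_um[0]
    x = (np.arange(geometry.n_fast) + 0.5) * geometry.dx_um - center_um[1]
    r = np.hypot(y[:, None], x[None, :])
    return (r >= inner_um) & (r <= outer_um)


def choroid_void_evidence(
    volume: OCTVolume,
    surfaces: LayerSurfaces,
    center_um: tuple[float, float],
    radius_um: float,
    void_fraction: float = 0.5,
) -> bool:
    """Choroidal signal void under a lesion: sub-RPE intensity below half
    of the surround level inside the (inner half of the) footprint."""
    geo = volume.geometry
    # the sub-RPE slab must follow the *sheet*, not the segmented surface:
    # inside a rupture the segmentation latches onto shallow lesion core,
    # which would pull the slab out of the choroid; a grey closing wider
    # than any rupture reconstructs the sheet from the valid surround
    k = max(int(round(260.0 / geo.dx_um)) | 1, 3)
    rpe_sheet = surfaces["rpe"].astype(np.float32)
    for ax in (0, 1):
        rpe_sheet = ndi.maximum_filter1d(rpe_sheet, size=k, axis=ax, mode="nearest")
    for ax in (0, 1):
        rpe_sheet = ndi.minimum_filter1d(rpe_sheet, size=k, axis=ax, mode="nearest")
    sheet_surfaces = LayerSurfaces(
        {**surfaces.surfaces, "rpe": rpe_sheet}, surfaces.validity, geo
    )
    ref, lo, hi = PLEXUS_BANDS["choroid"]
    slab = extract_slab(volume, sheet_surfaces, ref, lo, hi - lo)
    proj = slab.voxels.mean(axis=0)
    # the rupture core is a fraction of the lesion footprint; averaging
    # over the whole footprint would dilute the void below threshold
    inside = lesion_roi(geo, center_um, 0.35 * radius_um)
    around = annulus_roi(geo, center_um, 1.5 * radius_um, 2.5 * radius_um)
    if not inside.any() or not around.any():
        return False
    return float(proj[inside].mean()) < void_fraction * float(proj[around].mean())


def rupture_evidence(
    surfaces: LayerSurfaces,
    center_um: tuple[float, float],
    radius_um: float,
    invalid_fraction: float = 0.45,
) -> bool:
    """RPE rupture: the segmentation cannot find trustworthy outer bands
    over a substantial part of the lesion footprint."""
    inside = lesion_roi(surfaces.geometry, center_um, 0.35 * radius_um)
    if not inside.any():
        return False
    return float((~surfaces.validity[inside]).mean()) > invalid_fraction


@dataclass
class LesionAnalysis:
    """Collected per-lesion longitudinal evidence and its classification."""

    lesion_id: int
    days: np.ndarray
    dvp_density: np.ndarray
    dvp_baseline: np.ndarray
    heights_um: np.ndarray
    rupture_by_day: np.ndarray
    void_by_day: np.ndarray
    classification: LesionClassification


def analyze_eye(
    scene,
    volumes: "list[OCTVolume]",
    drop_fraction: float = 0.5,
    register: bool = True,
) -> list[LesionAnalysis]:
    """Run the full pipeline on a rendered timecourse of one eye.

    For every lesion of the scene and every timepoint: DVP vessel density
    inside the lesion cylinder (baseline = surround annulus at the same
    timepoint), lesion height from the lesion-centered B-scan, RPE-rupture
    and choroid-void evidence; then the acute/cnv classification from the
    combined evidence.
    """
    days = np.asarray(scene.timepoint_days, dtype=float)
    geo = scene.geometry
    n_lesions = len(scene.lesion_specs)
    dens = np.zeros((n_lesions, days.size))
    base = np.zeros((n_lesions, days.size))
    heights = np.zeros((n_lesions, days.size))
    rupt = np.zeros((n_lesions, days.size), dtype=bool)
    void = np.zeros((n_lesions, days.size), dtype=bool)

    for ti, (day, vol) in enumerate(zip(days, volumes)):
        vol, surfaces, vesselness, angiogram = run_octa(vol, register=register)
        # density band stops short of the ONL/OPL boundary: inside a lesion
        # that boundary is the bright core top, which would otherwise put a
        # false detection into every in-lesion column
        ref, lo, hi = PLEXUS_BANDS["DVP"][0], PLEXUS_BANDS["DVP"][1], -6.0
        dvp_slab = extract_slab(
            angiogram.mask.astype(np.uint8), surfaces, ref, lo, hi - lo
        )
        c_slab = extract_slab(vesselness.speckle_contrast, surfaces, ref, lo, hi - lo)
        for li, spec in enumerate(scene.lesion_specs):
            radius = spec.dims_at(day)[0] / 2 + 10.0
            roi = lesion_roi(geo, spec.center_um, radius)
            ring = annulus_roi(geo, spec.center_um, 1.5 * radius, 2.5 * radius)
            # re-gate the mask by flow wash calibrated on the healthy
            # surround: disrupted lesion tissue is bright and ridge-like
            # but carries static (grainy) speckle, not flow contrast
            ring_pos = (dvp_slab.voxels > 0) & ring[None]
            washed = dvp_slab.voxels > 0
            if ring_pos.any():
                c_ref = float(np.median(c_slab.voxels[ring_pos]))
                washed &= c_slab.voxels <= 1.4 * c_ref
            dens[li, ti] = float(washed[:, roi].mean())
            base[li, ti] = float(washed[:, ring].mean())
            si = int(np.clip(round(spec.center_um[0] / geo.dx_um - 0.5), 0, geo.n_slow - 1))
            m = measure_lesion(
                vol.intensities[:, si, :], surfaces, si, spec.center_um[1], li, day
            )
            heights[li, ti] = m.height_um
            rupt[li, ti] = rupture_evidence(surfaces, spec.center_um, radius)
            void[li, ti] = choroid_void_evidence(vol, surfaces, spec.center_um, radius)

    out = []
    for li, spec in enumerate(scene.lesion_specs):
        baseline = float(np.median(base[li]))
        tc = detect_nonperfusion(days, dens[li], baseline, drop_fraction, plexus="DVP")
        # single-timepoint dips are indistinguishable from measurement
        # noise; non-perfusion evidence needs a sustained interval
        sustained = any(
            ((days >= a) & (days <= b)).sum() >= 2
            for a, b in tc.nonperfusion_intervals
        )
        # likewise one day's height measurement must not set the phenotype
        h_sorted = np.sort(heights[li])
        evidence = LesionEvidence(
            rpe_rupture=bool(rupt[li].mean() > 0.5),
            choroid_void=bool(void[li].mean() > 0.5),
            max_height_um=float(h_sorted[-2] if h_sorted.size > 1 else h_sorted[-1]),
            dvp_nonperfusion=sustained,
        )
        out.append(
            LesionAnalysis(
                lesion_id=li,
                days=days,
                dvp_density=dens[li],
                dvp_baseline=base[li],
                heights_um=heights[li],
                rupture_by_day=rupt[li],
                void_by_day=void[li],
                classification=classify_lesion(evidence, li),
            )
        )
    return out
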