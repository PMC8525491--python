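"""En-face angiography: structural vessel enhancement and segmentation.

The angiographic contrast here is purely spatial: in a single high-density
scan, flowing blood changes the local speckle/reflectivity statistics of
the en-face (C-scan) images, so capillaries appear as bright tubular
structures once the slowly-varying layer background is removed.  The
enhancement is a sequential set of localized structural iterators applied
per C-scan:

1. local background removal — moving-median subtraction with a window much
   larger than the largest vessel diameter;
2. local contrast normalization — division by a local mean plus floor;
3. multiscale tubular enhancement — bright-ridge vesselness from the 2D
   second-derivative (Hessian) eigenstructure of each C-scan at scales
   matched to 5-40 um vessel diameters;

with steps 2-3 repeated ``n_iterations`` times and the result rescaled to
[0, 1].  Segmentation applies per-depth hysteresis thresholds and removes
small components; projection (shadow) artifacts below the superficial
plexus are rejected by comparing each voxel's score against the
superficial-band score in its own A-scan column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .volume_core import LayerSurfaces, OCTVolume

__all__ = [
    "VesselnessVolume",
    "Angiogram",
    "DepthProjection",
    "enhance_vessels",
    "segment_angiogram",
    "suppress_projection_artifacts",
    "depth_project",
    "decode_depth",
]


@dataclass
class VesselnessVolume:
    """Vesselness scores in [0, 1], co-registered to the source volume.

    ``normalized`` is the background-removed (mildly smoothed) intensity
    that the scores were computed from; segmentation uses it to trim the
    smooth halo of the tubular response back to the bright vessel lumen.
    ``speckle_contrast`` is the local sigma/mu of the raw intensity:
    flowing blood averages its speckle during the exposure, so vessels
    show a washed (low-contrast) pattern against grainy static tissue.
    """

    scores: np.ndarray
    geometry: "object"
    iterator_log: list = field(default_factory=list)
    normalized: "np.ndarray | None" = None
    speckle_contrast: "np.ndarray | None" = None

    def __post_init__(self) -> None:
        if not self.iterator_log:
            raise ValueError("iterator_log must record the applied stages")


@dataclass
class Angiogram:
    """Binary 3D vasculature mask with its processing provenance."""

    mask: np.ndarray
    provenance: dict = field(default_factory=dict)


@dataclass
class DepthProjection:
    """2D projection of an angiogram band.

    In ``depth_color`` mode the hue of each foreground pixel encodes the
    depth (um) of the brightest voxel in its column via the named
    perceptually-ordered colormap; ``depth_map_um`` retains the raw values
    and ``decode_lut`` the (rgb, depth) table used for decoding.
    """

    image: np.ndarray
    mode: str
    depth_range_um: tuple[float, float]
    colormap_name: str = "viridis"
    depth_map_um: "np.ndarray | None" = None
    decode_lut: "np.ndarray | None" = None


def _median_background(img: np.ndarray, window: int) -> np.ndarray:
    """Moving-median background of one C-scan via the fast rank filter."""
    from skimage.filters import rank

    lo, hi = float(img.min()), float(img.max())
    if hi - lo < 1e-12:
        return np.full_like(img, lo)
    q = np.clip((img - lo) / (hi - lo) * 255.0, 0, 255).astype(np.uint8)
    med = rank.median(q, footprint=np.ones((window, window), dtype=bool))
    return med.astype(np.float32) / 255.0 * (hi - lo) + lo


def _ridge_vesselness(
    img3d: np.ndarray, sigmas_vox: list[float], beta: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Frangi-style bright-ridge measure from per-C-scan 2D Hessians.

    Vectorized over the stack: smoothing/derivatives act on the two lateral
    axes only, so every C-scan is processed independently but in one pass.
    """
    # the structureness constant c must be shared across scales: a weak
    # large-scale response (e.g. midway between two nearby capillaries)
    # must not be amplified to parity with a strong matched-scale ridge
    best_shape = np.zeros_like(img3d)
    best_frob2 = np.zeros_like(img3d)
    best_proxy = np.zeros_like(img3d)
    best_sigma = np.zeros_like(img3d)
    for s in sigmas_vox:
        hxx = ndi.gaussian_filter(img3d, sigma=(0, s, s), order=(0, 0, 2)) * s**2
        hyy = ndi.gaussian_filter(img3d, sigma=(0, s, s), order=(0, 2, 0)) * s**2
        hxy = ndi.gaussian_filter(img3d, sigma=(0, s, s), order=(0, 1, 1)) * s**2
        tmp = np.sqrt(((hxx - hyy) * 0.5) ** 2 + hxy**2)
        mean = (hxx + hyy) * 0.5
        l1 = mean + tmp
        l2 = mean - tmp
        # order by magnitude: la small, lb large
        swap = np.abs(l1) > np.abs(l2)
        la = np.where(swap, l2, l1)
        lb = np.where(swap, l1, l2)
        frob2 = la**2 + lb**2
        rb2 = np.divide(la**2, lb**2, out=np.zeros_like(la), where=lb != 0)
        shape = np.where(lb < 0, np.exp(-rb2 / (2 * beta**2)), 0.0)  # bright ridges
        proxy = shape * frob2
        better = proxy > best_proxy
        best_proxy = np.where(better, proxy, best_proxy)
        best_shape = np.where(better, shape, best_shape)
        best_frob2 = np.where(better, frob2, best_frob2)
        best_sigma = np.where(better, np.float32(s), best_sigma)
    nz = best_frob2[best_frob2 > 0]
    if nz.size == 0:
        return np.zeros_like(img3d), best_sigma
    # a robust high quantile, not the max: a single huge-curvature outlier
    # must not crush the response of ordinary capillaries
    c2 = 0.5 * float(np.quantile(nz, 0.995))
    if c2 <= 0:
        return np.zeros_like(img3d), best_sigma
    return best_shape * (1.0 - np.exp(-best_frob2 / (2 * c2))), best_sigma


def enhance_vessels(
    volume: OCTVolume,
    n_iterations: int = 2,
    scales_um: tuple[float, ...] = (5.0, 10.0, 20.0, 40.0),
    background_window_um: float = 90.0,
    norm_window_um: float = 120.0,
    axial_sigma_um: float = 4.0,
    z_range: "tuple[int, int] | None" = None,
) -> VesselnessVolume:
    """Sequential localized structural enhancement of en-face images.

    After the iterated per-C-scan stages, the score is gated by an axial
    localization term (negative axial second derivative of the
    background-removed intensity): the in-plane tubular response smears a
    few voxels above and below a vessel, and the gate pins it to the
    bright axial core.  ``z_range`` restricts processing to an axial band
    (e.g. the inner retina); scores outside the band are zero.  A constant
    volume yields all-zero scores with a logged warning stage.
    """
    geo = volume.geometry
    z0, z1 = (0, geo.n_axial) if z_range is None else z_range
    z0, z1 = max(int(z0), 0), min(int(z1), geo.n_axial)
    data = volume.intensities[z0:z1].astype(np.float32)
    log: list = []

    if float(data.std()) < 1e-12:
        log.append({"stage": "constant-input", "warning": "all-zero scores"})
        scores = np.zeros(geo.shape, dtype=np.float32)
        return VesselnessVolume(scores, geo, log)

    win = max(int(round(background_window_um / geo.dx_um)) | 1, 9)
    bg = np.empty_like(data)
    for k in range(data.shape[0]):
        bg[k] = _median_background(data[k], win)
    base = data - bg
    log.append({"stage": "background-median", "window_vox": win})

    nwin = max(int(round(norm_window_um / geo.dx_um)) | 1, 5)
    sigmas = sorted({max(d / 2.0 / geo.dx_um, 0.8) for d in scales_um})
    work = base
    for it in range(n_iterations):
        local = ndi.uniform_filter(np.abs(work), size=(1, nwin, nwin))
        floor = 0.1 * float(np.abs(work).mean()) + 1e-8
        work = work / (local + floor)
        log.append({"stage": "contrast-normalize", "iteration": it, "window_vox": nwin})
        work, best_sigma = _ridge_vesselness(work, sigmas)
        log.append(
            {"stage": "tubular-enhance", "iteration": it, "sigmas_vox": list(sigmas)}
        )

    # the gate's axial scale follows the winning in-plane scale: a thick
    # lumen must not be thinned to a central sheet by a capillary-sized
    # gate, while a capillary keeps its tight localization
    gates = []
    for sz_um in (axial_sigma_um, 2.3 * axial_sigma_um):
        sz = max(sz_um / geo.dz_um, 0.8)
        axial = np.clip(
            -ndi.gaussian_filter(base, sigma=(sz, 1.0, 1.0), order=(2, 0, 0)) * sz**2,
            0.0,
            None,
        )
        pos = axial[axial > 0]
        q = float(np.quantile(pos, 0.75)) if pos.size else 1.0
        gates.append(axial / (axial + q))
    large_scale = best_sigma >= 5.0
    work = work * np.where(large_scale, gates[1], gates[0])
    log.append({"stage": "axial-gate", "sigma_um": [axial_sigma_um, 2.3 * axial_sigma_um]})

    # quantile-referenced rescale: a max-based scale would shrink with
    # volume size as the extreme-value tail grows, shifting every
    # downstream absolute threshold
    pos = work[work > 0]
    peak = float(np.quantile(pos, 0.999)) if pos.size else 0.0
    if peak > 0:
        work = np.clip(work / peak, 0.0, 1.0)
    log.append({"stage": "rescale", "peak": peak})

    scores = np.zeros(geo.shape, dtype=np.float32)
    scores[z0:z1] = work
    normalized = np.zeros(geo.shape, dtype=np.float32)
    normalized[z0:z1] = ndi.gaussian_filter(base, sigma=(1.5, 1.0, 1.0))
    m1 = ndi.uniform_filter(data, size=(1, 5, 5))
    m2 = ndi.uniform_filter(data * data, size=(1, 5, 5))
    contrast = np.ones(geo.shape, dtype=np.float32)
    contrast[z0:z1] = np.sqrt(np.clip(m2 - m1 * m1, 0, None)) / np.maximum(m1, 1e-6)
    log.append({"stage": "speckle-contrast", "window_vox": 5})
    return VesselnessVolume(
        scores, geo, log, normalized=normalized, speckle_contrast=contrast
    )


def segment_angiogram(
    vesselness: VesselnessVolume,
    high_quantile: float = 0.99,
    low_quantile: float = 0.70,
    min_component_voxels: int = 30,
    min_absolute: float = 0.03,
    intensity_factor: "float | None" = 0.75,
    lumen_grow: int = 1,
    wash_factor: "float | None" = 1.4,
) -> Angiogram:
    """Hysteresis-threshold the vesselness into a binary angiogram.

    High/low thresholds are per-C-scan quantiles (floored at an absolute
    minimum so empty slices stay empty); weak voxels survive only in
    3D-connected components that contain a strong voxel, and components
    below ``min_component_voxels`` are removed.  When the vesselness
    carries its normalized-intensity channel, candidate voxels must also
    exceed ``intensity_factor`` times the median intensity of the strong
    seeds — the self-calibrated lumen gate that trims the smooth tubular
    halo back to the bright vessel.  Deterministic for fixed input; an
    empty mask is a legal output.
    """
    s = vesselness.scores
    if float(s.max()) <= 0:
        return Angiogram(
            np.zeros_like(s, dtype=bool),
            {"empty_input": True, "high_quantile": high_quantile},
        )
    flat = s.reshape(s.shape[0], -1)
    hi = np.quantile(flat, high_quantile, axis=1)[:, None, None]
    lo = np.quantile(flat, low_quantile, axis=1)[:, None, None]
    hi = np.maximum(hi, min_absolute)
    lo = np.minimum(np.maximum(lo, 0.5 * min_absolute), hi)
    strong = s >= hi
    weak = s >= lo
    lumen_thr = None
    if (
        intensity_factor is not None
        and vesselness.normalized is not None
        and strong.any()
    ):
        w = vesselness.normalized
        lumen_thr = intensity_factor * float(np.median(w[strong]))
        bright = w >= lumen_thr
        strong = strong & bright
        weak = weak & bright
    labels, n = ndi.label(weak)
    if n:
        keep = np.zeros(n + 1, dtype=bool)
        keep[np.unique(labels[strong])] = True
        keep[0] = False
        mask = keep[labels]
    else:
        mask = np.zeros_like(weak)
    if min_component_voxels > 1 and mask.any():
        labels, n = ndi.label(mask)
        sizes = np.bincount(labels.ravel())
        mask = (sizes >= min_component_voxels)[labels] & mask
    if lumen_grow and lumen_thr is not None and mask.any():
        # the ridge response is centre-peaked, so vessel rims fail the
        # score threshold; grow the mask into adjacent bright-lumen voxels
        bright = vesselness.normalized >= lumen_thr
        for _ in range(lumen_grow):
            mask |= ndi.binary_dilation(mask) & bright
    if wash_factor is not None and vesselness.speckle_contrast is not None and mask.any():
        # speckle-wash gate: flowing blood shows low local speckle
        # contrast, static tissue is grainy; reject high-contrast voxels.
        # Calibrated on confident high-score voxels (clean vessel lumina).
        c = vesselness.speckle_contrast
        confident = s >= 0.2
        if confident.any():
            mask &= c <= wash_factor * float(np.median(c[confident]))
    return Angiogram(
        mask,
        {
            "high_quantile": high_quantile,
            "low_quantile": low_quantile,
            "min_component_voxels": min_component_voxels,
            "min_absolute": min_absolute,
            "lumen_threshold": lumen_thr,
            "shadow_rejected": False,
        },
    )


def suppress_projection_artifacts(
    angiogram: Angiogram,
    vesselness: VesselnessVolume,
    surfaces: LayerSurfaces,
    tail_factor: float = 1.5,
    svp_band_um: tuple[float, float] = (0.0, 34.0),
    min_superficial_score: float = 0.15,
) -> Angiogram:
    """Reject shadow/projection tails cast by the superficial plexus.

    A voxel below the SVP band is removed when the maximum vesselness in
    its column's SVP band exceeds ``tail_factor`` times the voxel's own
    score; SVP-band voxels are never touched and no voxel is ever added.
    """
    if surfaces is None:
        raise ValueError("surfaces are required for shadow rejection")
    geo = surfaces.geometry
    s = vesselness.scores
    ilm_vox = np.rint(surfaces["ilm"] / geo.dz_um).astype(int)
    b0 = ilm_vox + int(round(svp_band_um[0] / geo.dz_um))
    b1 = ilm_vox + int(round(svp_band_um[1] / geo.dz_um))
    z = np.arange(geo.n_axial)[:, None, None]
    in_band = (z >= b0[None]) & (z <= b1[None])
    svp_max = np.where(in_band, s, 0.0).max(axis=0)
    below = z > b1[None]
    # each voxel answers with its structure's local axial peak, so the dim
    # rim of a genuine deep vessel is not stripped while its core survives
    own = ndi.maximum_filter1d(s, size=max(int(round(12.0 / geo.dz_um)) | 1, 3), axis=0)
    # only a convincingly detected superficial vessel casts a shadow:
    # columns without one are never altered
    casting = svp_max > min_superficial_score
    remove = below & casting[None] & (svp_max[None] > tail_factor * own) & angiogram.mask
    mask = angiogram.mask & ~remove
    prov = dict(angiogram.provenance)
    prov.update({"shadow_rejected": True, "tail_factor": tail_factor})
    return Angiogram(mask, prov)


def depth_project(
    scores_or_mask: np.ndarray,
    band: "tuple[int, int] | None" = None,
    mode: str = "max_intensity",
    dz_um: float = 1.9,
    colormap: str = "viridis",
) -> DepthProjection:
    """Project an angiogram (or slab) band to a 2D en-face image.

    ``max_intensity`` is the per-column maximum; ``depth_color`` encodes
    the depth of each column's brightest voxel as hue (value scaled by the
    maximum itself).  Deterministic; an empty band yields an empty image.
    """
    data = np.asarray(scores_or_mask, dtype=np.float32)
    z0, z1 = (0, data.shape[0]) if band is None else band
    z0, z1 = max(int(z0), 0), min(int(z1), data.shape[0])
    depth_range = (z0 * dz_um, z1 * dz_um)
    if z1 <= z0:
        shape = data.shape[1:]
        img = np.zeros(shape + ((3,) if mode == "depth_color" else ()), np.float32)
        return DepthProjection(img, mode, depth_range, colormap)
    sub = data[z0:z1]
    mip = sub.max(axis=0)
    if mode == "max_intensity":
        return DepthProjection(mip, mode, depth_range, colormap)
    if mode != "depth_color":
        raise ValueError(f"unknown mode {mode!r}")
    import matplotlib

    argmax = sub.argmax(axis=0)
    depth_um = (z0 + argmax + 0.5) * dz_um
    n_band = sub.shape[0]
    cmap = matplotlib.colormaps[colormap]
    lut = cmap(np.linspace(0, 1, n_band))[:, :3].astype(np.float32)
    rgb = lut[argmax]
    fg = mip > 0
    peak = float(mip.max())
    value = (mip / peak if peak > 0 else mip)[..., None]
    img = np.where(fg[..., None], rgb * value, 0.0).astype(np.float32)
    depth_map = np.where(fg, depth_um, np.nan)
    return DepthProjection(img, mode, depth_range, colormap, depth_map, lut)


def decode_depth(projection: DepthProjection) -> np.ndarray:
    """Recover the depth map (um) from a depth-colored image via its LUT.

    Nearest-LUT-color matching on value-normalized pixels; background
    (zero) pixels decode to NaN.  Used to verify the hue-encodes-depth
    invariant without peeking at ``depth_map_um``.
    """
    if projection.mode != "depth_color" or projection.decode_lut is None:
        raise ValueError("decode_depth requires a depth_color projection")
    img = projection.image
    norm = np.linalg.norm(img, axis=-1, keepdims=True)
    fg = norm[..., 0] > 1e-6
    unit = np.where(norm > 0, img / np.maximum(norm, 1e-12), 0.0)
    lut = projection.decode_lut
    lut_unit = lut / np.maximum(np.linalg.norm(lut, axis=1, keepdims=True), 1e-12)
    idx = np.argmax(unit @ lut_unit.T, axis=-1)
    z0 = projection.depth_range_um[0]
    dz = (projection.depth_range_um[1] - projection.depth_range_um[0]) / max(
        len(lut), 1
    )
    depth = z0 + (idx + 0.5) * dz
    return np.where(fg, depth, np.nan)
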