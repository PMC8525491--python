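"""Core OCT volume containers and geometric operations.

A volume is a 3D grid of backscatter intensities indexed ``(axial, slow,
fast)``: the fast axis is the A-scan line within a B-scan, the slow axis
steps across consecutive B-scans, and the axial axis is depth.  All exported
measurements are in micrometres (voxel index times pitch); voxel indices are
0-based and increase with depth.

This module provides B-scan motion registration, orthogonal reslicing
(B-scan / C-scan / A-scan line views of the same cube), retinal surface
segmentation, and surface-referenced slab extraction (the 60 um optical
slabs used for en-face angiography).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

__all__ = [
    "VolumeGeometry",
    "OCTVolume",
    "LayerSurfaces",
    "Slab",
    "SegmentationError",
    "register_bscans",
    "reslice",
    "segment_surfaces",
    "extract_slab",
]

SURFACE_NAMES = ("ilm", "opl_onl", "elm", "isos", "rpe")


class SegmentationError(RuntimeError):
    """Raised when no retinal structure can be located in a volume."""


@dataclass(frozen=True)
class VolumeGeometry:
    """Voxel grid of an OCT acquisition.

    Parameters
    ----------
    n_fast, n_slow, n_axial:
        Voxel counts along the fast lateral axis (A-scans per B-scan), the
        slow axis (B-scans per volume) and depth.
    dx_um:
        Lateral voxel pitch in micrometres (both lateral axes; the scan is
        laterally isotropic).  Default 1.4 um.
    dz_um:
        Axial voxel pitch in micrometres.  Default 1.9 um.
    """

    n_fast: int
    n_slow: int
    n_axial: int
    dx_um: float = 1.4
    dz_um: float = 1.9

    def __post_init__(self) -> None:
        for name in ("n_fast", "n_slow", "n_axial"):
            if getattr(self, name) < 16:
                raise ValueError(f"{name} must be >= 16, got {getattr(self, name)}")
        if self.dx_um <= 0 or self.dz_um <= 0:
            raise ValueError("voxel pitches must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        """Array shape ``(n_axial, n_slow, n_fast)``."""
        return (self.n_axial, self.n_slow, self.n_fast)

    @property
    def field_um(self) -> tuple[float, float]:
        """Lateral field extent ``(slow, fast)`` in micrometres."""
        return (self.n_slow * self.dx_um, self.n_fast * self.dx_um)

    @property
    def depth_um(self) -> float:
        return self.n_axial * self.dz_um


@dataclass
class OCTVolume:
    """An OCT intensity cube with its geometry and acquisition metadata."""

    intensities: np.ndarray
    geometry: VolumeGeometry
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(self.intensities.shape) != self.geometry.shape:
            raise ValueError(
                f"intensity shape {self.intensities.shape} does not match "
                f"geometry {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    def copy_with(self, intensities: np.ndarray, **meta) -> "OCTVolume":
        md = dict(self.metadata)
        md.update(meta)
        return OCTVolume(intensities, self.geometry, md)


@dataclass
class LayerSurfaces:
    """Per-surface depth maps in micrometres from the volume top.

    ``surfaces`` maps each of ``ilm, opl_onl, elm, isos, rpe`` to an
    ``(n_slow, n_fast)`` array.  ``validity`` is False where the retina could
    not be segmented (e.g. inside an RPE rupture).  Depth ordering
    ilm < opl_onl < elm < isos < rpe holds wherever valid.
    """

    surfaces: dict[str, np.ndarray]
    validity: np.ndarray
    geometry: VolumeGeometry

    def __getitem__(self, name: str) -> np.ndarray:
        return self.surfaces[name]

    def check_ordering(self) -> bool:
        v = self.validity
        ok = True
        for a, b in zip(SURFACE_NAMES[:-1], SURFACE_NAMES[1:]):
            ok = ok and bool(np.all(self.surfaces[a][v] < self.surfaces[b][v]))
        return ok


@dataclass
class Slab:
    """A surface-referenced depth band extracted from a volume.

    Each A-scan column is shifted (nearest-voxel, no interpolation) so the
    reference surface is flat, then ``round(thickness_um / dz_um)`` rows are
    taken starting ``offset_um`` from the reference.  ``voxels`` has shape
    ``(band, n_slow, n_fast)``.
    """

    voxels: np.ndarray
    reference_surface: str
    offset_um: float
    thickness_um: float
    geometry: VolumeGeometry
    clipped: bool = False

    @property
    def band_voxels(self) -> int:
        return self.voxels.shape[0]


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

def _pair_shift(a: np.ndarray, b: np.ndarray, max_shift: int) -> tuple[int, int]:
    """Integer (axial, lateral) shift of ``b`` relative to ``a``.

    Normalized cross-correlation over integer shifts within ``+-max_shift``,
    evaluated via FFT on mean-subtracted images.  Returns the displacement of
    ``b``'s content: positive axial means ``b`` is shifted deeper than ``a``.
    """
    a = a - a.mean()
    b = b - b.mean()
    fa = np.fft.rfft2(a)
    fb = np.fft.rfft2(b)
    xc = np.fft.irfft2(fa * np.conj(fb), s=a.shape)
    # xc[dz, dx] ~ sum a[z, x] * b[z - dz, x - dx]; restrict to the window
    dz = np.r_[np.arange(0, max_shift + 1), np.arange(-max_shift, 0)]
    dx = dz
    win = xc[np.ix_(dz % a.shape[0], dx % a.shape[1])]
    k = int(np.argmax(win))
    i, j = divmod(k, win.shape[1])
    return -int(dz[i]), -int(dx[j])


def register_bscans(
    volume: OCTVolume,
    max_shift: int = 8,
    detrend_window: "int | None" = None,
    axes: str = "both",
) -> tuple[OCTVolume, pd.DataFrame]:
    """Rigidly align consecutive B-scans of a volume.

    Each B-scan is translated by the integer (axial, lateral) offset
    maximizing its normalized cross-correlation with its predecessor;
    pairwise shifts are chained into cumulative offsets anchored to the
    first B-scan.  Because the shifts are integers while anatomical
    curvature changes by far less than a voxel between consecutive
    B-scans, the chain corrects motion without flattening anatomy; an
    optional moving-median detrend (``detrend_window`` B-scans, rounded to
    integer so exact offsets stay exact) guards against slow drift of
    pairwise errors on very long scans, at the cost of absorbing any
    slowly-varying component of the true motion.

    Parameters
    ----------
    axes:
        ``"both"`` (default) estimates axial and lateral shifts, ``"axial"``
        restricts the search to axial-only motion.

    Returns
    -------
    (registered, offsets):
        The registered volume (corrections recorded in
        ``metadata["estimated_offsets"]``) and a table with columns
        ``bscan_index, dz_vox, dx_vox, flagged``; flagged marks featureless
        B-scans whose offset was pinned to 0.
    """
    vol = volume.intensities
    n_slow = vol.shape[1]
    if n_slow < 2:
        raise ValueError("registration needs at least 2 B-scans")

    rel = np.zeros((n_slow, 2), dtype=int)
    flagged = np.zeros(n_slow, dtype=bool)
    scale = float(vol.std())
    for k in range(1, n_slow):
        b = vol[:, k, :]
        if b.std() < 1e-6 * max(scale, 1e-12) or scale == 0.0:
            flagged[k] = True
            continue
        dz, dx = _pair_shift(vol[:, k - 1, :], b, max_shift)
        if axes == "axial":
            dx = 0
        rel[k] = (dz, dx)

    cum = np.cumsum(rel, axis=0)
    # re-center: anchoring to the first B-scan would leave the whole
    # volume displaced by that scan's own motion; with mean-reverting
    # motion the median offset is the natural zero reference
    if n_slow >= 9:
        cum = cum - np.round(np.median(cum, axis=0)).astype(int)
    if detrend_window is not None and n_slow >= 3 * detrend_window:
        # the trend is rounded before subtraction: pairwise shifts are
        # integers (the jitter is integer-voxel), so a sub-voxel trend
        # estimate must not corrupt otherwise-exact offsets
        trend = np.rint(
            ndi.median_filter(cum.astype(float), size=(detrend_window, 1), mode="nearest")
        ).astype(int)
        corr = -(cum - trend)
    else:
        corr = -cum

    fill = float(np.percentile(vol, 1))
    out = np.empty_like(vol)
    for k in range(n_slow):
        out[:, k, :] = _shift2d(vol[:, k, :], corr[k, 0], corr[k, 1], fill)

    table = pd.DataFrame(
        {
            "bscan_index": np.arange(n_slow),
            "dz_vox": corr[:, 0],
            "dx_vox": corr[:, 1],
            "flagged": flagged,
        }
    )
    reg = volume.copy_with(out, estimated_offsets=corr.copy(), registered=True)
    return reg, table


def _shift2d(img: np.ndarray, dz: int, dx: int, fill: float) -> np.ndarray:
    out = np.full_like(img, fill)
    zs = slice(max(dz, 0), img.shape[0] + min(dz, 0))
    xs = slice(max(dx, 0), img.shape[1] + min(dx, 0))
    zsrc = slice(max(-dz, 0), img.shape[0] + min(-dz, 0))
    xsrc = slice(max(-dx, 0), img.shape[1] + min(-dx, 0))
    out[zs, xs] = img[zsrc, xsrc]
    return out


# ---------------------------------------------------------------------------
# reslicing
# ---------------------------------------------------------------------------

def reslice(volume: OCTVolume, plane: str, index: int) -> np.ndarray:
    """Extract an orthogonal 2D slice from the cube.

    ``bscan`` returns the (axial, fast) cross-section at slow index;
    ``cscan`` the en-face (slow, fast) slice at an axial index; ``ascan-line``
    the (axial, slow) sheet at a fast index.  Slices are exact sub-grids:
    stacking every index along an axis reconstructs the volume bit-exactly.
    """
    vol = volume.intensities
    limits = {"bscan": vol.shape[1], "cscan": vol.shape[0], "ascan-line": vol.shape[2]}
    if plane not in limits:
        raise ValueError(f"unknown plane {plane!r}")
    if not 0 <= index < limits[plane]:
        raise IndexError(f"{plane} index {index} out of range [0, {limits[plane]})")
    if plane == "bscan":
        return vol[:, index, :].copy()
    if plane == "cscan":
        return vol[index, :, :].copy()
    return vol[:, :, index].copy()


# ---------------------------------------------------------------------------
# surface segmentation
# ---------------------------------------------------------------------------

def segment_surfaces(
    volume: OCTVolume,
    smooth_sigma_um: tuple[float, float] = (3.8, 2.2),
    median_window_um: float = 20.0,
) -> LayerSurfaces:
    """Segment retinal surfaces from a registered volume.

    Per A-scan gradient/peak analysis: the ILM is the first strong positive
    intensity edge from the vitreous, the RPE the center of the deepest
    bright band (the brightest reflector below the inner retina); the
    OPL/ONL boundary is the strongest negative axial edge between them and
    the ELM / IS-OS follow from the photoreceptor-band rise below the ONL.
    Surfaces are median-smoothed laterally and depth ordering is enforced.
    The validity mask is False where no convincing RPE peak exists (e.g.
    inside a choroidal rupture, where the bright outer bands are destroyed).
    """
    geo = volume.geometry
    vol = volume.intensities.astype(np.float32)
    if float(vol.std()) < 1e-9 * max(abs(float(vol.mean())), 1.0) or vol.std() == 0:
        raise SegmentationError("no detectable retina: volume is flat")

    # kernel sizes are physical so widefield (coarser-pitch) scans are not
    # over-smoothed relative to the anatomy
    s_lat = smooth_sigma_um[1] / geo.dx_um
    smooth_sigma = (smooth_sigma_um[0] / geo.dz_um, s_lat, s_lat)
    median_window = max(int(round(median_window_um / geo.dx_um)) | 1, 1)
    smooth = ndi.gaussian_filter(vol, sigma=smooth_sigma)
    lo = float(np.percentile(smooth, 5))
    hi = float(np.percentile(smooth, 99))
    if hi - lo < 1e-9:
        raise SegmentationError("no detectable retina: no intensity contrast")
    # vitreous/tissue separation: Otsu is robust to the speckle tail that
    # skews percentile-based thresholds
    from skimage.filters import threshold_otsu

    thr_ilm = float(threshold_otsu(smooth[:: max(smooth.shape[0] // 128, 1)]))

    nz, ns, nf = smooth.shape
    above = smooth > thr_ilm
    any_above = above.any(axis=0)
    if not any_above.any():
        raise SegmentationError("no detectable retina: nothing above threshold")
    ilm_vox = np.where(any_above, above.argmax(axis=0), 0).astype(np.int32)

    # RPE: brightest voxel well below the ILM
    gap = max(int(round(60.0 / geo.dz_um)), 4)
    z = np.arange(nz)[:, None, None]
    deep = np.where(z >= ilm_vox[None] + gap, smooth, -np.inf)
    rpe_vox = deep.argmax(axis=0).astype(np.int32)
    # validity: the column must show a credibly bright deep reflector at a
    # credible depth.  Where the outer bands are destroyed (choroidal
    # rupture) the brightest deep voxel is lesion core tissue sitting far
    # above the surrounding RPE sheet; a robust quadratic sheet model makes
    # such shallow outliers easy to flag, while dim-but-correctly-placed
    # columns (small lesions at coarse pitch) stay valid.
    rpe_peak = np.take_along_axis(smooth, rpe_vox[None], axis=0)[0]
    bright_ok = rpe_peak > 0.65 * np.median(rpe_peak)
    depth = rpe_vox * geo.dz_um
    yn = np.linspace(-1, 1, ns)[:, None] * np.ones((1, nf))
    xn = np.linspace(-1, 1, nf)[None, :] * np.ones((ns, 1))
    design = np.stack(
        [np.ones_like(yn), yn, xn, yn * yn, xn * xn, yn * xn], axis=-1
    ).reshape(-1, 6)
    target = depth.ravel()
    use = np.ones(target.size, dtype=bool)
    pred = target
    for _ in range(2):
        coef, *_ = np.linalg.lstsq(design[use], target[use], rcond=None)
        pred = design @ coef
        use = np.abs(target - pred) < 30.0
        if use.sum() < 12:
            break
    shallow = (pred.reshape(ns, nf) - depth) > 45.0
    validity = bright_ok & ~shallow

    # OPL/ONL: strongest negative axial gradient between ILM and RPE
    grad = ndi.gaussian_filter1d(smooth, sigma=1.5, axis=0, order=1)
    lo_b = ilm_vox[None] + max(int(round(40.0 / geo.dz_um)), 3)
    hi_b = rpe_vox[None] - max(int(round(55.0 / geo.dz_um)), 3)
    inner = np.where((z >= lo_b) & (z <= np.maximum(hi_b, lo_b + 1)), grad, np.inf)
    opl_vox = inner.argmin(axis=0).astype(np.int32)

    # photoreceptor band rise below the ONL: ELM edge, then IS/OS peak
    lo_e = opl_vox[None] + max(int(round(30.0 / geo.dz_um)), 2)
    hi_e = rpe_vox[None] - max(int(round(10.0 / geo.dz_um)), 1)
    outer = np.where((z >= lo_e) & (z <= np.maximum(hi_e, lo_e + 1)), grad, -np.inf)
    elm_vox = outer.argmax(axis=0).astype(np.int32)
    span = max(int(round(16.0 / geo.dz_um)), 2)
    band = np.where(
        (z >= elm_vox[None]) & (z <= elm_vox[None] + span), smooth, -np.inf
    )
    isos_vox = band.argmax(axis=0).astype(np.int32)

    surfaces: dict[str, np.ndarray] = {}
    for name, arr in (
        ("ilm", ilm_vox),
        ("opl_onl", opl_vox),
        ("elm", elm_vox),
        ("isos", isos_vox),
        ("rpe", rpe_vox),
    ):
        sm = ndi.median_filter(arr.astype(np.float32), size=median_window, mode="nearest")
        surfaces[name] = sm * geo.dz_um

    # enforce strict depth ordering where valid
    eps = 0.5 * geo.dz_um
    prev = surfaces["ilm"]
    for name in SURFACE_NAMES[1:]:
        surfaces[name] = np.maximum(surfaces[name], prev + eps)
        surfaces[name] = np.minimum(surfaces[name], geo.depth_um - eps)
        prev = surfaces[name]

    return LayerSurfaces(surfaces=surfaces, validity=validity, geometry=geo)


def flatten_to_surface(
    data: np.ndarray, surfaces: LayerSurfaces, reference: str = "ilm"
) -> tuple[np.ndarray, np.ndarray]:
    """Shift each A-scan column so the reference surface sits on one row.

    Nearest-voxel (integer) shifts, so the operation is exactly invertible
    by :func:`unflatten`.  Returns ``(flattened, shift)`` where ``shift``
    is the per-column number of rows the column was pulled up.  Rows
    shifted in from below are filled with the data's low percentile.
    """
    geo = surfaces.geometry
    ref_vox = np.rint(surfaces[reference] / geo.dz_um).astype(int)
    # anchor on a low percentile, not the minimum: a few failed columns
    # (e.g. motion-fill stripes at the field edge) must not displace the
    # whole volume
    shift = np.clip(ref_vox - int(np.percentile(ref_vox, 2)), 0, None)
    z = np.arange(geo.n_axial)[:, None, None]
    rows = z + shift[None]
    inside = rows < geo.n_axial
    rows_c = np.minimum(rows, geo.n_axial - 1)
    flat = np.take_along_axis(data, rows_c, axis=0)
    fill = float(np.percentile(data, 2)) if data.dtype.kind == "f" else 0
    return np.where(inside, flat, fill), shift


def unflatten(flat: np.ndarray, shift: np.ndarray, fill=0) -> np.ndarray:
    """Inverse of :func:`flatten_to_surface` (columns pushed back down)."""
    nz = flat.shape[0]
    z = np.arange(nz)[:, None, None]
    rows = z - shift[None]
    inside = rows >= 0
    rows_c = np.maximum(rows, 0)
    out = np.take_along_axis(flat, rows_c, axis=0)
    return np.where(inside, out, fill)


# ---------------------------------------------------------------------------
# slab extraction
# ---------------------------------------------------------------------------

def extract_slab(
    volume_or_scores: "OCTVolume | np.ndarray",
    surfaces: LayerSurfaces,
    reference: str = "ilm",
    offset_um: float = 0.0,
    thickness_um: float = 60.0,
) -> Slab:
    """Extract a surface-referenced depth band (default 60 um).

    Accepts an :class:`OCTVolume` or any array of matching shape (vesselness
    scores, a binary angiogram mask).  Columns are shifted nearest-voxel so
    the reference surface is flat; no lateral mixing occurs.  Bands that
    exceed the volume extent are clipped (zero-filled) and flagged.
    """
    if thickness_um <= 0:
        raise ValueError("thickness_um must be positive")
    if reference not in surfaces.surfaces:
        raise KeyError(f"unknown reference surface {reference!r}")
    geo = surfaces.geometry
    if isinstance(volume_or_scores, OCTVolume):
        data = volume_or_scores.intensities
    else:
        data = np.asarray(volume_or_scores)
    if tuple(data.shape) != geo.shape:
        raise ValueError("data shape does not match surface geometry")
    valid_frac = float(surfaces.validity.mean())
    if valid_frac < 0.5:
        raise ValueError(
            f"reference surface valid over only {valid_frac:.0%} of the field"
        )

    band = int(round(thickness_um / geo.dz_um))
    ref_vox = np.rint(surfaces[reference] / geo.dz_um).astype(int)
    start = ref_vox + int(round(offset_um / geo.dz_um))
    rows = start[None, :, :] + np.arange(band)[:, None, None]
    clipped = bool((rows < 0).any() or (rows >= geo.n_axial).any())
    if clipped:
        warnings.warn("slab band exceeds volume extent; clipping", stacklevel=2)
    inside = (rows >= 0) & (rows < geo.n_axial)
    rows_c = np.clip(rows, 0, geo.n_axial - 1)
    voxels = np.take_along_axis(data, rows_c, axis=0)
    if clipped:
        voxels = np.where(inside, voxels, 0)
    return Slab(
        voxels=voxels,
        reference_surface=reference,
        offset_um=offset_um,
        thickness_um=thickness_um,
        geometry=geo,
        clipped=clipped,
    )
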