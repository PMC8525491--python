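"""Scene construction: layered retina, capillary plexuses, lesion geometry.

The scene is the ground truth that the renderer turns into an intensity
volume: smooth layer surfaces (depth maps in um), per-plexus vessel
centerlines with diameters, and per-lesion dimension time courses drawn
around the published group means.  Everything is deterministic given
(parameters, seed).

Anatomical depth model (um from the volume top, before curvature):

    vitreous | ILM | inner retina (NFL..OPL composite) | ONL | ELM |
    IS/OS band | OS | RPE band | choroid | sclera

Lesions deform this model.  An acute lesion is a hyperreflective core
confined between a raised ONL/OPL boundary and the RPE (cylinder that the
narrative describes as evolving hourglass -> pyramid; the profile used here
is a flat-topped disc whose four defined widths are geometrically
unambiguous).  A CNV lesion additionally ruptures the RPE: the bright outer
bands are destroyed in the rupture core and the choroid signal beneath is
suppressed (the "void" appearance), and scheduled fractions of DVP
capillary voxels are removed inside the lesion cylinder (capillary
non-perfusion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from ..volume_core import VolumeGeometry
from .reference import DIMENSIONS, REFERENCE_DAYS, interp_table, reference_cvs, reference_means

__all__ = [
    "LesionSpec",
    "NoiseModel",
    "SceneGroundTruth",
    "PlacementError",
    "DimensionError",
    "simulate_scene",
]

# depth model (um)
ILM0 = 180.0
INNER_THICKNESS = 115.0
ONL_THICKNESS = 68.0
ELM_TO_ISOS = 6.0
ISOS_THICKNESS = 12.0
ISOS_TO_RPE = 10.0
RPE_THICKNESS = 13.0
CHOROID_THICKNESS = 85.0

BOUNDARY0 = ILM0 + INNER_THICKNESS
ELM0 = BOUNDARY0 + ONL_THICKNESS
ISOS_TOP0 = ELM0 + ELM_TO_ISOS
ISOS_CENTER0 = ISOS_TOP0 + ISOS_THICKNESS / 2
RPE_TOP0 = ISOS_TOP0 + ISOS_THICKNESS + ISOS_TO_RPE
RPE_CENTER0 = RPE_TOP0 + RPE_THICKNESS / 2
RPE_BOT0 = RPE_TOP0 + RPE_THICKNESS
CHOROID_BASE0 = RPE_BOT0 + CHOROID_THICKNESS
BASE_SEP = RPE_CENTER0 - BOUNDARY0  # baseline OPL/ONL -> RPE separation

# lesion shape parameters (um)
RPE_BUMP = {"acute": 18.0, "cnv": 24.0}
PR_LIFT = 26.0
EDGE_UM = 4.0  # lateral edge sharpness of lesion profiles
RUPTURE_FRACTION = 0.35  # rupture core width as a fraction of the RPE width

# plexus depth bands: (anchor, offset range um, diameter range um,
#                      vessels per mm of field, swell coupling)
PLEXUS_SPECS = {
    "SVP": ("ilm", (8.0, 26.0), (12.0, 26.0), 16.0, 0.78),
    "IVP": ("ilm", (55.0, 75.0), (6.0, 10.0), 22.0, 0.88),
    "DVP": ("opl_onl", (-24.0, -5.0), (5.0, 10.0), 26.0, 1.0),
    "choroid": ("rpe", (13.0, 75.0), (12.0, 30.0), 32.0, 0.0),
}
PLEXUS_ORDER = ("SVP", "IVP", "DVP", "choroid")


class PlacementError(ValueError):
    """Lesions cannot be placed without overlap at the requested clearance."""


class DimensionError(ValueError):
    """The lateral field is too small for a lesion of the requested size."""


@dataclass
class LesionSpec:
    """One lesion's ground-truth time course.

    ``true_dims`` has shape ``(n_timepoints, 4)`` with columns
    onl/rpe/height/pr in um; ``nonperfusion_schedule`` is the fraction of
    DVP vessel voxels removed inside the lesion cylinder per timepoint.
    """

    condition: str
    center_um: tuple[float, float]  # (slow, fast) lateral position
    timepoint_days: tuple[float, ...]
    true_dims: np.ndarray
    nonperfusion_schedule: np.ndarray
    dispersion_cv: np.ndarray
    rpe_rupture: bool

    def __post_init__(self) -> None:
        self.true_dims = np.asarray(self.true_dims, dtype=float)
        self.nonperfusion_schedule = np.asarray(self.nonperfusion_schedule, dtype=float)
        if np.any(self.true_dims < 0):
            raise ValueError("true_dims must be non-negative")
        if np.any((self.nonperfusion_schedule < 0) | (self.nonperfusion_schedule > 1)):
            raise ValueError("nonperfusion_schedule must lie in [0, 1]")
        if self.condition == "acute":
            if self.rpe_rupture or np.any(self.nonperfusion_schedule > 0):
                raise ValueError("acute lesions never rupture or lose perfusion")

    def _tp_index(self, day: float) -> int:
        days = np.asarray(self.timepoint_days, dtype=float)
        hits = np.nonzero(np.isclose(days, day, atol=1e-9))[0]
        if hits.size == 0:
            raise KeyError(f"timepoint {day} not on the scene grid {self.timepoint_days}")
        return int(hits[0])

    def dims_at(self, day: float) -> np.ndarray:
        """(onl, rpe, height, pr) in um at an on-grid timepoint."""
        return self.true_dims[self._tp_index(day)]

    def nonperfusion_at(self, day: float) -> float:
        return float(self.nonperfusion_schedule[self._tp_index(day)])


@dataclass(frozen=True)
class NoiseModel:
    """Imaging artefact model: multiplicative speckle, floor, motion jitter.

    ``speckle_contrast`` is the sigma/mu of the per-voxel multiplicative
    gamma speckle; ``motion_jitter_um`` the (axial, lateral) scale of the
    per-B-scan translation process (a bounded mean-reverting integer walk).
    Identical seed and parameters give bit-identical output.
    """

    speckle_contrast: float = 0.30
    background_level: float = 0.02
    motion_jitter_um: tuple[float, float] = (3.8, 2.8)
    max_jitter_vox: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speckle_contrast < 0:
            raise ValueError("speckle_contrast must be >= 0")
        if any(j < 0 for j in self.motion_jitter_um):
            raise ValueError("jitter scales must be >= 0")


@dataclass
class Vessel:
    plexus: str
    pts_um: np.ndarray  # (n, 2) lateral (slow, fast)
    depth_um: np.ndarray  # (n,) absolute baseline depth
    radius_um: float


@dataclass
class SceneGroundTruth:
    """Ground truth for one simulated eye."""

    geometry: VolumeGeometry
    condition: str
    surfaces: dict[str, np.ndarray]  # baseline depth maps (um)
    vessels: list[Vessel]
    lesion_specs: list[LesionSpec]
    timepoint_days: tuple[float, ...]
    seed: int

    @property
    def rpe_rupture(self) -> list[bool]:
        return [spec.rpe_rupture for spec in self.lesion_specs]

    @property
    def vessel_centerlines(self) -> list[tuple[np.ndarray, float]]:
        return [(v.pts_um, 2 * v.radius_um) for v in self.vessels]

    # -- lesion deformation -------------------------------------------------

    def _radius_map(self, spec: LesionSpec) -> np.ndarray:
        geo = self.geometry
        y = (np.arange(geo.n_slow) + 0.5) * geo.dx_um - spec.center_um[0]
        x = (np.arange(geo.n_fast) + 0.5) * geo.dx_um - spec.center_um[1]
        return np.hypot(y[:, None], x[None, :])

    def deformation(self, day: float | None) -> dict[str, np.ndarray]:
        """Displaced surface maps plus lesion footprints at a timepoint.

        ``day=None`` returns the undeformed baseline (used for control
        scenes and vessel queries without a timepoint).
        """
        geo = self.geometry
        base = self.surfaces
        shape = (geo.n_slow, geo.n_fast)
        rpe_disp = np.zeros(shape)
        pr_disp = np.zeros(shape)
        sep_extra = np.zeros(shape)
        core_fp = np.zeros(shape, dtype=bool)
        rupture_fp = np.zeros(shape, dtype=bool)
        if day is not None:
            for spec in self.lesion_specs:
                w_onl, w_rpe, height, w_pr = spec.dims_at(day)
                r = self._radius_map(spec)
                p_onl = _ramp(r, w_onl)
                rpe_disp += RPE_BUMP[spec.condition] * _ramp(r, w_rpe)
                pr_disp += PR_LIFT * _ramp(r, w_pr)
                sep_extra += (height - BASE_SEP) * p_onl
                core_fp |= p_onl > 0.5
                if spec.rpe_rupture:
                    rupture_fp |= _ramp(r, RUPTURE_FRACTION * w_rpe) > 0.5

        # outer bands stack on the displaced RPE; the photoreceptor
        # protrusion is an additional lift of the ELM/IS-OS above it
        rpe_c = base["rpe"] - rpe_disp
        elm = base["elm"] - rpe_disp - pr_disp
        isos = base["isos"] - rpe_disp - pr_disp
        top = rpe_c - np.maximum(BASE_SEP + sep_extra, 70.0)
        swell = np.maximum(base["opl_onl"] - top, 0.0)
        ilm = base["ilm"] - 0.78 * swell
        return {
            "ilm": ilm,
            "opl_onl": top,
            "elm": elm,
            "isos": isos,
            "rpe": rpe_c,
            "choroid_base": base["choroid_base"],
            "swell": swell,
            "core_footprint": core_fp,
            "rupture_footprint": rupture_fp,
        }

    def surfaces_at(self, day: float | None) -> dict[str, np.ndarray]:
        d = self.deformation(day)
        return {k: d[k] for k in ("ilm", "opl_onl", "elm", "isos", "rpe", "choroid_base")}

    # -- vessel masks -------------------------------------------------------

    def _removal_keep(self, v: Vessel, day: float | None) -> np.ndarray:
        """Per-sample keep flags implementing deep-plexus non-perfusion.

        The schedule acts on the two deep inner-retina beds (IVP and DVP),
        the ones reported to lose perfusion under the swelling lesion.
        """
        keep = np.ones(len(v.pts_um), dtype=bool)
        if day is None or v.plexus not in ("DVP", "IVP"):
            return keep
        for spec in self.lesion_specs:
            frac = spec.nonperfusion_at(day)
            if frac <= 0:
                continue
            radius = spec.dims_at(day)[0] / 2 + 10.0
            d = np.hypot(
                v.pts_um[:, 0] - spec.center_um[0], v.pts_um[:, 1] - spec.center_um[1]
            )
            inside = d < radius
            idx = np.nonzero(inside)[0]
            if idx.size == 0:
                continue
            # drop the central `frac` of each contiguous in-cylinder run
            splits = np.nonzero(np.diff(idx) > 1)[0] + 1
            for run in np.split(idx, splits):
                n_drop = int(round(frac * run.size))
                if n_drop == 0:
                    continue
                start = (run.size - n_drop) // 2
                keep[run[start : start + n_drop]] = False
        return keep

    def vessel_mask(
        self, plexus: str, day: float | None = None, deformation: dict | None = None
    ) -> np.ndarray:
        """Binary voxel mask of one plexus, displaced by lesion swelling.

        Inner plexus masks are clipped to the ILM..RPE band, the choroid
        mask to below the RPE, so masks of different plexuses are disjoint.
        """
        geo = self.geometry
        if deformation is None:
            deformation = self.deformation(day)
        anchor, _, _, _, coupling = PLEXUS_SPECS[plexus]
        swell = deformation["swell"]
        mask = np.zeros(geo.shape, dtype=bool)
        for v in self.vessels:
            if v.plexus != plexus:
                continue
            keep = self._removal_keep(v, day)
            if not keep.any():
                continue
            pts = v.pts_um[keep]
            yi = np.clip((pts[:, 0] / geo.dx_um).astype(int), 0, geo.n_slow - 1)
            xi = np.clip((pts[:, 1] / geo.dx_um).astype(int), 0, geo.n_fast - 1)
            depth = v.depth_um[keep] - coupling * swell[yi, xi]
            zi = np.rint(depth / geo.dz_um).astype(int)
            _stamp_tube(mask, zi, yi, xi, v.radius_um, geo)
        # clip to anatomical band
        z = np.arange(geo.n_axial)[:, None, None]
        if plexus == "choroid":
            lo = (deformation["rpe"] + RPE_THICKNESS / 2) / geo.dz_um
            hi = deformation["choroid_base"] / geo.dz_um
        else:
            lo = deformation["ilm"] / geo.dz_um
            hi = (deformation["rpe"] - RPE_THICKNESS / 2) / geo.dz_um
        mask &= (z >= lo[None]) & (z <= hi[None])
        return mask

    def vessel_masks(self, day: float | None = None) -> dict[str, np.ndarray]:
        """All plexus masks at once, made mutually disjoint."""
        deformation = self.deformation(day)
        out: dict[str, np.ndarray] = {}
        taken: np.ndarray | None = None
        for plexus in PLEXUS_ORDER:
            m = self.vessel_mask(plexus, day, deformation)
            if taken is not None:
                m &= ~taken
                taken = taken | m
            else:
                taken = m.copy()
            out[plexus] = m
        return out

    # -- tables -------------------------------------------------------------

    def lesion_table(self) -> pd.DataFrame:
        """True dimensions per lesion per timepoint (the morphometry oracle)."""
        rows = []
        for lid, spec in enumerate(self.lesion_specs):
            for ti, day in enumerate(spec.timepoint_days):
                onl, rpe, height, pr = spec.true_dims[ti]
                rows.append(
                    dict(
                        lesion_id=lid,
                        day=day,
                        onl_um=onl,
                        rpe_um=rpe,
                        height_um=height,
                        pr_um=pr,
                    )
                )
        cols = ["lesion_id", "day", "onl_um", "rpe_um", "height_um", "pr_um"]
        return pd.DataFrame(rows, columns=cols)


def _ramp(r: np.ndarray, width: float) -> np.ndarray:
    """Lateral lesion profile: 1 inside, 0 outside, linear edge of EDGE_UM.

    Crosses 0.5 exactly at r = width / 2, so thresholded footprints and
    full-width-at-half-maximum measurements both recover ``width``.
    """
    if width <= 0:
        return np.zeros_like(r)
    return np.clip((width / 2 + EDGE_UM / 2 - r) / EDGE_UM, 0.0, 1.0)


@lru_cache(maxsize=64)
def _ellipsoid_offsets(rl_vox: float, ra_vox: float) -> tuple[np.ndarray, ...]:
    rl = max(rl_vox, 0.5)
    ra = max(ra_vox, 0.5)
    nz, nl = int(math.ceil(ra)), int(math.ceil(rl))
    oz, oy, ox = np.mgrid[-nz : nz + 1, -nl : nl + 1, -nl : nl + 1]
    keep = (oz / ra) ** 2 + (oy / rl) ** 2 + (ox / rl) ** 2 <= 1.0
    return oz[keep], oy[keep], ox[keep]


def _stamp_tube(
    mask: np.ndarray,
    zi: np.ndarray,
    yi: np.ndarray,
    xi: np.ndarray,
    radius_um: float,
    geo: VolumeGeometry,
) -> None:
    rl = round(radius_um / geo.dx_um, 1)
    ra = round(radius_um / geo.dz_um, 1)
    oz, oy, ox = _ellipsoid_offsets(rl, ra)
    z = (zi[:, None] + oz[None, :]).ravel()
    y = (yi[:, None] + oy[None, :]).ravel()
    x = (xi[:, None] + ox[None, :]).ravel()
    ok = (
        (z >= 0)
        & (z < geo.n_axial)
        & (y >= 0)
        & (y < geo.n_slow)
        & (x >= 0)
        & (x < geo.n_fast)
    )
    mask[z[ok], y[ok], x[ok]] = True


# ---------------------------------------------------------------------------
# scene assembly
# ---------------------------------------------------------------------------

def _base_surfaces(geo: VolumeGeometry, rng: np.random.Generator) -> dict[str, np.ndarray]:
    ns, nf = geo.n_slow, geo.n_fast
    ry = (np.arange(ns) + 0.5) / ns * 2 - 1
    rx = (np.arange(nf) + 0.5) / nf * 2 - 1
    bowl = 12.0 * (ry[:, None] ** 2 + rx[None, :] ** 2)
    tilt = 3.0 * rx[None, :] + 0.0 * ry[:, None]
    und = ndi.gaussian_filter(
        rng.standard_normal((ns, nf)), sigma=max(25.0 / geo.dx_um, 2.0), mode="reflect"
    )
    sd = und.std()
    und = und / sd * 4.0 if sd > 0 else und
    base = bowl + tilt + und
    return {
        "ilm": ILM0 + base,
        "opl_onl": BOUNDARY0 + base,
        "elm": ELM0 + base,
        "isos": ISOS_CENTER0 + base,
        "rpe": RPE_CENTER0 + base,
        "choroid_base": CHOROID_BASE0 + base,
    }


def _generate_vessels(
    geo: VolumeGeometry, surfaces: dict[str, np.ndarray], rng: np.random.Generator
) -> list[Vessel]:
    fy, fx = geo.field_um
    vessels: list[Vessel] = []
    step = 4.0  # um along the centerline
    for plexus in PLEXUS_ORDER:
        anchor, band, diam, per_mm, _ = PLEXUS_SPECS[plexus]
        n = max(5, int(round(per_mm * (fy + fx) / 2 / 1000.0)))
        anchor_map = surfaces[anchor]
        if plexus == "choroid":
            anchor_map = anchor_map + RPE_THICKNESS / 2  # below the RPE band
        for _ in range(n):
            edge = rng.integers(4)
            t = rng.uniform(0.05, 0.95)
            if edge == 0:
                pos = np.array([0.0, t * fx])
                ang = rng.uniform(-0.7, 0.7) + math.pi / 2
            elif edge == 1:
                pos = np.array([fy, t * fx])
                ang = rng.uniform(-0.7, 0.7) - math.pi / 2
            elif edge == 2:
                pos = np.array([t * fy, 0.0])
                ang = rng.uniform(-0.7, 0.7)
            else:
                pos = np.array([t * fy, fx])
                ang = rng.uniform(-0.7, 0.7) + math.pi
            n_steps = int(2.5 * (fy + fx) / step)
            turns = rng.normal(0.0, 0.05, size=n_steps)
            pts = [pos.copy()]
            for dth in turns:
                ang += dth
                pos = pos + step * np.array([math.sin(ang), math.cos(ang)])
                if not (-20 < pos[0] < fy + 20 and -20 < pos[1] < fx + 20):
                    break
                pts.append(pos.copy())
            if len(pts) < 4:
                continue
            pts_arr = np.array(pts)
            radius = rng.uniform(*diam) / 2
            depth0 = rng.uniform(*band)
            phase = rng.uniform(0, 2 * math.pi)
            wob = 3.0 * np.sin(
                phase + np.linspace(0, rng.uniform(2, 5) * math.pi, len(pts_arr))
            )
            yi = np.clip((pts_arr[:, 0] / geo.dx_um).astype(int), 0, geo.n_slow - 1)
            xi = np.clip((pts_arr[:, 1] / geo.dx_um).astype(int), 0, geo.n_fast - 1)
            depth = anchor_map[yi, xi] + depth0 + wob
            # resample to sub-voxel spacing for gap-free stamping
            fine = max(int(round(step / (0.6 * min(geo.dx_um, geo.dz_um)))), 1)
            if fine > 1:
                s = np.arange(len(pts_arr))
                si = np.linspace(0, len(pts_arr) - 1, fine * (len(pts_arr) - 1) + 1)
                pts_arr = np.column_stack(
                    [np.interp(si, s, pts_arr[:, 0]), np.interp(si, s, pts_arr[:, 1])]
                )
                depth = np.interp(si, s, depth)
            vessels.append(Vessel(plexus, pts_arr, depth, radius))
    return vessels


def _place_lesions(
    geo: VolumeGeometry, n: int, max_diam: float, margin_frac: float
) -> list[tuple[float, float]]:
    fy, fx = geo.field_um
    margin = margin_frac * max_diam
    need = max_diam + 2 * margin
    # single lesions need clearance on the fast (measurement) axis only:
    # a narrow strip scanned across the lesion center is a legal acquisition
    if need > (fx if n == 1 else min(fy, fx)):
        raise DimensionError(
            f"lateral field {min(fy, fx):.0f} um cannot hold a {max_diam:.0f} um "
            f"lesion with {margin:.0f} um clearance"
        )
    if n == 1:
        return [(fy / 2, fx / 2)]
    if n <= 3:
        r_max = min(fy, fx) / 2 - (max_diam / 2 + margin)
        angles = [0.0, math.pi, math.pi / 2][:n]
        min_sep = max_diam + margin
        chord = 2 * r_max * (math.sin(math.pi / 4) if n > 2 else 1.0)
        if chord < min_sep:
            raise PlacementError(
                f"cannot separate {n} lesions of {max_diam:.0f} um by {min_sep:.0f} um"
            )
        return [
            (fy / 2 + r_max * math.sin(a), fx / 2 + r_max * math.cos(a)) for a in angles
        ]
    # four or more: one lesion per rectangular cell (n = 4 gives the four
    # retinal quadrants of the induction protocol)
    rows = int(math.ceil(math.sqrt(n)))
    cols = int(math.ceil(n / rows))
    cell_y, cell_x = fy / rows, fx / cols
    if min(cell_y, cell_x) < need:
        raise PlacementError(
            f"grid cells {cell_y:.0f}x{cell_x:.0f} um too small for "
            f"{max_diam:.0f} um lesions with clearance"
        )
    centers = []
    for k in range(n):
        i, j = divmod(k, cols)
        centers.append(((i + 0.5) * cell_y, (j + 0.5) * cell_x))
    return centers


def simulate_scene(
    geometry: VolumeGeometry,
    condition: str,
    n_lesions: int,
    seed: int,
    *,
    timepoints: tuple[float, ...] = REFERENCE_DAYS,
    include_1h: bool = False,
    dispersion: bool = True,
    dispersion_rho: float = 0.6,
    nonperfusion_schedule: dict[float, float] | None = None,
    nonperfusion_height_um: float = 200.0,
    nonperfusion_fraction: float = 0.8,
    margin_frac: float = 0.25,
) -> SceneGroundTruth:
    """Build a ground-truthed scene for one simulated eye.

    Per-timepoint mean lesion dimensions follow the packaged reference
    table for the condition (piecewise-linear between printed days); with
    ``dispersion`` on, each (lesion, dimension, day) receives a lognormal
    scale of mean exactly 1 whose CV matches the table's CV cell, with a
    shared per-(lesion, dimension) random effect (``dispersion_rho``) so a
    severe lesion stays severe over time.  ``include_1h`` prepends a 1-hour
    point (day 0.042) equal to the lesion's day-1 value.

    CNV lesions rupture the RPE and, by default, lose
    ``nonperfusion_fraction`` of their in-cylinder DVP voxels at timepoints
    where the lesion height is at least ``nonperfusion_height_um``; an
    explicit ``nonperfusion_schedule`` (day -> fraction) overrides this.
    Control scenes have zero lesions.

    Raises :class:`DimensionError` if a lesion cannot fit in the lateral
    field and :class:`PlacementError` if the requested number of lesions
    cannot be separated at ``margin_frac`` lesion-diameter clearance.
    """
    if condition not in ("acute", "cnv", "control"):
        raise ValueError(f"unknown condition {condition!r}")
    if n_lesions < 0:
        raise ValueError("n_lesions must be >= 0")
    if condition == "control" and n_lesions != 0:
        raise ValueError("control scenes have zero lesions")
    if condition != "control" and n_lesions == 0:
        raise ValueError(f"{condition} scenes need at least one lesion")

    rng = np.random.default_rng(seed)
    surfaces = _base_surfaces(geometry, rng)
    vessels = _generate_vessels(geometry, surfaces, rng)

    days = tuple(float(d) for d in timepoints)
    if include_1h:
        days = (1.0 / 24.0,) + days

    specs: list[LesionSpec] = []
    if n_lesions > 0:
        days_arr = np.asarray(days)
        means = interp_table(reference_means(condition), days_arr)  # (n_t, 4)
        cvs = interp_table(reference_cvs(condition), days_arr)
        if dispersion:
            sigma = np.sqrt(np.log1p(cvs**2))  # (n_t, 4)
            z_lesion = rng.standard_normal((n_lesions, 1, 4))
            z_day = rng.standard_normal((n_lesions, len(days), 4))
            rho = dispersion_rho
            z = rho * z_lesion + math.sqrt(1 - rho**2) * z_day
            scales = np.exp(sigma[None] * z - sigma[None] ** 2 / 2)
            # sub-day-1 points repeat the first on-or-after-day-1 draw
            early = days_arr < 1.0
            if early.any():
                ref = int(np.argmax(~early))
                scales[:, early, :] = scales[:, [ref], :]
        else:
            scales = np.ones((n_lesions, len(days), 4))
        dims = means[None] * scales  # (n_lesions, n_t, 4)

        lateral = dims[:, :, [0, 1, 3]]  # onl, rpe, pr widths
        max_diam = float(lateral.max())
        centers = _place_lesions(geometry, n_lesions, max_diam, margin_frac)

        for li in range(n_lesions):
            heights = dims[li, :, 2]
            if condition == "cnv":
                if nonperfusion_schedule is not None:
                    sched = np.array(
                        [float(nonperfusion_schedule.get(d, 0.0)) for d in days]
                    )
                else:
                    sched = np.where(
                        heights >= nonperfusion_height_um, nonperfusion_fraction, 0.0
                    )
                rupture = True
            else:
                sched = np.zeros(len(days))
                rupture = False
            specs.append(
                LesionSpec(
                    condition=condition,
                    center_um=centers[li],
                    timepoint_days=days,
                    true_dims=dims[li],
                    nonperfusion_schedule=sched,
                    dispersion_cv=cvs.copy(),
                    rpe_rupture=rupture,
                )
            )

    return SceneGroundTruth(
        geometry=geometry,
        condition=condition,
        surfaces=surfaces,
        vessels=vessels,
        lesion_specs=specs,
        timepoint_days=days,
        seed=seed,
    )
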