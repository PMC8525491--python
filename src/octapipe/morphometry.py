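"""Lesion morphometry and longitudinal dynamics.

Four dimensions are measured on the lesion-centered B-scan, following the
B-scan measurement scheme of the injury model: the lateral disruption
width at the ONL/OPL boundary (``onl``), the lateral RPE disruption width
(``rpe``), the maximal vertical OPL-RPE disruption (``height``) and the
widest ELM-IS/OS protrusion into the ONL (``pr``), all in micrometres.
Widths are full-width-at-half-maximum extents of the deviation of a local
layer profile from its smooth surround fit, gated at a noise-derived
detection threshold; FWHM is exact for symmetric smoothed edges, which
makes the widths insensitive to the precise threshold.

The dynamics model self-normalizes each lesion: percent change
P_t = 100 (M_t - M_0) / M_0 from the first measurement (expansion
positive), interval differences D1 normalized by the baseline, their
consecutive differences D2, and a steady-state onset defined as the
earliest timepoint after which every remaining interval change has
magnitude at most the significance threshold (default 5% of baseline).
Group consistency uses the coefficient of variation sigma/mu per
(dimension, day) cell, pooled as the unweighted mean over cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .synthetic_oct.reference import reference_cvs
from .volume_core import LayerSurfaces

__all__ = [
    "LesionMeasurement",
    "DynamicsTrace",
    "GroupStats",
    "measure_lesion",
    "percent_change_trace",
    "trace_from_values",
    "detect_steady_state",
    "group_statistics",
    "pooled_cv_from_reference",
]

DIMENSION_COLUMNS = {"onl": "onl_um", "rpe": "rpe_um", "height": "height_um", "pr": "pr_um"}


@dataclass
class LesionMeasurement:
    """One lesion's four dimensions (um) at one timepoint."""

    lesion_id: int
    day: float
    onl_um: float
    rpe_um: float
    height_um: float
    pr_um: float
    no_lesion: bool = False

    def __post_init__(self) -> None:
        for name in ("onl_um", "rpe_um", "height_um", "pr_um"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class DynamicsTrace:
    """Self-normalized longitudinal trace of one dimension.

    ``percent_change[0]`` is 0 by construction; ``first_diff[i]`` is the
    change over interval (days[i], days[i+1]) as a percentage of the
    baseline; ``second_diff`` are consecutive differences of
    ``first_diff``.  Expansion is positive.
    """

    days: np.ndarray
    values: np.ndarray
    baseline: float
    percent_change: np.ndarray
    first_diff: np.ndarray
    second_diff: np.ndarray
    significance_threshold: float = 5.0
    steady_onset: "float | None" = None


@dataclass
class GroupStats:
    """Per-(dimension, day) mean/std/CV cells and their pooled CV."""

    cells: pd.DataFrame
    pooled_cv: float
    condition: "str | None" = None
    excluded: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# B-scan measurement
# ---------------------------------------------------------------------------

def _robust_sigma(x: np.ndarray) -> float:
    x = x[np.isfinite(x)]
    if x.size == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def _quad_fit(x: np.ndarray, y: np.ndarray, use: np.ndarray) -> np.ndarray:
    if use.sum() < 6:
        return np.full_like(y, float(np.nanmedian(y[use])) if use.any() else np.nan)
    c = np.polyfit(x[use], y[use], 2)
    return np.polyval(c, x)


def _surround_fit(
    x: np.ndarray, depth: np.ndarray, valid: np.ndarray, surround: np.ndarray
) -> np.ndarray:
    """Smooth surround model of a surface profile around a lesion.

    A quadratic fit on the far surround alone extrapolates poorly into the
    center, so the deviating (lesion) interior is detected against that
    first fit and the quadratic refit on all remaining valid columns,
    turning the extrapolation into an interpolation.
    """
    fit = _quad_fit(x, depth, surround & valid)
    resid = fit - depth
    sig = _robust_sigma(resid[surround & valid])
    dev = (np.abs(resid) > max(3 * sig, 8.0)) & ~surround
    pad = max(x.size // 40, 5)
    excl = ndi.binary_dilation(dev, iterations=pad)
    use = valid & ~excl
    if use.sum() >= 12:
        fit = _quad_fit(x, depth, use)
    return fit


def _dominant_span(
    seg: np.ndarray, prof: np.ndarray, lo: int, level: float, gap_cols: int
) -> "tuple[int, int] | None":
    """Span of the dominant above-level run, merged across small gaps."""
    above = np.nonzero(seg >= level)[0]
    if above.size == 0:
        return None
    splits = np.nonzero(np.diff(above) > 1)[0] + 1
    runs = [r + lo for r in np.split(above, splits)]
    sums = [float(prof[r].sum()) for r in runs]
    k = int(np.argmax(sums))
    first, last = runs[k][0], runs[k][-1]
    for r in runs[k + 1 :]:
        if r[0] - last <= gap_cols:
            last = r[-1]
        else:
            break
    for r in runs[:k][::-1]:
        if first - r[-1] <= gap_cols:
            first = r[0]
        else:
            break
    return int(first), int(last)


def _fwhm(
    x_um: np.ndarray,
    prof: np.ndarray,
    center_idx: int,
    window: int,
    detect_thr: float = 0.0,
    gap_tolerance_um: float = 45.0,
) -> float:
    """Full width at half maximum of a plateau-like deviation profile.

    The profile is 5-wide-median filtered (single-column speckle spikes
    must not set the levels).  The half level is half the *median* of the
    detected plateau rather than half its peak, so local peaks (e.g. over
    a rupture) do not push the half level above a sagging shoulder.  Runs
    are merged across gaps up to ``gap_tolerance_um`` — vessel shadows cut
    narrow dips into the plateau — while distant above-level islands from
    isolated glitches are ignored.
    """
    dx0 = float(np.median(np.diff(x_um))) if x_um.size > 1 else 1.0
    med = max(int(round(10.0 / dx0)) | 1, 1)
    prof = ndi.median_filter(prof, size=med, mode="nearest")
    lo = max(center_idx - window, 0)
    hi = min(center_idx + window + 1, prof.size)
    seg = prof[lo:hi]
    peak = float(seg.max())
    if peak <= 0:
        return 0.0
    dx = float(np.median(np.diff(x_um))) if x_um.size > 1 else 1.0
    gap_cols = max(int(round(gap_tolerance_um / dx)), 2)
    region_thr = max(detect_thr, 0.25 * peak)
    span = _dominant_span(seg, prof, lo, region_thr, gap_cols)
    if span is None:
        return 0.0
    level = float(np.median(prof[span[0] : span[1] + 1]))
    half = max(level / 2.0, 0.5 * detect_thr)
    span = _dominant_span(seg, prof, lo, half, gap_cols)
    if span is None:
        return 0.0
    first, last = span
    left = x_um[first]
    if first > 0 and prof[first - 1] < half:
        f = (prof[first] - half) / max(prof[first] - prof[first - 1], 1e-12)
        left = x_um[first] - f * (x_um[first] - x_um[first - 1])
    right = x_um[last]
    if last < prof.size - 1 and prof[last + 1] < half:
        f = (prof[last] - half) / max(prof[last] - prof[last + 1], 1e-12)
        right = x_um[last] + f * (x_um[last + 1] - x_um[last])
    return float(right - left)


def _band_argmax(
    smooth: np.ndarray, lo_vox: np.ndarray, hi_vox: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    nz = smooth.shape[0]
    z = np.arange(nz)[:, None]
    inside = (z >= lo_vox[None, :]) & (z <= hi_vox[None, :])
    masked = np.where(inside, smooth, -np.inf)
    idx = masked.argmax(axis=0)
    val = masked[idx, np.arange(smooth.shape[1])]
    return idx, val


def _fill_invalid(x: np.ndarray, prof: np.ndarray, valid: np.ndarray) -> np.ndarray:
    out = prof.copy()
    if valid.all() or not valid.any():
        return out
    out[~valid] = np.interp(x[~valid], x[valid], prof[valid])
    return out


def measure_lesion(
    bscan: np.ndarray,
    surfaces: LayerSurfaces,
    slow_index: int,
    lesion_center_um: float,
    lesion_id: int = 0,
    day: float = 1.0,
    smooth_sigma_um: tuple[float, float] = (3.8, 2.8),
    surround_fraction: float = 0.7,
    core_run_um: float = 24.0,
    return_profiles: bool = False,
) -> "LesionMeasurement | tuple[LesionMeasurement, dict]":
    """Measure the four lesion dimensions on a lesion-centered B-scan.

    ``lesion_center_um`` is the lateral (fast-axis) position of the lesion
    midpoint, chosen by orthographic landmarking.  Surround layer profiles
    are fit with a robust quadratic over columns farther than
    ``surround_fraction`` of the center-to-edge distance; deviations are
    measured against these fits.  Columns whose outer bands are destroyed
    (RPE rupture) count as disrupted, their elevation interpolated from the
    rupture rim.  Returns an all-zero measurement flagged ``no_lesion``
    when no profile deviates beyond threshold.
    """
    geo = surfaces.geometry
    dx, dz = geo.dx_um, geo.dz_um
    # physical smoothing sizes so widefield pitches are not over-blurred
    smooth_sigma = (smooth_sigma_um[0] / dz, smooth_sigma_um[1] / dx)
    smooth = ndi.gaussian_filter(bscan.astype(np.float32), smooth_sigma)
    # band-position profiles use near-axial-only smoothing: lateral blur
    # lets a bright displaced band bleed into neighbouring columns and
    # biases the per-column argmax outward at lesion edges
    smooth_ax = ndi.gaussian_filter(
        bscan.astype(np.float32), (smooth_sigma[0], float(np.clip(2.2 / dx, 0.5, 0.8)))
    )
    # band-matched axial integration: the bright outer bands are ~12 um
    # thick, and integrating over that thickness suppresses speckle/texture
    # extremes that would otherwise flip a per-column argmax onto the core
    band_rows = max(int(round(12.0 / geo.dz_um)), 3)
    smooth_band = ndi.uniform_filter1d(smooth_ax, size=band_rows, axis=0)
    nz, nf = smooth.shape
    x_um = (np.arange(nf) + 0.5) * dx
    cx = float(lesion_center_um)
    cx_idx = int(np.clip(round(cx / dx - 0.5), 0, nf - 1))
    E = surround_fraction * min(cx, nf * dx - cx)
    surround = np.abs(x_um - cx) > E
    central_window = max(int(round(E / dx)), 4)

    ilm_row = surfaces["ilm"][slow_index]
    opl_row = surfaces["opl_onl"][slow_index]
    rpe_row = surfaces["rpe"][slow_index]
    all_ok = np.ones(nf, dtype=bool)
    opl_fit = _surround_fit(x_um, opl_row, all_ok, surround)
    ilm_fit = _quad_fit(x_um, ilm_row, surround)

    # --- RPE surface profile -------------------------------------------------
    # refine within a narrow window around the (median-smoothed) segmented
    # RPE: the window is too tight to flip onto the IS/OS band under
    # vessel shadows
    lo = np.clip(np.rint((rpe_row - 14.0) / dz), 0, nz - 1).astype(int)
    hi = np.clip(np.rint((rpe_row + 14.0) / dz), 0, nz - 1).astype(int)
    med_cols = max(int(round(10.0 / dx)) | 1, 1)
    rpe_idx, rpe_val = _band_argmax(smooth_band, lo, hi)
    rpe_depth = ndi.median_filter((rpe_idx + 0.5) * dz, size=med_cols, mode="nearest")
    rpe_valid = rpe_val > 0.8 * np.median(rpe_val[surround])
    rpe_fit = _quad_fit(x_um, rpe_depth, surround & rpe_valid)
    # depth plausibility: where the outer bands are destroyed the brightest
    # deep voxel is lesion core far above any credible RPE position
    rpe_valid &= np.abs(rpe_depth - rpe_fit) < 50.0
    rpe_fit = _surround_fit(x_um, rpe_depth, rpe_valid, surround)
    rpe_elev = rpe_fit - rpe_depth  # positive = raised toward the vitreous
    rpe_elev = _fill_invalid(x_um, rpe_elev, rpe_valid)
    rpe_used_depth = rpe_fit - rpe_elev  # measured where valid, else interpolated
    sig = _robust_sigma(rpe_elev[surround])
    rpe_thr = max(4 * sig, 7.0)
    pk = rpe_elev[max(cx_idx - central_window, 0) : cx_idx + central_window]
    rpe_um = (
        _fwhm(x_um, rpe_elev, cx_idx, central_window, rpe_thr) if pk.size and pk.max() > rpe_thr else 0.0
    )

    # --- photoreceptor band (ELM-IS/OS) profile ------------------------------
    # tracked by the band's bottom edge (the bright IS/OS falling to the
    # dark outer segments): this gradient is far stronger than anything
    # the lesion core can produce, so speckle/texture cannot flip it,
    # and it rides up with the protruding band.  Anchored to the RPE.
    grad_ax = ndi.gaussian_filter1d(smooth_ax, sigma=2.0, axis=0, order=1)
    lo = np.clip(np.rint((rpe_used_depth - 55.0) / dz), 0, nz - 1).astype(int)
    hi = np.clip(np.rint((rpe_used_depth - 10.0) / dz), 0, nz - 1).astype(int)
    hi = np.maximum(hi, lo + 1)
    isos_idx, isos_val = _band_argmax(-grad_ax, lo, hi)
    isos_depth = ndi.median_filter((isos_idx + 0.5) * dz, size=med_cols, mode="nearest")
    isos_valid = isos_val > 0.5 * np.median(isos_val[surround])
    # a destroyed RPE (rupture) takes the photoreceptor bands with it
    isos_valid &= rpe_valid
    isos_fit = _surround_fit(x_um, isos_depth, isos_valid, surround)
    # protrusion into the ONL is the band's lift relative to the RPE under
    # it, so a plain RPE dome (no protrusion) reads zero
    pr_elev = _fill_invalid(x_um, isos_fit - isos_depth, isos_valid) - rpe_elev
    sig = _robust_sigma(pr_elev[surround])
    pr_thr = max(4 * sig, 7.0)
    pk = pr_elev[max(cx_idx - central_window, 0) : cx_idx + central_window]
    pr_um = (
        _fwhm(x_um, pr_elev, cx_idx, central_window, pr_thr) if pk.size and pk.max() > pr_thr else 0.0
    )

    # --- ONL band intensity profile ------------------------------------------
    # low percentile over a thin band just below the boundary fit: thin
    # enough that a fully lifted photoreceptor complex (and the dark
    # OS/edema under it) stays below the band, with the percentile robust
    # to bright inner retina leaking in through boundary-fit error
    band_lo = np.clip(np.rint((opl_fit + 5.0) / dz), 0, nz - 1).astype(int)
    band_hi = np.clip(np.rint((opl_fit + 22.0) / dz), 0, nz - 1).astype(int)
    z = np.arange(nz)[:, None]
    in_band = (z >= band_lo[None, :]) & (z <= band_hi[None, :])
    onl_prof = np.nanpercentile(np.where(in_band, smooth, np.nan), 25, axis=0)
    # normalize by the same column's RPE peak (rupture columns filled from
    # the rim): vessel shadows attenuate both identically, so the ratio is
    # shadow-invariant
    rpe_val_filled = _fill_invalid(x_um, rpe_val, rpe_valid)
    onl_ratio = onl_prof / np.maximum(rpe_val_filled, 1e-6)
    onl_dev = onl_ratio - np.median(onl_ratio[surround])
    sig = _robust_sigma(onl_dev[surround])
    onl_thr = max(4 * sig, 0.06)
    pk = onl_dev[max(cx_idx - central_window, 0) : cx_idx + central_window]
    onl_um = (
        _fwhm(x_um, onl_dev, cx_idx, central_window, onl_thr) if pk.size and pk.max() > onl_thr else 0.0
    )

    if onl_um == 0.0 and rpe_um == 0.0 and pr_um == 0.0:
        return LesionMeasurement(lesion_id, day, 0.0, 0.0, 0.0, 0.0, no_lesion=True)

    # --- height: maximal vertical OPL-RPE disruption -------------------------
    fp_half = max(onl_um, rpe_um) / 2.0
    footprint = np.abs(x_um - cx) <= max(fp_half, 3 * dx)
    inner_level = float(
        np.median(
            smooth[
                np.clip(np.rint((ilm_fit.mean() + 15.0) / dz), 0, nz - 1).astype(int) : np.clip(
                    np.rint((opl_fit.mean() - 15.0) / dz), 1, nz
                ).astype(int),
            ][:, surround]
        )
    )
    core_level = float(np.percentile(onl_prof[footprint], 90))
    core_thr = 0.5 * (inner_level + max(core_level, inner_level + 1e-6))
    # the disrupted top can rise far above the surrounding boundary (tall
    # CNV swelling lifts it past the surround ILM level); rows above the
    # displaced inner retina are vitreous and cannot cross the threshold
    w_lo = np.clip(np.rint((opl_fit - 400.0) / dz), 0, nz - 1).astype(int)
    w_hi = np.clip(np.rint((rpe_used_depth - 15.0) / dz), 0, nz - 1).astype(int)
    run = max(int(round(core_run_um / dz)), 1)
    above = smooth >= core_thr
    sustained = (
        ndi.uniform_filter1d(above.astype(np.float32), size=run, axis=0, origin=-(run // 2))
        > 0.999
    )
    in_window = (z >= w_lo[None, :]) & (z <= w_hi[None, :])
    cand = sustained & in_window
    has = cand.any(axis=0)
    top_idx = np.where(has, cand.argmax(axis=0), 0)
    rpe_used = rpe_fit - rpe_elev
    heights = np.where(footprint & has, rpe_used - (top_idx + 0.5) * dz, 0.0)
    ok = heights > 0
    # the disrupted region is flat-topped, so the footprint median reads the
    # maximal extent while ignoring columns where a displaced capillary
    # bridges the core top (high outliers) or the rim tapers (low outliers)
    height_um = float(np.median(heights[ok])) if ok.any() else 0.0

    result = LesionMeasurement(
        lesion_id,
        day,
        float(max(onl_um, 0.0)),
        float(max(rpe_um, 0.0)),
        height_um,
        float(max(pr_um, 0.0)),
    )
    if return_profiles:
        return result, {
            "x_um": x_um,
            "surround": surround,
            "rpe_depth": rpe_depth,
            "rpe_valid": rpe_valid,
            "rpe_elev": rpe_elev,
            "rpe_thr": rpe_thr,
            "isos_depth": isos_depth,
            "isos_valid": isos_valid,
            "pr_elev": pr_elev,
            "pr_thr": pr_thr,
            "onl_dev": onl_dev,
            "onl_thr": onl_thr,
            "heights": heights,
            "opl_fit": opl_fit,
            "rpe_fit": rpe_fit,
        }
    return result


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def trace_from_values(
    days: np.ndarray, values: np.ndarray, significance_threshold: float = 5.0
) -> DynamicsTrace:
    """Build a dynamics trace from raw (day, value) series.

    Requires at least two strictly-increasing timepoints and a positive
    baseline (the first value).
    """
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    if days.size < 2:
        raise ValueError("need at least two timepoints")
    if np.any(np.diff(days) <= 0):
        raise ValueError("days must be strictly increasing")
    m0 = float(values[0])
    if m0 <= 0:
        raise ValueError("baseline measurement must be positive")
    p = 100.0 * (values - m0) / m0
    d1 = 100.0 * np.diff(values) / m0
    d2 = np.diff(d1)
    trace = DynamicsTrace(
        days=days,
        values=values,
        baseline=m0,
        percent_change=p,
        first_diff=d1,
        second_diff=d2,
        significance_threshold=significance_threshold,
    )
    trace.steady_onset = _steady_onset(trace)
    return trace


def percent_change_trace(
    measurements: "list[LesionMeasurement] | pd.DataFrame",
    dimension: str,
    significance_threshold: float = 5.0,
) -> DynamicsTrace:
    """Percent-change dynamics of one dimension across ordered timepoints."""
    col = DIMENSION_COLUMNS.get(dimension, dimension)
    if isinstance(measurements, pd.DataFrame):
        df = measurements.sort_values("day")
        days = df["day"].to_numpy(dtype=float)
        values = df[col].to_numpy(dtype=float)
    else:
        ms = sorted(measurements, key=lambda m: m.day)
        days = np.array([m.day for m in ms], dtype=float)
        values = np.array([getattr(m, col) for m in ms], dtype=float)
    return trace_from_values(days, values, significance_threshold)


def _steady_onset(trace: DynamicsTrace) -> "float | None":
    """Earliest timepoint after which all remaining |D1| are insignificant.

    Candidate onsets lie strictly before the last interval (there must be
    at least two remaining intervals to witness an asymptote), mirroring
    the second-derivative zero-asymptote reading of the trace.
    """
    d1 = trace.first_diff
    thr = trace.significance_threshold
    n = trace.days.size
    for i in range(0, n - 2):
        if np.all(np.abs(d1[i:]) <= thr):
            return float(trace.days[i])
    return None


def detect_steady_state(trace: DynamicsTrace) -> tuple["float | None", dict[float, str]]:
    """Steady-state onset plus inflammatory phase labels per timepoint.

    Phases follow the three-stage progression of the injury response:
    early (through day 3), transition (days 3-7), late (day 7 on).
    """
    if trace.days.size < 3:
        raise ValueError("need at least three timepoints")
    onset = _steady_onset(trace)
    phases: dict[float, str] = {}
    for d in trace.days:
        if d <= 3.0:
            phases[float(d)] = "early"
        elif d < 7.0:
            phases[float(d)] = "transition"
        else:
            phases[float(d)] = "late"
    return onset, phases


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def group_statistics(
    table: pd.DataFrame, condition: "str | None" = None
) -> GroupStats:
    """Per-(dimension, day) mean, population SD and CV, plus the pooled CV.

    ``table`` is a tidy measurement table (lesion_id, day, onl_um, rpe_um,
    height_um, pr_um).  Cells need at least two lesions; cells with zero
    mean are excluded from the pooled CV and reported in ``excluded``.
    The pooled CV is the unweighted arithmetic mean of the cell CVs.
    """
    rows = []
    excluded = []
    for dim, col in DIMENSION_COLUMNS.items():
        for day, sub in table.groupby("day"):
            vals = sub[col].to_numpy(dtype=float)
            if vals.size < 2:
                raise ValueError(
                    f"cell ({dim}, day {day}) has {vals.size} lesion(s); need >= 2"
                )
            mu = float(vals.mean())
            sigma = float(vals.std(ddof=0))
            if mu == 0.0:
                excluded.append((dim, float(day)))
                rows.append(dict(dimension=dim, day=float(day), mean=mu, std=sigma, cv=np.nan))
                continue
            rows.append(
                dict(dimension=dim, day=float(day), mean=mu, std=sigma, cv=sigma / mu)
            )
    cells = pd.DataFrame(rows)
    pooled = float(cells["cv"].dropna().mean())
    return GroupStats(cells=cells, pooled_cv=pooled, condition=condition, excluded=excluded)


def pooled_cv_from_reference(condition: str) -> float:
    """Pooled CV of the packaged reference table: mean of its 20 CV cells."""
    return float(reference_cvs(condition).to_numpy().mean())
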