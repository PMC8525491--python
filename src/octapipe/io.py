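"""Volume and table I/O.

Volumes travel as multipage TIFF (16-bit, one page per B-scan, fast axis =
page width) with a JSON sidecar carrying the voxel geometry, timepoint,
applied/estimated motion offsets, seed and the intensity scale used for
quantization.  Label/mask volumes use 8-bit multipage TIFF.  Measurement
tables are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .volume_core import OCTVolume, VolumeGeometry

__all__ = ["save_volume", "load_volume", "save_mask", "load_mask", "sidecar_path"]


def sidecar_path(tiff_path: "str | Path") -> Path:
    return Path(tiff_path).with_suffix(".json")


def save_volume(volume: OCTVolume, path: "str | Path") -> Path:
    """Write a volume as 16-bit multipage TIFF + JSON sidecar.

    Pages are B-scans (axial x fast); intensities are scaled to the full
    16-bit range and the scale is stored so loading round-trips to within
    quantization.
    """
    path = Path(path)
    vol = volume.intensities
    peak = float(vol.max())
    scale = 65535.0 / peak if peak > 0 else 1.0
    pages = np.clip(np.rint(vol * scale), 0, 65535).astype(np.uint16)
    # (axial, slow, fast) -> one page per B-scan
    tifffile.imwrite(path, np.moveaxis(pages, 1, 0), photometric="minisblack")
    geo = volume.geometry
    meta = {
        "dx_um": geo.dx_um,
        "dz_um": geo.dz_um,
        "n_fast": geo.n_fast,
        "n_slow": geo.n_slow,
        "n_axial": geo.n_axial,
        "intensity_scale": scale,
    }
    for key in ("timepoint_days", "seed", "scene_seed", "condition"):
        if key in volume.metadata:
            meta[key] = volume.metadata[key]
    for key in ("applied_offsets", "estimated_offsets"):
        if key in volume.metadata:
            meta[key] = np.asarray(volume.metadata[key]).tolist()
    sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def load_volume(path: "str | Path") -> OCTVolume:
    path = Path(path)
    pages = tifffile.imread(path)
    meta = json.loads(sidecar_path(path).read_text())
    vol = np.moveaxis(pages, 0, 1).astype(np.float32) / meta["intensity_scale"]
    geo = VolumeGeometry(
        n_fast=meta["n_fast"],
        n_slow=meta["n_slow"],
        n_axial=meta["n_axial"],
        dx_um=meta["dx_um"],
        dz_um=meta["dz_um"],
    )
    md = {
        k: v
        for k, v in meta.items()
        if k not in ("dx_um", "dz_um", "n_fast", "n_slow", "n_axial", "intensity_scale")
    }
    for key in ("applied_offsets", "estimated_offsets"):
        if key in md:
            md[key] = np.asarray(md[key], dtype=int)
    return OCTVolume(vol, geo, md)


def save_mask(mask: np.ndarray, path: "str | Path") -> Path:
    """Write a binary or label volume as 8-bit multipage TIFF."""
    path = Path(path)
    data = np.moveaxis(mask.astype(np.uint8), 1, 0)
    tifffile.imwrite(path, data, photometric="minisblack")
    return path


def load_mask(path: "str | Path") -> np.ndarray:
    return np.moveaxis(tifffile.imread(Path(path)), 0, 1)
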