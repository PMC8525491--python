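"""Published mean lesion dimensions and their coefficients of variation.

The packaged table gives, for each condition (acute photoreceptor injury
vs. laser-induced CNV) and imaging day (1, 3, 7, 14, 21), the group-mean
value of the four lesion dimensions measured on lesion-centered B-scans:

``onl``     lateral disruption width at the ONL/OPL boundary (um)
``rpe``     lateral RPE disruption width (um)
``height``  maximal vertical OPL-RPE disruption (um)
``pr``      widest ELM-IS/OS protrusion into the ONL (um)

together with the per-cell coefficient of variation (sigma/mu).  The
synthetic generator is calibrated so that, with dispersion off, generated
lesions reproduce these means exactly at the printed days and
piecewise-linearly in between.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

DIMENSIONS = ("onl", "rpe", "height", "pr")
REFERENCE_DAYS = (1.0, 3.0, 7.0, 14.0, 21.0)
CONDITIONS = ("acute", "cnv")

_cache: dict[str, pd.DataFrame] = {}


def load_reference_dimensions() -> pd.DataFrame:
    """Return the packaged reference table (tidy long format).

    Columns: ``condition, day, dimension, mean_um, cv``.
    """
    if "table" not in _cache:
        with resources.files("octapipe.data").joinpath("lesion_reference.csv").open() as fh:
            df = pd.read_csv(fh)
        _cache["table"] = df
    return _cache["table"].copy()


def _pivot(condition: str, value: str) -> pd.DataFrame:
    df = load_reference_dimensions()
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    sub = df[df.condition == condition]
    wide = sub.pivot(index="day", columns="dimension", values=value)
    return wide[list(DIMENSIONS)].sort_index()


def reference_means(condition: str) -> pd.DataFrame:
    """Mean dimensions (um), indexed by day, columns onl/rpe/height/pr."""
    return _pivot(condition, "mean_um")


def reference_cvs(condition: str) -> pd.DataFrame:
    """Coefficients of variation, indexed by day, same layout as means."""
    return _pivot(condition, "cv")


def interp_table(table: pd.DataFrame, days: np.ndarray) -> np.ndarray:
    """Piecewise-linear interpolation of a day-indexed table.

    Days before the first / after the last printed day clamp to the
    endpoint values.  Returns an array of shape ``(len(days), 4)``.
    """
    days = np.atleast_1d(np.asarray(days, dtype=float))
    ref_days = table.index.to_numpy(dtype=float)
    out = np.empty((days.size, table.shape[1]))
    for j, col in enumerate(table.columns):
        out[:, j] = np.interp(days, ref_days, table[col].to_numpy(dtype=float))
    return out
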