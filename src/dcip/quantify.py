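"""Per-nucleus intensity extraction from per-object maximum-intensity
projections, and the width-3 profile smoother used for line-profile plots.

For each labelled object the projection is restricted to the object's own
voxels: every (y, x) column takes the maximum over that object's z-extent,
per channel, with masked sfGFP voxels excluded from the maximum.  The
object's mean red/green intensities are means over the projected 2-D
footprint, and the green/red ratio is their quotient — the per-nucleus
readout of delivered complementation, invariant to common rescaling of both
channels.  A whole-column projection mode (maximum over the full z range of
the stack) is available behind ``whole_column=True``.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from dcip.io_formats import ROLE_MCHERRY, ROLE_SFGFP, ChannelStack
from dcip.segmentation import LabelVolume

logger = logging.getLogger(__name__)

#: Core per-nucleus measurement columns (provenance columns are added by the
#: caller; see io_formats.MEASUREMENT_COLUMNS for the full table contract).
RECORD_COLUMNS = (
    "stack_id",
    "label",
    "footprint_area",
    "mean_red",
    "mean_green",
    "green_red_ratio",
    "valid",
)


def measure_nuclei(
    labels: LabelVolume | np.ndarray,
    stack: ChannelStack,
    mask: np.ndarray | None = None,
    whole_column: bool = False,
    stack_id: str = "stack",
) -> pd.DataFrame:
    """Measure every labelled nucleus; returns one row per object.

    Records with a zero-unmasked-sfGFP footprint or non-positive mean red are
    flagged ``valid=False`` (their ratio is NaN) and must be excluded from
    scoring.  Zero objects yield an empty table, not an error.
    """
    lab = labels.labels if isinstance(labels, LabelVolume) else np.asarray(labels)
    if lab.shape != stack.shape:
        raise ValueError(f"label shape {lab.shape} does not match stack shape {stack.shape}")
    red = stack.channel(ROLE_MCHERRY).astype(np.float64)
    green = stack.channel(ROLE_SFGFP).astype(np.float64)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != stack.shape:
            raise ValueError(f"mask shape {mask.shape} does not match stack shape {stack.shape}")
        green = np.where(mask, np.nan, green)

    rows = []
    n_max = int(lab.max()) if lab.size else 0
    objects = ndimage.find_objects(lab) if n_max else []
    for i, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        obj = lab[sl] == i
        footprint = obj.any(axis=0)
        area = int(footprint.sum())
        if whole_column:
            # maximum over the full z range of every footprint column
            red_cols = red[:, sl[1], sl[2]]
            green_cols = green[:, sl[1], sl[2]]
            red_mip = red_cols.max(axis=0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                green_mip = np.nanmax(green_cols, axis=0)
        else:
            red_mip = np.where(obj, red[sl], -np.inf).max(axis=0)
            gvol = np.where(obj, green[sl], np.nan)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                green_mip = np.nanmax(gvol, axis=0)

        mean_red = float(red_mip[footprint].mean()) if area else np.nan
        gvals = green_mip[footprint]
        gvals = gvals[np.isfinite(gvals)]
        n_green = gvals.size
        mean_green = float(gvals.mean()) if n_green else np.nan
        valid = bool(area > 0 and n_green > 0 and mean_red > 0)
        ratio = mean_green / mean_red if valid else np.nan
        if not valid:
            logger.info(
                "object %d in %s flagged invalid (area=%d, unmasked green pixels=%d)",
                i, stack_id, area, n_green,
            )
        rows.append((stack_id, i, area, mean_red, mean_green, ratio, valid))

    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    logger.info("measured %d nuclei in %s (%d valid)", len(df), stack_id, int(df["valid"].sum()) if len(df) else 0)
    return df


def smooth_profile(series: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered moving-mean smoothing, then normalization to the maximum.

    Edges use a shrink-to-valid window (the first/last points average the
    available 2 values at ``window=3``).  The smoothed series is divided by
    its maximum so the peak equals 1; an all-zero input returns all zeros
    with a warning instead of dividing.
    """
    arr = np.asarray(series, dtype=np.float64)
    if arr.ndim != 1:
        raise ValueError("profile must be 1-D")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if arr.size < window:
        raise ValueError(f"series length {arr.size} is shorter than window {window}")
    smoothed = (
        pd.Series(arr).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )
    peak = smoothed.max()
    if peak <= 0:
        warnings.warn("profile has no positive signal; returning zeros", UserWarning, stacklevel=2)
        return np.zeros_like(smoothed)
    return smoothed / peak
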