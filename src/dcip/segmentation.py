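"""Object detection: slice-wise Otsu segmentation of mCherry nuclei,
chloroplast segmentation in the autofluorescence channel, and the sfGFP
exclusion mask.

Nuclei are thresholded slice by slice (each z-slice rescaled to a B-bin
histogram, Otsu's between-class-variance criterion applied), the binary
slices stacked, and 3-D connected components labelled so each nucleus is one
object.  No declumping is performed: nuclei touching in 3-D merge into a
single object, which is logged.  Masked sfGFP voxels are treated as missing
downstream, never zero-filled (zero-filling would corrupt per-object maxima).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from dcip.io_formats import ROLE_AUTOFLUOR, ROLE_MCHERRY, ROLE_SFGFP, ChannelStack

logger = logging.getLogger(__name__)


class DegenerateHistogramWarning(UserWarning):
    """All histogram mass sits in a single bin; no two-class split exists."""


@dataclass
class SegmentationParams:
    """Tunable knobs of nucleus/chloroplast segmentation.

    ``threshold_floor``: absolute lower bound applied to every per-slice Otsu
    threshold.  ``"auto"`` (default) uses ``floor_factor`` x the global Otsu
    threshold of the whole channel, which keeps slices containing only
    detector noise from producing spurious foreground; ``None`` disables the
    floor.
    """

    n_bins: int = 256
    connectivity: int = 26  # 6 or 26
    min_voxels: int = 20
    max_voxels: int | None = None
    threshold_floor: float | str | None = "auto"
    floor_factor: float = 0.5
    chloro_dilation: int = 1
    link_z: bool = True

    def __post_init__(self) -> None:
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.min_voxels < 0:
            raise ValueError("min_voxels must be >= 0")


@dataclass
class LabelVolume:
    """Integer object labels over a voxel grid; 0 is background."""

    labels: np.ndarray
    n_objects: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label volume must be 3-D (z, y, x)")


def otsu_threshold(histogram: np.ndarray) -> int:
    """Otsu's threshold on a histogram of counts: the bin index ``t`` that
    maximizes the between-class variance of the split {bins <= t} vs
    {bins > t}.

    Returns the first maximizing cut point (deterministic).  If all mass sits
    in one bin no split exists; the index of that bin is returned with a
    :class:`DegenerateHistogramWarning` (thresholding with ``> t`` then yields
    an empty foreground).
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.ndim != 1 or hist.size < 2:
        raise ValueError("histogram must be 1-D with at least 2 bins")
    if (hist < 0).any():
        raise ValueError("histogram counts must be non-negative")
    total = hist.sum()
    if total <= 0:
        raise ValueError("histogram must contain positive total count")
    nonzero = np.flatnonzero(hist)
    if nonzero.size == 1:
        warnings.warn(
            "degenerate histogram: all mass in one bin; no two-class split",
            DegenerateHistogramWarning,
            stacklevel=2,
        )
        return int(nonzero[0])

    bins = np.arange(hist.size, dtype=np.float64)
    w0 = np.cumsum(hist)[:-1]  # class {<= t} mass for t = 0..B-2
    w1 = total - w0
    cum = np.cumsum(hist * bins)[:-1]
    grand = float(np.sum(hist * bins))
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = np.where(w0 > 0, cum / w0, 0.0)
        m1 = np.where(w1 > 0, (grand - cum) / w1, 0.0)
        bcv = w0 * w1 * (m0 - m1) ** 2
    bcv[(w0 == 0) | (w1 == 0)] = -np.inf
    return int(np.argmax(bcv))


def _slice_threshold(img: np.ndarray, n_bins: int) -> float | None:
    """Otsu threshold value for one slice; None if the slice is constant."""
    lo = float(img.min())
    hi = float(img.max())
    if hi <= lo:
        return None
    hist, edges = np.histogram(img, bins=n_bins, range=(lo, hi))
    t = otsu_threshold(hist)
    # Foreground = bins above t, i.e. values >= the upper edge of bin t.
    return float(edges[t + 1])


def _global_floor(channel: np.ndarray, params: SegmentationParams) -> float | None:
    if params.threshold_floor is None:
        return None
    if params.threshold_floor != "auto":
        return float(params.threshold_floor)
    thr = _slice_threshold(channel, params.n_bins)
    if thr is None:
        return None
    return params.floor_factor * thr


def _binarize_slices(channel: np.ndarray, params: SegmentationParams) -> np.ndarray:
    floor = _global_floor(channel, params)
    binary = np.zeros(channel.shape, dtype=bool)
    for z in range(channel.shape[0]):
        thr = _slice_threshold(channel[z], params.n_bins)
        if thr is None:
            continue  # constant slice: empty foreground
        if floor is not None:
            thr = max(thr, floor)
        binary[z] = channel[z] >= thr
    return binary


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    return ndimage.generate_binary_structure(3, 1)


def segment_nuclei(stack: ChannelStack, params: SegmentationParams | None = None) -> LabelVolume:
    """Segment mCherry-bright nuclei.

    Per z-slice Otsu thresholding on the mCherry channel, 3-D connected
    components (``params.connectivity``), then a voxel-count size filter
    ``[min_voxels, max_voxels]``.  Surviving objects are relabelled 1..n in
    deterministic raster-scan order.  Empty foreground yields a valid result
    with ``n_objects == 0``.
    """
    params = params or SegmentationParams()
    stack.require_roles(ROLE_MCHERRY)
    red = stack.channel(ROLE_MCHERRY).astype(np.float64)
    binary = _binarize_slices(red, params)

    if params.link_z:
        labels, n = ndimage.label(binary, structure=_structure(params.connectivity))
    else:
        # per-slice 2-D objects, labels offset per slice (fidelity mode)
        struct2d = np.ones((3, 3), dtype=bool) if params.connectivity == 26 else ndimage.generate_binary_structure(2, 1)
        labels = np.zeros(binary.shape, dtype=np.int32)
        n = 0
        for z in range(binary.shape[0]):
            lab2d, k = ndimage.label(binary[z], structure=struct2d)
            labels[z] = np.where(lab2d > 0, lab2d + n, 0)
            n += k

    labels, n_kept = _size_filter(labels, n, params.min_voxels, params.max_voxels)
    if n_kept < n:
        logger.info("size filter removed %d of %d components", n - n_kept, n)
    logger.info(
        "segmented nuclei: %d objects (connectivity=%d, min_voxels=%d)",
        n_kept, params.connectivity, params.min_voxels,
    )
    return LabelVolume(
        labels=labels,
        n_objects=n_kept,
        provenance={
            "channel": ROLE_MCHERRY,
            "n_bins": params.n_bins,
            "connectivity": params.connectivity,
            "min_voxels": params.min_voxels,
            "max_voxels": params.max_voxels,
            "link_z": params.link_z,
        },
    )


def _size_filter(labels: np.ndarray, n: int, min_voxels: int, max_voxels: int | None):
    """Drop components outside [min_voxels, max_voxels]; relabel survivors
    1..k in order of first raster-scan occurrence."""
    if n == 0:
        return labels.astype(np.int32), 0
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    keep = counts >= min_voxels
    if max_voxels is not None:
        keep &= counts <= max_voxels
    keep[0] = False
    old = np.flatnonzero(keep)
    # scipy assigns labels in raster-scan order of first encounter, so
    # ascending old labels already follow scan order.
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[old] = np.arange(1, old.size + 1, dtype=np.int32)
    return remap[labels], int(old.size)


def segment_chloroplasts(
    stack: ChannelStack, params: SegmentationParams | None = None
) -> np.ndarray:
    """Build the sfGFP exclusion mask from the autofluorescence channel.

    Slice-wise Otsu thresholding, then morphological dilation by
    ``params.chloro_dilation`` voxels (full 26-neighbourhood) to cover
    bleed-through halos.  If the stack has no autofluorescence channel the
    mask is all-false and a warning is emitted (masking disabled).
    """
    params = params or SegmentationParams()
    if not stack.has_role(ROLE_AUTOFLUOR):
        warnings.warn(
            "stack has no autofluorescence channel; chloroplast masking disabled",
            UserWarning,
            stacklevel=2,
        )
        return np.zeros(stack.shape, dtype=bool)
    auto = stack.channel(ROLE_AUTOFLUOR).astype(np.float64)
    mask = _binarize_slices(auto, params)
    if params.chloro_dilation > 0 and mask.any():
        mask = ndimage.binary_dilation(
            mask, structure=np.ones((3, 3, 3), dtype=bool), iterations=params.chloro_dilation
        )
    logger.info("chloroplast exclusion mask covers %d voxels", int(mask.sum()))
    return mask


def apply_exclusion(stack: ChannelStack, mask: np.ndarray) -> np.ndarray:
    """Return the sfGFP channel with masked voxels flagged missing (NaN).

    Downstream statistics must ignore NaNs rather than treat them as zero;
    zero-filling would bias per-object maxima and means.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match stack shape {stack.shape}"
        )
    green = stack.channel(ROLE_SFGFP).astype(np.float64).copy()
    green[mask] = np.nan
    return green
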