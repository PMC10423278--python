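"""Synthetic confocal z-stacks and qPCR plates with known ground truth.

The generator emulates the quantification conditions of a split-GFP
complementation delivery assay in leaf tissue: mCherry-bright nuclear
ellipsoids scattered through a ~100 um z-extent, a subset of nuclei carrying
colocalized sfGFP from complementation (green intensity = true ratio x red
intensity), chloroplasts fluorescing in a far-red autofluorescence channel
with partial bleed-through into the sfGFP channel, anisotropic Gaussian
optical blur, and Poisson-Gaussian detector noise.  Every stack is returned
together with its :class:`GroundTruth` so downstream segmentation, ratio
measurement and positivity scoring can be validated against known answers.

Reproducibility: one master seed; titration datasets derive an independent
substream per (concentration index, field-of-view index) so any single stack
can be regenerated in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from dcip.io_formats import (
    ROLE_AUTOFLUOR,
    ROLE_MCHERRY,
    ROLE_SFGFP,
    ChannelStack,
)

logger = logging.getLogger(__name__)

#: Emission bands (nm) of the acquisition the simulator emulates; stored as
#: labels only, no spectral model is simulated.
EMISSION_BANDS_NM = {
    "BFP": (410, 529),
    "sfGFP": (493, 550),
    "mCherry": (578, 645),
    "autofluorescence": (652, 728),
}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic leaf z-stack.

    Units: ``voxel_size``, radii and ``min_separation`` are micrometers;
    ``psf_sigma`` is in voxels; intensities are arbitrary detector units.
    """

    volume_shape: tuple[int, int, int] = (32, 256, 256)
    voxel_size: tuple[float, float, float] = (3.0, 0.5, 0.5)
    n_nuclei: int = 60
    nucleus_radii: tuple[float, float] = (2.0, 4.0)
    #: log-normal (mu, sigma) of per-nucleus mCherry brightness.
    red_intensity: tuple[float, float] = (8.0, 0.3)
    positive_fraction: float = 0.5
    #: (mean, sd) of the true green/red ratio of delivered nuclei.
    ratio_positive: tuple[float, float] = (0.8, 0.15)
    #: (mean, sd) of the true green/red ratio of untouched nuclei.
    ratio_negative: tuple[float, float] = (0.05, 0.02)
    n_chloroplasts: int = 120
    chloro_intensity: float = 4000.0
    chloro_radii: tuple[float, float] = (0.8, 1.6)
    #: fraction of chloroplast signal added into the sfGFP channel.
    gfp_bleed: float = 0.08
    psf_sigma: tuple[float, float, float] = (1.0, 0.8, 0.8)
    #: photon gain of the Poisson shot-noise model; ``None`` disables it.
    poisson_gain: float | None = 2.0
    read_noise_sd: float = 5.0
    #: output quantization; ``None`` keeps unquantized float64.
    bit_depth: int | None = 16
    #: optional minimum center-to-center nucleus distance (um).
    min_separation: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must be in [0, 1]")
        if not 0.0 <= self.gfp_bleed <= 1.0:
            raise ValueError("gfp_bleed must be in [0, 1]")
        if self.n_nuclei < 0 or self.n_chloroplasts < 0:
            raise ValueError("object counts must be >= 0")
        if self.nucleus_radii[0] > self.nucleus_radii[1]:
            raise ValueError("nucleus_radii must be (min, max) with min <= max")
        if self.chloro_radii[0] > self.chloro_radii[1]:
            raise ValueError("chloro_radii must be (min, max) with min <= max")
        if any(s < 0 for s in self.psf_sigma):
            raise ValueError("psf_sigma must be >= 0")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")
        if self.poisson_gain is not None and self.poisson_gain <= 0:
            raise ValueError("poisson_gain must be positive (or None to disable)")
        if any(n <= 0 for n in self.volume_shape):
            raise ValueError("volume_shape must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")


@dataclass
class GroundTruth:
    """Per-nucleus truth plus rendered truth masks for one simulated stack.

    ``nuclei`` has one row per nucleus: voxel-coordinate center, radius (um),
    assigned true green/red ratio and the delivered flag.  ``label_volume``
    holds truth labels (1..n, later nuclei overwrite earlier ones where
    overlapping); ``chloroplast_mask`` marks true chloroplast voxels.
    """

    nuclei: pd.DataFrame
    positive_fraction: float
    label_volume: np.ndarray | None = None
    chloroplast_mask: np.ndarray | None = None

    @property
    def n_nuclei(self) -> int:
        return len(self.nuclei)

    @property
    def n_positive(self) -> int:
        return int(self.nuclei["is_positive"].sum()) if len(self.nuclei) else 0


TRUTH_COLUMNS = (
    "center_z",
    "center_y",
    "center_x",
    "radius_um",
    "true_ratio",
    "is_positive",
)


def _ellipsoid_mask(shape, center, semi_axes_vox):
    """Boolean mask of an axis-aligned ellipsoid, plus its bounding slices."""
    lo = [max(0, int(np.floor(c - a))) for c, a in zip(center, semi_axes_vox)]
    hi = [min(s, int(np.ceil(c + a)) + 1) for s, c, a in zip(shape, center, semi_axes_vox)]
    if any(l >= h for l, h in zip(lo, hi)):
        return None, None
    grids = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    d2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes_vox))
    return tuple(slice(l, h) for l, h in zip(lo, hi)), d2 <= 1.0


def _truncated_normal(rng, mean, sd, size):
    vals = rng.normal(mean, sd, size=size)
    return np.clip(vals, 0.0, None)


def generate_leaf_stack(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[ChannelStack, GroundTruth]:
    """Render one three-channel leaf stack and its ground truth.

    Exactly ``round(positive_fraction * n_nuclei)`` nuclei are delivered
    (drawn at random), so the realized positive fraction equals the parameter
    up to rounding.  Raises ``ValueError`` if the volume cannot contain the
    largest requested nucleus.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    shape = tuple(int(s) for s in config.volume_shape)
    vz, vy, vx = config.voxel_size
    extent = (shape[0] * vz, shape[1] * vy, shape[2] * vx)
    r_max = config.nucleus_radii[1]
    if config.n_nuclei > 0 and any(e <= 2 * r_max for e in extent):
        raise ValueError(
            f"volume extent {extent} um is too small for nuclei of radius {r_max} um"
        )

    red = np.zeros(shape, dtype=np.float64)
    green = np.zeros(shape, dtype=np.float64)
    auto = np.zeros(shape, dtype=np.float64)
    truth_labels = np.zeros(shape, dtype=np.int32)

    n = config.n_nuclei
    radii = rng.uniform(*config.nucleus_radii, size=n)
    intensities = rng.lognormal(*config.red_intensity, size=n)
    n_pos = int(round(config.positive_fraction * n))
    is_positive = np.zeros(n, dtype=bool)
    if n:
        is_positive[rng.permutation(n)[:n_pos]] = True
    ratios = np.where(
        is_positive,
        _truncated_normal(rng, *config.ratio_positive, n),
        _truncated_normal(rng, *config.ratio_negative, n),
    )

    centers = np.empty((n, 3), dtype=np.float64)
    voxel = np.array([vz, vy, vx])
    for i in range(n):
        margin = radii[i] / voxel  # keep the whole ellipsoid inside the volume
        lo = margin
        hi = np.array(shape) - 1 - margin
        for attempt in range(10_000):
            c = rng.uniform(lo, hi)
            if config.min_separation is None or i == 0:
                break
            d_um = (centers[:i] - c) * voxel
            if (np.sum(d_um**2, axis=1) >= config.min_separation**2).all():
                break
        else:
            raise ValueError(
                "could not place nuclei with the requested min_separation; "
                "volume too crowded"
            )
        centers[i] = c
        sl, mask = _ellipsoid_mask(shape, c, radii[i] / voxel)
        if sl is None:
            continue
        red[sl][mask] += intensities[i]
        green[sl][mask] += ratios[i] * intensities[i]
        truth_labels[sl][mask] = i + 1

    chloro_mask = np.zeros(shape, dtype=bool)
    for _ in range(config.n_chloroplasts):
        r = rng.uniform(*config.chloro_radii)
        margin = r / voxel
        c = rng.uniform(margin, np.array(shape) - 1 - margin)
        sl, mask = _ellipsoid_mask(shape, c, r / voxel)
        if sl is None:
            continue
        auto[sl][mask] += config.chloro_intensity
        green[sl][mask] += config.gfp_bleed * config.chloro_intensity
        chloro_mask[sl][mask] = True

    channels = [red, green, auto]
    if any(s > 0 for s in config.psf_sigma):
        channels = [ndimage.gaussian_filter(ch, sigma=config.psf_sigma) for ch in channels]
    if config.poisson_gain is not None:
        g = config.poisson_gain
        channels = [rng.poisson(ch / g).astype(np.float64) * g for ch in channels]
    if config.read_noise_sd > 0:
        channels = [ch + rng.normal(0.0, config.read_noise_sd, size=shape) for ch in channels]

    data = np.stack(channels, axis=-1)
    if config.bit_depth is not None:
        vmax = 2 ** int(config.bit_depth) - 1
        data = np.clip(np.rint(data), 0, vmax).astype(np.uint16 if config.bit_depth <= 16 else np.uint32)
    else:
        data = np.clip(data, 0.0, None)

    stack = ChannelStack(
        intensities=data,
        channel_roles={ROLE_MCHERRY: 0, ROLE_SFGFP: 1, ROLE_AUTOFLUOR: 2},
        voxel_size=config.voxel_size,
        bit_depth=config.bit_depth,
    )
    nuclei = pd.DataFrame(
        {
            "center_z": centers[:, 0] if n else np.array([]),
            "center_y": centers[:, 1] if n else np.array([]),
            "center_x": centers[:, 2] if n else np.array([]),
            "radius_um": radii,
            "true_ratio": ratios,
            "is_positive": is_positive,
        }
    )
    truth = GroundTruth(
        nuclei=nuclei,
        positive_fraction=(n_pos / n) if n else 0.0,
        label_volume=truth_labels,
        chloroplast_mask=chloro_mask,
    )
    logger.info(
        "simulated stack: %d nuclei (%d delivered), %d chloroplasts, shape=%s",
        n, n_pos, config.n_chloroplasts, shape,
    )
    return stack, truth


def logistic_fraction(concentration: float, fmax: float, ec50: float, hill: float) -> float:
    """Hill-logistic true delivered fraction: fmax * c^h / (c^h + EC50^h)."""
    if ec50 <= 0:
        raise ValueError("EC50 must be positive")
    if not 0.0 <= fmax <= 1.0:
        raise ValueError("fmax must be in [0, 1]")
    if hill <= 0:
        raise ValueError("hill coefficient must be positive")
    c = float(concentration)
    if c < 0:
        raise ValueError("concentrations must be >= 0")
    if c == 0:
        return 0.0
    return fmax * c**hill / (c**hill + ec50**hill)


@dataclass
class TitrationPoint:
    """One simulated field of view at one cargo concentration."""

    concentration: float
    fov: int
    true_fraction: float
    stack: ChannelStack
    truth: GroundTruth


def generate_titration(
    config: SimulationConfig,
    concentrations: list[float],
    fmax: float = 0.8,
    ec50: float = 80.0,
    hill: float = 1.5,
    n_fov: int = 4,
) -> list[TitrationPoint]:
    """Simulate a concentration titration with logistic true delivery.

    Each (concentration, FOV) pair gets an independent RNG substream keyed by
    ``[master seed, concentration index, fov index]``, so the dataset is
    reproducible piecewise.
    """
    points: list[TitrationPoint] = []
    for ci, conc in enumerate(concentrations):
        f = logistic_fraction(conc, fmax, ec50, hill)
        cfg = dataclasses.replace(config, positive_fraction=f)
        for fov in range(n_fov):
            rng = np.random.default_rng([config.seed % 2**31, ci, fov])
            stack, truth = generate_leaf_stack(cfg, rng=rng)
            points.append(TitrationPoint(float(conc), fov, f, stack, truth))
    return points


def generate_qpcr_plate(
    genes: list[str],
    true_fold_changes: dict[str, float],
    reference_gene: str,
    ct_base: float = 22.0,
    ct_noise_sd: float = 0.2,
    n_replicates: int = 4,
    n_technical: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a two-group qPCR plate (``control`` vs ``treated``).

    Each gene's treated Ct is shifted by ``-log2(fold)`` relative to control
    while the reference gene is unchanged, so the expected ddCt of gene g is
    ``-log2(fold_g)`` and the expected recovered fold change is ``fold_g``.
    Gaussian noise with sd ``ct_noise_sd`` is added to every technical
    replicate Ct.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    genes = list(genes)
    if reference_gene not in genes:
        genes = [reference_gene] + genes
    folds = dict(true_fold_changes)
    ref_fold = folds.setdefault(reference_gene, 1.0)
    if ref_fold != 1.0:
        raise ValueError("the reference gene has fold change 1 by definition")
    for g in genes:
        if g not in folds:
            raise ValueError(f"no true fold change given for gene {g!r}")
        if folds[g] <= 0:
            raise ValueError(f"fold change for {g!r} must be positive")

    rng = np.random.default_rng(seed)
    # A stable per-gene baseline Ct keeps genes distinguishable on the plate.
    gene_base = {g: ct_base + rng.uniform(-2.0, 2.0) for g in genes}
    rows = []
    for group in ("control", "treated"):
        for rep in range(1, n_replicates + 1):
            sample = f"{group}_{rep}"
            for g in genes:
                mean_ct = gene_base[g]
                if group == "treated":
                    mean_ct = mean_ct - np.log2(folds[g])
                for tech in range(1, n_technical + 1):
                    ct = mean_ct + (rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0)
                    rows.append((sample, group, g, ct, tech))
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "ct", "tech_rep"])


def write_truth(truth: GroundTruth, csv_path: str | Path, json_path: str | Path | None = None) -> None:
    """Write per-nucleus truth as CSV plus a JSON sidecar of global values."""
    truth.nuclei.to_csv(Path(csv_path), index=False, float_format="%.17g")
    if json_path is not None:
        Path(json_path).write_text(
            json.dumps(
                {
                    "n_nuclei": truth.n_nuclei,
                    "n_positive": truth.n_positive,
                    "positive_fraction": truth.positive_fraction,
                },
                indent=2,
                sort_keys=True,
            )
        )
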