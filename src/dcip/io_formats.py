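"""On-disk formats for the pipeline: multichannel TIFF stacks, label volumes,
measurement CSVs, Ct tables, and YAML/JSON configs.

Conventions (part of the public contract):

* voxel indices are 0-based and ordered ``(z, y, x)`` everywhere; stacks carry
  an extra trailing channel axis, ``(z, y, x, channel)``;
* channel roles are named ``mCherry``, ``sfGFP``, ``autofluorescence`` and
  optionally ``BFP``; ``mCherry`` and ``sfGFP`` are mandatory for
  quantification;
* CSVs are comma-separated UTF-8 with ``.`` decimal; floats are serialized
  with 17 significant digits so round trips are exact.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger(__name__)

ROLE_MCHERRY = "mCherry"
ROLE_SFGFP = "sfGFP"
ROLE_AUTOFLUOR = "autofluorescence"
ROLE_BFP = "BFP"
MANDATORY_ROLES = (ROLE_MCHERRY, ROLE_SFGFP)
KNOWN_ROLES = (ROLE_MCHERRY, ROLE_SFGFP, ROLE_AUTOFLUOR, ROLE_BFP)

#: Column contract for per-nucleus measurement tables.
MEASUREMENT_COLUMNS = (
    "stack_id",
    "treatment",
    "plant",
    "fov",
    "label",
    "footprint_area",
    "mean_red",
    "mean_green",
    "green_red_ratio",
    "valid",
)

#: Column contract for qPCR Ct tables.
CT_COLUMNS = ("sample", "group", "gene", "ct", "tech_rep")


class FormatError(ValueError):
    """A file does not match its declared layout (page counts, shapes...)."""


class SchemaError(ValueError):
    """A table is missing mandatory columns or violates uniqueness."""


@dataclass
class ChannelStack:
    """A ``(z, y, x, channel)`` intensity volume with channel-role metadata.

    Parameters
    ----------
    intensities
        Non-negative 4-D array.
    channel_roles
        Mapping from role name to channel index.  ``mCherry`` and ``sfGFP``
        must be present for quantification.
    voxel_size
        Physical voxel extent ``(z, y, x)`` in micrometers.
    bit_depth
        Quantization of the stored intensities; ``None`` means unquantized
        floating point (used by the simulator's noise-free mode).
    """

    intensities: np.ndarray
    channel_roles: dict[str, int]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    bit_depth: int | None = 16

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 4:
            raise FormatError(
                f"stack must be 4-D (z, y, x, channel), got shape {self.intensities.shape}"
            )
        n_channels = self.intensities.shape[3]
        for role, idx in self.channel_roles.items():
            if not 0 <= int(idx) < n_channels:
                raise FormatError(
                    f"role {role!r} maps to channel {idx}, but stack has {n_channels} channels"
                )
        if self.intensities.size and self.intensities.min() < 0:
            raise FormatError("stack intensities must be non-negative")
        if self.bit_depth is not None and self.intensities.size:
            if self.intensities.max() >= 2 ** int(self.bit_depth):
                raise FormatError(
                    f"intensities exceed declared {self.bit_depth}-bit range"
                )
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        """Spatial shape ``(z, y, x)``."""
        return self.intensities.shape[:3]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[3]

    def has_role(self, role: str) -> bool:
        return role in self.channel_roles

    def channel(self, role: str) -> np.ndarray:
        """Return the 3-D ``(z, y, x)`` view for a named channel role."""
        if role not in self.channel_roles:
            raise KeyError(f"stack has no channel with role {role!r}")
        return self.intensities[..., self.channel_roles[role]]

    def require_roles(self, *roles: str) -> None:
        missing = [r for r in roles if r not in self.channel_roles]
        if missing:
            raise FormatError(f"stack is missing mandatory channel roles: {missing}")


def _sidecar_path(path: Path) -> Path:
    return Path(str(path) + ".json")


def write_stack(stack: ChannelStack, path: str | Path, interleave: str = "zc") -> Path:
    """Write a stack as a multipage TIFF plus a JSON metadata sidecar.

    ``interleave`` declares the on-disk page order: ``"zc"`` stores all
    channels of slice 0, then slice 1, ... (channel-fastest); ``"cz"`` stores
    all slices of channel 0, then channel 1, ... (z-fastest).
    """
    path = Path(path)
    if interleave not in ("zc", "cz"):
        raise ValueError(f"unknown interleave dialect {interleave!r}")
    n_z, n_y, n_x, n_c = stack.intensities.shape
    if interleave == "zc":
        pages = np.ascontiguousarray(stack.intensities.transpose(0, 3, 1, 2))
    else:
        pages = np.ascontiguousarray(stack.intensities.transpose(3, 0, 1, 2))
    tifffile.imwrite(path, pages.reshape(n_z * n_c, n_y, n_x))
    meta = {
        "channel_roles": {k: int(v) for k, v in stack.channel_roles.items()},
        "voxel_size": list(stack.voxel_size),
        "bit_depth": stack.bit_depth,
        "interleave": interleave,
        "n_z": int(n_z),
        "n_channels": int(n_c),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    logger.info("wrote stack %s: shape=%s interleave=%s", path, stack.intensities.shape, interleave)
    return path


def read_stack(
    path: str | Path,
    channel_map: dict[str, int] | None = None,
    interleave: str | None = None,
    voxel_size: tuple[float, float, float] | None = None,
    bit_depth: int | None = None,
) -> ChannelStack:
    """Read a multipage TIFF into the canonical ``(z, y, x, channel)`` order.

    Metadata defaults come from the JSON sidecar written by :func:`write_stack`;
    explicit arguments override it.  The page count must be divisible by the
    declared channel count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    roles = channel_map if channel_map is not None else meta.get("channel_roles")
    if roles is None:
        raise FormatError(f"no channel map given and no sidecar metadata for {path}")
    for role in roles:
        if role not in KNOWN_ROLES:
            raise FormatError(f"unknown channel role {role!r}; expected one of {KNOWN_ROLES}")
    interleave = interleave if interleave is not None else meta.get("interleave", "zc")
    if interleave not in ("zc", "cz"):
        raise FormatError(f"unknown interleave dialect {interleave!r}")
    voxel_size = voxel_size if voxel_size is not None else tuple(meta.get("voxel_size", (1.0, 1.0, 1.0)))
    if bit_depth is None:
        bit_depth = meta.get("bit_depth", None)

    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    n_pages, n_y, n_x = pages.shape
    n_c = len(roles)
    if n_pages % n_c != 0:
        raise FormatError(
            f"{path}: page count {n_pages} is not divisible by declared "
            f"channel count {n_c}"
        )
    n_z = n_pages // n_c
    if interleave == "zc":
        data = pages.reshape(n_z, n_c, n_y, n_x).transpose(0, 2, 3, 1)
    else:
        data = pages.reshape(n_c, n_z, n_y, n_x).transpose(1, 2, 3, 0)
    return ChannelStack(
        intensities=np.ascontiguousarray(data),
        channel_roles={k: int(v) for k, v in roles.items()},
        voxel_size=voxel_size,
        bit_depth=bit_depth,
    )


def write_labels(labels: np.ndarray, path: str | Path) -> Path:
    """Write an integer label volume (or boolean mask) as a multipage TIFF."""
    path = Path(path)
    arr = np.asarray(labels)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    else:
        arr = arr.astype(np.int32)
    tifffile.imwrite(path, arr)
    return path


def read_labels(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(Path(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def write_measurements(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a per-nucleus measurement table with the documented header.

    Floats are serialized with 17 significant digits so that ratios round-trip
    exactly through :func:`read_measurements`.
    """
    _validate_measurements(table)
    path = Path(path)
    table.to_csv(path, index=False, float_format="%.17g")
    logger.info("wrote %d measurement rows to %s", len(table), path)
    return path


def read_measurements(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), float_precision="round_trip")
    _validate_measurements(df)
    if len(df):
        df["valid"] = df["valid"].astype(bool)
    return df


def _validate_measurements(df: pd.DataFrame) -> None:
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"measurement table is missing mandatory columns: {missing}")
    if len(df):
        if df.duplicated(subset=["stack_id", "label"]).any():
            raise SchemaError("(stack_id, label) pairs must be unique")
        if df["treatment"].isna().any():
            raise SchemaError("treatment labels must not be missing")


def write_ct_table(table: pd.DataFrame, path: str | Path) -> Path:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"Ct table is missing mandatory columns: {missing}")
    path = Path(path)
    table.to_csv(path, index=False, float_format="%.17g")
    return path


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), float_precision="round_trip")
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"Ct table is missing mandatory columns: {missing}")
    if not np.isfinite(df["ct"]).all():
        raise SchemaError("Ct values must be finite")
    return df


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON; JSON is a YAML subset) config file into a dict."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"config {path} must contain a mapping at top level")
    return cfg


def configure_logging(level: str | int = "INFO") -> None:
    logging.basicConfig(
        level=level,
        format="%(levelname)s %(name)s: %(message)s",
    )
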