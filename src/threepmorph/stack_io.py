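"""Image-stack and mask I/O, voxel-spacing metadata, tabular export, configuration.

All volumes are indexed ``(z, y, x)`` with z index 0 the shallowest plane.
Voxel coordinates are 0-based and voxel-centered: the physical position of
voxel ``(k, j, i)`` is ``(i*dx, j*dy, k*dz)`` in micrometres, and every
physical distance downstream is an index difference times the spacing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("threepmorph")

CHANNELS = ("vessel", "plaque", "thg")


@dataclass(frozen=True)
class VoxelSpacing:
    """Physical voxel spacing in micrometres: in-plane ``dx``, ``dy`` and axial ``dz``."""

    dx: float = 0.98
    dy: float = 0.98
    dz: float = 5.0

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "dz"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"spacing {name} must be strictly positive, got {v!r}")
            object.__setattr__(self, name, v)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel, dx*dy*dz (μm³)."""
        return self.dx * self.dy * self.dz

    @property
    def zyx(self) -> tuple[float, float, float]:
        """Spacing in array-axis order (dz, dy, dx), for anisotropy-aware transforms."""
        return (self.dz, self.dy, self.dx)

    def scale(self, factor: float) -> "VoxelSpacing":
        return VoxelSpacing(self.dx * factor, self.dy * factor, self.dz * factor)


DEFAULT_SPACING = VoxelSpacing(0.98, 0.98, 5.0)


def _infer_bit_depth_max(arr: np.ndarray) -> float:
    if np.issubdtype(arr.dtype, np.integer):
        return float(np.iinfo(arr.dtype).max)
    mx = float(arr.max()) if arr.size else 1.0
    return max(1.0, mx)


@dataclass
class ImageStack:
    """One channel of a 3D acquisition with physical spacing and session metadata.

    ``voxels`` holds nonnegative intensities indexed ``(z, y, x)``;
    ``bit_depth_max`` is the full-scale intensity of the acquisition
    (inferred from the dtype when not given, so 8- and 16-bit data are both
    accepted without assumptions).
    """

    voxels: np.ndarray
    spacing: VoxelSpacing = DEFAULT_SPACING
    channel: str = "vessel"
    session_id: str | None = None
    bit_depth_max: float | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"stack must be 3D (z, y, x); got shape {self.voxels.shape}")
        if any(s < 1 for s in self.voxels.shape):
            raise ValueError(f"stack dimensions must all be >= 1; got {self.voxels.shape}")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if self.bit_depth_max is None:
            self.bit_depth_max = _infer_bit_depth_max(self.voxels)
        if self.voxels.size and float(self.voxels.min()) < 0:
            raise ValueError("stack intensities must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def nz(self) -> int:
        return self.voxels.shape[0]

    def with_voxels(self, voxels: np.ndarray) -> "ImageStack":
        """Same metadata, new voxel data (shape may differ only in z)."""
        return ImageStack(
            voxels=voxels,
            spacing=self.spacing,
            channel=self.channel,
            session_id=self.session_id,
            bit_depth_max=self.bit_depth_max,
        )


@dataclass
class BinaryMask:
    """A {0,1} volume sharing shape and spacing with its source stack."""

    voxels: np.ndarray
    spacing: VoxelSpacing = DEFAULT_SPACING

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D; got shape {arr.shape}")
        if arr.dtype != bool:
            vals = np.unique(arr)
            allowed = {0, 1, 255}
            if not set(vals.tolist()) <= allowed:
                raise ValueError(
                    f"mask values must be binary (0/1 or 0/255); found values {vals[:10]}"
                )
            arr = arr > 0
        self.voxels = arr

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def count(self) -> int:
        """Number of foreground voxels."""
        return int(self.voxels.sum())


# ---------------------------------------------------------------------------
# TIFF I/O


def read_stack(
    path: str | Path,
    spacing: VoxelSpacing = DEFAULT_SPACING,
    channel: str = "vessel",
    session_id: str | None = None,
) -> ImageStack:
    """Read a multi-page TIFF into an ImageStack (one page per z-plane).

    Pages must share a single shape and sample format; intensities are
    preserved bit-exactly. Fails with the offending page named otherwise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack file not found: {path}")
    with tifffile.TiffFile(str(path)) as tf:
        pages = tf.pages
        n = len(pages)
        if n == 0:
            raise ValueError(f"{path}: TIFF contains no pages")
        first = pages[0].asarray()
        if first.ndim != 2:
            # single-page volumetric TIFF (e.g. written by imwrite of a 3D array)
            arr = tf.asarray()
            if arr.ndim == 2:
                arr = arr[None]
            if arr.ndim != 3:
                raise ValueError(f"{path}: unsupported TIFF dimensionality {arr.ndim}")
            return ImageStack(arr, spacing=spacing, channel=channel, session_id=session_id)
        planes = [first]
        for i in range(1, n):
            p = pages[i].asarray()
            if p.shape != first.shape:
                raise ValueError(
                    f"{path}: page {i} shape {p.shape} differs from page 0 shape {first.shape}"
                )
            if p.dtype != first.dtype:
                raise ValueError(
                    f"{path}: page {i} sample format {p.dtype} differs from page 0 ({first.dtype})"
                )
            planes.append(p)
        arr = np.stack(planes, axis=0)
    return ImageStack(arr, spacing=spacing, channel=channel, session_id=session_id)


def write_stack(stack: ImageStack | np.ndarray, path: str | Path) -> None:
    """Write a stack as a multi-page TIFF, preserving the dtype bit-exactly."""
    arr = stack.voxels if isinstance(stack, ImageStack) else np.asarray(stack)
    tifffile.imwrite(str(path), arr, photometric="minisblack")


def read_mask(path: str | Path, spacing: VoxelSpacing = DEFAULT_SPACING) -> BinaryMask:
    """Read a binary mask TIFF; {0,255} and {0,1} encodings both map to {0,1}."""
    stack = read_stack(path, spacing=spacing, channel="vessel")
    return BinaryMask(stack.voxels, spacing=spacing)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as 8-bit TIFF with foreground = 255."""
    tifffile.imwrite(str(path), (mask.voxels.astype(np.uint8)) * 255, photometric="minisblack")


def read_labels(path: str | Path) -> np.ndarray:
    """Read an integer label volume from TIFF."""
    with tifffile.TiffFile(str(path)) as tf:
        arr = tf.asarray()
    if arr.ndim == 2:
        arr = arr[None]
    return arr.astype(np.int32)


def write_labels(labels: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(str(path), np.asarray(labels).astype(np.int32), photometric="minisblack")


# ---------------------------------------------------------------------------
# Tabular export


def write_table(
    records: Sequence[Mapping] | pd.DataFrame,
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write metric records to CSV with a header row.

    Floats are serialized with 8 significant digits so that a re-parsed
    table reproduces the source values to float round-trip accuracy. An
    empty record list with ``columns`` given yields a header-only CSV.
    """
    if isinstance(records, pd.DataFrame):
        df = records
        if columns is not None:
            df = df.reindex(columns=list(columns))
    else:
        if not records and columns is None:
            raise ValueError("empty record list requires an explicit column schema")
        df = pd.DataFrame(list(records), columns=list(columns) if columns else None)
    df.to_csv(path, index=False, float_format="%.8g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Configuration

#: Every threshold used by the pipeline, overridable from a YAML config file.
DEFAULT_CONFIG: dict = {
    "spacing": {"dx": 0.98, "dy": 0.98, "dz": 5.0},
    # preprocessing
    "clahe_clip_limit": 0.01,
    "clahe_tile_grid": [8, 8],
    "crosstalk_alpha": "auto",
    "crosstalk_source_percentile": 99.0,
    "dura_boundary": "from-thg",
    "dura_top_fraction": 0.2,
    "dura_sd_factor": 2.0,
    "saturation_fraction": 0.95,
    "denoise_method": "median3d",
    "denoise_radius": 1,
    "motion_n_structures": 5,
    "motion_threshold": "otsu",
    # vessel morphometry
    "dice_qc_threshold": 0.70,
    "segment_min_nodes": 3,
    "centerline_smooth_window": 15,
    "baseline_min_component_voxels": 27,
    # plaque morphometry
    "plaque_min_area_um2": 49.0,
    "plaque_area_filter_mode": "max_slice",  # or "total"
    "plaque_min_object_px": 5,
    "plaque_fill_holes": True,
    # signal quality
    "signal_top_fraction": 0.005,
    "sbr_n_extreme": 15,
    # statistics
    "alpha": 0.05,
    "holm_correction": False,
}


def load_config(path: str | Path | None = None, overrides: Mapping | None = None) -> dict:
    """Return the default config merged with an optional YAML file and overrides."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        cfg.update(user)
    if overrides:
        cfg.update({k: v for k, v in overrides.items() if v is not None})
    return cfg


def config_spacing(cfg: Mapping) -> VoxelSpacing:
    sp = cfg.get("spacing", {})
    return VoxelSpacing(sp.get("dx", 0.98), sp.get("dy", 0.98), sp.get("dz", 5.0))


def config_hash(cfg: Mapping) -> str:
    """Stable hash of a config mapping, for run summaries."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_run_summary(path: str | Path, inputs: Mapping, cfg: Mapping) -> None:
    """One JSON summary per invocation: inputs, config + hash, package versions."""
    from . import __version__

    summary = {
        "inputs": {k: str(v) for k, v in inputs.items()},
        "config": cfg,
        "config_hash": config_hash(cfg),
        "versions": {
            "threepmorph": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def setup_logging(level: int = logging.INFO) -> None:
    """Timestamped logging to stderr for CLI runs."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("threepmorph")
    root.handlers[:] = [handler]
    root.setLevel(level)
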