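"""Amyloid-plaque segmentation and morphometry.

Semi-automatic segmentation follows a multilevel-Otsu recipe: four
thresholds (five classes) over the whole volume, plaques taken as the two
highest-intensity classes, per-plane morphological cleanup (hole filling
and small-object removal), then 3D connected-component labeling. Components
whose largest single-plane cross-section is smaller than 49 μm² are
excluded. Per-plaque volume is the sum of per-slice areas times the slice
thickness, and the reported radius is the equivalent-sphere radius of that
volume. Nearest plaque-to-vessel distances are 3D Euclidean distances from
plaque centroids to vessel foreground voxels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.morphology import remove_small_objects

from .stack_io import BinaryMask, ImageStack, VoxelSpacing

logger = logging.getLogger("threepmorph")

#: 3×3 cross structuring element for per-plane hole filling
_CROSS_2D = ndi.generate_binary_structure(2, 1)
#: 26-connectivity for 3D component labeling
_CONN_3D = np.ones((3, 3, 3), dtype=bool)


@dataclass
class PlaqueRegion:
    """One 3D-connected plaque component and its per-slice morphometry."""

    label: int
    slice_areas: list[tuple[int, float]]  # (plane index, area μm²)
    volume_um3: float
    equivalent_radius_um: float
    centroid_um: np.ndarray  # (x, y, z)
    n_voxels: int
    nearest_vessel_distance_um: float | None = None

    def to_record(self) -> dict:
        cx, cy, cz = self.centroid_um
        return {
            "label": self.label,
            "n_voxels": self.n_voxels,
            "volume_um3": self.volume_um3,
            "equivalent_radius_um": self.equivalent_radius_um,
            "centroid_x_um": cx,
            "centroid_y_um": cy,
            "centroid_z_um": cz,
            "max_slice_area_um2": max(a for _, a in self.slice_areas),
            "nearest_vessel_distance_um": self.nearest_vessel_distance_um,
        }


# ---------------------------------------------------------------------------
# Segmentation


def segment_plaques(
    stack: ImageStack | None = None,
    mode: str = "semi_auto",
    manual: BinaryMask | None = None,
    min_object_px: int = 5,
    fill_holes: bool = True,
    max_foreground_fraction: float = 0.05,
) -> np.ndarray:
    """Label plaque voxels; returns an int32 label volume (0 = background).

    ``semi_auto``: multilevel-Otsu thresholding of the whole volume (four
    thresholds, five classes), keeping the top two intensity classes, then
    per-plane hole filling and removal of objects below ``min_object_px``
    pixels, then 26-connected 3D labeling. ``manual_mask``: label an
    externally edited binary mask directly (the manual-annotation route).
    """
    if mode == "manual_mask":
        if manual is None:
            raise ValueError("manual_mask mode requires a mask")
        labels, n = ndi.label(manual.voxels, structure=_CONN_3D)
        return labels.astype(np.int32)
    if mode != "semi_auto":
        raise ValueError(f"unknown plaque segmentation mode {mode!r}")
    if stack is None:
        raise ValueError("semi_auto mode requires an image stack")
    v = stack.voxels.astype(float)
    if v.max() == v.min():
        raise ValueError("cannot segment a constant stack")
    uniq = np.unique(v)
    if uniq.size >= 5:
        # plaques are a sparse bright minority; when the dominant background
        # mode captures the thresholds, recompute them on the above-threshold
        # subset until the selected fraction is plaque-like
        thresholds = threshold_multiotsu(v, classes=5)
        binary = v >= thresholds[2]  # top two of five classes
        for _ in range(16):
            if binary.mean() <= max_foreground_fraction:
                break
            sub = v[binary]
            if np.unique(sub).size < 5:
                break
            new_thresholds = threshold_multiotsu(sub, classes=5)
            if new_thresholds[2] <= thresholds[2]:
                break
            thresholds = new_thresholds
            binary = v >= thresholds[2]
    else:
        logger.warning(
            "segment_plaques: only %d distinct intensities; falling back to binary Otsu",
            uniq.size,
        )
        binary = v > threshold_otsu(v)
    if binary.mean() > max_foreground_fraction:
        logger.warning(
            "segment_plaques: %.0f%% of the volume above threshold — "
            "no plaque-like sparse foreground, returning no regions",
            100 * binary.mean(),
        )
        return np.zeros(v.shape, dtype=np.int32)
    cleaned = np.zeros_like(binary)
    for k in range(binary.shape[0]):
        plane = binary[k]
        if min_object_px > 1:
            plane = remove_small_objects(plane, max_size=int(min_object_px) - 1)
        if fill_holes:
            plane = ndi.binary_fill_holes(plane, structure=_CROSS_2D)
        cleaned[k] = plane
    labels, n = ndi.label(cleaned, structure=_CONN_3D)
    if n == 0:
        logger.warning("segment_plaques: no plaque regions found")
    return labels.astype(np.int32)


def _per_label_plane_counts(labels: np.ndarray) -> dict[int, dict[int, int]]:
    """{label: {plane index: pixel count}} for every nonzero label."""
    out: dict[int, dict[int, int]] = {}
    for k in range(labels.shape[0]):
        plane = labels[k]
        vals, counts = np.unique(plane[plane != 0], return_counts=True)
        for v, c in zip(vals, counts):
            out.setdefault(int(v), {})[k] = int(c)
    return out


def filter_small_regions(
    labels: np.ndarray,
    spacing: VoxelSpacing,
    min_area_um2: float = 49.0,
    mode: str = "max_slice",
) -> np.ndarray:
    """Remove labeled components by the 49 μm² cross-sectional area criterion.

    With ``mode="max_slice"`` (default) a 3D component is removed iff its
    maximum single-plane cross-sectional area (pixel count × Δx·Δy) is
    strictly smaller than ``min_area_um2``; ``mode="total"`` uses the summed
    area over all planes instead. Retained labels are re-indexed
    contiguously from 1 (in ascending original-label order), so the filter
    is idempotent.
    """
    if mode not in ("max_slice", "total"):
        raise ValueError(f"unknown area-filter mode {mode!r}")
    pixel_area = spacing.dx * spacing.dy
    counts = _per_label_plane_counts(labels)
    keep = []
    for lbl in sorted(counts):
        per_plane = counts[lbl].values()
        area = (max(per_plane) if mode == "max_slice" else sum(per_plane)) * pixel_area
        if area < min_area_um2:
            continue
        keep.append(lbl)
    out = np.zeros_like(labels)
    for new, old in enumerate(keep, start=1):
        out[labels == old] = new
    return out


# ---------------------------------------------------------------------------
# Per-plaque quantities


def plaque_volume(slice_pixel_counts, spacing: VoxelSpacing) -> float:
    """V = Σ_planes (pixel count × Δx·Δy) × Δz.

    ``slice_pixel_counts`` maps plane index → pixel count (or is a plain
    sequence of per-plane counts).
    """
    if hasattr(slice_pixel_counts, "values"):
        counts = list(slice_pixel_counts.values())
    else:
        counts = list(slice_pixel_counts)
    if not counts or sum(counts) == 0:
        raise ValueError("plaque volume undefined for an empty region")
    return float(sum(counts) * spacing.dx * spacing.dy * spacing.dz)


def plaque_radius(volume_um3: float) -> float:
    """Equivalent-sphere radius r = (3V / 4π)^(1/3)."""
    if volume_um3 <= 0:
        raise ValueError("equivalent radius undefined for non-positive volume")
    return float((3.0 * volume_um3 / (4.0 * np.pi)) ** (1.0 / 3.0))


def nearest_plaque_vessel_distance(
    centroids_um, vessel_mask: BinaryMask
) -> np.ndarray:
    """Per plaque centroid, the minimum 3D Euclidean distance (μm) to any
    vessel foreground voxel center."""
    c = np.atleast_2d(np.asarray(centroids_um, dtype=float))
    if c.size == 0:
        raise ValueError("no plaque centroids given")
    coords = np.argwhere(vessel_mask.voxels)
    if coords.size == 0:
        raise ValueError("nearest-vessel distance undefined: vessel mask is empty")
    sp = vessel_mask.spacing
    vessel_um = np.column_stack(
        [coords[:, 2] * sp.dx, coords[:, 1] * sp.dy, coords[:, 0] * sp.dz]
    )
    tree = cKDTree(vessel_um)
    d, _ = tree.query(c, k=1)
    return np.asarray(d, dtype=float)


def measure_plaques(
    labels: np.ndarray,
    spacing: VoxelSpacing,
    vessel_mask: BinaryMask | None = None,
) -> list[PlaqueRegion]:
    """Per-label morphometry: slice areas, volume, equivalent radius,
    centroid, and (when a vessel mask is given) nearest-vessel distance."""
    pixel_area = spacing.dx * spacing.dy
    counts = _per_label_plane_counts(labels)
    regions: list[PlaqueRegion] = []
    for lbl in sorted(counts):
        per_plane = counts[lbl]
        slice_areas = [(k, per_plane[k] * pixel_area) for k in sorted(per_plane)]
        vol = plaque_volume(per_plane, spacing)
        coords = np.argwhere(labels == lbl)
        centroid = np.array(
            [
                coords[:, 2].mean() * spacing.dx,
                coords[:, 1].mean() * spacing.dy,
                coords[:, 0].mean() * spacing.dz,
            ]
        )
        regions.append(
            PlaqueRegion(
                label=lbl,
                slice_areas=slice_areas,
                volume_um3=vol,
                equivalent_radius_um=plaque_radius(vol),
                centroid_um=centroid,
                n_voxels=int(coords.shape[0]),
            )
        )
    if vessel_mask is not None and regions:
        dists = nearest_plaque_vessel_distance(
            [r.centroid_um for r in regions], vessel_mask
        )
        for r, d in zip(regions, dists):
            r.nearest_vessel_distance_um = float(d)
    return regions


def total_plaque_volume(regions: list[PlaqueRegion]) -> float:
    return float(sum(r.volume_um3 for r in regions))
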