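"""Vascular morphometry: skeleton → segments → diameter, length, tortuosity,
total volume, inter-vessel distance, plus segmentation quality control.

Per-segment quantities follow the standard vascular-graph conventions:

* radius at a centerline point = minimum Euclidean distance to the nearest
  background voxel, computed in PHYSICAL micrometres (the axial spacing is
  typically 5 μm against ~1 μm in plane, so voxel-unit distances would be
  wrong by up to 5×);
* diameter D = 2 × median(r_j) along the centerline;
* length L = sum of consecutive Euclidean point distances;
* tortuosity T = L / endpoint chord (1 for a straight vessel);
* total vascular volume = foreground voxel count × voxel volume;
* inter-vessel distance (IVD) = per segment, the minimum centroid-to-centroid
  distance to any other segment, the centroid being the unweighted mean of
  the segment's skeleton coordinates.

A Dice coefficient against manual annotation flags stacks for manual
correction below a QC threshold of 0.70.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial.distance import cdist
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects, skeletonize as sk_skeletonize

from .stack_io import BinaryMask, ImageStack, VoxelSpacing

logger = logging.getLogger("threepmorph")

#: offsets of the 26-neighborhood
_NEIGHBOR_OFFSETS = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


# ---------------------------------------------------------------------------
# Quality control


@dataclass(frozen=True)
class DiceResult:
    """Dice similarity with its QC verdict against the 0.70 threshold."""

    value: float
    threshold: float = 0.70

    @property
    def flagged(self) -> bool:
        """True when manual correction is recommended (Dice below threshold)."""
        return self.value < self.threshold


def dice_coefficient(
    pred: BinaryMask, truth: BinaryMask, qc_threshold: float = 0.70
) -> DiceResult:
    """Dice similarity 2|A∩B| / (|A|+|B|) between two masks of equal shape."""
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    a, b = pred.voxels, truth.voxels
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        raise ValueError("Dice undefined: both masks are empty")
    value = 2.0 * int(np.logical_and(a, b).sum()) / denom
    res = DiceResult(value=value, threshold=qc_threshold)
    if res.flagged:
        logger.warning("Dice %.3f below %.2f: manual correction recommended", value, qc_threshold)
    return res


# ---------------------------------------------------------------------------
# Baseline segmentation (classical stand-in; external masks may be imported)


def baseline_segment(
    stack: ImageStack,
    method: str = "otsu3d",
    invert: bool = False,
    min_component_voxels: int = 27,
    max_foreground_fraction: float = 0.2,
    open_in_plane: bool = True,
) -> BinaryMask:
    """Global-Otsu vessel segmentation over the whole volume.

    A classical baseline for when no externally produced mask (e.g. from a
    learned segmenter) is available; imported masks pass through the same
    Dice QC and metric chain. ``invert`` handles dark-vessel contrast.
    Components smaller than ``min_component_voxels`` are dropped.

    Vessels occupy a small fraction of a cortical volume, a regime where a
    single two-class Otsu threshold tends to split the dominant background
    mode instead of separating signal from background. Whenever the
    foreground fraction exceeds ``max_foreground_fraction`` the threshold
    is therefore recomputed on the above-threshold voxels only, until the
    fraction is plausible (deterministic, at most a few iterations).
    """
    if method != "otsu3d":
        raise ValueError(f"unknown segmentation method {method!r}")
    v = stack.voxels.astype(float)
    if v.max() == v.min():
        raise ValueError("cannot segment a constant stack")
    if invert:
        v = v.max() - v
    from ._thresholds import sparse_otsu_threshold

    thr = sparse_otsu_threshold(v, max_foreground_fraction)
    fg = v > thr
    if open_in_plane:
        # per-plane opening with a 3×3 cross strips the single-pixel noise
        # halo without touching structures only one plane thick in z
        cross = ndi.generate_binary_structure(2, 1)
        fg = np.stack([ndi.binary_opening(p, structure=cross) for p in fg])
    if min_component_voxels > 1:
        fg = remove_small_objects(fg, max_size=int(min_component_voxels) - 1)
    if not fg.any():
        logger.warning("baseline_segment: empty mask (no foreground above threshold)")
    return BinaryMask(fg, spacing=stack.spacing)


# ---------------------------------------------------------------------------
# Skeletonization and segment splitting


@dataclass
class Skeleton:
    """Medial axis of a vessel mask as a 26-connected voxel graph."""

    nodes: list[tuple[int, int, int]]
    adjacency: dict[tuple[int, int, int], set[tuple[int, int, int]]]
    spacing: VoxelSpacing

    @property
    def branch_points(self) -> set[tuple[int, int, int]]:
        return {n for n, nb in self.adjacency.items() if len(nb) >= 3}

    @property
    def end_points(self) -> set[tuple[int, int, int]]:
        return {n for n, nb in self.adjacency.items() if len(nb) == 1}

    def degree(self, node: tuple[int, int, int]) -> int:
        return len(self.adjacency[node])


def skeletonize(mask: BinaryMask) -> Skeleton:
    """3D topological thinning to a one-voxel-wide medial axis.

    Every skeleton voxel is foreground in the source mask and the number of
    connected components is preserved.
    """
    if not mask.voxels.any():
        raise ValueError("cannot skeletonize an empty mask")
    skel = sk_skeletonize(mask.voxels)
    # 3D thinning erases components only one voxel thick in z (a thin
    # capillary can occupy a single plane at coarse axial sampling);
    # recover them by per-plane 2D thinning so mask connectivity is kept.
    labels, n = ndi.label(mask.voxels, structure=np.ones((3, 3, 3), dtype=bool))
    surviving = set(np.unique(labels[skel]).tolist()) - {0}
    for lbl in range(1, n + 1):
        if lbl in surviving:
            continue
        comp = labels == lbl
        for k in range(comp.shape[0]):
            if comp[k].any():
                skel[k] |= sk_skeletonize(comp[k])
    coords = [tuple(int(c) for c in p) for p in np.argwhere(skel)]
    node_set = set(coords)
    adjacency: dict[tuple[int, int, int], set] = {n: set() for n in coords}
    for n in coords:
        z, y, x = n
        for dz, dy, dx in _NEIGHBOR_OFFSETS:
            m = (z + dz, y + dy, x + dx)
            if m in node_set:
                adjacency[n].add(m)
    return Skeleton(nodes=sorted(node_set), adjacency=adjacency, spacing=mask.spacing)


def split_segments(
    skel: Skeleton, min_nodes: int = 3
) -> list[list[tuple[int, int, int]]]:
    """Split a skeleton into maximal branch-point-free voxel paths.

    Segment terminals are branch points (≥3 neighbors) and end points
    (1 neighbor); every non-branch voxel belongs to exactly one segment.
    Paths shorter than ``min_nodes`` are discarded as spurs. Isolated
    cycles (no terminal) are returned as closed paths.
    """
    if not skel.nodes:
        raise ValueError("empty skeleton")
    terminals = {n for n in skel.nodes if skel.degree(n) != 2}
    visited_edges: set[frozenset] = set()
    paths: list[list[tuple[int, int, int]]] = []

    def walk(start, first):
        path = [start, first]
        visited_edges.add(frozenset((start, first)))
        prev, cur = start, first
        while cur not in terminals:
            nxts = [m for m in skel.adjacency[cur] if m != prev]
            if not nxts:
                break
            nxt = nxts[0]
            edge = frozenset((cur, nxt))
            if edge in visited_edges:
                break
            visited_edges.add(edge)
            path.append(nxt)
            prev, cur = cur, nxt
        return path

    for t in sorted(terminals):
        for nb in sorted(skel.adjacency[t]):
            if frozenset((t, nb)) not in visited_edges:
                paths.append(walk(t, nb))

    # isolated cycles: all remaining nodes have degree 2 and unvisited edges
    for n in skel.nodes:
        if n in terminals or skel.degree(n) == 0:
            continue
        for nb in sorted(skel.adjacency[n]):
            if frozenset((n, nb)) not in visited_edges:
                paths.append(walk(n, nb))
                break

    return [p for p in paths if len(p) >= min_nodes]


# ---------------------------------------------------------------------------
# Per-segment metrics


def radius_map(mask: BinaryMask) -> np.ndarray:
    """Anisotropy-aware Euclidean distance (μm) from each foreground voxel to
    the nearest background voxel (the per-point vessel radius field)."""
    if not (~mask.voxels).any():
        raise ValueError("radius undefined: mask has no background voxels")
    return ndi.distance_transform_edt(mask.voxels, sampling=mask.spacing.zyx)


def vessel_radius_profile(
    segment: list[tuple[int, int, int]], mask: BinaryMask
) -> np.ndarray:
    """Radii r_j along a centerline path: distance to nearest background (μm)."""
    edt = radius_map(mask)
    radii = np.array([edt[p] for p in segment], dtype=float)
    if np.any(radii <= 0):
        raise ValueError("segment contains background voxels (radius would be 0)")
    return radii


def vessel_diameter(radii) -> float:
    """D = 2 × median(r_j); even-count median = mean of the two central values."""
    radii = np.asarray(radii, dtype=float)
    if radii.size == 0:
        raise ValueError("diameter undefined for empty radius list")
    return float(2.0 * np.median(radii))


def vessel_length(points) -> float:
    """L = Σ ‖p_{i+1} − p_i‖ over consecutive centerline points (physical units)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("length requires at least 2 points")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def vessel_tortuosity(points) -> float:
    """T = path length / endpoint chord; ≥ 1, with 1 for a straight segment."""
    pts = np.asarray(points, dtype=float)
    chord = float(np.linalg.norm(pts[-1] - pts[0]))
    if chord == 0:
        raise ValueError("tortuosity undefined: coincident endpoints (closed loop)")
    return vessel_length(pts) / chord


def total_vessel_volume(mask: BinaryMask) -> float:
    """V_vessel = N_vessel × Δx·Δy·Δz, exactly."""
    return mask.count * mask.spacing.voxel_volume


def inter_vessel_distance(centroids) -> np.ndarray:
    """Per segment, the minimum centroid-to-centroid distance to any other
    segment (physical units). Requires at least two segments."""
    c = np.atleast_2d(np.asarray(centroids, dtype=float))
    if c.shape[0] < 2:
        raise ValueError("inter-vessel distance requires at least 2 segments")
    d = cdist(c, c)
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


# ---------------------------------------------------------------------------
# Full measurement chain


@dataclass
class VesselSegment:
    """One branch-free centerline path with its morphometric quantities.

    ``points_um`` are ordered (x, y, z) centerline coordinates in μm;
    ``centroid_um`` is the unweighted mean of the segment's skeleton
    coordinates. ``tortuosity`` is NaN for closed loops, ``ivd_um`` NaN when
    the stack has a single segment.
    """

    voxels: list[tuple[int, int, int]]
    points_um: np.ndarray
    radii_um: np.ndarray
    diameter_um: float
    length_um: float
    tortuosity: float
    centroid_um: np.ndarray
    ivd_um: float = float("nan")

    def to_record(self) -> dict:
        cx, cy, cz = self.centroid_um
        return {
            "n_points": len(self.voxels),
            "diameter_um": self.diameter_um,
            "length_um": self.length_um,
            "tortuosity": self.tortuosity,
            "ivd_um": self.ivd_um,
            "centroid_x_um": cx,
            "centroid_y_um": cy,
            "centroid_z_um": cz,
        }


@dataclass
class SegmentSet:
    """All segments of one stack plus the volume totals of the source mask."""

    segments: list[VesselSegment]
    n_vessel_voxels: int
    voxel_volume: float

    @property
    def total_volume(self) -> float:
        """Exact identity: foreground voxel count times voxel volume."""
        return self.n_vessel_voxels * self.voxel_volume

    def to_records(self) -> list[dict]:
        return [s.to_record() for s in self.segments]


def _voxels_to_um(path, spacing: VoxelSpacing) -> np.ndarray:
    """(z, y, x) index path → (x, y, z) physical coordinates in μm."""
    arr = np.asarray(path, dtype=float)
    return np.column_stack(
        [arr[:, 2] * spacing.dx, arr[:, 1] * spacing.dy, arr[:, 0] * spacing.dz]
    )


def smooth_path(points: np.ndarray, window: int = 15) -> np.ndarray:
    """Moving-average smoothing of a polyline (reduces voxel stair-stepping).

    Raw 26-connected voxel paths overestimate arc length at oblique angles;
    a short uniform filter recovers the underlying smooth centerline while
    leaving genuinely curved paths essentially unchanged.
    """
    if window <= 1 or points.shape[0] <= 2:
        return points
    out = ndi.uniform_filter1d(points, size=int(window), axis=0, mode="nearest")
    return out


def measure_vessels(
    mask: BinaryMask,
    min_nodes: int = 3,
    smooth_window: int = 15,
) -> SegmentSet:
    """Run the full chain mask → skeleton → segments → metrics.

    Diameters come from the anisotropic distance transform sampled along
    each raw voxel path; length and tortuosity are computed on the smoothed
    physical polyline; centroids and IVD use the raw skeleton coordinates.
    """
    skel = skeletonize(mask)
    paths = split_segments(skel, min_nodes=min_nodes)
    edt = radius_map(mask)
    segments: list[VesselSegment] = []
    for path in paths:
        radii = np.array([edt[p] for p in path], dtype=float)
        pts = _voxels_to_um(path, mask.spacing)
        smoothed = smooth_path(pts, window=smooth_window)
        length = vessel_length(smoothed)
        chord = float(np.linalg.norm(smoothed[-1] - smoothed[0]))
        tort = length / chord if chord > 0 else float("nan")
        segments.append(
            VesselSegment(
                voxels=path,
                points_um=pts,
                radii_um=radii,
                diameter_um=vessel_diameter(radii),
                length_um=length,
                tortuosity=tort,
                centroid_um=pts.mean(axis=0),
            )
        )
    if len(segments) >= 2:
        ivds = inter_vessel_distance([s.centroid_um for s in segments])
        for s, d in zip(segments, ivds):
            s.ivd_um = float(d)
    return SegmentSet(
        segments=segments,
        n_vessel_voxels=mask.count,
        voxel_volume=mask.spacing.voxel_volume,
    )
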