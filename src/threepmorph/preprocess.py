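"""Preprocessing chain for two-channel stacks and motion-artifact assessment.

The pipeline order is fixed: adaptive histogram equalization → crosstalk
removal → dura removal → depth normalization → denoising. Motion is only
assessed, never corrected: frame-to-frame shifts of bright vascular
structures are measured so a user can decide whether registration is needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label

from .stack_io import BinaryMask, ImageStack

logger = logging.getLogger("threepmorph")


@dataclass
class MotionReport:
    """Per-plane-pair centroid shifts of tracked vascular structures.

    ``shifts`` rows are (plane index of the later frame, structure id,
    shift magnitude in pixels); ``max_shift`` is the maximum over all rows
    (0 when no consecutive pair was trackable).
    """

    shifts: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def max_shift(self) -> float:
        return max((s for _, _, s in self.shifts), default=0.0)

    def to_records(self) -> list[dict]:
        return [
            {"plane": p, "structure": sid, "shift_px": s} for p, sid, s in self.shifts
        ]


# ---------------------------------------------------------------------------


def adaptive_hist_eq(
    stack: ImageStack, clip_limit: float = 0.01, tile_grid: tuple[int, int] = (8, 8)
) -> ImageStack:
    """Per-plane contrast-limited adaptive histogram equalization (CLAHE).

    Each plane is equalized independently and rescaled to the stack's
    intensity range [0, bit_depth_max]. All-constant planes pass through
    unchanged (nothing to equalize).
    """
    if not (0 < clip_limit <= 1):
        raise ValueError(f"clip_limit must lie in (0, 1], got {clip_limit}")
    bdm = float(stack.bit_depth_max)
    ny, nx = stack.shape[1:]
    kernel = (max(1, ny // int(tile_grid[0])), max(1, nx // int(tile_grid[1])))
    out = np.empty(stack.shape, dtype=float)
    for k, plane in enumerate(stack.voxels):
        plane = np.asarray(plane, dtype=float)
        if plane.max() == plane.min():
            out[k] = plane
            continue
        eq = exposure.equalize_adapthist(
            plane / bdm, kernel_size=kernel, clip_limit=clip_limit
        )
        out[k] = eq * bdm
    return stack.with_voxels(out)


def remove_crosstalk(
    target: ImageStack,
    source: ImageStack,
    alpha: float | str = "auto",
    source_percentile: float = 99.0,
) -> ImageStack:
    """Clamped linear spectral unmixing: corrected = max(target − α·source, 0).

    With ``alpha="auto"`` the bleed-through coefficient is estimated as the
    least-squares slope of target vs. source over voxels where the source
    channel exceeds its ``source_percentile`` percentile (bright source
    structure dominates the mixture there).
    """
    if target.shape != source.shape:
        raise ValueError(
            f"shape mismatch: target {target.shape} vs source {source.shape}"
        )
    if alpha == "auto":
        alpha = estimate_crosstalk_alpha(target, source, source_percentile)
    alpha = float(alpha)
    if not (0 <= alpha < 1):
        raise ValueError(f"alpha must lie in [0, 1), got {alpha}")
    corrected = np.maximum(target.voxels.astype(float) - alpha * source.voxels, 0.0)
    return target.with_voxels(corrected)


def estimate_crosstalk_alpha(
    target: ImageStack, source: ImageStack, source_percentile: float = 99.0
) -> float:
    """Robust slope of target on source over bright source voxels.

    Both channels are first reduced by their median (a robust estimate of
    the background level), so a nonzero baseline in the target does not
    bias the slope. Bright source voxels are those above both the given
    percentile and a sparse-aware Otsu cut — structures typically occupy
    well under 1% of a deep-tissue volume, so a percentile alone would
    drag background into the fit. The slope is the median of per-voxel
    ratios, which keeps the estimate stable where the target's own
    structures (e.g. a vessel crossing a plaque) overlap bright source
    voxels.
    """
    from ._thresholds import sparse_otsu_threshold

    s = source.voxels.astype(float).ravel()
    t = target.voxels.astype(float).ravel()
    s = s - np.median(s)
    t = t - np.median(t)
    cut = np.percentile(s, source_percentile)
    if s.max() > s.min():
        cut = max(cut, sparse_otsu_threshold(s))
    sel = s > cut
    if not np.any(sel):
        sel = s >= cut
    ss = s[sel]
    pos = ss > 0
    if not np.any(pos):
        return 0.0
    slope = float(np.median(t[sel][pos] / ss[pos]))
    return float(np.clip(slope, 0.0, 0.999))


def remove_dura(
    stack: ImageStack,
    boundary: int | str = "from-thg",
    thg: ImageStack | None = None,
    top_fraction: float = 0.2,
    sd_factor: float = 2.0,
) -> ImageStack:
    """Discard superficial planes above the dura mater boundary.

    With an integer ``boundary`` the planes z < boundary are dropped. With
    ``"from-thg"`` the boundary is located from the third-harmonic channel:
    the deepest plane in the top ``top_fraction`` of the stack whose mean
    THG intensity exceeds (global mean + sd_factor·SD), plus one. The
    restriction to superficial planes prevents deep bright structures from
    being misread as dura.
    """
    nz = stack.nz
    if boundary == "from-thg":
        if thg is None:
            raise ValueError('"from-thg" dura removal requires a THG stack')
        if thg.shape != stack.shape:
            raise ValueError("THG stack shape must match the target stack")
        v = thg.voxels.astype(float)
        thresh = v.mean() + sd_factor * v.std()
        top = max(1, int(np.ceil(top_fraction * nz)))
        plane_means = v[:top].mean(axis=(1, 2))
        hits = np.nonzero(plane_means > thresh)[0]
        boundary = int(hits.max()) + 1 if hits.size else 0
        logger.info("dura boundary from THG: plane %d", boundary)
    boundary = int(boundary)
    if boundary >= nz:
        raise ValueError(f"dura boundary {boundary} >= stack depth {nz}")
    if boundary < 0:
        raise ValueError("dura boundary must be nonnegative")
    return stack.with_voxels(stack.voxels[boundary:])


def normalize_stack(stack: ImageStack, saturation_fraction: float = 0.95) -> ImageStack:
    """Match every plane's intensity range to the last non-overexposed plane.

    The reference is the deepest plane whose maximum intensity does not
    exceed ``saturation_fraction`` of full scale (the deepest plane when
    none qualifies); each plane's [min, max] is mapped linearly onto the
    reference's [min, max]. Compensates depth attenuation so structures
    stay comparably bright throughout the stack.
    """
    v = stack.voxels.astype(float)
    bdm = float(stack.bit_depth_max)
    plane_max = v.max(axis=(1, 2))
    plane_min = v.min(axis=(1, 2))
    ok = np.nonzero(plane_max <= saturation_fraction * bdm)[0]
    ref = int(ok.max()) if ok.size else stack.nz - 1
    ref_min, ref_max = plane_min[ref], plane_max[ref]
    if ref_max == ref_min:
        logger.warning(
            "normalize_stack: reference plane %d is constant; passing stack through", ref
        )
        return stack.with_voxels(v)
    out = np.empty_like(v)
    for k in range(stack.nz):
        lo, hi = plane_min[k], plane_max[k]
        if hi == lo:
            out[k] = v[k]
        else:
            out[k] = (v[k] - lo) / (hi - lo) * (ref_max - ref_min) + ref_min
    return stack.with_voxels(out)


def denoise(stack: ImageStack, method: str = "median3d", radius: int = 1) -> ImageStack:
    """3D median filtering (edge-preserving, suited to tubular structures)."""
    if method != "median3d":
        raise ValueError(f"unknown denoise method {method!r}")
    if radius < 1:
        raise ValueError("denoise radius must be >= 1")
    size = 2 * int(radius) + 1
    out = ndi.median_filter(stack.voxels.astype(float), size=size, mode="nearest")
    return stack.with_voxels(out)


# ---------------------------------------------------------------------------
# Motion assessment


def _binarize_planes(v: np.ndarray, threshold: float | str) -> np.ndarray:
    binary = np.zeros(v.shape, dtype=bool)
    for k, plane in enumerate(v):
        if threshold == "otsu":
            if plane.max() == plane.min():
                continue
            thr = threshold_otsu(plane)
        else:
            thr = float(threshold)
        binary[k] = plane > thr
    return binary


def _plane_regions(binary_plane: np.ndarray) -> np.ndarray:
    return sk_label(binary_plane, connectivity=2)


def assess_motion(
    stack: ImageStack,
    n_structures: int = 5,
    threshold: float | str = "otsu",
) -> MotionReport:
    """Measure frame-to-frame shift of single vascular structures.

    Each plane of the raw stack is binarized (per-plane Otsu by default)
    and 2D-labeled; structures are chained across consecutive planes by
    maximal pixel overlap (nearest-centroid fallback when a jittered frame
    has no overlap). For each of the up-to-``n_structures`` longest chains,
    the shift between consecutive planes is the Euclidean distance in
    pixels between the intensity-weighted centroids of the structure's
    cross-sections.
    """
    v = stack.voxels.astype(float)
    nz = stack.nz
    binary = _binarize_planes(v, threshold)
    if not binary.any():
        raise ValueError("motion assessment: no foreground structure found after binarization")
    if np.count_nonzero(binary.any(axis=(1, 2))) < 2:
        raise ValueError("motion assessment requires foreground in at least 2 planes")

    labels = [_plane_regions(binary[k]) for k in range(nz)]

    def centroid(k: int, lbl: int) -> np.ndarray:
        sel = labels[k] == lbl
        w = v[k][sel]
        ys, xs = np.nonzero(sel)
        tot = w.sum()
        if tot == 0:
            return np.array([ys.mean(), xs.mean()])
        return np.array([(ys * w).sum() / tot, (xs * w).sum() / tot])

    # chain structures forward through the stack by maximal overlap
    used: list[set[int]] = [set() for _ in range(nz)]
    chains: list[list[tuple[int, int]]] = []  # list of (plane, label)
    for k0 in range(nz):
        lbls0 = [l for l in np.unique(labels[k0]) if l != 0 and l not in used[k0]]
        # largest regions first, for deterministic structure selection
        lbls0.sort(key=lambda l: (-int(np.sum(labels[k0] == l)), int(l)))
        for l0 in lbls0:
            chain = [(k0, int(l0))]
            used[k0].add(int(l0))
            k, cur = k0, int(l0)
            while k + 1 < nz:
                nxt_labels = labels[k + 1]
                cur_sel = labels[k] == cur
                overlap = nxt_labels[cur_sel]
                overlap = overlap[overlap != 0]
                nxt = 0
                if overlap.size:
                    counts = np.bincount(overlap)
                    order = np.argsort(-counts[1:], kind="stable") + 1
                    for cand in order:
                        if counts[cand] > 0 and int(cand) not in used[k + 1]:
                            nxt = int(cand)
                            break
                if nxt == 0:
                    # fallback: nearest centroid among unused regions of the next plane
                    cands = [
                        l
                        for l in np.unique(nxt_labels)
                        if l != 0 and int(l) not in used[k + 1]
                    ]
                    if cands:
                        c0 = centroid(k, cur)
                        dists = [
                            (float(np.linalg.norm(centroid(k + 1, int(l)) - c0)), int(l))
                            for l in cands
                        ]
                        d, l = min(dists)
                        if d <= 16.0:  # do not chain across unrelated structures
                            nxt = l
                if nxt == 0:
                    break
                used[k + 1].add(nxt)
                chain.append((k + 1, nxt))
                k, cur = k + 1, nxt
            if len(chain) >= 2:
                chains.append(chain)

    chains.sort(key=lambda c: (-len(c), c[0]))
    chains = chains[: int(n_structures)]
    if not chains:
        raise ValueError("motion assessment: no structure spans two consecutive planes")

    report = MotionReport()
    for sid, chain in enumerate(chains):
        for (k_prev, l_prev), (k_next, l_next) in zip(chain[:-1], chain[1:]):
            c_prev = centroid(k_prev, l_prev)
            c_next = centroid(k_next, l_next)
            shift = float(np.linalg.norm(c_next - c_prev))
            report.shifts.append((k_next, sid, shift))
    return report


# ---------------------------------------------------------------------------


def preprocess_stack(
    target: ImageStack,
    source: ImageStack | None = None,
    thg: ImageStack | None = None,
    cfg: dict | None = None,
) -> ImageStack:
    """Run the full fixed-order chain on one channel.

    equalize → crosstalk-correct (if the paired channel is given) →
    dura-remove → normalize → denoise. Thresholds come from the config
    mapping (see ``stack_io.DEFAULT_CONFIG``).
    """
    from .stack_io import DEFAULT_CONFIG

    cfg = {**DEFAULT_CONFIG, **(cfg or {})}
    out = adaptive_hist_eq(
        target, clip_limit=cfg["clahe_clip_limit"], tile_grid=tuple(cfg["clahe_tile_grid"])
    )
    if source is not None:
        src = adaptive_hist_eq(
            source, clip_limit=cfg["clahe_clip_limit"], tile_grid=tuple(cfg["clahe_tile_grid"])
        )
        out = remove_crosstalk(
            out,
            src,
            alpha=cfg["crosstalk_alpha"],
            source_percentile=cfg["crosstalk_source_percentile"],
        )
    boundary = cfg["dura_boundary"]
    if boundary == "from-thg" and thg is None:
        boundary = 0  # nothing to locate the dura with; keep all planes
    if boundary != 0:
        out = remove_dura(
            out,
            boundary=boundary,
            thg=thg,
            top_fraction=cfg["dura_top_fraction"],
            sd_factor=cfg["dura_sd_factor"],
        )
    out = normalize_stack(out, saturation_fraction=cfg["saturation_fraction"])
    out = denoise(out, method=cfg["denoise_method"], radius=cfg["denoise_radius"])
    return out
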