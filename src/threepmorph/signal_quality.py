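"""Image-quality metrics: signal strength, signal-to-background ratio (SBR),
full-width-at-half-maximum resolution, and their depth profiles.

Signal strength of a frame is the mean of its top 0.5% brightest pixels.
SBR of a 1D intensity profile is the mean of its 15 brightest over the mean
of its 15 darkest samples; the default profile is the image row through the
brightest pixel of each plane (a line profile through the brightest vessel).
Both depend only on the intensity multiset, so they are permutation
invariant, strength scales linearly and SBR is invariant under positive
rescaling.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .stack_io import ImageStack

logger = logging.getLogger("threepmorph")


def signal_strength(plane, top_fraction: float = 0.005) -> float:
    """Mean of the k = max(1, floor(top_fraction·N)) brightest pixels."""
    v = np.asarray(plane, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("signal strength undefined for an empty plane")
    k = max(1, math.floor(top_fraction * v.size))
    top = np.partition(v, v.size - k)[v.size - k :]
    return float(top.mean())


def sbr(profile, n_extreme: int = 15) -> float:
    """Mean of the ``n_extreme`` brightest over the ``n_extreme`` darkest samples.

    Returns ``inf`` (with a warning) when the darkest mean is zero.
    """
    v = np.asarray(profile, dtype=float).ravel()
    if v.size < 2 * n_extreme:
        raise ValueError(
            f"SBR requires at least {2 * n_extreme} samples, got {v.size}"
        )
    srt = np.sort(v)
    dark = srt[:n_extreme].mean()
    bright = srt[-n_extreme:].mean()
    if dark == 0:
        logger.debug("SBR: darkest-%d mean is zero; reporting infinite SBR", n_extreme)
        return float("inf")
    return float(bright / dark)


def profile_line(plane: np.ndarray) -> np.ndarray:
    """Default line profile: the image row through the plane's brightest pixel."""
    plane = np.asarray(plane, dtype=float)
    iy, ix = np.unravel_index(int(np.argmax(plane)), plane.shape)
    return plane[iy]


def depth_profile(
    stack: ImageStack,
    top_fraction: float = 0.005,
    n_extreme: int = 15,
) -> pd.DataFrame:
    """Per-plane signal strength and SBR versus depth.

    Depth is the z index times the axial spacing (origin at the first plane
    of the — typically dura-removed — stack). SBR is computed on the row
    through each plane's brightest pixel; NaN where the plane is too small.
    """
    records = []
    dz = stack.spacing.dz
    for k, plane in enumerate(stack.voxels):
        line = profile_line(plane)
        try:
            plane_sbr = sbr(line, n_extreme=n_extreme)
        except ValueError:
            plane_sbr = float("nan")
        records.append(
            {
                "z": k,
                "depth_um": k * dz,
                "signal_strength": signal_strength(plane, top_fraction),
                "sbr": plane_sbr,
                "channel": stack.channel,
            }
        )
    return pd.DataFrame.from_records(records)


def fwhm(profile, spacing: float = 1.0) -> float:
    """Full width at half maximum of a single-peak 1D profile.

    Baseline = profile minimum; the half level is baseline + (max−baseline)/2;
    the two half-level crossings are located by linear interpolation between
    bracketing samples and their distance is returned in physical units.
    Raises when the peak is truncated (no crossing on one side).
    """
    v = np.asarray(profile, dtype=float).ravel()
    if v.size < 3:
        raise ValueError("FWHM requires at least 3 samples")
    baseline = v.min()
    peak = int(np.argmax(v))
    if v[peak] == baseline:
        raise ValueError("FWHM undefined: flat profile")
    half = baseline + (v[peak] - baseline) / 2.0

    def cross(idx_range, forward: bool) -> float:
        prev = peak
        for i in idx_range:
            if v[i] < half <= v[prev] or (v[i] < half and v[prev] >= half):
                # linear interpolation between samples i and prev
                frac = (half - v[i]) / (v[prev] - v[i])
                return i + frac * (prev - i)
            prev = i
        raise ValueError(
            "FWHM undefined: peak truncated (no half-maximum crossing on the "
            + ("right" if forward else "left")
            + " side)"
        )

    left = cross(range(peak - 1, -1, -1), forward=False)
    right = cross(range(peak + 1, v.size), forward=True)
    return float((right - left) * spacing)


def fit_attenuation_length(depths_um, strengths, background: float = 0.0) -> float:
    """Effective attenuation length (μm) from a depth profile.

    Fits log(strength − background) linearly against depth and returns
    −1/slope; assumes a single-exponential decay of signal with depth.
    """
    d = np.asarray(depths_um, dtype=float)
    s = np.asarray(strengths, dtype=float) - background
    sel = s > 0
    if sel.sum() < 2:
        raise ValueError("attenuation fit requires at least 2 positive samples")
    slope = np.polyfit(d[sel], np.log(s[sel]), 1)[0]
    if slope >= 0:
        return float("inf")
    return float(-1.0 / slope)
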