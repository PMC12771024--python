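"""Shared phantom fixtures. Everything is generated programmatically."""

import numpy as np
import pytest

import threepmorph as tpm


@pytest.fixture(scope="session")
def demo_phantom():
    """Noiseless 256×256×64 two-channel phantom: 5 tubes, 3 spheres, attenuation."""
    return tpm.generate_phantom(tpm.demo_phantom_spec(seed=1))


@pytest.fixture(scope="session")
def noisy_phantom():
    """Same geometry with Gaussian noise SD = 10% of the tube peak intensity."""
    return tpm.generate_phantom(tpm.demo_phantom_spec(seed=2, gaussian_sd=10.0))


def axial_tube_spec(seed: int = 1, jitter=None, **overrides) -> tpm.PhantomSpec:
    """Three perfectly axial (z-penetrating) tubes — the geometry the
    frame-to-frame motion assessment is defined on."""
    tubes = [
        tpm.straight_tube((60.0, 60.0, 10.0), (60.0, 60.0, 300.0), 3.0),
        tpm.straight_tube((180.0, 170.0, 10.0), (180.0, 170.0, 300.0), 4.0),
        tpm.straight_tube((120.0, 220.0, 30.0), (120.0, 220.0, 280.0), 2.5),
    ]
    params = dict(
        shape=(64, 256, 256),
        vessels=tubes,
        attenuation_length=np.inf,
        seed=seed,
        jitter=jitter,
    )
    params.update(overrides)
    return tpm.PhantomSpec(**params)


@pytest.fixture(scope="session")
def axial_phantom():
    return tpm.generate_phantom(axial_tube_spec(seed=1))


@pytest.fixture(scope="session")
def sphere_phantom():
    """Four plaques r = 8–15 μm, no attenuation, mild noise (continuous
    histogram so the multilevel-Otsu path is exercised)."""
    spheres = [
        tpm.PlaqueTruth((60.0, 60.0, 100.0), 8.0),
        tpm.PlaqueTruth((180.0, 70.0, 160.0), 10.0),
        tpm.PlaqueTruth((70.0, 180.0, 220.0), 12.0),
        tpm.PlaqueTruth((180.0, 190.0, 90.0), 15.0),
    ]
    spec = tpm.PhantomSpec(
        shape=(64, 256, 256),
        plaques=spheres,
        attenuation_length=np.inf,
        gaussian_sd=2.0,
        seed=5,
    )
    return tpm.generate_phantom(spec)


def match_segments_to_truth(segset, vessels, min_points: int = 20):
    """Pair each true tube with the measured segment whose centroid is nearest.

    Short spurious segments (noise specks) are ignored via ``min_points``.
    Returns [(VesselTruth, VesselSegment), ...]; raises if a tube has no match.
    """
    candidates = [s for s in segset.segments if len(s.voxels) >= min_points]
    pairs = []
    for tube in vessels:
        t_centroid = tube.centerline.mean(axis=0)
        best = min(
            candidates,
            key=lambda s: float(np.linalg.norm(s.centroid_um - t_centroid)),
        )
        pairs.append((tube, best))
    return pairs
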