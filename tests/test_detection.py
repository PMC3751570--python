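"""Hotspot detection and classification on controlled synthetic inputs."""

import numpy as np
import pytest

from bsitrack.atlas import ViewImage
from bsitrack.detection import (
    DetectionConfig,
    DetectionError,
    Hotspot,
    classify_hotspot,
    detect_hotspots,
)

from .conftest import identity_warp, make_hotspot

HALF_MAX = np.sqrt(2.0 * np.log(2.0))


def plant_gaussian(atlas, center, radius, amplitude_ratio):
    """Template counts with one multiplicative Gaussian focal lesion."""
    px = atlas.anterior.pixels.astype(float)
    sigma = radius / HALF_MAX
    rr = np.arange(px.shape[0])[:, None] - center[0]
    cc = np.arange(px.shape[1])[None, :] - center[1]
    blob = np.exp(-(rr ** 2 + cc ** 2) / (2 * sigma ** 2))
    px *= 1.0 + (amplitude_ratio - 1.0) * blob * atlas.skeleton_mask("anterior")
    return ViewImage(np.rint(px).astype(np.uint16), "anterior")


def add_square(pixels, r0, c0, side=3, boost=1.0):
    pixels = pixels.astype(float)
    pixels[r0:r0 + side, c0:c0 + side] *= (1.0 + boost)
    return pixels


def test_single_planted_blob_recovered_with_area(atlas):
    """A 60 px half-max blob at 2x uptake gives one hotspot, area +/-15%."""
    radius = np.sqrt(60 / np.pi)
    scan = plant_gaussian(atlas, (250, 128), radius, 2.0)
    hotspots = detect_hotspots(scan, identity_warp(atlas.shape), atlas)
    assert len(hotspots) == 1
    assert hotspots[0].area == pytest.approx(60, rel=0.15)
    assert hotspots[0].region_id == 3  # thoracic spine


def test_uniform_scan_yields_no_hotspots(atlas):
    hotspots = detect_hotspots(atlas.anterior, identity_warp(atlas.shape), atlas)
    assert hotspots == []


def test_connectivity_separates_and_merges_blobs(atlas):
    base = atlas.anterior.pixels
    # two 3x3 boosted squares in the lumbar spine, 3 background columns apart
    sep = add_square(add_square(base, 360, 120), 360, 126)
    hs = detect_hotspots(ViewImage(np.rint(sep).astype(np.uint16), "anterior"),
                         identity_warp(atlas.shape), atlas)
    assert len(hs) == 2
    # diagonally adjacent squares are 8-connected: one hotspot
    adj = add_square(add_square(base, 360, 120), 363, 123)
    hs = detect_hotspots(ViewImage(np.rint(adj).astype(np.uint16), "anterior"),
                         identity_warp(atlas.shape), atlas)
    assert len(hs) == 1


def test_detection_invariant_to_global_intensity_scale(atlas):
    radius = np.sqrt(60 / np.pi)
    scan = plant_gaussian(atlas, (250, 128), radius, 2.0)
    scaled = ViewImage(scan.pixels * np.uint16(3), "anterior")
    h1 = detect_hotspots(scan, identity_warp(atlas.shape), atlas)
    h2 = detect_hotspots(scaled, identity_warp(atlas.shape), atlas)
    assert len(h1) == len(h2) == 1
    assert np.array_equal(np.sort(h1[0].pixels, axis=0), np.sort(h2[0].pixels, axis=0))


def test_every_seed_component_is_claimed_by_a_hotspot(atlas):
    """Brute-force oracle: each above-threshold 8-connected component of
    sufficient area contributes its peak to some detected hotspot."""
    from scipy import ndimage

    rng = np.random.default_rng(4)
    scan = atlas.anterior.pixels.astype(float)
    for _ in range(4):
        r = int(rng.integers(200, 320))
        c = int(rng.integers(120, 136))
        scan = add_square(scan, r, c, side=3, boost=1.2)
    scan_img = ViewImage(np.rint(scan).astype(np.uint16), "anterior")
    config = DetectionConfig()
    hotspots = detect_hotspots(scan_img, identity_warp(atlas.shape), atlas, config)
    covered = set()
    for h in hotspots:
        covered.update(map(tuple, h.pixels))

    # independent re-derivation of the seed mask
    ratio = scan / np.median(scan[atlas.anterior_labels.labels == 9])
    smooth = ndimage.gaussian_filter(ratio, config.smooth_sigma)
    labels = atlas.anterior_labels.labels
    seed = np.zeros_like(smooth, dtype=bool)
    for rid in np.unique(labels[labels > 0]):
        med = np.median(smooth[labels == rid])
        seed |= (labels == rid) & (smooth > config.tau * med)
    comp, n = ndimage.label(seed, structure=np.ones((3, 3), int))
    for k in range(1, n + 1):
        coords = np.argwhere(comp == k)
        if len(coords) < config.min_area:
            continue
        peak = coords[np.argmax(smooth[coords[:, 0], coords[:, 1]])]
        assert tuple(peak) in covered


def test_hotspots_sorted_by_area_then_centroid(atlas):
    base = atlas.anterior.pixels
    scan = add_square(add_square(base, 360, 120, side=3), 250, 124, side=5)
    hs = detect_hotspots(ViewImage(np.rint(scan).astype(np.uint16), "anterior"),
                         identity_warp(atlas.shape), atlas)
    areas = [h.area for h in hs]
    assert areas == sorted(areas, reverse=True)


def test_unregistered_scan_rejected(atlas):
    with pytest.raises(DetectionError):
        detect_hotspots(atlas.anterior, None, atlas)


def test_classifier_is_deterministic_and_thresholded():
    strong = make_hotspot((250, 128), area=80,
                          features={"area": 80, "peak_ratio": 2.1, "mean_ratio": 1.7,
                                    "eccentricity": 0.3, "boundary_sharpness": 0.1})
    assert classify_hotspot(strong) == "metastasis"
    assert classify_hotspot(strong) == "metastasis"  # idempotent
    speck = make_hotspot((250, 128), area=4,
                         features={"area": 4, "peak_ratio": 1.45, "mean_ratio": 1.42,
                                   "eccentricity": 0.2, "boundary_sharpness": 0.2})
    assert classify_hotspot(speck) == "not_metastasis"


def test_classifier_requires_features():
    h = make_hotspot((10, 10))
    h.features = None
    with pytest.raises(DetectionError, match="features"):
        classify_hotspot(h)


def test_hotspot_invariants_on_phantom(analyzed_phantom):
    for h in analyzed_phantom["followup"].hotspots:
        assert h.area == len(h.pixels)
        r, c = h.centroid
        assert h.pixels[:, 0].min() <= r <= h.pixels[:, 0].max()
        assert h.pixels[:, 1].min() <= c <= h.pixels[:, 1].max()
        assert h.region_id > 0


def test_invalid_config_rejected():
    with pytest.raises(DetectionError):
        DetectionConfig(tau=0.9)
    with pytest.raises(DetectionError):
        DetectionConfig(min_area=0)
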