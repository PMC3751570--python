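"""Shared fixtures: the bundled atlas and one fully analysed phantom patient.

The analysed phantom (simulate -> register -> detect -> link -> compare) is
expensive, so it is built once per session and reused by the registration,
detection, linking, BSI and pipeline tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from bsitrack import (
    LesionSpec,
    compare_pair,
    default_atlas,
    simulate_patient,
)
from bsitrack.detection import Hotspot
from bsitrack.registration import WarpField


@pytest.fixture(scope="session")
def atlas():
    return default_atlas()


#: one stable lesion + two new lesions, sizes >= 30 px, contrast ~2x
PHANTOM_LESIONS = [
    LesionSpec(region_id=3, seed_point=(250, 128), radius=4.4,
               amplitude_ratio=2.0, present_at=frozenset({0, 1})),
    LesionSpec(region_id=7, seed_point=(490, 100), radius=4.0,
               amplitude_ratio=1.9, present_at=frozenset({1})),
    LesionSpec(region_id=9, seed_point=(650, 95), radius=3.6,
               amplitude_ratio=2.2, present_at=frozenset({1})),
]

PHANTOM_SEED = 20260201


@pytest.fixture(scope="session")
def phantom(atlas):
    """(series, truth) for a progressor with 2 new lesions, 6 mm deformation."""
    return simulate_patient(atlas, PHANTOM_LESIONS, deform_magnitude=6.0,
                            counts_scale=100.0, seed=PHANTOM_SEED)


@pytest.fixture(scope="session")
def analyzed_phantom(atlas, phantom):
    """Full serial comparison of the session phantom."""
    series, truth = phantom
    comparison, base, follow = compare_pair(series.baseline, series.followup, atlas)
    return {"series": series, "truth": truth, "comparison": comparison,
            "baseline": base, "followup": follow}


def identity_warp(shape, view="anterior") -> WarpField:
    return WarpField(np.zeros((2,) + tuple(shape)), view, quality=0.0)


def make_hotspot(centroid, area=25, view="anterior", time_point=0, region_id=3,
                 features=None, label="unclassified") -> Hotspot:
    """Synthetic hotspot with template geometry equal to scan geometry."""
    side = int(np.ceil(np.sqrt(area)))
    r0, c0 = int(centroid[0] - side // 2), int(centroid[1] - side // 2)
    pix = np.array([(r0 + k // side, c0 + k % side) for k in range(area)], dtype=int)
    if features is None:
        features = {"area": area, "peak_ratio": 2.0, "mean_ratio": 1.8,
                    "eccentricity": 0.3, "boundary_sharpness": 0.1}
    h = Hotspot(pixels=pix, view=view, time_point=time_point, region_id=region_id,
                features=features, label=label)
    h.template_pixels = pix.astype(float)
    h.template_centroid = h.template_pixels.mean(axis=0)
    return h
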