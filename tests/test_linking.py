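"""Temporal/cross-view linking: edge rule, partitions, group labels, counting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsitrack.detection import DetectionConfig, score_features
from bsitrack.linking import (
    LesionGroup,
    LinkingConfig,
    LinkingError,
    compare_serial,
    hotspots_connected,
    label_group,
    link_hotspots,
)

from .conftest import make_hotspot


def brute_force_partition(hotspots, atlas, config):
    """Independent oracle: repeated merging until transitive closure."""
    groups = [{i} for i in range(len(hotspots))]
    changed = True
    while changed:
        changed = False
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                if any(hotspots_connected(hotspots[i], hotspots[j], atlas, config)
                       for i in groups[a] for j in groups[b]):
                    groups[a] |= groups[b]
                    del groups[b]
                    changed = True
                    break
            if changed:
                break
    return {frozenset(g) for g in groups}


def partition_of(groups, hotspots):
    index = {id(h): i for i, h in enumerate(hotspots)}
    return {frozenset(index[id(m)] for m in g.members) for g in groups}


def test_nearby_hotspots_form_one_group(atlas):
    a = make_hotspot((250, 128), time_point=0)
    b = make_hotspot((252, 130), time_point=1)
    groups = link_hotspots([a, b], atlas=atlas)
    assert len(groups) == 1
    assert groups[0].time_points_present == {0, 1}


def test_chain_is_transitively_linked(atlas):
    """A-B and B-C edges with A-C distant still give one group of three."""
    a = make_hotspot((250, 128), time_point=0)
    b = make_hotspot((257, 128), time_point=1)
    c = make_hotspot((264, 128), time_point=0)
    assert not hotspots_connected(a, c, atlas)
    groups = link_hotspots([a, b, c], atlas=atlas)
    assert partition_of(groups, [a, b, c]) == brute_force_partition([a, b, c], atlas,
                                                                    LinkingConfig())
    assert len(groups) == 1 and len(groups[0].members) == 3


def test_distant_hotspots_stay_separate(atlas):
    a = make_hotspot((250, 128), time_point=0)
    b = make_hotspot((400, 128), time_point=1)
    assert len(link_hotspots([a, b], atlas=atlas)) == 2


def test_overlap_alone_links(atlas):
    cfg = LinkingConfig(d_max=1e-6, o_min=0.2)
    a = make_hotspot((250, 128), area=36, time_point=0)
    b = make_hotspot((252, 130), area=36, time_point=1)
    assert hotspots_connected(a, b, atlas, cfg)
    far = make_hotspot((270, 128), area=36, time_point=1)
    assert not hotspots_connected(a, far, atlas, cfg)


def test_cross_view_mirror_pairing(atlas):
    ant = make_hotspot((250, 100), view="anterior")
    post = make_hotspot((250, atlas.mirror_column(100)), view="posterior")
    assert hotspots_connected(ant, post, atlas)
    groups = link_hotspots([ant, post], atlas=atlas)
    assert len(groups) == 1
    off = LinkingConfig(cross_view_merge=False)
    assert not hotspots_connected(ant, post, atlas, off)


def test_matches_brute_force_on_random_fixtures(atlas):
    rng = np.random.default_rng(7)
    for trial in range(5):
        n = int(rng.integers(5, 50))
        hotspots = [
            make_hotspot((float(rng.uniform(180, 500)), float(rng.uniform(70, 190))),
                         area=int(rng.integers(9, 49)),
                         view="anterior" if rng.random() < 0.7 else "posterior",
                         time_point=int(rng.integers(0, 2)))
            for _ in range(n)
        ]
        groups = link_hotspots(hotspots, atlas=atlas)
        assert partition_of(groups, hotspots) == brute_force_partition(
            hotspots, atlas, LinkingConfig())
        # the groups partition the hotspot set
        assert sum(len(g.members) for g in groups) == n


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.permutations(list(range(8))))
def test_partition_invariant_under_input_order(perm):
    from bsitrack import default_atlas

    atlas = _cached_atlas_holder.setdefault("atlas", default_atlas())
    centers = [(200 + 9 * k, 120 + (k % 3)) for k in range(8)]
    hotspots = [make_hotspot(c, time_point=k % 2) for k, c in enumerate(centers)]
    ref = partition_of(link_hotspots(hotspots, atlas=atlas), hotspots)
    shuffled = [hotspots[i] for i in perm]
    got = partition_of(link_hotspots(shuffled, atlas=atlas), hotspots)
    assert got == ref


_cached_atlas_holder: dict = {}


def test_adding_hotspot_never_splits_groups(atlas):
    rng = np.random.default_rng(11)
    hotspots = [make_hotspot((float(rng.uniform(180, 460)), float(rng.uniform(80, 180))))
                for _ in range(12)]
    before = partition_of(link_hotspots(hotspots, atlas=atlas), hotspots)
    extra = make_hotspot((300.0, 128.0))
    after_groups = link_hotspots(hotspots + [extra], atlas=atlas)
    index = {id(h): i for i, h in enumerate(hotspots)}
    after = {frozenset(index[id(m)] for m in g.members if id(m) in index)
             for g in after_groups}
    after.discard(frozenset())
    for g in before:
        assert any(g <= h for h in after)


def test_singleton_group_label_reduces_to_hotspot_classifier(atlas):
    h = make_hotspot((250, 128), area=60)
    group = LesionGroup([h], group_id=0)
    from bsitrack.detection import classify_hotspot

    expected = classify_hotspot(make_hotspot((250, 128), area=60))
    assert label_group(group) == expected == h.label


def test_mixed_group_label_matches_hand_pooled_features(atlas):
    f1 = {"area": 60, "peak_ratio": 2.2, "mean_ratio": 1.9,
          "eccentricity": 0.2, "boundary_sharpness": 0.1}
    f2 = {"area": 20, "peak_ratio": 1.3, "mean_ratio": 1.2,
          "eccentricity": 0.6, "boundary_sharpness": 0.05}
    a = make_hotspot((250, 128), area=60, features=f1, time_point=0)
    b = make_hotspot((252, 128), area=20, features=f2, time_point=1)
    group = LesionGroup([a, b], group_id=0)
    label = label_group(group)
    pooled = {k: (60 * f1[k] + 20 * f2[k]) / 80.0
              for k in ("peak_ratio", "mean_ratio", "eccentricity", "boundary_sharpness")}
    pooled["area"] = 40  # 80 px over two acquisitions
    expected_score = score_features(pooled, 3, DetectionConfig())
    expected = "metastasis" if expected_score >= 0.5 else "not_metastasis"
    assert label == expected
    assert a.label == b.label == label


def test_compare_serial_counts_new_metastatic_groups(atlas):
    stable0 = make_hotspot((250, 128), area=60, time_point=0)
    stable1 = make_hotspot((251, 129), area=60, time_point=1)
    new1 = make_hotspot((480, 100), area=50, time_point=1)
    new2 = make_hotspot((650, 95), area=40, time_point=1, region_id=9)
    cmp_ = compare_serial([stable0], [stable1, new1, new2], atlas)
    assert cmp_.n_new_lesions == 2
    assert cmp_.pcwg2_progression is True


def test_single_new_lesion_is_not_progression(atlas):
    base = make_hotspot((250, 128), area=60, time_point=0)
    follow = make_hotspot((251, 128), area=60, time_point=1)
    new1 = make_hotspot((480, 100), area=50, time_point=1)
    cmp_ = compare_serial([base], [follow, new1], atlas)
    assert cmp_.n_new_lesions == 1
    assert cmp_.pcwg2_progression is False


def test_identical_scans_give_zero_new_lesions(atlas):
    base = [make_hotspot((250, 128), area=60, time_point=0),
            make_hotspot((480, 100), area=50, time_point=0)]
    follow = [make_hotspot((250, 128), area=60, time_point=1),
              make_hotspot((480, 100), area=50, time_point=1)]
    cmp_ = compare_serial(base, follow, atlas)
    assert cmp_.n_new_lesions == 0
    assert cmp_.pcwg2_progression is False


def test_same_time_point_rejected(atlas):
    a = make_hotspot((250, 128))
    with pytest.raises(LinkingError, match="differ"):
        compare_serial([a], [a], atlas, baseline_t=1, followup_t=1)


def test_hotspot_without_geometry_and_warp_rejected(atlas):
    h = make_hotspot((250, 128))
    h.template_centroid = None
    h.template_pixels = None
    with pytest.raises(LinkingError, match="warp"):
        link_hotspots([h], atlas=atlas)
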