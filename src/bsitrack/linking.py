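"""Linking hotspots across time points and views; new-lesion counting.

All scans share the template coordinate frame, so hotspots from different
acquisitions can be compared geometrically after mapping their pixels to
template space.  Two same-view hotspots are connected when their template
centroids are close (``<= d_max`` pixels) or their template footprints
overlap (intersection over the smaller footprint ``>= o_min``); an
anterior-posterior edge is added when the mirrored centroids are within
``d_pair``, so one anatomical lesion seen in both views is counted once.
Connected components of this graph are lesion groups; each group receives a
single metastasis/not-metastasis label from the area-weighted pooled features
of its members.

A *new lesion* is a metastatic group present at follow-up with no baseline
member, and progression by the consensus-criterion used in prostate-cancer
trials (PCWG2) means two or more new lesions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atlas import TemplateAtlas
from .bsi import BsiResult, bsi_change, compute_bsi
from .detection import DetectionConfig, Hotspot, score_features


class LinkingError(RuntimeError):
    pass


@dataclass(frozen=True)
class LinkingConfig:
    d_max: float = 8.0          # template px, same-view centroid proximity
    o_min: float = 0.2          # overlap / smaller area
    d_pair: float = 12.0        # template px, cross-view (mirrored) proximity
    cross_view_merge: bool = True

    def __post_init__(self):
        if self.d_max <= 0 or self.d_pair <= 0 or not 0 <= self.o_min <= 1:
            raise LinkingError("invalid linking thresholds")


@dataclass
class LesionGroup:
    members: list[Hotspot]
    group_id: int
    label: str = "unclassified"

    @property
    def time_points_present(self) -> frozenset[int]:
        return frozenset(h.time_point for h in self.members)

    def is_new(self, baseline_t: int, followup_t: int) -> bool:
        present = self.time_points_present
        return followup_t in present and baseline_t not in present


@dataclass
class SerialComparison:
    n_new_lesions: int
    pcwg2_progression: bool
    bsi_baseline: BsiResult
    bsi_followup: BsiResult
    bsi_ratio: float
    bsi_percent_change: float
    bsi_direction: str
    groups: list[LesionGroup]


def _template_geometry(h: Hotspot, warps) -> None:
    if h.template_centroid is not None:
        return
    if warps is None or (h.time_point, h.view) not in warps:
        raise LinkingError(
            f"hotspot at t={h.time_point} view={h.view} has no template coordinates "
            "and no warp was supplied"
        )
    warp = warps[(h.time_point, h.view)]
    h.template_pixels = warp.inverse_points(h.pixels.astype(float), warn_on_fold=False)
    h.template_centroid = h.template_pixels.mean(axis=0)


def hotspots_connected(a: Hotspot, b: Hotspot, atlas: TemplateAtlas,
                       config: LinkingConfig = LinkingConfig()) -> bool:
    """The pairwise edge predicate of the linking graph."""
    ca, cb = a.template_centroid, b.template_centroid
    if a.view == b.view:
        if float(np.hypot(*(ca - cb))) <= config.d_max:
            return True
        pa = {tuple(p) for p in np.rint(a.template_pixels).astype(int)}
        pb = {tuple(p) for p in np.rint(b.template_pixels).astype(int)}
        overlap = len(pa & pb) / min(len(pa), len(pb))
        return overlap >= config.o_min
    if not config.cross_view_merge:
        return False
    mirrored = np.array([cb[0], atlas.mirror_column(cb[1])])
    return float(np.hypot(*(ca - mirrored))) <= config.d_pair


def link_hotspots(
    hotspots: list[Hotspot],
    warps=None,
    atlas: TemplateAtlas | None = None,
    config: LinkingConfig = LinkingConfig(),
) -> list[LesionGroup]:
    """Partition hotspots into lesion groups by connected components.

    ``warps`` maps ``(time_point, view)`` to the scan's warp and is only
    needed for hotspots that do not already carry template-space geometry.
    Groups are returned in deterministic order (by smallest member template
    centroid) regardless of input order.
    """
    if atlas is None:
        raise LinkingError("atlas required for cross-view correspondence")
    hotspots = list(hotspots)
    for h in hotspots:
        _template_geometry(h, warps)

    # order-independent canonical indexing
    order = sorted(range(len(hotspots)),
                   key=lambda i: (tuple(hotspots[i].template_centroid),
                                  hotspots[i].time_point, hotspots[i].view))
    parent = list(range(len(hotspots)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for ii in range(len(order)):
        for jj in range(ii + 1, len(order)):
            i, j = order[ii], order[jj]
            if hotspots_connected(hotspots[i], hotspots[j], atlas, config):
                union(i, j)

    comps: dict[int, list[Hotspot]] = {}
    for i, h in enumerate(hotspots):
        comps.setdefault(find(i), []).append(h)

    groups = [
        LesionGroup(sorted(members, key=lambda h: (tuple(h.template_centroid),
                                                   h.time_point, h.view)),
                    group_id=0)
        for members in comps.values()
    ]
    groups.sort(key=lambda g: tuple(g.members[0].template_centroid))
    for k, g in enumerate(groups):
        g.group_id = k
    return groups


def label_group(group: LesionGroup,
                config: DetectionConfig = DetectionConfig()) -> str:
    """One label for the whole group from area-weighted pooled features.

    A singleton group gets exactly the label its member would get from the
    per-hotspot classifier.
    """
    weights = np.array([float(h.area) for h in group.members])
    weights /= weights.sum()
    pooled = {"area": int(sum(h.area for h in group.members))}
    for key in ("peak_ratio", "mean_ratio", "eccentricity", "boundary_sharpness"):
        pooled[key] = float(sum(w * h.features[key]
                                for w, h in zip(weights, group.members)))
    # pooled area over one time point, not the whole series: average per scan
    n_scans = len({(h.time_point, h.view) for h in group.members})
    pooled["area"] = max(int(round(pooled["area"] / n_scans)), 1)
    rids = [h.region_id for h in group.members]
    rid = int(np.bincount(rids).argmax())
    score = score_features(pooled, rid, config)
    group.label = "metastasis" if score >= 0.5 else "not_metastasis"
    for h in group.members:
        h.label = group.label
        h.score = score
    return group.label


def compare_serial(
    baseline_hotspots: list[Hotspot],
    followup_hotspots: list[Hotspot],
    atlas: TemplateAtlas,
    baseline_t: int = 0,
    followup_t: int = 1,
    linking: LinkingConfig = LinkingConfig(),
    classifier: DetectionConfig = DetectionConfig(),
    view_rule: str = "mean",
) -> SerialComparison:
    """Full serial comparison of two analysed scans.

    Links the two scans' hotspots jointly, labels each group, counts the
    metastatic groups with no baseline member, applies the two-or-more-new-
    lesions progression rule, and computes per-scan BSI and its change.
    """
    if baseline_t == followup_t:
        raise LinkingError("baseline and follow-up time points must differ")
    for h in baseline_hotspots:
        h.time_point = baseline_t
    for h in followup_hotspots:
        h.time_point = followup_t

    groups = link_hotspots(baseline_hotspots + followup_hotspots,
                           atlas=atlas, config=linking)
    for g in groups:
        label_group(g, classifier)

    n_new = sum(1 for g in groups
                if g.label == "metastasis" and g.is_new(baseline_t, followup_t))

    bsi_b = compute_bsi(baseline_hotspots, atlas, view_rule)
    bsi_f = compute_bsi(followup_hotspots, atlas, view_rule)
    change = bsi_change(bsi_b, bsi_f)
    return SerialComparison(
        n_new_lesions=n_new,
        pcwg2_progression=n_new >= 2,
        bsi_baseline=bsi_b,
        bsi_followup=bsi_f,
        bsi_ratio=change.ratio,
        bsi_percent_change=change.percent_change,
        bsi_direction=change.direction,
        groups=groups,
    )
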