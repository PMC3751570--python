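"""Bone Scan Index: skeletal tumour burden as a percentage of skeletal mass.

Each hotspot classified as metastatic contributes ``(a / A_r) * w_r``, where
``a`` is the hotspot area in pixels, ``A_r`` the pixel area of its skeletal
region in the same view, and ``w_r`` the region's fraction of total skeletal
weight.  The quotient ``a / A_r`` estimates the volumetric fraction of the
region occupied by the lesion; weighting by ``w_r`` converts it to a fraction
of the whole skeleton.  The BSI is 100 times the sum over all lesions.

Regions seen in both planar views would be double counted if the per-view
contributions were simply added; by default the anterior and posterior
contributions of a region are averaged (``view_rule="mean"``).  ``"max"`` and
``"sum"`` are available for sensitivity analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .atlas import TemplateAtlas, region_area


class BsiError(ValueError):
    pass


VIEW_RULES = ("mean", "max", "sum")


@dataclass(frozen=True)
class BsiResult:
    """BSI for one scan with its per-region breakdown."""

    #: raw per-(region, view) contributions: (region_id, view, sum a/A_r * w_r)
    per_view: tuple[tuple[int, str, float], ...]
    #: per-region contributions after view combination: (region_id, fraction)
    per_region: tuple[tuple[int, float], ...]
    total_bsi: float          # percentage of total skeletal mass
    n_metastatic_hotspots: int
    view_rule: str = "mean"


@dataclass(frozen=True)
class BsiChange:
    ratio: float              # BSI_followup / BSI_baseline (nan when undefined)
    percent_change: float     # 100 * (ratio - 1)
    direction: str            # increase | decrease | unchanged


def compute_bsi(hotspots, atlas: TemplateAtlas, view_rule: str = "mean") -> BsiResult:
    """BSI of one scan from its labelled hotspots.

    Hotspots labelled ``not_metastasis`` (or left unclassified) contribute
    nothing.  Region areas ``A_r`` are taken in the hotspot's own view.
    """
    if view_rule not in VIEW_RULES:
        raise BsiError(f"view_rule must be one of {VIEW_RULES}")
    per_view: dict[tuple[int, str], float] = {}
    n_met = 0
    for h in hotspots:
        if h.label != "metastasis":
            continue
        n_met += 1
        try:
            info = atlas.labels(h.view).region(h.region_id)
            a_r = region_area(atlas, h.region_id, h.view)
        except KeyError as exc:
            raise BsiError(f"hotspot in unknown region {h.region_id}") from exc
        key = (h.region_id, h.view)
        per_view[key] = per_view.get(key, 0.0) + (h.area / a_r) * info.weight_fraction

    combined: dict[int, float] = {}
    for rid in {k[0] for k in per_view}:
        info = atlas.anterior_labels.region(rid)
        vals = [per_view.get((rid, v), 0.0) for v in info.views]
        if view_rule == "mean":
            combined[rid] = sum(vals) / len(vals)
        elif view_rule == "max":
            combined[rid] = max(vals)
        else:
            combined[rid] = sum(vals)

    total = 100.0 * sum(combined.values())
    return BsiResult(
        per_view=tuple(sorted((rid, v, c) for (rid, v), c in per_view.items())),
        per_region=tuple(sorted(combined.items())),
        total_bsi=total,
        n_metastatic_hotspots=n_met,
        view_rule=view_rule,
    )


def bsi_change(baseline: BsiResult | float, followup: BsiResult | float) -> BsiChange:
    """Change in BSI between baseline and follow-up.

    Conventions: a zero baseline with positive follow-up has an undefined
    ratio (reported as nan) but counts as an increase; two zero scans are
    unchanged with 0% change.  Direction requires exact (in)equality.
    """
    b = baseline.total_bsi if isinstance(baseline, BsiResult) else float(baseline)
    f = followup.total_bsi if isinstance(followup, BsiResult) else float(followup)
    if b < 0 or f < 0:
        raise BsiError("BSI values cannot be negative")
    if b == 0:
        if f == 0:
            return BsiChange(ratio=1.0, percent_change=0.0, direction="unchanged")
        return BsiChange(ratio=math.nan, percent_change=math.nan, direction="increase")
    ratio = f / b
    pct = 100.0 * (ratio - 1.0)
    direction = "increase" if pct > 0 else ("decrease" if pct < 0 else "unchanged")
    return BsiChange(ratio=ratio, percent_change=pct, direction=direction)
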