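"""Synthetic serial bone-scan phantom with known ground truth.

Real serial bone scans cannot be redistributed, so every downstream stage is
exercised on simulated patients instead: the template skeleton's uptake map,
focal lesions of configurable size and contrast, a smooth random anatomical
deformation unique to each time point, and Poisson counting noise (planar
scintigraphy counts are Poisson to a very good approximation).

A lesion is an isotropic Gaussian focal multiplier on top of bone uptake,
clipped to the skeleton.  Its ``radius`` is the half-maximum radius, so the
ground-truth mask (the disk ``r <= radius``) matches the full-width-at-half-
maximum support that an intensity-based detector measures, independently of
lesion contrast.

All randomness flows from a single integer seed through numpy's
``SeedSequence``; sub-streams are derived deterministically per patient, time
point and view, so identical seeds give bit-identical images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .atlas import VIEWS, TemplateAtlas, ViewImage
from .bsi import BsiResult, compute_bsi
from .detection import Hotspot

DEFAULT_COUNTS_SCALE = 100.0   # mean counts per pixel in normal reference bone
DEFAULT_DEFORM_MM = 6.0        # peak anatomical deformation between acquisitions
DEFORM_SMOOTHNESS_PX = 40.0    # Gaussian sigma of the random displacement field

_HALF_MAX = np.sqrt(2.0 * np.log(2.0))  # radius -> Gaussian sigma conversion


class PhantomError(ValueError):
    pass


@dataclass(frozen=True)
class LesionSpec:
    """A planted focal lesion, defined in template coordinates.

    The seed point is given in the anterior view; the posterior position is
    the horizontal mirror (the same anatomical site seen from behind).
    ``present_at`` lists the time-point indices at which the lesion exists.
    """

    region_id: int
    seed_point: tuple[int, int]
    radius: float
    amplitude_ratio: float
    present_at: frozenset[int]

    def __post_init__(self):
        if self.radius < 1:
            raise PhantomError("lesion radius must be >= 1 pixel")
        if self.amplitude_ratio <= 1:
            raise PhantomError("lesion-to-bone uptake ratio must exceed 1")
        object.__setattr__(self, "present_at", frozenset(self.present_at))


@dataclass
class ScanPair:
    """Anterior + posterior views of one acquisition."""

    anterior: ViewImage
    posterior: ViewImage
    time_point: int
    patient_id: str = "phantom"

    def view(self, view: str) -> ViewImage:
        return self.anterior if view == "anterior" else self.posterior


@dataclass
class ScanSeries:
    patient_id: str
    scans: list[ScanPair]

    @property
    def baseline(self) -> ScanPair:
        return min(self.scans, key=lambda s: s.time_point)

    @property
    def followup(self) -> ScanPair:
        return max(self.scans, key=lambda s: s.time_point)


@dataclass
class PhantomTruth:
    """Ground truth for one simulated patient."""

    lesions: list[LesionSpec]
    #: masks[time_point][view] -> list of boolean scan-space masks, one per
    #: lesion (None where the lesion is absent at that time point)
    masks: dict[int, dict[str, list[np.ndarray | None]]]
    true_new_lesion_count: int
    true_bsi: dict[int, float]
    #: sampling displacement u per (time_point, view): scan grid -> template
    deformation_fields: dict[tuple[int, str], np.ndarray]
    rng_seed: int


def _lesion_seed_for_view(atlas: TemplateAtlas, spec: LesionSpec, view: str) -> tuple[float, float]:
    r, c = spec.seed_point
    if view == "posterior":
        c = atlas.mirror_column(c)
    return float(r), float(c)


def _validate_lesion(atlas: TemplateAtlas, spec: LesionSpec) -> None:
    for view in VIEWS:
        r, c = _lesion_seed_for_view(atlas, spec, view)
        labels = atlas.labels(view).labels
        if not (0 <= r < labels.shape[0] and 0 <= c < labels.shape[1]):
            raise PhantomError(f"lesion seed {spec.seed_point} outside image in {view} view")
        if labels[int(round(r)), int(round(c))] != spec.region_id:
            raise PhantomError(
                f"lesion seed {spec.seed_point} not inside region {spec.region_id} "
                f"in {view} view"
            )


def _gaussian_blob(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    sigma = radius / _HALF_MAX
    rr = np.arange(shape[0])[:, None] - center[0]
    cc = np.arange(shape[1])[None, :] - center[1]
    return np.exp(-(rr * rr + cc * cc) / (2.0 * sigma * sigma))


def _smooth_displacement(shape: tuple[int, int], magnitude_px: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Gaussian-filtered white-noise displacement field with given peak magnitude."""
    if magnitude_px == 0:
        return np.zeros((2,) + shape)
    field = rng.standard_normal((2,) + shape)
    for k in range(2):
        field[k] = ndimage.gaussian_filter(field[k], sigma=DEFORM_SMOOTHNESS_PX)
    mag = np.sqrt(field[0] ** 2 + field[1] ** 2)
    peak = mag.max()
    if peak > 0:
        field *= magnitude_px / peak
    return field


def _warp_by_sampling(image: np.ndarray, u: np.ndarray, order: int) -> np.ndarray:
    """out(y) = image(y + u(y)) — sampling-field warp."""
    rows, cols = np.meshgrid(
        np.arange(image.shape[0], dtype=float),
        np.arange(image.shape[1], dtype=float),
        indexing="ij",
    )
    coords = np.stack([rows + u[0], cols + u[1]])
    return ndimage.map_coordinates(image, coords, order=order, mode="nearest")


def _truth_bsi(atlas: TemplateAtlas,
               masks_by_view: dict[str, list[np.ndarray | None]],
               lesions: list[LesionSpec]) -> float:
    """Apply the BSI formula directly to the planted scan-space masks."""
    pseudo: list[Hotspot] = []
    for view in VIEWS:
        for spec, mask in zip(lesions, masks_by_view[view]):
            if mask is None or not mask.any():
                continue
            rr, cc = np.nonzero(mask)
            pseudo.append(
                Hotspot(
                    pixels=np.column_stack([rr, cc]),
                    view=view,
                    time_point=0,
                    region_id=spec.region_id,
                    label="metastasis",
                )
            )
    return compute_bsi(pseudo, atlas).total_bsi


def simulate_patient(
    atlas: TemplateAtlas,
    lesions: list[LesionSpec],
    deform_magnitude: float = DEFAULT_DEFORM_MM,
    counts_scale: float | None = DEFAULT_COUNTS_SCALE,
    seed: int = 0,
    n_time_points: int = 2,
    patient_id: str = "phantom",
) -> tuple[ScanSeries, PhantomTruth]:
    """Simulate one patient's serial scans plus ground truth.

    Per time point and view the activity map is the template uptake with the
    planted lesions applied, warped by a smooth random deformation unique to
    that time point, then Poisson-sampled.  ``counts_scale=None`` disables
    noise (deterministic mode: the rounded activity map is returned and the
    template's own count scale is kept).

    ``deform_magnitude`` is the peak displacement in millimetres.
    """
    if n_time_points < 1:
        raise PhantomError("at least one time point required")
    if deform_magnitude < 0:
        raise PhantomError("deform_magnitude must be >= 0")
    for spec in lesions:
        _validate_lesion(atlas, spec)

    magnitude_px = deform_magnitude / atlas.pixel_spacing
    ss = np.random.SeedSequence(seed)
    scans: list[ScanPair] = []
    masks: dict[int, dict[str, list[np.ndarray | None]]] = {}
    fields: dict[tuple[int, str], np.ndarray] = {}
    true_bsi: dict[int, float] = {}

    for t in range(n_time_points):
        per_view_images: dict[str, ViewImage] = {}
        masks[t] = {}
        for view in VIEWS:
            tpl = atlas.image(view)
            skeleton = atlas.skeleton_mask(view)
            scale = 1.0 if counts_scale is None else (
                counts_scale / max(float(np.median(tpl.pixels[skeleton])), 1.0)
            )
            activity = tpl.pixels.astype(float) * scale

            lesion_masks_tpl: list[np.ndarray | None] = []
            multiplier = np.ones_like(activity)
            for spec in lesions:
                if t not in spec.present_at:
                    lesion_masks_tpl.append(None)
                    continue
                center = _lesion_seed_for_view(atlas, spec, view)
                blob = _gaussian_blob(activity.shape, center, spec.radius)
                multiplier += (spec.amplitude_ratio - 1.0) * blob * skeleton
                rr = np.arange(activity.shape[0])[:, None] - center[0]
                cc = np.arange(activity.shape[1])[None, :] - center[1]
                disk = (rr * rr + cc * cc) <= spec.radius ** 2
                lesion_masks_tpl.append(disk & skeleton)
            activity *= multiplier

            # deterministic sub-stream per (time point, view)
            child = np.random.SeedSequence(
                entropy=ss.entropy, spawn_key=(t, VIEWS.index(view))
            )
            rng = np.random.default_rng(child)

            u = _smooth_displacement(activity.shape, magnitude_px, rng)
            fields[(t, view)] = u
            warped = _warp_by_sampling(activity, u, order=1)
            warped_masks: list[np.ndarray | None] = []
            for m in lesion_masks_tpl:
                if m is None:
                    warped_masks.append(None)
                else:
                    warped_masks.append(_warp_by_sampling(m.astype(float), u, order=1) > 0.5)
            masks[t][view] = warped_masks

            if counts_scale is None:
                counts = np.rint(warped).astype(np.uint16)
            else:
                counts = rng.poisson(np.clip(warped, 0, None)).astype(np.uint16)
            per_view_images[view] = ViewImage(counts, view, tpl.pixel_spacing)

        scans.append(ScanPair(per_view_images["anterior"], per_view_images["posterior"],
                              time_point=t, patient_id=patient_id))
        true_bsi[t] = _truth_bsi(atlas, masks[t], lesions)

    baseline_t, followup_t = 0, n_time_points - 1
    n_new = sum(
        1 for spec in lesions
        if followup_t in spec.present_at and baseline_t not in spec.present_at
    )
    truth = PhantomTruth(
        lesions=list(lesions),
        masks=masks,
        true_new_lesion_count=n_new,
        true_bsi=true_bsi,
        deformation_fields=fields,
        rng_seed=seed,
    )
    return ScanSeries(patient_id, scans), truth


# ---------------------------------------------------------------------------
# Lesion placement and cohort simulation
# ---------------------------------------------------------------------------

#: regions eligible for random lesion placement (large enough to host a blob)
PLACEMENT_REGIONS = (3, 4, 5, 7, 9, 1)

MIN_LESION_SEPARATION_PX = 26.0

# distance-to-region-border maps, cached per atlas (placement is hot in
# cohort simulation); the atlas reference pins the id
_DIST_CACHE: dict[int, tuple] = {}


def _interior_distance_maps(atlas: TemplateAtlas) -> dict[int, np.ndarray]:
    key = id(atlas)
    if key not in _DIST_CACHE:
        labels = atlas.anterior_labels.labels
        maps = {rid: ndimage.distance_transform_edt(labels == rid)
                for rid in PLACEMENT_REGIONS}
        _DIST_CACHE[key] = (atlas, maps)
    return _DIST_CACHE[key][1]


def sample_lesion_sites(
    atlas: TemplateAtlas,
    n: int,
    radius_range: tuple[float, float],
    rng: np.random.Generator,
    existing: list[tuple[float, float]] | None = None,
) -> list[tuple[int, tuple[int, int], float]]:
    """Sample ``n`` well-separated lesion sites: (region_id, seed, radius).

    Sites keep ``radius + 2`` pixels clear of the region border (so the
    planted disk stays inside the skeleton in both views) and at least
    ``MIN_LESION_SEPARATION_PX`` from each other.
    """
    taken = list(existing or [])
    out = []
    dist_in = _interior_distance_maps(atlas)
    for _ in range(n):
        for _attempt in range(400):
            rid = int(rng.choice(PLACEMENT_REGIONS))
            radius = float(rng.uniform(*radius_range))
            candidates = np.argwhere(dist_in[rid] >= radius + 2)
            if len(candidates) == 0:
                continue
            r, c = candidates[rng.integers(len(candidates))]
            if all((r - tr) ** 2 + (c - tc) ** 2 >= MIN_LESION_SEPARATION_PX ** 2
                   for tr, tc in taken):
                taken.append((float(r), float(c)))
                out.append((rid, (int(r), int(c)), radius))
                break
        else:
            raise PhantomError("could not place a well-separated lesion")
    return out


def simulate_cohort(
    n_patients: int,
    progression_prevalence: float = 0.5,
    new_lesion_count_distribution: dict | None = None,
    survival_model: tuple[float, float] = (0.04, 0.005),
    seed: int = 0,
    deform_magnitude: float = DEFAULT_DEFORM_MM,
    counts_scale: float | None = DEFAULT_COUNTS_SCALE,
    radius_range: tuple[float, float] = (3.2, 5.0),
    amplitude_range: tuple[float, float] = (1.8, 2.4),
    censor_horizon_months: float = 60.0,
    atlas: TemplateAtlas | None = None,
    imaging: bool = True,
) -> tuple[pd.DataFrame, list[ScanSeries | None], list[PhantomTruth | None]]:
    """Simulate a cohort of patients with baseline + follow-up scans.

    Progressors receive 2-5 new lesions at follow-up; non-progressors 0 or 1.
    Every patient carries 1-3 stable lesions present at both time points so
    that the baseline BSI is positive.  Survival times follow a proportional-
    hazards model with the true percentage BSI change as covariate:
    ``h(t) = h0 * exp(beta * pct_change)``; administrative censoring at
    ``censor_horizon_months``.

    ``imaging=False`` skips image synthesis (the truth-derived covariates and
    survival outcomes are still produced), which is enough for studying the
    survival machinery on its own.
    """
    if not 0 <= progression_prevalence <= 1:
        raise PhantomError("prevalence must lie in [0, 1]")
    if n_patients < 1:
        raise PhantomError("need at least one patient")
    dist = new_lesion_count_distribution or {"kind": "uniform_int", "low": 2, "high": 5}
    if dist.get("kind") != "uniform_int" or dist.get("low", 0) < 2:
        raise PhantomError(f"unsupported new-lesion distribution spec: {dist!r}")
    h0, beta = survival_model
    if h0 <= 0:
        raise PhantomError("baseline hazard must be positive")

    if atlas is None:
        from .atlas import default_atlas
        atlas = default_atlas()

    master = np.random.SeedSequence(seed)
    rows = []
    series_list: list[ScanSeries | None] = []
    truth_list: list[PhantomTruth | None] = []
    for k in range(n_patients):
        pat_ss = np.random.SeedSequence(entropy=master.entropy, spawn_key=(1000 + k,))
        rng = np.random.default_rng(pat_ss)
        progressor = bool(rng.random() < progression_prevalence)
        n_new = int(rng.integers(dist["low"], dist["high"] + 1)) if progressor \
            else int(rng.integers(0, 2))
        n_stable = int(rng.integers(1, 4))

        sites = sample_lesion_sites(atlas, n_stable + n_new, radius_range, rng)
        lesions = []
        for i, (rid, pt, rad) in enumerate(sites):
            amp = float(rng.uniform(*amplitude_range))
            present = frozenset({0, 1}) if i < n_stable else frozenset({1})
            lesions.append(LesionSpec(rid, pt, rad, amp, present))

        patient_seed = int(pat_ss.generate_state(1)[0] % (2**31))
        pid = f"patient_{k:03d}"
        if imaging:
            series, truth = simulate_patient(
                atlas, lesions, deform_magnitude, counts_scale,
                seed=patient_seed, patient_id=pid,
            )
        else:
            series, truth = None, None

        # covariates from planted truth (independent of the imaging pipeline)
        bsi0 = _planted_bsi(atlas, [l for l in lesions if 0 in l.present_at])
        bsi1 = _planted_bsi(atlas, [l for l in lesions if 1 in l.present_at])
        pct_change = 100.0 * (bsi1 / bsi0 - 1.0) if bsi0 > 0 else 0.0

        hazard = h0 * np.exp(beta * pct_change)
        t_event = float(rng.exponential(1.0 / hazard))
        time = min(t_event, censor_horizon_months)
        event = t_event <= censor_horizon_months

        rows.append({
            "patient_id": pid,
            "progressor": progressor,
            "true_new_lesions": n_new,
            "true_bsi_baseline": bsi0,
            "true_bsi_followup": bsi1,
            "bsi_pct_change": pct_change,
            "time_months": time,
            "event": event,
            "seed": patient_seed,
        })
        series_list.append(series)
        truth_list.append(truth)

    return pd.DataFrame(rows), series_list, truth_list


def _disk_area_in_skeleton(atlas: TemplateAtlas, spec: LesionSpec, view: str) -> int:
    """Pixel area of the planted (undeformed) disk, clipped to the skeleton."""
    cr, cc0 = _lesion_seed_for_view(atlas, spec, view)
    r = spec.radius
    h, w = atlas.shape
    r0, r1 = max(int(cr - r) - 1, 0), min(int(cr + r) + 2, h)
    c0, c1 = max(int(cc0 - r) - 1, 0), min(int(cc0 + r) + 2, w)
    rr = np.arange(r0, r1)[:, None] - cr
    cc = np.arange(c0, c1)[None, :] - cc0
    disk = (rr * rr + cc * cc) <= r * r
    skel = atlas.labels(view).labels[r0:r1, c0:c1] > 0
    return int((disk & skel).sum())


def _planted_bsi(atlas: TemplateAtlas, lesions: list[LesionSpec]) -> float:
    """BSI of the undeformed planted disks (mean view-combination rule)."""
    from .atlas import region_area

    per_view: dict[tuple[int, str], float] = {}
    for view in VIEWS:
        for spec in lesions:
            a = _disk_area_in_skeleton(atlas, spec, view)
            w_r = atlas.anterior_labels.region(spec.region_id).weight_fraction
            key = (spec.region_id, view)
            per_view[key] = per_view.get(key, 0.0) + a / region_area(
                atlas, spec.region_id, view) * w_r
    combined: dict[int, float] = {}
    for (rid, _view), c in per_view.items():
        combined[rid] = combined.get(rid, 0.0) + c / 2.0
    return 100.0 * sum(combined.values())
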