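"""Hotspot detection and metastasis/non-metastasis classification.

A hotspot is an 8-connected region of focally increased tracer uptake.
Detection is ratio-based and therefore invariant to the global count scale:

1.  The scan is normalised by the median count over a reference normal bone
    region (the femoral shafts), giving an uptake-ratio image.
2.  The ratio image is smoothed (1 px Gaussian) and thresholded per skeletal
    region at ``tau`` times the regional median ratio; skeletal regions are
    carried over from the template through the estimated warp.
3.  Each seed component is refined to its full-width-at-half-maximum support
    (pixels above the midpoint between the component peak and the regional
    baseline), so the measured area does not grow with lesion contrast.

Classification replaces the proprietary learned classifier of the original
system with a transparent linear scoring rule over hotspot features (mean and
peak uptake ratio, area, eccentricity, boundary sharpness) with per-region
intercepts; any callable with the same signature can be plugged in instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import measure

from .atlas import REFERENCE_REGION_ID, TemplateAtlas, ViewImage
from .registration import WarpField


class DetectionError(RuntimeError):
    pass


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable detection / classification parameters (all ratio-scale)."""

    tau: float = 1.4              # regional threshold multiplier
    min_area: int = 4             # px, smallest hotspot kept
    smooth_sigma: float = 1.0     # px, pre-threshold Gaussian
    # linear classifier: score = sigmoid(intercept + region offset + w . f)
    intercept: float = -4.0
    w_mean_ratio: float = 2.0     # per unit of (mean ratio - 1)
    w_peak_ratio: float = 0.5     # per unit of (peak ratio - 1)
    w_log_area: float = 1.0       # per log-pixel of area
    w_eccentricity: float = 0.0
    w_sharpness: float = 0.0
    region_offsets: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.tau <= 1 or self.min_area < 1 or self.smooth_sigma < 0:
            raise DetectionError("invalid detection thresholds")


@dataclass
class Hotspot:
    """One detected focal-uptake component in a single scan view."""

    pixels: np.ndarray                  # (n, 2) int scan-space (row, col)
    view: str
    time_point: int
    region_id: int
    features: dict | None = None
    label: str = "unclassified"
    score: float | None = None
    template_pixels: np.ndarray | None = None   # (n, 2) float, template space
    template_centroid: np.ndarray | None = None
    scan_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.shape[1] != 2 or len(self.pixels) == 0:
            raise DetectionError("hotspot pixel set must be a nonempty (n, 2) array")

    @property
    def area(self) -> int:
        return len(self.pixels)

    @property
    def centroid(self) -> tuple[float, float]:
        return tuple(self.pixels.mean(axis=0))


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def classify_hotspot(hotspot: Hotspot, config: DetectionConfig = DetectionConfig()) -> str:
    """Deterministic metastasis/not-metastasis label from the linear scorer."""
    score = score_features(hotspot.features, hotspot.region_id, config)
    hotspot.score = score
    hotspot.label = "metastasis" if score >= 0.5 else "not_metastasis"
    return hotspot.label


def score_features(features: dict | None, region_id: int,
                   config: DetectionConfig = DetectionConfig()) -> float:
    """Linear scoring rule shared by per-hotspot and per-group labelling."""
    if not features:
        raise DetectionError("hotspot features missing; run detect_hotspots first")
    z = (
        config.intercept
        + config.region_offsets.get(region_id, 0.0)
        + config.w_mean_ratio * (features["mean_ratio"] - 1.0)
        + config.w_peak_ratio * (features["peak_ratio"] - 1.0)
        + config.w_log_area * np.log(max(features["area"], 1))
        + config.w_eccentricity * features.get("eccentricity", 0.0)
        + config.w_sharpness * features.get("boundary_sharpness", 0.0)
    )
    return float(_sigmoid(z))


def normalized_ratio_image(scan: ViewImage, labels_scan: np.ndarray) -> np.ndarray:
    """Counts divided by the median count over the reference bone region."""
    ref = scan.pixels[labels_scan == REFERENCE_REGION_ID]
    if ref.size == 0 or np.median(ref) <= 0:
        raise DetectionError("reference region empty or zero; cannot normalise")
    return scan.pixels.astype(float) / float(np.median(ref))


def warp_labels_to_scan(warp: WarpField, atlas: TemplateAtlas, view: str) -> np.ndarray:
    """Template region labels resampled into scan space (nearest neighbour)."""
    inv = warp.inverse_grid()
    return ndimage.map_coordinates(atlas.labels(view).labels, inv, order=0, mode="constant")


def _fwhm_support(smooth, in_region, peak_rc, peak, base, frac, min_area):
    """Connected support above ``base + frac*(peak-base)``, within one region."""
    level = base + frac * (peak - base)
    mask = (smooth >= level) & in_region
    if not mask[peak_rc]:
        return None
    lab, _ = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    support = lab == lab[peak_rc]
    return support if support.sum() >= min_area else None


def detect_hotspots(
    scan: ViewImage,
    warp: WarpField,
    atlas: TemplateAtlas,
    config: DetectionConfig = DetectionConfig(),
    time_point: int = 0,
    scan_id: str = "",
) -> list[Hotspot]:
    """Detect hotspots in one scan view.

    Requires the scan's warp (region assignment and template coordinates come
    from it).  Returns hotspots sorted by area descending, ties broken by
    centroid (row, col); labels are left ``unclassified``.
    """
    if warp is None:
        raise DetectionError("scan must be registered before detection")
    if warp.shape != scan.pixels.shape:
        raise DetectionError("warp does not match this scan's geometry")
    if warp.view != scan.view:
        raise DetectionError("warp/scan view mismatch")

    labels_scan = warp_labels_to_scan(warp, atlas, scan.view)
    ratio = normalized_ratio_image(scan, labels_scan)
    smooth = ndimage.gaussian_filter(ratio, sigma=config.smooth_sigma)

    region_ids = [r.region_id for r in atlas.regions()]
    regional_median = {}
    seed_mask = np.zeros(smooth.shape, dtype=bool)
    for rid in region_ids:
        in_region = labels_scan == rid
        if not in_region.any():
            continue
        med = float(np.median(smooth[in_region]))
        regional_median[rid] = med
        seed_mask |= in_region & (smooth > config.tau * med)

    seed_labels = measure.label(seed_mask, connectivity=2)
    grad = np.hypot(*np.gradient(smooth))
    hotspots: list[Hotspot] = []
    claimed = np.zeros(smooth.shape, dtype=bool)
    skeleton_scan = labels_scan > 0

    for comp in measure.regionprops(seed_labels):
        if comp.area < config.min_area:
            continue
        rows, cols = comp.coords[:, 0], comp.coords[:, 1]
        peak_idx = np.argmax(smooth[rows, cols])
        peak_rc = (rows[peak_idx], cols[peak_idx])
        if claimed[peak_rc]:
            continue  # already absorbed into an earlier hotspot's FWHM support

        # majority region of the seed component sets the baseline; the
        # support is confined to that region so the half-level flood cannot
        # leak into a neighbouring region whose normal uptake exceeds it
        comp_regions = labels_scan[rows, cols]
        comp_regions = comp_regions[comp_regions > 0]
        if comp_regions.size == 0:
            continue
        rid = int(np.bincount(comp_regions).argmax())
        base = regional_median[rid]
        in_region = labels_scan == rid
        region_sel = in_region[rows, cols]
        if not region_sel.any():
            continue
        peak_idx = np.argmax(np.where(region_sel, smooth[rows, cols], -np.inf))
        peak_rc = (rows[peak_idx], cols[peak_idx])
        peak = float(smooth[peak_rc])

        support = _fwhm_support(smooth, in_region, peak_rc, peak, base,
                                0.5, config.min_area)
        if support is None:
            continue
        # the pre-threshold Gaussian widens the half-maximum footprint; shrink
        # it back assuming a Gaussian focal profile: with sigma_eff^2 estimated
        # from the measured support and sigma_lesion^2 = sigma_eff^2 - sigma_s^2,
        # the unsmoothed half-max level sits at fraction 2^-(sl^2/se^2) of the
        # (peak - base) excess
        se2 = support.sum() / (np.pi * 2.0 * np.log(2.0))
        sl2 = max(se2 - config.smooth_sigma ** 2, 0.25 * config.smooth_sigma ** 2)
        frac = 2.0 ** (-sl2 / se2)
        refined = _fwhm_support(smooth, in_region, peak_rc, peak, base,
                                frac, config.min_area)
        if refined is not None:
            support = refined
        support &= ~claimed
        if support.sum() < config.min_area:
            continue
        claimed |= support

        srows, scols = np.nonzero(support)
        pix = np.column_stack([srows, scols])

        # features on the ratio scale, relative to the regional baseline
        boundary = support & ~ndimage.binary_erosion(support)
        ecc = measure.regionprops(support.astype(int))[0].eccentricity
        features = {
            "area": int(support.sum()),
            "peak_ratio": peak / base,
            "mean_ratio": float(smooth[srows, scols].mean()) / base,
            "eccentricity": float(ecc),
            "boundary_sharpness": float(grad[boundary].mean() / base) if boundary.any() else 0.0,
        }

        tpl_pix = warp.inverse_grid()[:, srows, scols].T
        hotspots.append(
            Hotspot(
                pixels=pix,
                view=scan.view,
                time_point=time_point,
                region_id=rid,
                features=features,
                template_pixels=tpl_pix,
                template_centroid=tpl_pix.mean(axis=0),
                scan_id=scan_id,
            )
        )

    hotspots.sort(key=lambda h: (-h.area, h.centroid))
    return hotspots
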