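"""Template atlas: reference scan, skeletal region segmentation and weight fractions.

The atlas provides the shared coordinate frame for serial comparison.  Every
individual scan is registered to the template; hotspot correspondence across
time points and views, region assignment and the region areas ``A_r`` entering
the Bone Scan Index all live in template space.

The bundled default atlas is synthetic: a stylised adult skeleton painted on
the standard 1024 x 256 whole-body matrix, with smooth per-region uptake.  The
per-region weight fractions ``w_r`` (fraction of total skeletal mass) follow
ICRP reference-man values and are shipped as a plain-text table so users can
substitute their own.

Coordinate convention: row-major, 0-based, origin at the top-left (head at
row 0).  Anterior and posterior views are stored in their native orientation;
cross-view correspondence uses an explicit horizontal mirror
(``mirror_column``).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

VIEWS = ("anterior", "posterior")

#: default pixel spacing in mm (1024 rows ~ 2.3 m scan length)
DEFAULT_PIXEL_SPACING_MM = 2.26

DEFAULT_SHAPE = (1024, 256)


class AtlasError(ValueError):
    """Raised when an atlas violates its invariants or cannot be loaded."""


@dataclass(frozen=True)
class ViewImage:
    """A single planar whole-body view as a non-negative integer count grid."""

    pixels: np.ndarray
    view: str
    pixel_spacing: float = DEFAULT_PIXEL_SPACING_MM

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise AtlasError(f"view image must be 2-D, got shape {px.shape}")
        if self.view not in VIEWS:
            raise AtlasError(f"unknown view {self.view!r}")
        if np.issubdtype(px.dtype, np.floating):
            raise AtlasError("count images must be integer-typed")
        if px.min() < 0:
            raise AtlasError("count images must be non-negative")
        if self.pixel_spacing <= 0:
            raise AtlasError("pixel spacing must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class RegionInfo:
    region_id: int
    name: str
    weight_fraction: float
    views: tuple[str, ...]


@dataclass(frozen=True)
class RegionLabelMap:
    """Integer label grid plus the region table (id, name, w_r, views)."""

    labels: np.ndarray
    region_table: tuple[RegionInfo, ...]

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise AtlasError("label map must be 2-D")
        known = {r.region_id for r in self.region_table}
        present = set(np.unique(labels)) - {0}
        if not present <= known:
            raise AtlasError(f"labels {sorted(present - known)} missing from region table")
        total = sum(r.weight_fraction for r in self.region_table)
        if total > 1.0 + 1e-9:
            raise AtlasError(f"weight fractions sum to {total:.3f} > 1")
        if any(r.weight_fraction <= 0 for r in self.region_table):
            raise AtlasError("weight fractions must be positive")
        object.__setattr__(self, "labels", labels)

    def region(self, region_id: int) -> RegionInfo:
        for r in self.region_table:
            if r.region_id == region_id:
                return r
        raise KeyError(f"unknown region id {region_id}")


@dataclass(frozen=True)
class TemplateAtlas:
    """Reference scan pair with segmentation — the shared coordinate frame."""

    anterior: ViewImage
    posterior: ViewImage
    anterior_labels: RegionLabelMap
    posterior_labels: RegionLabelMap
    version: str = "bsitrack-default-1"
    _area_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if self.anterior.shape != self.posterior.shape:
            raise AtlasError(
                f"anterior {self.anterior.shape} and posterior "
                f"{self.posterior.shape} shapes differ"
            )
        if self.anterior_labels.labels.shape != self.anterior.shape:
            raise AtlasError("anterior label map shape mismatch")
        if self.posterior_labels.labels.shape != self.posterior.shape:
            raise AtlasError("posterior label map shape mismatch")
        by_id: dict[int, RegionInfo] = {}
        for table in (self.anterior_labels.region_table, self.posterior_labels.region_table):
            for r in table:
                prev = by_id.setdefault(r.region_id, r)
                if (prev.name, prev.weight_fraction) != (r.name, r.weight_fraction):
                    raise AtlasError(f"region id {r.region_id} inconsistent between views")
        # each region listed for a view must have nonzero area there
        for view in VIEWS:
            lm = self.labels(view)
            for r in lm.region_table:
                if view in r.views and not (lm.labels == r.region_id).any():
                    raise AtlasError(f"region {r.name} has zero area in {view} view")

    @property
    def shape(self) -> tuple[int, int]:
        return self.anterior.shape

    @property
    def pixel_spacing(self) -> float:
        return self.anterior.pixel_spacing

    def image(self, view: str) -> ViewImage:
        return self.anterior if view == "anterior" else self.posterior

    def labels(self, view: str) -> RegionLabelMap:
        return self.anterior_labels if view == "anterior" else self.posterior_labels

    def regions(self) -> tuple[RegionInfo, ...]:
        return self.anterior_labels.region_table

    def mirror_column(self, col: np.ndarray | float) -> np.ndarray | float:
        """Map a column index to the horizontally mirrored one (cross-view)."""
        return (self.shape[1] - 1) - col

    def skeleton_mask(self, view: str) -> np.ndarray:
        return self.labels(view).labels > 0


def region_area(atlas: TemplateAtlas, region_id: int, view: str) -> int:
    """Pixel area A_r of a skeletal region in one view.

    Raises ``KeyError`` when the region does not exist or has no pixels in
    the requested view.
    """
    if view not in VIEWS:
        raise AtlasError(f"unknown view {view!r}")
    key = (region_id, view)
    if key in atlas._area_cache:
        return atlas._area_cache[key]
    lm = atlas.labels(view)
    lm.region(region_id)  # raises KeyError for unknown ids
    area = int((lm.labels == region_id).sum())
    if area == 0:
        raise KeyError(f"region {region_id} absent from {view} view")
    atlas._area_cache[key] = area
    return area


# ---------------------------------------------------------------------------
# Default synthetic atlas
# ---------------------------------------------------------------------------

# per-region baseline uptake (arbitrary count units before scaling)
_REGION_UPTAKE = {
    1: 110.0,   # skull
    2: 115.0,   # cervical spine
    3: 120.0,   # thoracic spine
    4: 120.0,   # lumbar spine
    5: 90.0,    # ribs + sternum
    6: 95.0,    # scapulae + clavicles
    7: 110.0,   # pelvis + sacrum
    8: 85.0,    # humeri
    9: 100.0,   # femora
    10: 80.0,   # tibiae + fibulae
}

_SOFT_TISSUE = 6.0

#: region used to normalise scan intensities (normal reference bone)
REFERENCE_REGION_ID = 9  # femora


def _ellipse(labels: np.ndarray, rid: int, center, axes) -> None:
    rr, cc = np.ogrid[: labels.shape[0], : labels.shape[1]]
    mask = ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0
    labels[mask & (labels == 0)] = rid


def _bar(labels: np.ndarray, rid: int, rows, cols) -> None:
    block = labels[rows[0] : rows[1], cols[0] : cols[1]]
    block[block == 0] = rid


def _paint_skeleton(shape: tuple[int, int]) -> np.ndarray:
    """Stylised adult skeleton label map (anterior orientation)."""
    labels = np.zeros(shape, dtype=np.uint8)
    h, w = shape
    mid = w // 2
    # painted in priority order; _ellipse/_bar never overwrite earlier labels
    _ellipse(labels, 1, (62, mid), (46, 32))                     # skull
    _bar(labels, 2, (112, 172), (mid - 8, mid + 8))              # cervical spine
    _bar(labels, 3, (172, 332), (mid - 10, mid + 10))            # thoracic spine
    _bar(labels, 4, (332, 432), (mid - 12, mid + 12))            # lumbar spine
    _bar(labels, 6, (142, 152), (mid - 88, mid + 88))            # clavicles
    _ellipse(labels, 6, (188, mid - 72), (36, 18))               # left scapula
    _ellipse(labels, 6, (188, mid + 72), (36, 18))               # right scapula
    _ellipse(labels, 5, (252, mid), (86, 66))                    # rib cage
    _ellipse(labels, 7, (492, mid), (64, 70))                    # pelvis + sacrum
    _bar(labels, 8, (160, 400), (mid - 112, mid - 94))           # left humerus
    _bar(labels, 8, (160, 400), (mid + 94, mid + 112))           # right humerus
    _bar(labels, 9, (556, 800), (mid - 44, mid - 24))            # left femur
    _bar(labels, 9, (556, 800), (mid + 24, mid + 44))            # right femur
    _bar(labels, 10, (800, min(h - 14, 1012)), (mid - 38, mid - 24))  # left tibia/fibula
    _bar(labels, 10, (800, min(h - 14, 1012)), (mid + 24, mid + 38))  # right tibia/fibula
    return labels


def _render_template(labels: np.ndarray, scale: float = 1.0) -> np.ndarray:
    activity = np.full(labels.shape, _SOFT_TISSUE, dtype=float)
    for rid, uptake in _REGION_UPTAKE.items():
        activity[labels == rid] = uptake
    activity = gaussian_filter(activity, sigma=1.2)
    return np.rint(activity * scale).astype(np.uint16)


def _load_region_table(path: Path | None = None) -> tuple[RegionInfo, ...]:
    if path is None:
        src = resources.files("bsitrack.data").joinpath("regions.csv")
        text = src.read_text()
    else:
        text = Path(path).read_text()
    rows = list(csv.DictReader(text.splitlines()))
    table = tuple(
        RegionInfo(
            region_id=int(r["region_id"]),
            name=r["name"],
            weight_fraction=float(r["weight_fraction"]),
            views=tuple(r["views"].split("+")),
        )
        for r in rows
    )
    if not table:
        raise AtlasError("empty region table")
    return table


def default_atlas(shape: tuple[int, int] = DEFAULT_SHAPE,
                  pixel_spacing: float = DEFAULT_PIXEL_SPACING_MM) -> TemplateAtlas:
    """Build the bundled synthetic template atlas.

    The posterior view is the horizontal mirror of the anterior geometry,
    which keeps the cross-view correspondence exact by construction.
    """
    ant_labels = _paint_skeleton(shape)
    post_labels = np.fliplr(ant_labels).copy()
    table = _load_region_table()
    ant_img = _render_template(ant_labels)
    post_img = _render_template(post_labels)
    return TemplateAtlas(
        anterior=ViewImage(ant_img, "anterior", pixel_spacing),
        posterior=ViewImage(post_img, "posterior", pixel_spacing),
        anterior_labels=RegionLabelMap(ant_labels, table),
        posterior_labels=RegionLabelMap(post_labels, table),
    )


# ---------------------------------------------------------------------------
# On-disk layout: <dir>/{anterior,posterior}.png, {anterior,posterior}_labels.png,
#                 regions.csv, atlas.json
# ---------------------------------------------------------------------------

def save_atlas(atlas: TemplateAtlas, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for view in VIEWS:
        img = atlas.image(view)
        Image.fromarray(img.pixels.astype(np.uint16)).save(path / f"{view}.png")
        Image.fromarray(atlas.labels(view).labels.astype(np.uint8), mode="L").save(
            path / f"{view}_labels.png"
        )
    with open(path / "regions.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["region_id", "name", "weight_fraction", "views"])
        for r in atlas.regions():
            writer.writerow([r.region_id, r.name, repr(r.weight_fraction), "+".join(r.views)])
    (path / "atlas.json").write_text(
        json.dumps({"version": atlas.version, "pixel_spacing_mm": atlas.pixel_spacing}, indent=2)
    )
    return path


def load_atlas(path: str | Path) -> TemplateAtlas:
    """Load and validate an atlas from its on-disk directory layout."""
    path = Path(path)
    required = [
        "anterior.png", "posterior.png",
        "anterior_labels.png", "posterior_labels.png",
        "regions.csv", "atlas.json",
    ]
    for name in required:
        if not (path / name).exists():
            raise AtlasError(f"atlas file missing: {path / name}")
    meta = json.loads((path / "atlas.json").read_text())
    spacing = float(meta.get("pixel_spacing_mm", DEFAULT_PIXEL_SPACING_MM))
    table = _load_region_table(path / "regions.csv")

    def read_view(view: str) -> tuple[ViewImage, RegionLabelMap]:
        px = np.asarray(Image.open(path / f"{view}.png")).astype(np.uint16)
        lab = np.asarray(Image.open(path / f"{view}_labels.png")).astype(np.uint8)
        return ViewImage(px, view, spacing), RegionLabelMap(lab, table)

    ant, ant_lm = read_view("anterior")
    post, post_lm = read_view("posterior")
    return TemplateAtlas(ant, post, ant_lm, post_lm, version=str(meta.get("version", "unknown")))
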