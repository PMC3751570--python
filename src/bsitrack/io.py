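"""File formats: 16-bit PNG scans with JSON sidecars, reports, overlays.

On-disk phantom layout::

    patient_<k>/
        t<j>_anterior.png   16-bit grayscale counts
        t<j>_posterior.png
        truth.json          planted lesions, true new-lesion count, true BSI

Reports are JSON/CSV; hotspot pixel sets are run-length encoded per row to
keep the JSON compact; warp fields are stored as compressed numpy arrays with
a JSON header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from .atlas import VIEWS, ViewImage
from .bsi import BsiResult
from .detection import Hotspot
from .linking import SerialComparison
from .phantom import LesionSpec, PhantomTruth, ScanPair, ScanSeries
from .registration import WarpField


class IOError_(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------

def write_view_png(image: ViewImage, path: str | Path) -> None:
    Image.fromarray(image.pixels.astype(np.uint16)).save(path)


def read_view_png(path: str | Path, view: str,
                  pixel_spacing: float) -> ViewImage:
    path = Path(path)
    if not path.exists():
        raise IOError_(f"missing view image: {path}")
    px = np.asarray(Image.open(path)).astype(np.uint16)
    return ViewImage(px, view, pixel_spacing)


def save_scan_pair(pair: ScanPair, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for view in VIEWS:
        write_view_png(pair.view(view), directory / f"t{pair.time_point}_{view}.png")
    meta = {
        "patient_id": pair.patient_id,
        "time_point": pair.time_point,
        "pixel_spacing_mm": pair.anterior.pixel_spacing,
    }
    (directory / f"t{pair.time_point}_meta.json").write_text(json.dumps(meta, indent=2))


def load_scan_pair(directory: str | Path, time_point: int) -> ScanPair:
    directory = Path(directory)
    meta_path = directory / f"t{time_point}_meta.json"
    if not meta_path.exists():
        raise IOError_(f"missing metadata: {meta_path}")
    meta = json.loads(meta_path.read_text())
    spacing = float(meta["pixel_spacing_mm"])
    views = {
        view: read_view_png(directory / f"t{time_point}_{view}.png", view, spacing)
        for view in VIEWS
    }
    return ScanPair(views["anterior"], views["posterior"],
                    time_point=time_point, patient_id=str(meta["patient_id"]))


def save_series(series: ScanSeries, truth: PhantomTruth | None,
                directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for pair in series.scans:
        save_scan_pair(pair, directory)
    if truth is not None:
        (directory / "truth.json").write_text(json.dumps(truth_to_dict(truth), indent=2))
    return directory


def load_series(directory: str | Path) -> ScanSeries:
    directory = Path(directory)
    metas = sorted(directory.glob("t*_meta.json"))
    if not metas:
        raise IOError_(f"no scans found in {directory}")
    time_points = sorted(int(p.name.split("_")[0][1:]) for p in metas)
    pairs = [load_scan_pair(directory, t) for t in time_points]
    return ScanSeries(pairs[0].patient_id, pairs)


def truth_to_dict(truth: PhantomTruth) -> dict:
    return {
        "rng_seed": truth.rng_seed,
        "true_new_lesion_count": truth.true_new_lesion_count,
        "true_bsi": {str(t): v for t, v in truth.true_bsi.items()},
        "lesions": [
            {
                "region_id": l.region_id,
                "seed_point": list(l.seed_point),
                "radius": l.radius,
                "amplitude_ratio": l.amplitude_ratio,
                "present_at": sorted(l.present_at),
            }
            for l in truth.lesions
        ],
    }


# ---------------------------------------------------------------------------
# hotspots and reports
# ---------------------------------------------------------------------------

def _rle_encode(pixels: np.ndarray) -> list[list[int]]:
    """Row-wise run-length encoding: [row, col_start, length]."""
    runs = []
    order = np.lexsort((pixels[:, 1], pixels[:, 0]))
    px = pixels[order]
    start = px[0]
    length = 1
    for prev, cur in zip(px[:-1], px[1:]):
        if cur[0] == prev[0] and cur[1] == prev[1] + 1:
            length += 1
        else:
            runs.append([int(start[0]), int(start[1]), length])
            start, length = cur, 1
    runs.append([int(start[0]), int(start[1]), length])
    return runs


def _rle_decode(runs: list[list[int]]) -> np.ndarray:
    return np.array([(r, c0 + k) for r, c0, n in runs for k in range(n)], dtype=int)


def hotspot_to_dict(h: Hotspot) -> dict:
    return {
        "scan_id": h.scan_id,
        "view": h.view,
        "time_point": h.time_point,
        "region_id": h.region_id,
        "area": h.area,
        "centroid": list(h.centroid),
        "label": h.label,
        "score": h.score,
        "features": h.features,
        "pixels_rle": _rle_encode(h.pixels),
    }


def hotspot_from_dict(d: dict) -> Hotspot:
    return Hotspot(
        pixels=_rle_decode(d["pixels_rle"]),
        view=d["view"],
        time_point=d["time_point"],
        region_id=d["region_id"],
        features=d.get("features"),
        label=d.get("label", "unclassified"),
        score=d.get("score"),
        scan_id=d.get("scan_id", ""),
    )


def hotspots_to_csv(hotspots: list[Hotspot], path: str | Path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["scan_id", "view", "time_point", "area",
                         "centroid_row", "centroid_col", "region_id", "score", "label"])
        for h in hotspots:
            r, c = h.centroid
            writer.writerow([h.scan_id, h.view, h.time_point, h.area,
                             f"{r:.2f}", f"{c:.2f}", h.region_id,
                             "" if h.score is None else f"{h.score:.4f}", h.label])


def bsi_to_dict(res: BsiResult) -> dict:
    return {
        "total_bsi": res.total_bsi,
        "n_metastatic_hotspots": res.n_metastatic_hotspots,
        "view_rule": res.view_rule,
        "per_region": [[rid, c] for rid, c in res.per_region],
        "per_view": [[rid, v, c] for rid, v, c in res.per_view],
    }


def comparison_to_dict(cmp_: SerialComparison) -> dict:
    return {
        "n_new_lesions": cmp_.n_new_lesions,
        "pcwg2_progression": cmp_.pcwg2_progression,
        "bsi_baseline": bsi_to_dict(cmp_.bsi_baseline),
        "bsi_followup": bsi_to_dict(cmp_.bsi_followup),
        "bsi_ratio": None if cmp_.bsi_ratio != cmp_.bsi_ratio else cmp_.bsi_ratio,
        "bsi_percent_change": (None if cmp_.bsi_percent_change != cmp_.bsi_percent_change
                               else cmp_.bsi_percent_change),
        "bsi_direction": cmp_.bsi_direction,
        "groups": [
            {
                "group_id": g.group_id,
                "label": g.label,
                "time_points": sorted(g.time_points_present),
                "n_members": len(g.members),
            }
            for g in cmp_.groups
        ],
    }


# ---------------------------------------------------------------------------
# overlays: old lesions yellow, new lesions red
# ---------------------------------------------------------------------------

def write_overlay_png(scan: ViewImage, comparison: SerialComparison,
                      time_point: int, path: str | Path) -> None:
    img = scan.pixels.astype(float)
    top = np.percentile(img, 99.5)
    gray = np.clip(img / max(top, 1.0), 0, 1)
    rgb = np.stack([gray, gray, gray], axis=-1)
    baseline_t = min(min(h.time_point for h in g.members) for g in comparison.groups) \
        if comparison.groups else 0
    for g in comparison.groups:
        if g.label != "metastasis":
            continue
        color = (1.0, 0.0, 0.0) if baseline_t not in g.time_points_present else (1.0, 0.9, 0.0)
        for h in g.members:
            if h.time_point != time_point or h.view != scan.view:
                continue
            rr, cc = h.pixels[:, 0], h.pixels[:, 1]
            for k in range(3):
                rgb[rr, cc, k] = 0.5 * rgb[rr, cc, k] + 0.5 * color[k]
    Image.fromarray((rgb * 255).astype(np.uint8), mode="RGB").save(path)


# ---------------------------------------------------------------------------
# warp fields
# ---------------------------------------------------------------------------

def save_warp(warp: WarpField, path: str | Path) -> None:
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), displacement=warp.displacement)
    header = {"view": warp.view, "shape": list(warp.shape), "quality": warp.quality}
    path.with_suffix(".json").write_text(json.dumps(header, indent=2))


def load_warp(path: str | Path) -> WarpField:
    path = Path(path)
    header = json.loads(path.with_suffix(".json").read_text())
    data = np.load(path.with_suffix(".npz"))
    return WarpField(data["displacement"], header["view"], header.get("quality", np.nan))
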