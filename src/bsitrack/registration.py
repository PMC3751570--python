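"""Non-rigid registration of the template to individual scans.

Each scan view is brought into correspondence with the template by a
free-form (B-spline) deformation estimated with a multi-resolution
mean-squared-intensity criterion.  Separate warps are computed for the
anterior and posterior views.  Because every scan is registered to the same
template, any point in one scan can be connected to the anatomically
corresponding point in another scan by passing through template space.

Intensities are rank-normalised before the dissimilarity is computed: planar
count scales vary with injected dose, uptake time and scan speed, and the
quantile transform removes that nuisance scale exactly.

The forward map goes template -> scan (``phi(x) = x + d(x)`` with ``d``
sampled on the template grid).  The scan -> template direction is the
numerical inverse of ``phi``, computed by fixed-point iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from scipy.stats import rankdata

from .atlas import TemplateAtlas, ViewImage


class RegistrationError(RuntimeError):
    pass


# B-spline control grid (x = columns, y = rows) and multi-resolution schedule
BSPLINE_MESH = (3, 12)
SHRINK_FACTORS = (8, 4)
SMOOTHING_SIGMAS = (2.0, 1.0)
LBFGSB_ITERATIONS = (30, 30)

INVERSE_MAX_ITER = 20
INVERSE_TOL_PX = 0.1


def rank_normalize(image: np.ndarray) -> np.ndarray:
    """Map intensities to their normalised ranks in (0, 1]; scale-free."""
    flat = rankdata(image, method="average") / image.size
    return flat.reshape(image.shape).astype(np.float32)


@dataclass
class WarpField:
    """Dense template->scan displacement for one view.

    ``displacement[0]`` and ``displacement[1]`` hold the row and column
    displacement (pixels) sampled on the template grid, so the forward map is
    ``phi(r, c) = (r, c) + displacement[:, r, c]``.
    """

    displacement: np.ndarray
    view: str
    quality: float = np.nan
    _inverse_grid: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        d = np.asarray(self.displacement, dtype=float)
        if d.ndim != 3 or d.shape[0] != 2:
            raise RegistrationError("displacement must have shape (2, rows, cols)")
        if not np.isfinite(d).all():
            raise RegistrationError("displacement field contains non-finite values")
        self.displacement = d

    @property
    def shape(self) -> tuple[int, int]:
        return self.displacement.shape[1:]

    # -- forward: template -> scan ------------------------------------------

    def _interp_displacement(self, points: np.ndarray) -> np.ndarray:
        coords = np.asarray(points, dtype=float).T  # (2, n)
        return np.stack([
            ndimage.map_coordinates(self.displacement[k], coords, order=1, mode="nearest")
            for k in range(2)
        ], axis=1)  # (n, 2)

    def forward_points(self, points: np.ndarray) -> np.ndarray:
        """Map template-space points (n, 2) to scan space."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts + self._interp_displacement(pts)

    # -- inverse: scan -> template ------------------------------------------

    def inverse_points(self, points: np.ndarray, warn_on_fold: bool = True) -> np.ndarray:
        """Map scan-space points (n, 2) to template space.

        Fixed-point iteration ``x <- y - d(x)``.  Points in a non-invertible
        (folded) zone are flagged with a warning and returned at the nearest
        fixed-point estimate reached.
        """
        y = np.atleast_2d(np.asarray(points, dtype=float))
        x = y.copy()
        for _ in range(INVERSE_MAX_ITER):
            step = y - self._interp_displacement(x) - x
            x += step
            if np.abs(step).max() < INVERSE_TOL_PX:
                break
        residual = np.abs(self.forward_points(x) - y).max(axis=1)
        bad = residual > 0.5
        if bad.any() and warn_on_fold:
            warnings.warn(
                f"{int(bad.sum())} point(s) fall in a non-invertible zone of the warp; "
                "nearest-valid estimates returned",
                RuntimeWarning,
            )
        return x

    def inverse_grid(self) -> np.ndarray:
        """Dense scan->template coordinate grid, shape (2, rows, cols), cached."""
        if self._inverse_grid is None:
            h, w = self.shape
            rows, cols = np.meshgrid(np.arange(h, dtype=float),
                                     np.arange(w, dtype=float), indexing="ij")
            y = np.stack([rows.ravel(), cols.ravel()], axis=1)
            x = y.copy()
            for _ in range(INVERSE_MAX_ITER):
                step = y - self._interp_displacement(x) - x
                x += step
                if np.abs(step).max() < INVERSE_TOL_PX:
                    break
            self._inverse_grid = x.T.reshape(2, h, w)
        return self._inverse_grid


def to_template(warp: WarpField, point: tuple[float, float]) -> tuple[float, float]:
    """Map one scan-space point to template space (numeric warp inverse)."""
    h, w = warp.shape
    r, c = point
    if not (0 <= r < h and 0 <= c < w):
        raise RegistrationError(f"point {point} outside image bounds {h}x{w}")
    out = warp.inverse_points(np.array([[r, c]], dtype=float))[0]
    return float(out[0]), float(out[1])


def transfer(warp_a: WarpField, warp_b: WarpField,
             point_in_a: tuple[float, float]) -> tuple[float, float]:
    """Carry a point from scan A to the corresponding point in scan B.

    Both scans share the template frame, so the transfer is the composition
    ``forward_b( to_template_a(point) )``.
    """
    if warp_a.view != warp_b.view:
        raise RegistrationError(
            f"cannot transfer between views {warp_a.view!r} and {warp_b.view!r}"
        )
    tpl = to_template(warp_a, point_in_a)
    out = warp_b.forward_points(np.array([tpl]))[0]
    return float(out[0]), float(out[1])


def _as_sitk(arr: np.ndarray) -> sitk.Image:
    return sitk.GetImageFromArray(arr.astype(np.float32))


def register(atlas: TemplateAtlas, scan: ViewImage) -> WarpField:
    """Estimate the template->scan free-form deformation for one view.

    Multi-resolution B-spline registration of the rank-normalised template
    (fixed) to the rank-normalised scan (moving) with a mean-squared
    criterion and L-BFGS-B optimisation over the control points.  Fully
    sampled metric and a fixed schedule make the result deterministic for
    identical inputs.
    """
    template = atlas.image(scan.view)
    if scan.pixels.shape != template.shape:
        raise RegistrationError(
            f"scan shape {scan.pixels.shape} does not match template {template.shape}"
        )
    if scan.pixels.max() == 0:
        raise RegistrationError("degenerate all-zero scan cannot be registered")

    fixed = _as_sitk(rank_normalize(template.pixels))
    moving = _as_sitk(rank_normalize(scan.pixels))
    skeleton = atlas.skeleton_mask(scan.view)

    tx = sitk.BSplineTransformInitializer(fixed, list(BSPLINE_MESH), order=3)
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetMetricSamplingStrategy(reg.NONE)  # full sampling: deterministic
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsLBFGSB(
        gradientConvergenceTolerance=1e-7,
        numberOfIterations=max(LBFGSB_ITERATIONS),
        maximumNumberOfCorrections=5,
    )
    reg.SetInitialTransform(tx, inPlace=True)
    reg.SetShrinkFactorsPerLevel(list(SHRINK_FACTORS))
    reg.SetSmoothingSigmasPerLevel(list(SMOOTHING_SIGMAS))
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    reg.Execute(fixed, moving)

    # dense displacement on the template grid; sitk components are (x, y)
    disp_img = sitk.TransformToDisplacementField(
        tx, sitk.sitkVectorFloat64,
        fixed.GetSize(), fixed.GetOrigin(), fixed.GetSpacing(), fixed.GetDirection(),
    )
    disp_xy = sitk.GetArrayFromImage(disp_img)  # (rows, cols, 2) with (dx, dy)
    displacement = np.stack([disp_xy[..., 1], disp_xy[..., 0]])

    warped = sitk.GetArrayFromImage(sitk.Resample(moving, fixed, tx, sitk.sitkLinear, 0.0))
    tpl_ranked = sitk.GetArrayFromImage(fixed)
    quality = float(np.mean((warped[skeleton] - tpl_ranked[skeleton]) ** 2))
    return WarpField(displacement, scan.view, quality)


def registration_residual(atlas: TemplateAtlas, scan: ViewImage,
                          warp: WarpField | None = None) -> float:
    """Mean squared rank-intensity mismatch over the skeleton.

    With ``warp=None`` the identity alignment is scored, which gives the
    pre-registration baseline that a successful registration must not exceed.
    """
    template = atlas.image(scan.view)
    skeleton = atlas.skeleton_mask(scan.view)
    tpl = rank_normalize(template.pixels)
    scn = rank_normalize(scan.pixels)
    if warp is None:
        return float(np.mean((scn[skeleton] - tpl[skeleton]) ** 2))
    h, w = warp.shape
    rows, cols = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float),
                             indexing="ij")
    coords = np.stack([rows + warp.displacement[0], cols + warp.displacement[1]])
    warped = ndimage.map_coordinates(scn, coords, order=1, mode="nearest")
    return float(np.mean((warped[skeleton] - tpl[skeleton]) ** 2))
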