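"""Nuclear morphometry: geometric and densitometric features of a delineated nucleus.

A nucleus (or any delineated structure, e.g. a colloid fragment) is described
by a closed boundary polygon drawn on a digitized cytology image.  From the
polygon alone we derive 13 geometric descriptors (area, axes, calipers,
radii, perimeter, roundness, fractal dimension); from the RGB pixels inside
the polygon we derive 10 densitometric descriptors based on optical density
(OD), a proxy for chromatin stain uptake.

Conventions: 0-based pixel-center coordinates, x rightward, y downward; the
polygon is implicitly closed (last vertex connects to the first);
point-in-polygon tests are boundary-inclusive.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import Point, Polygon

logger = logging.getLogger(__name__)

__all__ = [
    "MorphometryError",
    "DegeneratePolygonError",
    "NucleusBoundary",
    "ImagePatch",
    "FeatureVector",
    "RadialStats",
    "FEATURE_NAMES",
    "polygon_area",
    "polygon_perimeter",
    "caliper_diameters",
    "radial_stats",
    "ellipse_axes",
    "roundness",
    "fractal_dimension",
    "background_correct",
    "optical_density_map",
    "densitometric_features",
    "extract_features",
]


class MorphometryError(ValueError):
    """Invalid input to a morphometry operation."""


class DegeneratePolygonError(MorphometryError):
    """Fewer than 3 vertices, collinear vertices, or zero signed area."""


# Fixed feature order: 13 geometric then 10 densitometric.
FEATURE_NAMES: tuple[str, ...] = (
    "area",
    "major_axis",
    "minor_axis",
    "aspect_ratio",
    "max_caliper",
    "min_caliper",
    "mean_caliper",
    "max_radius",
    "min_radius",
    "radius_ratio",
    "perimeter",
    "roundness",
    "fractal_dimension",
    "iod",
    "mean_red",
    "mean_green",
    "mean_blue",
    "mean_od",
    "max_od",
    "min_od",
    "sd_od",
    "margination",
    "heterogeneity",
)

#: BT.601 luma weights used to collapse RGB to a single transmitted intensity.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class NucleusBoundary:
    """Closed polygon outlining one nucleus, in pixel coordinates."""

    vertices: np.ndarray  # (n, 2) float array of (x, y)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise MorphometryError("vertices must be an (n, 2) array of (x, y)")
        if v.shape[0] < 3:
            raise DegeneratePolygonError("a boundary needs at least 3 vertices")
        object.__setattr__(self, "vertices", v)
        if not np.isfinite(v).all():
            raise MorphometryError("vertices must be finite")
        poly = Polygon(v)
        if poly.area == 0.0:
            raise DegeneratePolygonError("zero-area (collinear) boundary")
        if not poly.is_valid:
            raise MorphometryError("self-intersecting boundary")

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def closed_vertices(self) -> np.ndarray:
        """Vertices with the first repeated at the end."""
        return np.vstack([self.vertices, self.vertices[:1]])


@dataclass
class ImagePatch:
    """8-bit RGB image, optionally paired with a blank-field exposure."""

    pixels: np.ndarray  # (H, W, 3) uint8
    blank_field: np.ndarray | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise MorphometryError("pixels must be H x W x 3")
        self.pixels = px
        if self.blank_field is not None:
            bf = np.asarray(self.blank_field)
            if bf.shape != px.shape:
                raise MorphometryError("blank_field dimensions must match pixels")
            self.blank_field = bf

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class FeatureVector:
    """The 23 morphometric measurements of one structure.

    Geometric features are in pixel units (area px², lengths px); the
    densitometric block is in OD units except the three channel means
    (0–255) and the two fractions margination / heterogeneity.
    """

    area: float
    major_axis: float
    minor_axis: float
    aspect_ratio: float
    max_caliper: float
    min_caliper: float
    mean_caliper: float
    max_radius: float
    min_radius: float
    radius_ratio: float
    perimeter: float
    roundness: float
    fractal_dimension: float
    iod: float
    mean_red: float
    mean_green: float
    mean_blue: float
    mean_od: float
    max_od: float
    min_od: float
    sd_od: float
    margination: float
    heterogeneity: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    def __post_init__(self) -> None:
        eps = 1e-9  # float reductions may cross exact bounds by one ulp
        checks = (
            (self.area > 0, "area must be positive"),
            (self.min_caliper - eps <= self.mean_caliper
             <= self.max_caliper + eps, "caliper ordering violated"),
            (self.min_radius <= self.max_radius + eps,
             "radius ordering violated"),
            (self.aspect_ratio >= 1 - eps, "aspect_ratio must be >= 1"),
            (self.min_od - eps <= self.mean_od <= self.max_od + eps,
             "OD ordering violated"),
            (1 - eps <= self.fractal_dimension <= 2 + eps,
             "fractal_dimension outside [1, 2]"),
        )
        for ok, msg in checks:
            if not ok:
                raise MorphometryError(msg)


@dataclass(frozen=True)
class RadialStats:
    max_radius: float
    min_radius: float
    radius_ratio: float
    centroid_inside: bool  # False flags a pathological non-convex shape

    def __iter__(self):
        return iter((self.max_radius, self.min_radius, self.radius_ratio))


def polygon_area(boundary: NucleusBoundary) -> float:
    """Enclosed area in px² (shoelace / triangle decomposition), orientation-free."""
    return float(boundary.polygon().area)


def polygon_perimeter(boundary: NucleusBoundary) -> float:
    """Sum of Euclidean edge lengths, including the closing edge."""
    return float(boundary.polygon().exterior.length)


def caliper_diameters(
    boundary: NucleusBoundary, n_angles: int = 180
) -> tuple[float, float, float]:
    """Feret (caliper) diameters of the vertex set.

    The projection width of the vertices is evaluated on a uniform angular
    grid over [0, π); returns (max, min, mean) over the grid.  The maximum is
    additionally lower-bounded by the exact maximum pairwise vertex distance,
    which is the true maximum Feret diameter of the polygon.
    """
    if n_angles < 2:
        raise MorphometryError("n_angles must be >= 2")
    v = boundary.vertices
    theta = np.arange(n_angles) * (np.pi / n_angles)
    dirs = np.stack([np.cos(theta), np.sin(theta)])  # (2, n_angles)
    proj = v @ dirs  # (n_vertices, n_angles)
    widths = proj.max(axis=0) - proj.min(axis=0)
    d = v[:, None, :] - v[None, :, :]
    max_pairwise = float(np.sqrt((d ** 2).sum(-1)).max())
    return (
        max(float(widths.max()), max_pairwise),
        float(widths.min()),
        float(widths.mean()),
    )


def _resample_closed(vertices: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a closed polyline at n_points equally spaced arc-length positions."""
    closed = np.vstack([vertices, vertices[:1]])
    seg = np.sqrt(((np.diff(closed, axis=0)) ** 2).sum(axis=1))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    s = np.linspace(0.0, total, n_points, endpoint=False)
    x = np.interp(s, cum, closed[:, 0])
    y = np.interp(s, cum, closed[:, 1])
    return np.column_stack([x, y])


def radial_stats(boundary: NucleusBoundary, n_points: int = 1024) -> RadialStats:
    """Max/min distance from the area centroid to the resampled boundary.

    The boundary is resampled at ``n_points`` (>= 256) equally spaced
    arc-length positions.  A centroid falling outside the polygon (extreme
    non-convex shape) is flagged via ``centroid_inside`` but the radii are
    still reported.
    """
    if n_points < 256:
        raise MorphometryError("n_points must be >= 256")
    poly = boundary.polygon()
    c = poly.centroid
    pts = _resample_closed(boundary.vertices, n_points)
    r = np.sqrt((pts[:, 0] - c.x) ** 2 + (pts[:, 1] - c.y) ** 2)
    rmax, rmin = float(r.max()), float(r.min())
    inside = bool(poly.covers(c))
    if not inside:
        logger.warning("polygon centroid lies outside the boundary")
    ratio = math.inf if rmin == 0 else rmax / rmin
    return RadialStats(rmax, rmin, ratio, inside)


def _polygon_moments(vertices: np.ndarray) -> tuple[float, float, float, float, float, float]:
    """Exact area, centroid and central second moments of the polygon interior."""
    x, y = vertices[:, 0], vertices[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a = cross.sum() / 2.0
    if a == 0:
        raise DegeneratePolygonError("zero-area polygon")
    cx = ((x + x1) * cross).sum() / (6.0 * a)
    cy = ((y + y1) * cross).sum() / (6.0 * a)
    ixx = ((x * x + x * x1 + x1 * x1) * cross).sum() / 12.0
    iyy = ((y * y + y * y1 + y1 * y1) * cross).sum() / 12.0
    ixy = ((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross).sum() / 24.0
    # central, normalized by area; sign of a handles orientation
    mxx = ixx / a - cx * cx
    myy = iyy / a - cy * cy
    mxy = ixy / a - cx * cy
    return abs(a), cx, cy, mxx, myy, mxy


def ellipse_axes(boundary: NucleusBoundary) -> tuple[float, float, float]:
    """Axes of the ellipse sharing the polygon's second-order area moments.

    Returns (major_axis, minor_axis, aspect_ratio); full axis lengths, so a
    rendered ellipse with semi-axes (a, b) yields (2a, 2b).
    """
    _, _, _, mxx, myy, mxy = _polygon_moments(boundary.vertices)
    cov = np.array([[mxx, mxy], [mxy, myy]])
    lam = np.linalg.eigvalsh(cov)  # ascending
    lam = np.clip(lam, 0.0, None)
    minor = 4.0 * math.sqrt(lam[0])
    major = 4.0 * math.sqrt(lam[1])
    if minor == 0:
        raise DegeneratePolygonError("degenerate (zero-width) polygon")
    return major, minor, major / minor


def roundness(area: float, perimeter: float) -> float:
    """4πA / P²: 1 for a circle, smaller for irregular outlines."""
    if area <= 0 or perimeter <= 0:
        raise MorphometryError("area and perimeter must be positive")
    return 4.0 * math.pi * area / perimeter ** 2


def fractal_dimension(
    boundary: NucleusBoundary,
    grid_size: int = 1024,
    box_sizes: Sequence[int] = (8, 16, 32, 64, 128, 256),
) -> float:
    """Box-counting dimension of the rasterized boundary curve, clamped to [1, 2].

    The outline is rescaled so its longest extent spans ``grid_size`` cells
    (making the estimate invariant to the nucleus's absolute size), traced
    densely onto the grid, and occupied-box counts N(s) at dyadic box sizes
    are fit by least squares in log-log space; the negated slope is the
    dimension estimate.  The default sizes span grid/128 to grid/4, the
    window where a boundary's self-similar structure is resolved.
    """
    v = boundary.vertices - boundary.vertices.min(axis=0)
    extent = v.max()
    if extent == 0:
        raise DegeneratePolygonError("zero-extent polygon")
    v = v * (grid_size / extent)
    # dense trace: step of ~0.3 px guarantees every crossed pixel is marked
    closed = np.vstack([v, v[:1]])
    seg = np.sqrt((np.diff(closed, axis=0) ** 2).sum(axis=1))
    n_samples = max(int(seg.sum() / 0.3), 64)
    pts = _resample_closed(v, n_samples)
    occ = np.unique(np.floor(pts).astype(np.int64), axis=0)
    sizes, counts = [], []
    for s in box_sizes:
        if s > grid_size:
            break
        sizes.append(s)
        counts.append(len(np.unique(occ // s, axis=0)))
    if len(sizes) < 2:
        raise MorphometryError("boundary too small for box counting")
    slope = np.polyfit(np.log(sizes), np.log(counts), 1)[0]
    return float(np.clip(-slope, 1.0, 2.0))


def background_correct(patch: ImagePatch) -> ImagePatch:
    """Flat-field correction: raw × mean(blank channel) / blank pixel, per channel.

    Removes lens vignetting / illumination gradients recorded in the blank
    field.  A uniform blank field leaves the image unchanged.  Missing blank
    field → identity with a warning; blank pixels of 0 are treated as 1.
    """
    if patch.blank_field is None:
        logger.warning("no blank field supplied; background correction skipped")
        return ImagePatch(patch.pixels.copy())
    blank = patch.blank_field.astype(float)
    blank = np.where(blank == 0, 1.0, blank)
    gains = blank.mean(axis=(0, 1), keepdims=True) / blank
    corrected = np.clip(np.rint(patch.pixels.astype(float) * gains), 0, 255)
    return ImagePatch(corrected.astype(np.uint8))


def _mask_and_luminance(
    patch: ImagePatch, boundary: NucleusBoundary
) -> tuple[np.ndarray, np.ndarray]:
    """Boundary-inclusive pixel-center mask and luminance image over the patch."""
    h, w = patch.shape
    v = boundary.vertices
    if (v[:, 0].min() < -0.5 or v[:, 1].min() < -0.5
            or v[:, 0].max() > w - 0.5 or v[:, 1].max() > h - 0.5):
        raise MorphometryError("boundary extends outside the image")
    poly = boundary.polygon()
    x0 = max(int(math.floor(v[:, 0].min())), 0)
    x1 = min(int(math.ceil(v[:, 0].max())), w - 1)
    y0 = max(int(math.floor(v[:, 1].min())), 0)
    y1 = min(int(math.ceil(v[:, 1].max())), h - 1)
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    inside = shapely.intersects_xy(poly, xs.ravel(), ys.ravel()).reshape(xs.shape)
    mask = np.zeros((h, w), dtype=bool)
    mask[y0:y1 + 1, x0:x1 + 1] = inside
    if not mask.any():
        raise MorphometryError("boundary encloses no pixel centers")
    lum = patch.pixels.astype(float) @ _LUMA
    return mask, lum


def optical_density_map(
    patch: ImagePatch, boundary: NucleusBoundary, i0: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel optical density over the nucleus mask.

    OD = −log10((L + 1) / (I₀ + 1)) with L the BT.601 luminance and I₀ the
    incident intensity (255, or the mean blank-field luminance when the
    patch carries one); clipped at 0 from below.  Returns ``(od, mask)`` as
    full-size arrays; ``od`` is 0 outside the mask.
    """
    mask, lum = _mask_and_luminance(patch, boundary)
    if i0 is None:
        if patch.blank_field is not None:
            i0 = float((patch.blank_field.astype(float) @ _LUMA).mean())
        else:
            i0 = 255.0
    od = np.zeros(mask.shape)
    od[mask] = np.clip(-np.log10((lum[mask] + 1.0) / (i0 + 1.0)), 0.0, None)
    return od, mask


@dataclass(frozen=True)
class DensitometricFeatures:
    iod: float
    mean_red: float
    mean_green: float
    mean_blue: float
    mean_od: float
    max_od: float
    min_od: float
    sd_od: float
    margination: float
    heterogeneity: float

    def __iter__(self):
        return iter(dataclasses.astuple(self))


def densitometric_features(
    patch: ImagePatch, boundary: NucleusBoundary, i0: float | None = None
) -> DensitometricFeatures:
    """The 10 densitometric descriptors over the nucleus mask.

    * iod: integrated optical density, Σ OD over the mask.
    * margination: fraction of the IOD carried by the peripheral band of
      pixels whose distance to the boundary is at most 10% of the
      equivalent-circle radius (0 when IOD is 0).
    * heterogeneity: fraction of mask pixels with |OD − mean| > SD of OD
      (population SD; 0 when the SD is 0).
    """
    od, mask = optical_density_map(patch, boundary, i0=i0)
    vals = od[mask]
    px = patch.pixels[mask].astype(float)
    iod = float(vals.sum())
    mean_od = float(vals.mean())
    sd_od = float(vals.std())  # population denominator N
    area = polygon_area(boundary)
    r_eq = math.sqrt(area / math.pi)
    ys, xs = np.nonzero(mask)
    ring = boundary.polygon().exterior
    dists = shapely.distance(shapely.points(np.column_stack([xs, ys])), ring)
    band = dists <= 0.1 * r_eq
    margination = float(od[mask][band].sum() / iod) if iod > 0 else 0.0
    heterogeneity = (
        float((np.abs(vals - mean_od) > sd_od).mean()) if sd_od > 0 else 0.0
    )
    return DensitometricFeatures(
        iod=iod,
        mean_red=float(px[:, 0].mean()),
        mean_green=float(px[:, 1].mean()),
        mean_blue=float(px[:, 2].mean()),
        mean_od=mean_od,
        max_od=float(vals.max()),
        min_od=float(vals.min()),
        sd_od=sd_od,
        margination=margination,
        heterogeneity=heterogeneity,
    )


def extract_features(
    patch: ImagePatch, boundary: NucleusBoundary, i0: float | None = None
) -> FeatureVector:
    """Assemble the full 23-feature vector for one delineated structure."""

    def _step(name: str, fn, *args):
        try:
            return fn(*args)
        except MorphometryError as exc:
            raise MorphometryError(f"{name}: {exc}") from exc

    area = _step("area", polygon_area, boundary)
    perim = _step("perimeter", polygon_perimeter, boundary)
    major, minor, aspect = _step("major_axis", ellipse_axes, boundary)
    cal_max, cal_min, cal_mean = _step("max_caliper", caliper_diameters, boundary)
    rad = _step("max_radius", radial_stats, boundary)
    rnd = _step("roundness", roundness, area, perim)
    fd = _step("fractal_dimension", fractal_dimension, boundary)
    dens = _step("iod", densitometric_features, patch, boundary, i0)
    return FeatureVector(
        area=area,
        major_axis=major,
        minor_axis=minor,
        aspect_ratio=aspect,
        max_caliper=cal_max,
        min_caliper=cal_min,
        mean_caliper=cal_mean,
        max_radius=rad.max_radius,
        min_radius=rad.min_radius,
        radius_ratio=rad.radius_ratio,
        perimeter=perim,
        roundness=rnd,
        fractal_dimension=fd,
        **dataclasses.asdict(dens),
    )
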