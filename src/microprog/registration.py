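"""Landmark registration of autofluorescence images and ring-to-degrees mapping.

A hyperautofluorescent ring (HAR) is traced on a short-wavelength
autofluorescence (SW-AF) image in pixel coordinates.  To relate it to the
microperimetry grid it must be brought into the MAIA cSLO pixel frame via a
similarity transform fitted to manually selected landmark pairs, then
converted to field degrees using the device pixel scales (MAIA: 36° over
1024 px; SW-AF: 30° over 768 px) relative to the grid centre.  Image rows
increase downwards, so y is negated when converting to field coordinates
(y-up).

The transform family is a similarity (uniform scale, rotation, translation):
both instruments image the same fundus, so scale and rotation suffice and a
richer family would overfit the few manual landmarks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import LinearRing, LineString, Polygon, box
from skimage.transform import SimilarityTransform as _SkSimilarity

__all__ = [
    "ImageSpec",
    "MAIA_IMAGE",
    "SWAF_IMAGE",
    "RingPolygon",
    "SimilarityTransform",
    "circle_polygon",
    "fit_similarity",
    "ring_to_degrees",
    "transects",
]


@dataclass(frozen=True)
class ImageSpec:
    """Square fundus-image geometry: field of view (degrees) and resolution (px)."""

    field_of_view: float
    resolution: int

    @property
    def degrees_per_pixel(self) -> float:
        return self.field_of_view / self.resolution

    @property
    def center_px(self) -> tuple[float, float]:
        return (self.resolution / 2.0, self.resolution / 2.0)


MAIA_IMAGE = ImageSpec(field_of_view=36.0, resolution=1024)
SWAF_IMAGE = ImageSpec(field_of_view=30.0, resolution=768)


@dataclass(frozen=True)
class SimilarityTransform:
    """2-D similarity ``p -> scale·R(rotation)·p + translation`` with fit RMSE.

    ``rmse`` is the root-mean-square landmark residual per coordinate
    (pixels): sqrt(RSS / 2n) for n landmark pairs.
    """

    scale: float
    rotation: float
    translation: tuple[float, float]
    rmse: float = 0.0

    @property
    def matrix(self) -> np.ndarray:
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix.T + np.asarray(self.translation)

    def inverse(self) -> "SimilarityTransform":
        inv_scale = 1.0 / self.scale
        inv_rot = -self.rotation
        c, s = math.cos(inv_rot), math.sin(inv_rot)
        m = inv_scale * np.array([[c, -s], [s, c]])
        t = -m @ np.asarray(self.translation)
        return SimilarityTransform(inv_scale, inv_rot, (t[0], t[1]))


IDENTITY = SimilarityTransform(scale=1.0, rotation=0.0, translation=(0.0, 0.0))


def fit_similarity(src: np.ndarray, dst: np.ndarray) -> SimilarityTransform:
    """Least-squares similarity transform from landmark pairs.

    Parameters
    ----------
    src, dst
        (n, 2) arrays of corresponding points (source frame → target frame),
        n ≥ 2.  Source points must not all coincide.

    Returns the transform minimising the sum of squared target residuals,
    with the RMS residual per coordinate reported as ``rmse``.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.ndim != 2 or src.shape[1] != 2 or src.shape != dst.shape:
        raise ValueError("landmarks must be matching (n, 2) arrays")
    n = src.shape[0]
    if n < 2:
        raise ValueError("at least 2 landmark pairs are required")
    if not (np.all(np.isfinite(src)) and np.all(np.isfinite(dst))):
        raise ValueError("landmarks must be finite")
    if np.allclose(src, src[0]):
        raise ValueError(
            "degenerate landmark configuration: all source points coincide"
        )
    if hasattr(_SkSimilarity, "from_estimate"):
        tf = _SkSimilarity.from_estimate(src, dst)
        if not tf:
            raise ValueError("similarity estimation failed")
    else:  # scikit-image < 0.26
        tf = _SkSimilarity(dimensionality=2)
        if not tf.estimate(src, dst):
            raise ValueError("similarity estimation failed")
    resid = tf(src) - dst
    rmse = float(np.sqrt(np.sum(resid**2) / (2 * n)))
    return SimilarityTransform(
        scale=float(tf.scale),
        rotation=float(tf.rotation),
        translation=(float(tf.translation[0]), float(tf.translation[1])),
        rmse=rmse,
    )


# --------------------------------------------------------------------------
# Ring polygons


@dataclass(frozen=True)
class RingPolygon:
    """Closed, simple ring boundary in degrees relative to the grid centre.

    ``vertices`` excludes the repeated closing vertex; closure is implicit.
    Incomplete rings (the boundary eroded by atrophy) are represented with
    ``is_complete=False`` and rejected by analyses that need a closed
    boundary.
    """

    vertices: np.ndarray
    is_complete: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("ring vertices must be an (n, 2) array")
        if len(v) >= 2 and np.allclose(v[0], v[-1]):
            v = v[:-1]  # normalize away an explicit closing vertex
        if self.is_complete:
            if len(v) < 3:
                raise ValueError("a complete ring needs at least 3 vertices")
            if not LinearRing(v).is_simple:
                raise ValueError("ring boundary is self-intersecting")
        object.__setattr__(self, "vertices", v)

    @property
    def boundary(self) -> LinearRing:
        if not self.is_complete:
            raise ValueError("incomplete ring has no closed boundary")
        return LinearRing(self.vertices)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def transform(self, fn) -> "RingPolygon":
        return RingPolygon(fn(self.vertices), is_complete=self.is_complete)


def circle_polygon(
    radius: float,
    center: tuple[float, float] = (0.0, 0.0),
    axis_ratio: float = 1.0,
    max_chord: float = 0.25,
) -> RingPolygon:
    """Polygonized circle/ellipse with chord length ≤ ``max_chord``.

    ``axis_ratio`` scales the x semi-axis relative to ``radius`` (the y
    semi-axis).  The 0.25° default chord bounds polygonization error of the
    transection test below 0.05°.
    """
    if radius <= 0 or axis_ratio <= 0:
        raise ValueError("radius and axis_ratio must be positive")
    rmax = radius * max(1.0, axis_ratio)
    # chord = 2 r sin(θ/2) ≤ max_chord
    n = max(8, int(math.ceil(math.pi / math.asin(min(1.0, max_chord / (2 * rmax))))))
    th = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
    xs = center[0] + radius * axis_ratio * np.cos(th)
    ys = center[1] + radius * np.sin(th)
    return RingPolygon(np.column_stack([xs, ys]))


def ring_to_degrees(
    ring_px: np.ndarray,
    t: SimilarityTransform,
    af: ImageSpec = SWAF_IMAGE,
    maia: ImageSpec = MAIA_IMAGE,
    grid_center_px: tuple[float, float] | None = None,
    is_complete: bool = True,
) -> RingPolygon:
    """Map a ring traced in AF pixels to field degrees about the grid centre.

    The vertices are sent through ``t`` (AF px → MAIA px), offset by the grid
    centre (defaulting to the MAIA image centre — fixation offsets can be
    supplied), scaled by the MAIA degrees-per-pixel, and y-negated (image
    rows grow downward, field y grows upward).
    """
    v = np.atleast_2d(np.asarray(ring_px, dtype=float))
    if is_complete:
        if len(v) >= 2 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        if len(v) < 3:
            raise ValueError("ring must have at least 3 vertices")
        if not LinearRing(v).is_simple:
            raise ValueError("ring is self-intersecting in pixel space")
    if grid_center_px is None:
        grid_center_px = maia.center_px
    maia_px = t.apply(v)
    dpp = maia.degrees_per_pixel
    deg = (maia_px - np.asarray(grid_center_px)) * dpp
    deg[:, 1] *= -1.0
    return RingPolygon(deg, is_complete=is_complete)


def transects(
    square: tuple[float, float, float, float], ring: RingPolygon
) -> bool:
    """True iff the ring *boundary* intersects the closed square.

    Equivalent to the square containing points on both sides of the boundary
    or the boundary touching it; a ring strictly containing or strictly
    avoiding the square does not transect it.  Total function: never raises
    for a complete ring.
    """
    if not ring.is_complete:
        raise ValueError("transection is undefined for an incomplete ring")
    xmin, ymin, xmax, ymax = square
    rect = box(xmin, ymin, xmax, ymax)
    return bool(LineString(np.vstack([ring.vertices, ring.vertices[:1]])).intersects(rect))
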