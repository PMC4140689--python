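"""Centroid estimation and polar conversion of keypoint constellations.

Image coordinates are top-left origin with y pointing down; the polar
conversion flips the y axis so that angles are counter-clockwise-positive in
the conventional mathematical orientation.  Angles live in ``(-180, 180]``
with +180 assigned to the negative x axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientFeaturesError
from .keypoints import KeyPoint

__all__ = [
    "Centroid",
    "PolarPoint",
    "wrap_angle",
    "centroid_median",
    "centroid_mean",
    "to_polar",
    "polar_to_cartesian",
]


@dataclass(frozen=True)
class Centroid:
    """Origin of the polar frame, in image pixel coordinates."""

    x: float
    y: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("a centroid requires at least one point")


@dataclass(frozen=True)
class PolarPoint:
    """A keypoint re-expressed as (r, theta) about the centroid.

    ``theta`` is in degrees, counter-clockwise positive, in ``(-180, 180]``.
    """

    r: float
    theta: float
    source: KeyPoint | None = None

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError("r must be >= 0")
        if not (-180.0 < self.theta <= 180.0):
            raise ValueError("theta must lie in (-180, 180]")


def wrap_angle(angle):
    """Fold angle(s) in degrees into ``(-180, 180]``."""
    a = (np.asarray(angle, dtype=float) + 180.0) % 360.0 - 180.0
    a = np.where(a == -180.0, 180.0, a)
    if np.ndim(angle) == 0:
        return float(a)
    return a


def _coords(points: list[KeyPoint]) -> np.ndarray:
    return np.array([(p.x, p.y) for p in points], dtype=float)


def centroid_median(points: list[KeyPoint]) -> Centroid:
    """Component-wise median of the keypoint coordinates.

    For even counts each component is the mean of the two middle order
    statistics.  Note that for constellations mirrored about an oblique axis
    the component-wise median does not in general lie on the axis; see
    :func:`centroid_mean` for the reflection-equivariant estimate.
    """
    if not points:
        raise InsufficientFeaturesError("cannot take the centroid of no points")
    xy = _coords(points)
    med = np.median(xy, axis=0)
    return Centroid(x=float(med[0]), y=float(med[1]), n_points=len(points))


def centroid_mean(points: list[KeyPoint]) -> Centroid:
    """Arithmetic mean of the keypoint coordinates.

    The mean commutes with reflections, so for an exactly mirrored
    constellation it lies exactly on the symmetry axis.
    """
    if not points:
        raise InsufficientFeaturesError("cannot take the centroid of no points")
    xy = _coords(points)
    mean = xy.mean(axis=0)
    return Centroid(x=float(mean[0]), y=float(mean[1]), n_points=len(points))


def to_polar(points: list[KeyPoint], center: Centroid) -> list[PolarPoint]:
    """Convert keypoints to polar coordinates about ``center``.

    The image y axis is flipped before taking the angle so that increasing
    theta is counter-clockwise in maths orientation.  A point coincident with
    the centroid maps to ``(r=0, theta=0)``.
    """
    out = []
    for p in points:
        dx = p.x - center.x
        dy = center.y - p.y  # flip raster y so angles are CCW-positive
        r = float(np.hypot(dx, dy))
        theta = wrap_angle(np.rad2deg(np.arctan2(dy, dx))) if r > 0 else 0.0
        out.append(PolarPoint(r=r, theta=theta, source=p))
    return out


def polar_to_cartesian(point: PolarPoint) -> tuple[float, float]:
    """Centered Cartesian coordinates (x right, y up) of a polar point."""
    t = np.deg2rad(point.theta)
    return (point.r * float(np.cos(t)), point.r * float(np.sin(t)))
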