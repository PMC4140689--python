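"""Ground-truthed synthetic fixtures.

Everything is generated procedurally from a seed, so test images never need
to be shipped or downloaded.  Mirrored images are built as functions of the
axis-frame coordinates ``(|s|, t)`` — ``s`` the signed distance to the axis,
``t`` the position along it — which makes them mirror-symmetric about the
requested line by construction (and pixel-exactly so for axis angles whose
reflection maps the pixel grid onto itself: 0, 45, 90, 135 degrees).

The mirrored objects are unions of anisotropic Gaussian spots placed in
mirrored pairs with mirrored orientations, plus a few self-mirrored spots on
the axis; anisotropy gives the keypoints stable gradient orientations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .geometry import PolarPoint, wrap_angle
from .keypoints import KeyPoint

__all__ = [
    "FixtureSpec",
    "make_mirrored_image",
    "make_cluttered_image",
    "make_point_constellation",
    "default_suite",
]

KINDS = ("mirrored_image", "mirrored_points", "asymmetric_points", "cluttered_image")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic fixture; (spec, seed) fixes every byte."""

    kind: str
    seed: int
    true_alpha: float | None = None
    n_points: int = 40
    jitter_r: float = 0.0
    jitter_theta: float = 0.0
    clutter_density: float = 0.0  # clutter features per 10^4 px^2
    size: int = 192
    n_features: int = 14

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise InvalidParameterError(f"unknown fixture kind {self.kind!r}")
        mirrored = self.kind in ("mirrored_image", "mirrored_points", "cluttered_image")
        if mirrored and self.true_alpha is None:
            raise InvalidParameterError(f"{self.kind} requires true_alpha")
        if not mirrored and self.true_alpha is not None:
            raise InvalidParameterError(f"{self.kind} must not carry true_alpha")
        if mirrored and not (0.0 <= self.true_alpha < 180.0):
            raise InvalidParameterError("true_alpha must lie in [0, 180)")
        if self.jitter_r < 0 or self.jitter_theta < 0:
            raise InvalidParameterError("jitters must be >= 0")


def _axis_frame(size: int, alpha: float):
    """Axis-frame coordinate fields for a square canvas.

    Returns ``s`` (signed perpendicular distance to the line through the
    canvas centre at ``alpha``) and ``t`` (coordinate along the line), both
    in maths orientation.
    """
    c = (size - 1) / 2.0
    rows, cols = np.mgrid[0:size, 0:size]
    xm = cols - c
    ym = c - rows
    a = np.deg2rad(alpha)
    s = -np.sin(a) * xm + np.cos(a) * ym
    t = np.cos(a) * xm + np.sin(a) * ym
    return s, t, xm, ym


def _aniso(u, v, su, sv):
    return np.exp(-(u**2 / (2.0 * su**2) + v**2 / (2.0 * sv**2)))


def _paint_object(s, t, rng, size: int, n_features: int) -> np.ndarray:
    """Mirror-symmetric object: paired anisotropic spots plus on-axis spots."""
    img = np.full(s.shape, 0.35)
    # keep every feature inside the inscribed disc: the square canvas is not
    # reflection-invariant for oblique axes, so features near a corner could
    # lose their mirror partner to the border
    r_disc = 0.49 * size
    t_span = 0.37 * size
    for _ in range(n_features):
        si = rng.uniform(0.04 * size, 0.33 * size)
        su = rng.uniform(2.0, 7.0)
        sv = rng.uniform(2.0, 7.0)
        r_budget = r_disc - 3.0 * max(su, sv)
        t_lim = min(t_span, float(np.sqrt(max(r_budget**2 - si**2, 1.0))))
        ti = rng.uniform(-t_lim, t_lim)
        phi = rng.uniform(0, np.pi)
        amp = rng.uniform(0.3, 0.65) * rng.choice([-1.0, 1.0])
        for sign in (1.0, -1.0):
            u = np.cos(sign * phi) * (s - sign * si) + np.sin(sign * phi) * (t - ti)
            v = -np.sin(sign * phi) * (s - sign * si) + np.cos(sign * phi) * (t - ti)
            img += amp * _aniso(u, v, su, sv)
    for _ in range(3):
        ti = rng.uniform(-t_span, t_span)
        su = rng.uniform(2.0, 6.0)
        sv = rng.uniform(2.0, 6.0)
        amp = rng.uniform(0.3, 0.65) * rng.choice([-1.0, 1.0])
        phi = rng.choice([0.0, np.pi / 2])  # self-mirrored orientations only
        u = np.cos(phi) * s + np.sin(phi) * (t - ti)
        v = -np.sin(phi) * s + np.cos(phi) * (t - ti)
        img += amp * _aniso(u, v, su, sv)
    return img


def _quantize(img: np.ndarray) -> np.ndarray:
    return np.round(np.clip(img, 0.0, 1.0) * 255.0).astype(np.uint8)


def make_mirrored_image(spec: FixtureSpec) -> tuple[np.ndarray, dict]:
    """A single mirror-symmetric object on a plain background.

    Returns an 8-bit grayscale image and a ground-truth record with the axis
    angle and the canvas centre (which lies on the axis).
    """
    if spec.kind not in ("mirrored_image", "cluttered_image"):
        raise InvalidParameterError("spec.kind must be mirrored_image/cluttered_image")
    rng = np.random.default_rng(spec.seed)
    s, t, xm, ym = _axis_frame(spec.size, spec.true_alpha)
    img = _paint_object(s, t, rng, spec.size, spec.n_features)
    n_clutter = int(round(spec.clutter_density * spec.size**2 / 1e4))
    if n_clutter > 0:
        # independent substream so the object is identical with clutter off
        crng = np.random.default_rng((spec.seed, 0xC1))
        half = spec.size / 2.0
        for _ in range(n_clutter):
            px = crng.uniform(-half, half)
            py = crng.uniform(-half, half)
            sig = crng.uniform(1.5, 4.0)
            amp = crng.uniform(0.2, 0.6) * crng.choice([-1.0, 1.0])
            img += amp * np.exp(-(((xm - px) ** 2 + (ym - py) ** 2) / (2.0 * sig**2)))
    truth = {
        "symmetric": True,
        "true_alpha": float(spec.true_alpha),
        "center": ((spec.size - 1) / 2.0, (spec.size - 1) / 2.0),
        "clutter_density": float(spec.clutter_density),
    }
    return _quantize(img), truth


def make_cluttered_image(spec: FixtureSpec) -> tuple[np.ndarray, dict]:
    """A mirrored object over a cluttered background; truth is unchanged."""
    if spec.clutter_density < 0:
        raise InvalidParameterError("clutter_density must be >= 0")
    return make_mirrored_image(spec)


def make_point_constellation(
    spec: FixtureSpec,
) -> tuple[list[tuple[PolarPoint, KeyPoint]], dict]:
    """A polar keypoint constellation with ground truth.

    Mirrored kind: ``n_points/2`` random points, each reflected about the
    axis with gradient orientation reflected and magnitude copied, then
    jittered in r and theta.  Asymmetric kind: fully random points and
    attributes, labelled "no axis".
    """
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "mirrored_points":
        if spec.n_points % 2:
            raise InvalidParameterError("mirrored constellations need even n_points")
        half = spec.n_points // 2
        alpha = spec.true_alpha
        r = rng.uniform(10.0, 90.0, half)
        theta = rng.uniform(-180.0, 180.0, half)
        mag = rng.uniform(20.0, 100.0, half)
        ori = rng.uniform(0.0, 360.0, half)
        rs = np.concatenate([r, r])
        ths = np.concatenate([theta, wrap_angle(2.0 * alpha - theta)])
        mags = np.concatenate([mag, mag])
        oris = np.concatenate([ori, (2.0 * alpha - ori) % 360.0])
        if spec.jitter_r > 0:
            rs = np.maximum(0.0, rs + rng.uniform(-spec.jitter_r, spec.jitter_r, len(rs)))
        if spec.jitter_theta > 0:
            ths = wrap_angle(ths + rng.uniform(-spec.jitter_theta, spec.jitter_theta, len(ths)))
        truth = {"symmetric": True, "true_alpha": float(alpha)}
    elif spec.kind == "asymmetric_points":
        rs = rng.uniform(5.0, 90.0, spec.n_points)
        ths = rng.uniform(-180.0, 180.0, spec.n_points)
        ths = wrap_angle(np.where(ths == -180.0, 180.0, ths))
        mags = rng.uniform(20.0, 100.0, spec.n_points)
        oris = rng.uniform(0.0, 360.0, spec.n_points)
        truth = {"symmetric": False, "true_alpha": None}
    else:
        raise InvalidParameterError("spec.kind must be a point-constellation kind")

    center = (spec.size - 1) / 2.0
    items = []
    for rr, th, m, q in zip(rs, ths, mags, oris):
        th = float(wrap_angle(th))
        t = np.deg2rad(th)
        kp = KeyPoint(
            x=center + float(rr * np.cos(t)),
            y=center - float(rr * np.sin(t)),
            scale=1.0,
            grad_magnitude=float(m),
            grad_orientation=float(q % 360.0),
        )
        items.append((PolarPoint(r=float(rr), theta=th, source=kp), kp))
    return items, truth


def default_suite(
    n_symmetric: int = 100,
    n_cluttered: int = 50,
    n_asymmetric: int = 50,
    seed: int = 0,
    size: int = 192,
    clutter_density: float = 2.0,
) -> list[FixtureSpec]:
    """The standard evaluation cohort: clean mirrored images, cluttered
    mirrored images and asymmetric control constellations."""
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n_symmetric):
        specs.append(
            FixtureSpec(
                kind="mirrored_image",
                seed=int(rng.integers(2**31)),
                true_alpha=float(rng.uniform(0.0, 180.0)),
                size=size,
            )
        )
    for _ in range(n_cluttered):
        specs.append(
            FixtureSpec(
                kind="cluttered_image",
                seed=int(rng.integers(2**31)),
                true_alpha=float(rng.uniform(0.0, 180.0)),
                clutter_density=clutter_density,
                size=size,
            )
        )
    for _ in range(n_asymmetric):
        specs.append(
            FixtureSpec(
                kind="asymmetric_points",
                seed=int(rng.integers(2**31)),
                n_points=60,
                size=size,
            )
        )
    return specs
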