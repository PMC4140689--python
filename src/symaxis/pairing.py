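"""Mirror-pair matching in polar coordinates.

Two points are geometric mirrors with respect to a candidate axis at angle
``alpha`` when their radii agree within ``theta_r`` and the folded residual
``theta_1 + theta_2 - 2*alpha`` is within ``theta_theta``; with ``alpha = 0``
this is exactly the polar-axis rule ``r1 = r2, theta1 = -theta2``.  A
geometric pair is confirmed when the two keypoints' gradient magnitudes agree
within a band and the orientation of one matches the mirror reflection
``2*alpha - Q`` of the other within a bin-distance band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import PolarPoint, polar_to_cartesian, wrap_angle
from .keypoints import KeyPoint

logger = logging.getLogger(__name__)

__all__ = [
    "ToleranceConfig",
    "SymmetricPair",
    "geometric_pair_test",
    "gradient_pair_test",
    "pair_residual",
    "find_symmetric_pairs",
    "normalize_magnitudes",
]


@dataclass(frozen=True)
class ToleranceConfig:
    """Acceptance bands for mirror pairing.

    ``theta_r`` (pixels) and ``theta_theta`` (degrees) bound the geometric
    residuals; ``grad_mag_tol`` bounds the magnitude difference on the
    normalized 0..100 scale and ``grad_ori_tol`` bounds the orientation
    mismatch in histogram bins.  All comparisons are inclusive.
    """

    theta_r: float
    theta_theta: float
    grad_mag_tol: float = 5.0
    grad_ori_tol: float = 2.0

    def __post_init__(self) -> None:
        for name in ("theta_r", "theta_theta", "grad_mag_tol", "grad_ori_tol"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SymmetricPair:
    """Two polar points accepted as mirrors for a candidate axis."""

    a: PolarPoint
    b: PolarPoint
    axis_angle: float
    midpoint: tuple[float, float]  # centered Cartesian (x right, y up)

    @classmethod
    def build(cls, a: PolarPoint, b: PolarPoint, axis_angle: float) -> "SymmetricPair":
        ax, ay = polar_to_cartesian(a)
        bx, by = polar_to_cartesian(b)
        return cls(a=a, b=b, axis_angle=axis_angle, midpoint=((ax + bx) / 2.0, (ay + by) / 2.0))


def angular_mirror_residual(a: PolarPoint, b: PolarPoint, alpha: float) -> float:
    """Folded residual of the mirror condition ``theta_a + theta_b = 2*alpha``."""
    return abs(wrap_angle(a.theta + b.theta - 2.0 * alpha))


def geometric_pair_test(
    a: PolarPoint, b: PolarPoint, alpha: float, tol: ToleranceConfig
) -> bool:
    """True iff a and b are geometric mirrors about the axis at ``alpha``."""
    if abs(a.r - b.r) > tol.theta_r:
        return False
    return angular_mirror_residual(a, b, alpha) <= tol.theta_theta


def gradient_pair_test(
    a: KeyPoint,
    b: KeyPoint,
    alpha: float,
    tol: ToleranceConfig,
    bin_width: float = 10.0,
) -> bool:
    """True iff the keypoints' gradient attributes are mirror-consistent.

    The orientation of ``b`` is reflected about the axis
    (``reflect(Q, alpha) = 2*alpha - Q``) and compared with the orientation
    of ``a`` as a circular distance in histogram bins.  Magnitudes are
    compared as an absolute difference; callers are expected to have
    normalized them (see :func:`normalize_magnitudes`).  When secondary
    orientation hypotheses are present the test passes if any combination
    does — gradient histograms of near-bimodal patches may present either
    lobe as the primary peak.

    Unoriented keypoints never pass (logged, not raised).
    """
    if not a.oriented or not b.oriented:
        logger.debug("pair rejected: unoriented keypoint")
        return False
    for mag_a, ori_a in a.orientation_hypotheses():
        for mag_b, ori_b in b.orientation_hypotheses():
            if abs(mag_a - mag_b) > tol.grad_mag_tol:
                continue
            bin_dist = abs(wrap_angle(ori_a + ori_b - 2.0 * alpha)) / bin_width
            if bin_dist <= tol.grad_ori_tol:
                return True
    return False


def pair_residual(
    a: PolarPoint, b: PolarPoint, alpha: float, tol: ToleranceConfig
) -> float:
    """Combined geometric residual used to rank candidate pairs.

    Each term is normalized by its tolerance so the two residuals are
    commensurate; zero tolerances contribute zero (the pair can then only
    have passed with an exact match).
    """
    res = 0.0
    if tol.theta_r > 0:
        res += abs(a.r - b.r) / tol.theta_r
    if tol.theta_theta > 0:
        res += angular_mirror_residual(a, b, alpha) / tol.theta_theta
    return res


def find_symmetric_pairs(
    points: list[tuple[PolarPoint, KeyPoint]],
    alpha: float,
    tol: ToleranceConfig,
    bin_width: float = 10.0,
    min_radius: float = 1.0,
    use_gradient: bool = True,
) -> list[SymmetricPair]:
    """All accepted mirror pairs for the candidate axis at ``alpha``.

    Candidate pairs must pass both the geometric and the gradient test;
    accepted pairs are made one-to-one by a greedy pass over candidates in
    ascending combined residual (ties broken on the point index pair).
    Points with ``r`` below ``min_radius`` lie on every axis and are skipped.
    """
    candidates = []
    n = len(points)
    for i in range(n):
        pi, ki = points[i]
        if pi.r < min_radius:
            continue
        for j in range(i + 1, n):
            pj, kj = points[j]
            if pj.r < min_radius:
                continue
            if not geometric_pair_test(pi, pj, alpha, tol):
                continue
            if use_gradient and not gradient_pair_test(ki, kj, alpha, tol, bin_width):
                continue
            candidates.append((pair_residual(pi, pj, alpha, tol), i, j))
    candidates.sort()
    used = [False] * n
    pairs = []
    for _, i, j in candidates:
        if used[i] or used[j]:
            continue
        used[i] = used[j] = True
        pairs.append(SymmetricPair.build(points[i][0], points[j][0], alpha))
    return pairs


def normalize_magnitudes(
    points: list[KeyPoint], mode: str = "log"
) -> list[KeyPoint]:
    """Rescale gradient magnitudes of oriented keypoints so the maximum is 100.

    ``linear`` divides by the constellation maximum; ``log`` applies
    ``100 * log1p(M) / log1p(max M)``, compressing the upper range so that
    the +-5 acceptance band tolerates the relative noise of histogram peak
    masses.  Secondary hypotheses are rescaled with the same map.
    """
    from dataclasses import replace

    mags = [p.grad_magnitude for p in points if p.oriented]
    if not mags:
        return list(points)
    peak = max(mags)
    if peak <= 0:
        return list(points)

    if mode == "linear":
        def f(m):
            return 100.0 * m / peak
    elif mode == "log":
        def f(m):
            return 100.0 * np.log1p(m) / np.log1p(peak)
    else:
        raise ValueError(f"unknown magnitude normalization {mode!r}")

    out = []
    for p in points:
        if not p.oriented:
            out.append(p)
            continue
        hyp = tuple((float(f(m)), q) for m, q in p.orientation_hypotheses())
        out.append(
            replace(p, grad_magnitude=float(f(p.grad_magnitude)), hypotheses=hyp)
        )
    return out
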