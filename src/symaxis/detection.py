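"""Candidate-axis sweep, vote-based selection and the full detection pipeline.

Candidate symmetry lines at ``alpha = 0, d, 2d, ...`` (axes are undirected,
so 180 degrees of sweep suffice) each collect one vote per accepted mirror
pair; the axis with the most votes wins.  The verdict is *symmetric* when
the winning vote count reaches a floor that scales with the number of usable
keypoints, *asymmetric* otherwise, and *undetermined* when the keypoint or
centroid stages fail upstream.

Because the polar mirror rule only requires the origin to lie somewhere on
the symmetry line, the pipeline optionally refines the origin: a coarse
geometric sweep proposes axes, the midpoints of their mirror pairs (which
straddle the true line) re-anchor the origin, and the final fine sweep runs
from there.  This recovers the votes that a centroid offset of even a pixel
or two would otherwise destroy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from skimage.util import img_as_float

from .config import DetectorConfig
from .errors import InvalidParameterError, NoAxisError
from .geometry import (
    Centroid,
    PolarPoint,
    centroid_mean,
    centroid_median,
    to_polar,
    wrap_angle,
)
from .keypoints import (
    KeyPoint,
    compute_gradient_features,
    extract_keypoints,
    to_intensity,
)
from .pairing import (
    SymmetricPair,
    ToleranceConfig,
    find_symmetric_pairs,
    gradient_pair_test,
    normalize_magnitudes,
    pair_residual,
)

SCHEMA_VERSION = 1

__all__ = [
    "AxisCandidate",
    "DetectionReport",
    "sweep_axes",
    "select_axis",
    "min_votes_for",
    "detect",
    "detect_constellation",
    "render_symmetry_line",
]


@dataclass(frozen=True)
class AxisCandidate:
    """One candidate symmetry line with its supporting pairs."""

    alpha: float
    pairs: tuple[SymmetricPair, ...]

    @property
    def votes(self) -> int:
        return len(self.pairs)


@dataclass
class DetectionReport:
    """Final detection verdict plus everything needed to audit it."""

    verdict: str  # "symmetric" | "asymmetric" | "undetermined"
    best_axis: AxisCandidate | None
    centroid: Centroid | None
    vote_table: list[tuple[float, int]] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    reason: str | None = None

    @property
    def best_alpha(self) -> float | None:
        return None if self.best_axis is None else self.best_axis.alpha

    def midpoints_image(self) -> list[tuple[float, float]]:
        """Pair midpoints in image pixel coordinates, ordered by their
        projection onto the axis direction."""
        if self.best_axis is None or self.centroid is None:
            return []
        a = np.deg2rad(self.best_axis.alpha)
        ux, uy = np.cos(a), np.sin(a)  # axis direction, maths orientation
        items = []
        for pair in self.best_axis.pairs:
            mx, my = pair.midpoint
            proj = mx * ux + my * uy
            items.append((proj, (self.centroid.x + mx, self.centroid.y - my)))
        items.sort(key=lambda t: t[0])
        return [xy for _, xy in items]

    def to_dict(self) -> dict:
        d = {
            "schema_version": SCHEMA_VERSION,
            "verdict": self.verdict,
            "best_alpha": self.best_alpha,
            "best_votes": None if self.best_axis is None else self.best_axis.votes,
            "centroid": None
            if self.centroid is None
            else {"x": self.centroid.x, "y": self.centroid.y, "n_points": self.centroid.n_points},
            "vote_table": [[float(a), int(v)] for a, v in self.vote_table],
            "symmetry_line": {
                "midpoints": [list(m) for m in self.midpoints_image()],
                "angle": self.best_alpha,
            },
            "parameters": self.parameters,
            "counts": self.counts,
            "reason": self.reason,
        }
        if self.best_axis is not None and self.centroid is not None:
            d["pairs"] = [
                {
                    "a": {"x": p.a.source.x, "y": p.a.source.y} if p.a.source else None,
                    "b": {"x": p.b.source.x, "y": p.b.source.y} if p.b.source else None,
                    "midpoint": [
                        self.centroid.x + p.midpoint[0],
                        self.centroid.y - p.midpoint[1],
                    ],
                    "axis_angle": p.axis_angle,
                }
                for p in self.best_axis.pairs
            ]
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _candidate_alphas(delta_alpha: float) -> np.ndarray:
    n = 180.0 / delta_alpha
    if abs(n - round(n)) > 1e-9:
        raise InvalidParameterError("delta_alpha must divide 180 evenly")
    return np.arange(int(round(n))) * delta_alpha


def sweep_axes(
    points: list[tuple[PolarPoint, KeyPoint]],
    delta_alpha: float,
    tol: ToleranceConfig,
    bin_width: float = 10.0,
    min_radius: float = 1.0,
    use_gradient: bool = True,
) -> list[AxisCandidate]:
    """Evaluate every candidate axis in ``[0, 180)`` at ``delta_alpha`` steps.

    Produces, for each candidate, the same one-to-one pair set as
    :func:`symaxis.pairing.find_symmetric_pairs`; the geometric screen is
    vectorised across pairs for speed, the confirmation and greedy
    assignment reuse the reference routines.
    """
    alphas = _candidate_alphas(delta_alpha)
    n = len(points)
    if n < 2:
        return [AxisCandidate(alpha=float(a), pairs=()) for a in alphas]
    r = np.array([p.r for p, _ in points])
    theta = np.array([p.theta for p, _ in points])
    valid = r >= min_radius
    ii, jj = np.triu_indices(n, 1)
    keep = valid[ii] & valid[jj]
    ii, jj = ii[keep], jj[keep]
    dr_ok = np.abs(r[ii] - r[jj]) <= tol.theta_r
    ii, jj = ii[dr_ok], jj[dr_ok]
    theta_sum = theta[ii] + theta[jj]

    candidates = []
    for alpha in alphas:
        residual = np.abs(wrap_angle(theta_sum - 2.0 * alpha))
        hits = residual <= tol.theta_theta
        accepted = []
        for i, j in zip(ii[hits], jj[hits]):
            pi, ki = points[i]
            pj, kj = points[j]
            if use_gradient and not gradient_pair_test(ki, kj, float(alpha), tol, bin_width):
                continue
            accepted.append((pair_residual(pi, pj, float(alpha), tol), int(i), int(j)))
        accepted.sort()
        used = np.zeros(n, dtype=bool)
        pairs = []
        for _, i, j in accepted:
            if used[i] or used[j]:
                continue
            used[i] = used[j] = True
            pairs.append(SymmetricPair.build(points[i][0], points[j][0], float(alpha)))
        candidates.append(AxisCandidate(alpha=float(alpha), pairs=tuple(pairs)))
    return candidates


def min_votes_for(n_usable: int, config: DetectorConfig) -> int:
    """Verdict floor: ``max(floor, ceil(vote_fraction * N/2))`` votes."""
    return max(
        config.min_votes_floor, int(np.ceil(config.vote_fraction * n_usable / 2.0))
    )


def select_axis(
    candidates: list[AxisCandidate], min_votes: int
) -> tuple[str, AxisCandidate | None]:
    """Pick the candidate with the most votes (ties: smallest alpha).

    Returns ``("symmetric", best)`` when the winner reaches ``min_votes``,
    ``("asymmetric", best-or-None)`` otherwise; a winner with zero votes is
    reported as absent.
    """
    if not candidates:
        raise InvalidParameterError("select_axis requires at least one candidate")
    best = max(candidates, key=lambda c: (c.votes, -c.alpha))
    if best.votes == 0:
        return "asymmetric", None
    verdict = "symmetric" if best.votes >= min_votes else "asymmetric"
    return verdict, best


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------


def _tolerances(r: np.ndarray, config: DetectorConfig, theta_r_floor: float,
                theta_theta: float) -> ToleranceConfig:
    r_range = float(r.max() - r.min()) if len(r) > 1 else 0.0
    return ToleranceConfig(
        theta_r=max(config.theta_r_fraction * r_range, theta_r_floor),
        theta_theta=theta_theta,
        grad_mag_tol=config.grad_mag_tol,
        grad_ori_tol=config.grad_ori_tol,
    )


def _polar_items(keypoints: list[KeyPoint], center: Centroid):
    polar = to_polar(keypoints, center)
    return list(zip(polar, keypoints))


def _sweep_at(keypoints, center, config, theta_r_floor, theta_theta, delta_alpha,
              use_gradient):
    items = _polar_items(keypoints, center)
    r = np.array([p.r for p, _ in items])
    tol = _tolerances(r, config, theta_r_floor, theta_theta)
    cands = sweep_axes(
        items,
        delta_alpha,
        tol,
        bin_width=config.bin_width,
        min_radius=config.min_radius,
        use_gradient=use_gradient,
    )
    return cands, tol


def _refined_center(center: Centroid, pairs, min_pairs: int) -> Centroid:
    """Move the polar origin to the mean midpoint of the supporting pairs.

    Midpoints of true mirror pairs straddle the symmetry line, so their mean
    lies on it up to averaged jitter — exactly where the origin needs to be.
    """
    if len(pairs) < min_pairs:
        return center
    mx = float(np.mean([p.midpoint[0] for p in pairs]))
    my = float(np.mean([p.midpoint[1] for p in pairs]))
    return Centroid(x=center.x + mx, y=center.y - my, n_points=center.n_points)


def _axis_separation(a: float, b: float) -> float:
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def detect_constellation(
    points: list[tuple[PolarPoint, KeyPoint]],
    config: DetectorConfig | None = None,
) -> DetectionReport:
    """Run the sweep + verdict stages on an existing polar constellation."""
    config = config or DetectorConfig()
    params = {"config": config.to_dict()}
    usable = [
        (p, k) for p, k in points if k.oriented and p.r >= config.min_radius
    ]
    counts = {"n_points": len(points), "n_usable": len(usable)}
    if len(usable) < 2:
        return DetectionReport(
            verdict="undetermined",
            best_axis=None,
            centroid=None,
            parameters=params,
            counts=counts,
            reason="fewer than 2 usable keypoints",
        )
    keypoints = normalize_magnitudes([k for _, k in usable], config.magnitude_norm)
    items = [(p, k) for (p, _), k in zip(usable, keypoints)]
    r = np.array([p.r for p, _ in items])
    tol = _tolerances(
        r, config, config.theta_r_floor,
        config.theta_theta_factor * config.delta_alpha,
    )
    cands = sweep_axes(
        items,
        config.delta_alpha,
        tol,
        bin_width=config.bin_width,
        min_radius=config.min_radius,
    )
    verdict, best = select_axis(cands, min_votes_for(len(items), config))
    params["tolerances"] = {
        "theta_r": tol.theta_r,
        "theta_theta": tol.theta_theta,
        "grad_mag_tol": tol.grad_mag_tol,
        "grad_ori_tol": tol.grad_ori_tol,
    }
    return DetectionReport(
        verdict=verdict,
        best_axis=best,
        centroid=Centroid(x=0.0, y=0.0, n_points=len(items)),
        vote_table=[(c.alpha, c.votes) for c in cands],
        parameters=params,
        counts=counts,
    )


def detect(image, config: DetectorConfig | None = None) -> DetectionReport:
    """Full pipeline: intensity, keypoints, gradient features, centroid,
    polar conversion, axis sweep (with origin refinement) and verdict."""
    config = config or DetectorConfig()
    params = {"config": config.to_dict()}

    gray = to_intensity(
        image, rgb_weights=config.rgb_weights, smoothing_sigma=config.smoothing_sigma
    )
    gray = img_as_float(np.asarray(gray))
    raw = extract_keypoints(gray, config)
    counts = {"n_keypoints": len(raw)}
    if len(raw) < 2:
        return DetectionReport(
            verdict="undetermined",
            best_axis=None,
            centroid=None,
            parameters=params,
            counts=counts,
            reason="fewer than 2 keypoints detected",
        )

    featured = compute_gradient_features(gray, raw, config)
    oriented = [k for k in featured if k.oriented]
    counts["n_oriented"] = len(oriented)
    if len(oriented) < 2:
        return DetectionReport(
            verdict="undetermined",
            best_axis=None,
            centroid=None,
            parameters=params,
            counts=counts,
            reason="fewer than 2 oriented keypoints",
        )
    oriented = normalize_magnitudes(oriented, config.magnitude_norm)

    # the centroid uses every detection: the raw constellation is better
    # mirror-balanced than the oriented subset
    centroid_of = centroid_mean if config.centroid_method == "mean" else centroid_median
    center0 = centroid_of(featured)

    fine_tt = config.theta_theta_factor * config.delta_alpha

    if not config.refine:
        cands, tol = _sweep_at(
            oriented, center0, config, config.theta_r_floor, fine_tt,
            config.delta_alpha, True,
        )
        best_center, best_cands, best_tol = center0, cands, tol
    else:
        coarse, _ = _sweep_at(
            oriented, center0, config, config.coarse_theta_r_floor,
            config.coarse_theta_theta, config.coarse_delta_alpha, False,
        )
        votes = np.array([c.votes for c in coarse])
        order = np.argsort(-votes, kind="stable")
        seeds: list[AxisCandidate] = []
        for o in order:
            if coarse[o].votes == 0:
                break
            if all(
                _axis_separation(coarse[o].alpha, s.alpha) > config.coarse_theta_theta
                for s in seeds
            ):
                seeds.append(coarse[o])
            if len(seeds) >= config.refine_topk:
                break
        if not seeds:
            seeds = [max(coarse, key=lambda c: (c.votes, -c.alpha))]

        best_center, best_cands, best_tol, best_votes = None, None, None, -1
        for seed in seeds:
            center = _refined_center(center0, seed.pairs, config.refine_min_pairs)
            for _ in range(config.refine_mid_passes):
                mid, _ = _sweep_at(
                    oriented, center, config, config.mid_theta_r_floor,
                    config.mid_theta_theta, config.coarse_delta_alpha, True,
                )
                top = max(mid, key=lambda c: (c.votes, -c.alpha))
                center = _refined_center(center, top.pairs, config.refine_min_pairs)
            cands, tol = _sweep_at(
                oriented, center, config, config.theta_r_floor, fine_tt,
                config.delta_alpha, True,
            )
            top_votes = max(c.votes for c in cands)
            if top_votes > best_votes:
                best_center, best_cands, best_tol, best_votes = (
                    center, cands, tol, top_votes,
                )

    n_usable = sum(
        1
        for p, _ in _polar_items(oriented, best_center)
        if p.r >= config.min_radius
    )
    counts["n_usable"] = n_usable
    min_votes = min_votes_for(n_usable, config)
    verdict, best = select_axis(best_cands, min_votes)
    params["tolerances"] = {
        "theta_r": best_tol.theta_r,
        "theta_theta": best_tol.theta_theta,
        "grad_mag_tol": best_tol.grad_mag_tol,
        "grad_ori_tol": best_tol.grad_ori_tol,
    }
    params["min_votes"] = min_votes
    return DetectionReport(
        verdict=verdict,
        best_axis=best,
        centroid=best_center,
        vote_table=[(c.alpha, c.votes) for c in best_cands],
        parameters=params,
        counts=counts,
    )


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------


def _line_endpoints(cx, cy, alpha, shape):
    """Integer endpoints of the axis line clipped to the image rectangle."""
    h, w = shape[:2]
    a = np.deg2rad(alpha)
    dx, dy = np.cos(a), -np.sin(a)  # raster orientation (y down)
    ts = []
    if abs(dx) > 1e-12:
        ts += [(0 - cx) / dx, (w - 1 - cx) / dx]
    if abs(dy) > 1e-12:
        ts += [(0 - cy) / dy, (h - 1 - cy) / dy]
    pts = []
    for t in ts:
        x, y = cx + t * dx, cy + t * dy
        if -0.5 <= x <= w - 0.5 and -0.5 <= y <= h - 0.5:
            pts.append((int(round(np.clip(y, 0, h - 1))), int(round(np.clip(x, 0, w - 1)))))
    pts = sorted(set(pts))
    if len(pts) < 2:
        return None
    return pts[0], pts[-1]


def render_symmetry_line(report: DetectionReport, image) -> np.ndarray:
    """Draw the pair midpoints, the midpoint polyline and the straight axis
    through the centroid onto a copy of ``image`` (returned as RGB uint8)."""
    from skimage.draw import disk, line

    if report.verdict != "symmetric":
        raise NoAxisError("render_symmetry_line requires a symmetric verdict")
    arr = np.asarray(image)
    gray = img_as_float(to_intensity(arr))
    canvas = np.stack([gray, gray, gray], axis=-1)
    canvas = (np.clip(canvas, 0, 1) * 255).astype(np.uint8)
    h, w = gray.shape

    axis_color = (220, 40, 40)
    poly_color = (40, 160, 220)
    mid_color = (250, 210, 40)

    ends = _line_endpoints(
        report.centroid.x, report.centroid.y, report.best_axis.alpha, gray.shape
    )
    if ends is not None:
        rr, cc = line(*ends[0], *ends[1])
        canvas[rr, cc] = axis_color

    mids = report.midpoints_image()
    for (x0, y0), (x1, y1) in zip(mids, mids[1:]):
        rr, cc = line(
            int(round(np.clip(y0, 0, h - 1))),
            int(round(np.clip(x0, 0, w - 1))),
            int(round(np.clip(y1, 0, h - 1))),
            int(round(np.clip(x1, 0, w - 1))),
        )
        canvas[rr, cc] = poly_color
    for x, y in mids:
        rr, cc = disk((y, x), 2.5, shape=gray.shape)
        canvas[rr, cc] = mid_color
    return canvas
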