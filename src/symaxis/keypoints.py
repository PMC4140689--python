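"""Keypoint extraction and per-keypoint gradient statistics.

A keypoint carries a subpixel location, a detection scale and — after
:func:`gradient_features` — a gradient magnitude/orientation pair obtained
from a Gaussian-weighted orientation histogram of the pixels around it.
Keypoints whose histogram peak is too weak relative to the total mass are
flagged ``unoriented`` and excluded from mirror pairing downstream.

The detector backend is scikit-image's SIFT, which is deterministic for a
fixed image and parameter set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.feature import SIFT
from skimage.util import img_as_float

from .config import DEFAULT_RGB_WEIGHTS, DetectorConfig
from .errors import InvalidInputError, InvalidParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "KeyPoint",
    "GradientHistogram",
    "to_intensity",
    "extract_keypoints",
    "gradient_features",
    "compute_gradient_features",
    "orientation_histogram",
    "keypoints_to_frame",
    "frame_to_keypoints",
    "write_keypoints",
    "read_keypoints",
]


@dataclass(frozen=True)
class KeyPoint:
    """An image feature with location, scale and gradient attributes.

    ``grad_magnitude`` is the mass of the peak orientation-histogram bin and
    ``grad_orientation`` is the centre of that bin in degrees ``[0, 360)``.
    ``hypotheses`` optionally stores additional (magnitude, orientation)
    candidates from secondary histogram peaks; the first entry always equals
    the primary pair.
    """

    x: float
    y: float
    scale: float
    grad_magnitude: float | None = None
    grad_orientation: float | None = None
    unoriented: bool = False
    hypotheses: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.grad_magnitude is not None and self.grad_magnitude < 0:
            raise ValueError("grad_magnitude must be >= 0")
        if self.grad_orientation is not None and not (
            0.0 <= self.grad_orientation < 360.0
        ):
            raise ValueError("grad_orientation must lie in [0, 360)")

    @property
    def oriented(self) -> bool:
        return self.grad_magnitude is not None and not self.unoriented

    def orientation_hypotheses(self) -> tuple[tuple[float, float], ...]:
        """All (magnitude, orientation) candidates, primary first."""
        if self.hypotheses:
            return self.hypotheses
        if self.grad_magnitude is None or self.grad_orientation is None:
            return ()
        return ((self.grad_magnitude, self.grad_orientation),)


@dataclass(frozen=True)
class GradientHistogram:
    """Orientation histogram of Gaussian-weighted gradient magnitudes."""

    n_bins: int
    weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.n_bins < 1 or len(self.weights) != self.n_bins:
            raise ValueError("weights length must equal n_bins")
        if np.any(np.asarray(self.weights) < 0):
            raise ValueError("histogram weights must be >= 0")

    @property
    def bin_width(self) -> float:
        return 360.0 / self.n_bins

    @property
    def total_mass(self) -> float:
        return float(np.sum(self.weights))

    def bin_center(self, index: int) -> float:
        return (index + 0.5) * self.bin_width


def to_intensity(image, rgb_weights=DEFAULT_RGB_WEIGHTS, smoothing_sigma=0.0):
    """Collapse an RGB raster to a single intensity channel.

    Already single-channel images are returned unchanged.  RGB(A) input is
    combined with the given luma weights into a float image in ``[0, 1]``.
    Optional Gaussian pre-smoothing is off by default.
    """
    arr = np.asarray(image)
    if arr.size == 0 or arr.ndim < 2:
        raise InvalidInputError("empty or non-2D image")
    if arr.ndim == 2:
        out = arr.copy()
    elif arr.ndim == 3 and arr.shape[2] == 1:
        out = arr[:, :, 0].copy()
    elif arr.ndim == 3 and arr.shape[2] in (3, 4):
        rgb = img_as_float(arr[:, :, :3])
        w = np.asarray(rgb_weights, dtype=float)
        w = w / w.sum()
        out = rgb @ w
    else:
        raise InvalidInputError(f"unsupported image shape {arr.shape}")
    if smoothing_sigma > 0:
        from scipy.ndimage import gaussian_filter

        out = gaussian_filter(img_as_float(out), smoothing_sigma)
    return out


def extract_keypoints(image, config: DetectorConfig | None = None) -> list[KeyPoint]:
    """Detect scale-invariant keypoints on a single-channel image.

    Returns keypoints with subpixel locations and scales only; gradient
    attributes are filled in by :func:`compute_gradient_features`.  An empty
    list is a valid result (e.g. for structureless images).
    """
    config = config or DetectorConfig()
    arr = img_as_float(np.asarray(image))
    if arr.ndim != 2:
        raise InvalidInputError("extract_keypoints expects a single-channel image")
    if min(arr.shape) < 16:
        raise InvalidInputError("image min dimension must be >= 16 px")
    detector = SIFT(**config.sift_params)
    try:
        detector.detect(arr)
    except RuntimeError:
        # the backend raises when no keypoints survive; an empty result is valid
        return []
    pos = detector.positions  # (row, col), subpixel
    scales = detector.sigmas
    if len(pos) == 0:
        return []
    # drop duplicate detections (same location and scale)
    key = np.round(
        np.column_stack([pos, scales[:, None]]), config.dedup_decimals
    )
    _, idx = np.unique(key, axis=0, return_index=True)
    idx = np.sort(idx)
    return [
        KeyPoint(x=float(pos[i, 1]), y=float(pos[i, 0]), scale=float(scales[i]))
        for i in idx
    ]


def _gradient_fields(image):
    """Central-difference gradients (one-sided at borders), magnitude and
    orientation in degrees with counter-clockwise-positive convention."""
    arr = img_as_float(np.asarray(image))
    gy, gx = np.gradient(arr)  # np.gradient: central interior, one-sided edges
    magnitude = np.hypot(gx, gy)
    # raster y points down; negate gy so 0 deg means a gradient along +x
    orientation = np.rad2deg(np.arctan2(-gy, gx)) % 360.0
    return magnitude, orientation


def orientation_histogram(
    magnitude,
    orientation,
    weights,
    n_bins: int,
    smooth_passes: int = 0,
) -> GradientHistogram:
    """Accumulate weighted gradient magnitudes into an orientation histogram.

    ``smooth_passes`` applies a circular box filter [1,1,1]/3 that preserves
    the total mass.
    """
    bw = 360.0 / n_bins
    bins = np.minimum((np.asarray(orientation) / bw).astype(int), n_bins - 1)
    hist = np.zeros(n_bins)
    np.add.at(hist, bins.ravel(), (np.asarray(magnitude) * np.asarray(weights)).ravel())
    for _ in range(smooth_passes):
        hist = (np.roll(hist, 1) + hist + np.roll(hist, -1)) / 3.0
    return GradientHistogram(n_bins=n_bins, weights=hist)


def _window_bounds(shape, x, y, window):
    """Pixel bounds of a window centred on (x, y); even windows put the extra
    pixel on the high side."""
    h, w = shape
    ri, ci = int(round(y)), int(round(x))
    lo = (window - 1) // 2
    hi = window // 2
    r0, r1 = ri - lo, ri + hi + 1
    c0, c1 = ci - lo, ci + hi + 1
    clipped = r0 < 0 or c0 < 0 or r1 > h or c1 > w
    return max(0, r0), min(h, r1), max(0, c0), min(w, c1), clipped


def gradient_features(
    image,
    point: KeyPoint,
    window: int = 16,
    sigma: float | None = None,
    n_bins: int = 36,
    orientation_floor: float = 0.05,
    smooth_passes: int = 0,
    return_histogram: bool = False,
):
    """Compute a keypoint's gradient magnitude and orientation.

    Gradients are taken with central differences inside a ``window`` around
    the keypoint, weighted by a Gaussian of width ``sigma`` (default
    1.5 x keypoint scale) centred on the subpixel location, and accumulated
    into an ``n_bins`` orientation histogram.  The keypoint's orientation is
    the centre of the peak bin, its magnitude the peak bin mass.  If the peak
    holds no more than ``orientation_floor`` of the total mass the keypoint
    is flagged unoriented.

    The window is clipped (with a logged warning) when it reaches the image
    border; a window larger than the image is a parameter error.
    """
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise InvalidInputError("gradient_features expects a single-channel image")
    if n_bins < 4:
        raise InvalidParameterError("n_bins must be >= 4")
    if window > min(arr.shape):
        raise InvalidParameterError(
            f"window {window} larger than image {arr.shape}"
        )
    if sigma is None:
        sigma = 1.5 * point.scale
    magnitude, orientation = _gradient_fields(arr)
    r0, r1, c0, c1, clipped = _window_bounds(arr.shape, point.x, point.y, window)
    if clipped:
        logger.warning(
            "gradient window clipped at image border for keypoint (%.1f, %.1f)",
            point.x,
            point.y,
        )
    rr, cc = np.mgrid[r0:r1, c0:c1]
    gauss = np.exp(-(((rr - point.y) ** 2 + (cc - point.x) ** 2) / (2.0 * sigma**2)))
    hist = orientation_histogram(
        magnitude[r0:r1, c0:c1],
        orientation[r0:r1, c0:c1],
        gauss,
        n_bins,
        smooth_passes=smooth_passes,
    )
    total = hist.total_mass
    peak = int(np.argmax(hist.weights))
    peak_mass = float(hist.weights[peak])
    if total <= 0 or peak_mass <= orientation_floor * total:
        out = replace(
            point,
            grad_magnitude=0.0,
            grad_orientation=0.0,
            unoriented=True,
            hypotheses=None,
        )
    else:
        out = replace(
            point,
            grad_magnitude=peak_mass,
            grad_orientation=hist.bin_center(peak),
            unoriented=False,
            hypotheses=None,
        )
    if return_histogram:
        return out, hist
    return out


def _orientation_hypotheses(hist: GradientHistogram, ratio: float, max_n: int):
    """Local histogram maxima within ``ratio`` of the global peak, strongest
    first.  Keeping secondary peaks avoids the lobe-flip instability of
    near-bimodal gradient distributions."""
    w = hist.weights
    peak = w.max()
    is_local = (w >= np.roll(w, 1)) & (w >= np.roll(w, -1)) & (w >= ratio * peak)
    idx = np.flatnonzero(is_local)
    order = np.argsort(-w[idx], kind="stable")
    idx = idx[order][:max_n]
    return tuple((float(w[i]), hist.bin_center(int(i))) for i in idx)


def compute_gradient_features(
    image, points: list[KeyPoint], config: DetectorConfig | None = None
) -> list[KeyPoint]:
    """Vectorised batch version of :func:`gradient_features` used by the
    detection pipeline.

    With ``config.window`` unset the window adapts to the keypoint scale
    (covering ~3 Gaussian widths) so that large-scale keypoints are not
    truncated.  Secondary orientation hypotheses are recorded per keypoint.
    """
    config = config or DetectorConfig()
    arr = img_as_float(np.asarray(image))
    magnitude, orientation = _gradient_fields(arr)
    out = []
    for pt in points:
        sigma = config.sigma_factor * pt.scale
        if config.window is not None:
            window = config.window
        else:
            window = min(config.max_window, int(2 * np.ceil(3 * sigma) + 1))
        window = min(window, min(arr.shape))
        r0, r1, c0, c1, _ = _window_bounds(arr.shape, pt.x, pt.y, window)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        gauss = np.exp(-(((rr - pt.y) ** 2 + (cc - pt.x) ** 2) / (2.0 * sigma**2)))
        hist = orientation_histogram(
            magnitude[r0:r1, c0:c1],
            orientation[r0:r1, c0:c1],
            gauss,
            config.n_bins,
            smooth_passes=config.smooth_passes,
        )
        total = hist.total_mass
        peak = int(np.argmax(hist.weights))
        peak_mass = float(hist.weights[peak])
        if total <= 0 or peak_mass <= config.orientation_floor * total:
            out.append(
                replace(
                    pt,
                    grad_magnitude=0.0,
                    grad_orientation=0.0,
                    unoriented=True,
                    hypotheses=None,
                )
            )
            continue
        hyp = _orientation_hypotheses(
            hist, config.secondary_peak_ratio, config.max_hypotheses
        )
        out.append(
            replace(
                pt,
                grad_magnitude=peak_mass,
                grad_orientation=hist.bin_center(peak),
                unoriented=False,
                hypotheses=hyp,
            )
        )
    return out


# --------------------------------------------------------------------------
# keypoint table import/export
# --------------------------------------------------------------------------

_COLUMNS = ["x", "y", "scale", "grad_magnitude", "grad_orientation", "unoriented"]


def keypoints_to_frame(points: list[KeyPoint]) -> pd.DataFrame:
    rows = [
        {
            "x": p.x,
            "y": p.y,
            "scale": p.scale,
            "grad_magnitude": p.grad_magnitude,
            "grad_orientation": p.grad_orientation,
            "unoriented": p.unoriented,
        }
        for p in points
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def frame_to_keypoints(frame: pd.DataFrame) -> list[KeyPoint]:
    pts = []
    for row in frame.itertuples(index=False):
        mag = None if pd.isna(row.grad_magnitude) else float(row.grad_magnitude)
        ori = None if pd.isna(row.grad_orientation) else float(row.grad_orientation)
        pts.append(
            KeyPoint(
                x=float(row.x),
                y=float(row.y),
                scale=float(row.scale),
                grad_magnitude=mag,
                grad_orientation=ori,
                unoriented=bool(row.unoriented),
            )
        )
    return pts


def write_keypoints(points: list[KeyPoint], path) -> None:
    """Write keypoints as CSV or JSON, by file extension."""
    path = str(path)
    frame = keypoints_to_frame(points)
    if path.endswith(".json"):
        with open(path, "w") as fh:
            json.dump(frame.to_dict(orient="records"), fh, indent=2)
    else:
        frame.to_csv(path, index=False)


def read_keypoints(path) -> list[KeyPoint]:
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            frame = pd.DataFrame(json.load(fh), columns=_COLUMNS)
    else:
        frame = pd.read_csv(path)
    return frame_to_keypoints(frame)
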