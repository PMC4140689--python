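"""Detector configuration.

Every tolerance, window, bin, sweep and vote parameter of the pipeline lives
here so that a run is fully described by (image, config).  The defaults are
the reference configuration used throughout the test-suite; ``symaxis config
--show`` prints them as YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

#: ITU-R BT.709 luma weights, the scikit-image ``rgb2gray`` convention.
DEFAULT_RGB_WEIGHTS = (0.2125, 0.7154, 0.0721)


@dataclass
class DetectorConfig:
    """Full parameter set of the symmetry-axis detector.

    Attributes are grouped by pipeline stage.  ``theta_theta_factor`` and
    ``theta_r_fraction`` define the pairing tolerances relative to the sweep
    increment and the constellation's radial range respectively, which keeps
    behaviour resolution-independent; absolute overrides are available
    through :class:`symaxis.pairing.ToleranceConfig` when calling the pairing
    layer directly.
    """

    # -- intensity conversion -------------------------------------------------
    rgb_weights: tuple[float, float, float] = DEFAULT_RGB_WEIGHTS
    smoothing_sigma: float = 0.0          # optional pre-blur, off by default
    equalize: bool = False                # optional contrast step, off by default

    # -- keypoint detector ----------------------------------------------------
    sift_params: dict = field(default_factory=dict)  # forwarded to skimage SIFT
    dedup_decimals: int = 3               # rounding used to drop duplicate detections

    # -- gradient features ----------------------------------------------------
    window: int | None = None             # None -> scale-adaptive window
    max_window: int = 65
    sigma_factor: float = 1.5             # Gaussian sigma = factor * keypoint scale
    n_bins: int = 36
    smooth_passes: int = 2                # circular [1,1,1]/3 histogram smoothing
    orientation_floor: float = 0.05       # peak must exceed this fraction of mass
    secondary_peak_ratio: float = 0.8     # extra orientation hypotheses above this
    max_hypotheses: int = 3

    # -- centroid -------------------------------------------------------------
    centroid_method: str = "mean"         # "mean" or "median"

    # -- pairing tolerances ---------------------------------------------------
    theta_r_fraction: float = 0.02        # fraction of the constellation r-range
    theta_r_floor: float = 1.0            # pixels
    theta_theta_factor: float = 2.0       # multiples of delta_alpha
    grad_mag_tol: float = 5.0             # on the normalized 0..100 scale
    grad_ori_tol: float = 2.0             # histogram bins
    magnitude_norm: str = "log"           # "log" or "linear", both map max -> 100
    min_radius: float = 1.0               # points closer to the origin are skipped

    # -- axis sweep -----------------------------------------------------------
    delta_alpha: float = 1.0              # degrees between candidate axes

    # -- verdict --------------------------------------------------------------
    vote_fraction: float = 0.2            # of floor(N/2) usable-keypoint pairs
    min_votes_floor: int = 3

    # -- origin refinement ----------------------------------------------------
    refine: bool = True
    refine_topk: int = 5
    refine_mid_passes: int = 2
    coarse_delta_alpha: float = 2.0
    coarse_theta_theta: float = 16.0
    coarse_theta_r_floor: float = 8.0
    mid_theta_theta: float = 6.0
    mid_theta_r_floor: float = 3.0
    refine_min_pairs: int = 3             # pairs needed before the origin moves

    def __post_init__(self) -> None:
        if self.centroid_method not in ("mean", "median"):
            raise ValueError(f"unknown centroid_method {self.centroid_method!r}")
        if self.magnitude_norm not in ("log", "linear"):
            raise ValueError(f"unknown magnitude_norm {self.magnitude_norm!r}")
        if self.n_bins < 4:
            raise ValueError("n_bins must be >= 4")

    @property
    def bin_width(self) -> float:
        return 360.0 / self.n_bins

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rgb_weights"] = list(self.rgb_weights)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "DetectorConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        if "rgb_weights" in data:
            data["rgb_weights"] = tuple(data["rgb_weights"])
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "DetectorConfig":
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    @classmethod
    def load(cls, path) -> "DetectorConfig":
        with open(path) as fh:
            return cls.from_yaml(fh.read())

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_yaml())

    def replace(self, **changes) -> "DetectorConfig":
        return dataclasses.replace(self, **changes)
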