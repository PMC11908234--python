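"""Image-quantification operators for telophase HBCs.

Deterministic operators on numeric arrays mirroring the manual ImageJ
procedures used on confocal z-stacks: background-subtracted integrated
intensity over a region of interest, sister-chromatid asymmetry calls
from two integrated signals, division-angle classification relative to
the basal layer, and rank-correlation colocalization of two channels.
Segmentation is out of scope — regions of interest are inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr, pearsonr

__all__ = [
    "ZStack",
    "AsymmetryCall",
    "integrated_signal",
    "chromatid_asymmetry",
    "classify_division_angle",
    "colocalization",
    "DIVISION_ANGLE_CLASSES",
    "DEFAULT_ASYMMETRY_THRESHOLD",
]

#: ratio cut separating the symmetric (~1.1) and asymmetric (~1.6)
#: clusters of the fitted ratio mixture; configurable per call
DEFAULT_ASYMMETRY_THRESHOLD = 1.5

DIVISION_ANGLE_CLASSES = ("parallel", "intermediate", "perpendicular")


@dataclass(frozen=True)
class ZStack:
    """A 3-D gray-value array (z, y, x) with a scalar background level.

    `background` is the mean gray value of a user-chosen background
    region, estimated upstream; it is subtracted per voxel.
    """

    voxels: np.ndarray
    background: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=float)
        if v.ndim != 3:
            raise ValueError(f"voxels must be 3-D (z, y, x), got shape {v.shape}")
        if np.any(v < 0):
            raise ValueError("gray values must be non-negative")
        if self.background < 0:
            raise ValueError("background must be non-negative")
        object.__setattr__(self, "voxels", v)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape


@dataclass(frozen=True)
class AsymmetryCall:
    """Asymmetry classification of one chromatid pair."""

    ratio: float
    label: str  # "asymmetric" | "symmetric"
    threshold: float


def integrated_signal(
    stack: ZStack, roi: np.ndarray, per_slice: bool = False
) -> float | np.ndarray:
    """Background-subtracted integrated intensity over a region mask.

    Sums (raw - background) over the ROI voxels of every z-slice — the
    3-D analogue of summing per-slice RawIntDen values after background
    subtraction.  Negative per-voxel differences are kept (not clamped)
    so the total matches a subtraction of summed gray values.

    With ``per_slice=True`` returns the z-profile of per-slice sums
    instead of the grand total.
    """
    roi = np.asarray(roi)
    if roi.dtype != bool:
        raise ValueError("roi must be a boolean mask")
    if roi.shape != stack.shape:
        raise ValueError(f"roi shape {roi.shape} != stack shape {stack.shape}")
    if not roi.any():
        raise ValueError("roi is empty")
    diff = (stack.voxels - stack.background) * roi
    if per_slice:
        return diff.sum(axis=(1, 2))
    return float(diff.sum())


def chromatid_asymmetry(
    signal_a: float,
    signal_b: float,
    threshold: float = DEFAULT_ASYMMETRY_THRESHOLD,
) -> AsymmetryCall:
    """Call a chromatid pair asymmetric when max/min >= threshold."""
    if signal_a <= 0 or signal_b <= 0:
        raise ValueError(
            "both integrated signals must be positive; resolve background "
            "over-subtraction upstream"
        )
    if threshold < 1:
        raise ValueError(f"threshold must be >= 1, got {threshold!r}")
    ratio = max(signal_a, signal_b) / min(signal_a, signal_b)
    label = "asymmetric" if ratio >= threshold else "symmetric"
    return AsymmetryCall(ratio=ratio, label=label, threshold=threshold)


def classify_division_angle(angle: float) -> str:
    """Classify a division angle (degrees to the basal layer).

    [0, 30) -> parallel, [30, 60) -> intermediate, [60, 90] ->
    perpendicular.  Half-open bins give a deterministic convention at
    the 30 and 60 degree boundaries.
    """
    if not 0 <= angle <= 90:
        raise ValueError(
            f"angle must lie in [0, 90] degrees (fold larger angles upstream), "
            f"got {angle!r}"
        )
    if angle < 30:
        return "parallel"
    if angle < 60:
        return "intermediate"
    return "perpendicular"


def colocalization(
    channel1: np.ndarray, channel2: np.ndarray, method: str = "spearman"
) -> float:
    """Colocalization of two channels over the same ROI voxels.

    Spearman rank correlation (midrank ties) of the paired intensities:
    +1 perfect colocalization, 0 none, -1 perfect anti-correlation.
    ``method="pearson"`` gives the linear-correlation variant.
    """
    c1 = np.asarray(channel1, dtype=float).ravel()
    c2 = np.asarray(channel2, dtype=float).ravel()
    if c1.shape != c2.shape:
        raise ValueError("channels must have the same number of voxels")
    if c1.size < 3:
        raise ValueError("need at least 3 paired voxels")
    if np.ptp(c1) == 0 or np.ptp(c2) == 0:
        raise ValueError("correlation undefined for a constant channel")
    if method == "spearman":
        rho = spearmanr(c1, c2).statistic
    elif method == "pearson":
        rho = pearsonr(c1, c2).statistic
    else:
        raise ValueError(f"method must be 'spearman' or 'pearson', got {method!r}")
    return float(rho)
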