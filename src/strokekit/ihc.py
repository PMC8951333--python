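"""IHC quantification: BBB leakage ratios and EV-homing fluorescence.

Blood-brain-barrier damage is quantified on two-channel fluorescence
sections co-stained for CD31 (endothelium) and mouse IgG (serum protein
that extravasates when the barrier leaks): within rectangular ROIs
placed in the infarct, penumbral and healthy areas, both channels are
thresholded with one fixed setting per channel per batch, and IgG
extravasation is the IgG-positive area divided by the CD31-positive
area, subsequently normalized per animal to the healthy-region ratio.

EV homing is quantified on whole-brain fluorescence scans of labeled
vesicles: mean intensity in equal-area ROIs (1 mm² in the source
protocol) of the ischemic hemisphere is normalized to mirrored ROIs of
the healthy hemisphere, cancelling labeling-efficiency differences.

ROI placement is always supplied by the caller (config-driven); the
module never auto-places ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TwoChannelImage",
    "ROI",
    "threshold_channel",
    "quantify_rois",
    "extravasation_ratio",
    "normalize_to_healthy",
    "roi_mean_fluorescence",
    "normalize_hemispheres",
]


@dataclass
class TwoChannelImage:
    """CD31 + IgG channels on a shared pixel grid."""

    cd31: np.ndarray
    igg: np.ndarray
    pixel_size_mm: float

    def __post_init__(self) -> None:
        self.cd31 = np.asarray(self.cd31, dtype=float)
        self.igg = np.asarray(self.igg, dtype=float)
        if self.cd31.shape != self.igg.shape:
            raise ValueError("channels must share dimensions")
        if np.any(self.cd31 < 0) or np.any(self.igg < 0):
            raise ValueError("intensities must be nonnegative")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")


@dataclass(frozen=True)
class ROI:
    """Axis-aligned rectangular region of interest."""

    label: str
    row: int
    col: int
    height: int
    width: int

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row, self.row + self.height), slice(self.col, self.col + self.width)

    def validate(self, shape: tuple[int, int]) -> None:
        if (
            self.row < 0
            or self.col < 0
            or self.height <= 0
            or self.width <= 0
            or self.row + self.height > shape[0]
            or self.col + self.width > shape[1]
        ):
            raise ValueError(f"ROI {self.label!r} at ({self.row},{self.col}) "
                             f"size {self.height}x{self.width} outside image {shape}")

    @property
    def area_px(self) -> int:
        return self.height * self.width


def threshold_channel(channel: np.ndarray, threshold: float) -> np.ndarray:
    """Positive-pixel mask: intensities strictly above a fixed threshold.

    The threshold is one global setting shared across an entire study
    batch, mirroring an "analyze everything with the same settings"
    convention; record it alongside the results.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    return np.asarray(channel) > threshold


def quantify_rois(
    cd31_mask: np.ndarray,
    igg_mask: np.ndarray,
    rois: Sequence[ROI],
    pixel_size_mm: float,
) -> pd.DataFrame:
    """Positive areas (mm²) of both channels inside each ROI.

    Returns one row per ROI with columns ``region``, ``cd31_area_mm2``,
    ``igg_area_mm2``. ROIs of the same region are averaged downstream by
    :func:`extravasation_ratio`.
    """
    px_area = pixel_size_mm**2
    rows = []
    for roi in rois:
        roi.validate(cd31_mask.shape)
        rs, cs = roi.slices()
        rows.append(
            {
                "region": roi.label,
                "cd31_area_mm2": float(cd31_mask[rs, cs].sum() * px_area),
                "igg_area_mm2": float(igg_mask[rs, cs].sum() * px_area),
            }
        )
    return pd.DataFrame(rows)


def extravasation_ratio(quant: pd.DataFrame) -> pd.DataFrame:
    """Per-region IgG/CD31 area ratio from an ROI table.

    ROIs of the same region are first averaged (per section), then the
    ratio of mean IgG area to mean CD31 area is taken. Regions with zero
    CD31 area are flagged (``ratio`` NaN) and excluded from downstream
    averages.
    """
    grouped = quant.groupby("region", sort=False)[["cd31_area_mm2", "igg_area_mm2"]].mean()
    out = grouped.reset_index()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = out["igg_area_mm2"] / out["cd31_area_mm2"]
    out["ratio"] = ratio.where(out["cd31_area_mm2"] > 0, np.nan)
    return out


def normalize_to_healthy(
    ratios: pd.DataFrame, healthy_label: str = "healthy"
) -> pd.DataFrame:
    """Normalize per-region ratios to the healthy-region ratio.

    Input: per-region table with a ``ratio`` column (one animal,
    typically section-averaged). Adds ``normalized_ratio`` =
    ratio / healthy ratio; the healthy region maps to exactly 1.
    """
    sel = ratios.loc[ratios["region"] == healthy_label, "ratio"]
    if sel.empty or not np.isfinite(sel.iloc[0]) or sel.iloc[0] <= 0:
        raise ValueError("healthy-region ratio missing or nonpositive")
    healthy = float(sel.iloc[0])
    out = ratios.copy()
    out["normalized_ratio"] = out["ratio"] / healthy
    out.loc[out["region"] == healthy_label, "normalized_ratio"] = 1.0
    return out


def roi_mean_fluorescence(image: np.ndarray, rois: Sequence[ROI]) -> pd.DataFrame:
    """Arithmetic mean intensity per ROI (equal-area ROIs expected)."""
    image = np.asarray(image)
    areas = {roi.area_px for roi in rois}
    if len(areas) > 1:
        raise ValueError("homing ROIs must all have identical area")
    rows = []
    for i, roi in enumerate(rois):
        roi.validate(image.shape)
        rs, cs = roi.slices()
        rows.append({"roi": i, "region": roi.label, "mean": float(image[rs, cs].mean())})
    return pd.DataFrame(rows)


def normalize_hemispheres(
    ischemic_means: Sequence[float], healthy_means: Sequence[float]
) -> tuple[float, np.ndarray]:
    """Hemisphere-normalized homing ratio.

    Ratio of the average ischemic-ROI mean to the average healthy-ROI
    mean, computed from paired equal-area ROIs; per-pair ratios are also
    returned. Invariant to global positive rescaling of the image, which
    removes labeling-efficiency differences between EV preparations.
    """
    isch = np.asarray(ischemic_means, dtype=float)
    heal = np.asarray(healthy_means, dtype=float)
    if isch.shape != heal.shape or isch.size == 0:
        raise ValueError("need equally many ischemic and healthy ROI means")
    if np.any(heal == 0):
        raise ValueError("healthy ROI mean of 0 cannot normalize")
    return float(isch.mean() / heal.mean()), isch / heal
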