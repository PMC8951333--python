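"""Hemodynamic image analysis for wide-field stroke imaging.

Implements the analysis chain applied to laser-speckle perfusion and
multispectral oxy-/deoxyhemoglobin image time series of mice undergoing
transient middle cerebral artery occlusion (tMCAO) with reperfusion:

1. temporal downsampling of 1 frame/s recordings to 1 frame/min,
2. masking of large cortical vessels by intensity thresholding,
3. baseline flow from the healthy hemisphere before reperfusion,
4. segmentation of the ischemic hemisphere into ischemic core (< 33 % of
   baseline), penumbra (33–70 %) and normally perfused tissue (> 70 %),
5. frame-by-frame tracking of the ischemic-core area, and
6. extraction of per-region relative signal traces scaled to start at 1,
   with the time axis aligned so that reperfusion is minute 0.

All masks operate on a pixel grid in row-major order with 0-based frame
indices. Physical units enter only through pixel-size metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "BACKGROUND",
    "HEALTHY",
    "ISCHEMIC",
    "PerfusionStack",
    "HemisphereGeometry",
    "VesselMask",
    "RegionMasks",
    "CoreTrack",
    "TraceSet",
    "downsample_to_minutes",
    "reference_map",
    "detect_vessels",
    "compute_baseline",
    "build_region_masks",
    "track_core",
    "extract_region_traces",
    "FlowAnalysis",
    "analyze_flow",
]

#: Hemisphere label codes used in :class:`HemisphereGeometry.labels`.
BACKGROUND, HEALTHY, ISCHEMIC = 0, 1, 2

#: Default perfusion thresholds, as fractions of baseline.
THETA_CORE = 0.33
THETA_NORMAL = 0.70

REGIONS = ("core", "penumbra", "normal")
SIGNALS = ("flow", "oxyhb", "deoxyhb")


@dataclass
class PerfusionStack:
    """A time-ordered stack of 2D intensity frames with event metadata.

    Parameters
    ----------
    frames
        Array of shape ``(T, H, W)``. Flow frames are nonnegative relative
        perfusion; hemoglobin frames may be signed concentration changes.
    timestamps
        Seconds from recording start, strictly increasing, one per frame.
    injection_frame, reperfusion_frame
        Frame indices of the EV/vehicle injection and of reperfusion.
        Injection happens during occlusion, so it precedes reperfusion.
    pixel_size_mm
        Edge length of one pixel in mm.
    signal
        One of ``"flow"``, ``"oxyhb"``, ``"deoxyhb"``.
    """

    frames: np.ndarray
    timestamps: np.ndarray
    injection_frame: int
    reperfusion_frame: int
    pixel_size_mm: float
    signal: str = "flow"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        n = self.frames.shape[0]
        if self.timestamps.shape != (n,):
            raise ValueError("one timestamp per frame required")
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        for name in ("injection_frame", "reperfusion_frame"):
            idx = getattr(self, name)
            if not 0 <= idx < n:
                raise ValueError(f"{name}={idx} outside frame range [0, {n})")
        if not self.injection_frame < self.reperfusion_frame:
            raise ValueError("injection_frame must precede reperfusion_frame")
        if self.signal not in SIGNALS:
            raise ValueError(f"signal must be one of {SIGNALS}")
        if self.signal == "flow" and np.any(self.frames < 0):
            raise ValueError("flow frames must be nonnegative")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class HemisphereGeometry:
    """Per-pixel hemisphere labels: background, healthy or ischemic side."""

    labels: np.ndarray
    ischemic_side: str = "left"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.ischemic_side not in ("left", "right"):
            raise ValueError("ischemic_side must be 'left' or 'right'")
        if not np.isin(self.labels, (BACKGROUND, HEALTHY, ISCHEMIC)).all():
            raise ValueError("labels must contain only codes 0/1/2")
        if not (self.labels == HEALTHY).any() or not (self.labels == ISCHEMIC).any():
            raise ValueError("both hemispheres must be non-empty")

    @property
    def healthy(self) -> np.ndarray:
        return self.labels == HEALTHY

    @property
    def ischemic(self) -> np.ndarray:
        return self.labels == ISCHEMIC

    @property
    def brain(self) -> np.ndarray:
        return self.labels != BACKGROUND


@dataclass
class VesselMask:
    """Boolean mask of large vessels plus the threshold that produced it."""

    mask: np.ndarray
    threshold: float
    method: str = "percentile"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class RegionMasks:
    """Core/penumbra/normal partition of the ischemic-hemisphere parenchyma."""

    core: np.ndarray
    penumbra: np.ndarray
    normal: np.ndarray
    baseline: float
    theta_core: float = THETA_CORE
    theta_normal: float = THETA_NORMAL
    reference_frames: tuple[int, int] = (0, 0)  # [start, stop) averaged

    def __post_init__(self) -> None:
        if not 0 < self.theta_core < self.theta_normal < 1:
            raise ValueError("require 0 < theta_core < theta_normal < 1")
        overlap = (self.core & self.penumbra) | (self.core & self.normal) | (
            self.penumbra & self.normal
        )
        if overlap.any():
            raise ValueError("region masks overlap")

    def __getitem__(self, region: str) -> np.ndarray:
        if region not in REGIONS:
            raise KeyError(region)
        return getattr(self, region)

    @property
    def union(self) -> np.ndarray:
        return self.core | self.penumbra | self.normal


@dataclass
class CoreTrack:
    """Ischemic-core pixel count and hemisphere fraction over time."""

    time_min: np.ndarray
    counts: np.ndarray
    fractions: np.ndarray
    parenchyma_pixels: int

    def __post_init__(self) -> None:
        if np.any((self.fractions < 0) | (self.fractions > 1)):
            raise ValueError("core fractions must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.time_min,
                "core_pixels": self.counts,
                "core_fraction": self.fractions,
            }
        )


@dataclass
class TraceSet:
    """Relative per-region traces, each scaled to start at exactly 1."""

    time_min: np.ndarray
    traces: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def __getitem__(self, key: tuple[str, str]) -> np.ndarray:
        return self.traces[key]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: time_min, region, signal, value."""
        rows = []
        for (signal, region), values in self.traces.items():
            rows.append(
                pd.DataFrame(
                    {
                        "time_min": self.time_min,
                        "region": region,
                        "signal": signal,
                        "value": values,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# pipeline operations
# ---------------------------------------------------------------------------


def downsample_to_minutes(stack: PerfusionStack, frames_per_minute: int = 60) -> PerfusionStack:
    """Reduce a ~1 frame/s stack to one frame per minute.

    Each output frame is the pixelwise arithmetic mean of its minute's
    source frames; a trailing partial minute is dropped and event indices
    are remapped to the minute that contains them.
    """
    n_minutes = stack.n_frames // frames_per_minute
    if n_minutes < 1:
        raise ValueError(
            f"need at least {frames_per_minute} frames to form one minute, "
            f"got {stack.n_frames}"
        )
    used = n_minutes * frames_per_minute
    grouped = stack.frames[:used].reshape(
        n_minutes, frames_per_minute, *stack.shape
    )
    frames = grouped.mean(axis=1)
    timestamps = stack.timestamps[:used].reshape(n_minutes, frames_per_minute).mean(axis=1)
    return replace(
        stack,
        frames=frames,
        timestamps=timestamps,
        injection_frame=min(stack.injection_frame // frames_per_minute, n_minutes - 1),
        reperfusion_frame=min(stack.reperfusion_frame // frames_per_minute, n_minutes - 1),
    )


def reference_map(stack: PerfusionStack) -> np.ndarray:
    """Pixelwise mean of all frames strictly before reperfusion."""
    if stack.reperfusion_frame < 1:
        raise ValueError("no frames before reperfusion")
    return stack.frames[: stack.reperfusion_frame].mean(axis=0)


def detect_vessels(
    reference: np.ndarray,
    geometry: HemisphereGeometry,
    percentile: float = 95.0,
) -> VesselMask:
    """Mask large vessels as pixels above a percentile of brain intensities.

    Vessels carry specular, flow-independent signal in speckle imaging and
    are excluded from every downstream region statistic. A constant
    (degenerate) reference map yields an empty mask with a warning.
    """
    if not 50 < percentile < 100:
        raise ValueError("percentile must lie in (50, 100)")
    brain = geometry.brain
    values = reference[brain]
    if np.ptp(values) == 0:
        warnings.warn("constant reference map: returning empty vessel mask", stacklevel=2)
        return VesselMask(np.zeros_like(brain, dtype=bool), float("inf"),
                          f"percentile-{percentile:g}")
    threshold = float(np.percentile(values, percentile))
    mask = brain & (reference > threshold)
    return VesselMask(mask, threshold, f"percentile-{percentile:g}")


def compute_baseline(
    stack: PerfusionStack,
    geometry: HemisphereGeometry,
    vessels: VesselMask,
) -> float:
    """Baseline flow: mean healthy-hemisphere parenchyma intensity pre-reperfusion."""
    if stack.signal != "flow":
        raise ValueError("baseline is defined on the flow signal")
    if stack.reperfusion_frame < 1:
        raise ValueError("no frames before reperfusion")
    pixels = geometry.healthy & ~vessels.mask
    pre = stack.frames[: stack.reperfusion_frame]
    return float(pre[:, pixels].mean())


def _classify(
    reference: np.ndarray,
    baseline: float,
    theta_core: float,
    theta_normal: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # Compare the ratio to the threshold literal, not the intensity to
    # theta*B: with decimal thresholds the product picks up rounding that
    # would misclassify values sitting exactly on a printed boundary
    # (e.g. 33.0 at B = 100 must be penumbra, not core).
    ratio = reference / baseline
    core = ratio < theta_core
    normal = ratio > theta_normal
    penumbra = ~core & ~normal
    return core, penumbra, normal


def build_region_masks(
    stack: PerfusionStack,
    geometry: HemisphereGeometry,
    vessels: VesselMask,
    baseline: float,
    theta_core: float = THETA_CORE,
    theta_normal: float = THETA_NORMAL,
) -> RegionMasks:
    """Segment the ischemic hemisphere by pre-reperfusion flow vs baseline.

    Pixels of the pre-reperfusion mean flow map are assigned to the
    ischemic core (ratio < ``theta_core``), penumbra (closed interval) or
    normally perfused tissue (ratio > ``theta_normal``); vessel pixels are
    excluded. The three masks tile the ischemic-hemisphere parenchyma.
    """
    if stack.signal != "flow":
        raise ValueError("region masks are defined on the flow signal")
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    ref = reference_map(stack)
    core, penumbra, normal = _classify(ref, baseline, theta_core, theta_normal)
    parenchyma = geometry.ischemic & ~vessels.mask
    return RegionMasks(
        core=core & parenchyma,
        penumbra=penumbra & parenchyma,
        normal=normal & parenchyma,
        baseline=baseline,
        theta_core=theta_core,
        theta_normal=theta_normal,
        reference_frames=(0, stack.reperfusion_frame),
    )


def track_core(
    stack: PerfusionStack,
    geometry: HemisphereGeometry,
    vessels: VesselMask,
    baseline: float,
    theta_core: float = THETA_CORE,
) -> CoreTrack:
    """Track the ischemic-core area frame by frame.

    Unlike the static region masks, every frame is re-classified: the core
    at time t is the set of ischemic-hemisphere parenchyma pixels whose
    flow is below ``theta_core`` of baseline in that frame. The fraction is
    reported relative to the ischemic-hemisphere parenchyma pixel count,
    and the time axis (minutes for a downsampled stack) puts reperfusion
    at 0.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    parenchyma = geometry.ischemic & ~vessels.mask
    denominator = int(parenchyma.sum())
    ratios = stack.frames[:, parenchyma] / baseline
    counts = (ratios < theta_core).sum(axis=1)
    time_min = np.arange(stack.n_frames, dtype=float) - stack.reperfusion_frame
    return CoreTrack(
        time_min=time_min,
        counts=counts,
        fractions=counts / denominator,
        parenchyma_pixels=denominator,
    )


def extract_region_traces(
    stacks: Mapping[str, PerfusionStack],
    masks: RegionMasks,
    regions: tuple[str, ...] = REGIONS,
) -> TraceSet:
    """Extract relative per-region traces for each signal.

    For every signal and region, the per-frame mean over the (static)
    region mask is divided by its own first value, so each trace starts at
    exactly 1; the time axis is shifted so the reperfusion frame is
    minute 0. Regions with an empty mask are omitted with a warning; a
    first value of 0 cannot be scaled and raises.
    """
    items = list(stacks.items())
    if not items:
        raise ValueError("no stacks given")
    n = items[0][1].n_frames
    rep = items[0][1].reperfusion_frame
    for _, stk in items:
        if stk.n_frames != n or stk.reperfusion_frame != rep:
            raise ValueError("all stacks must share frame count and event indices")
    time_min = np.arange(n, dtype=float) - rep
    out = TraceSet(time_min=time_min)
    for signal, stk in items:
        for region in regions:
            mask = masks[region]
            if not mask.any():
                warnings.warn(f"empty {region} mask: trace omitted", stacklevel=2)
                continue
            means = stk.frames[:, mask].mean(axis=1)
            if means[0] == 0:
                raise ValueError(
                    f"first value of {signal}/{region} trace is 0; cannot scale to 1"
                )
            trace = means / means[0]
            trace[0] = 1.0  # exact by contract, immune to rounding
            out.traces[(signal, region)] = trace
    return out


@dataclass
class FlowAnalysis:
    """Bundle of everything the flow pipeline derives from one recording."""

    stack: PerfusionStack  # downsampled
    vessels: VesselMask
    baseline: float
    masks: RegionMasks
    track: CoreTrack


def analyze_flow(
    stack: PerfusionStack,
    geometry: HemisphereGeometry,
    vessel_percentile: float = 95.0,
    theta_core: float = THETA_CORE,
    theta_normal: float = THETA_NORMAL,
    downsample: bool = True,
) -> FlowAnalysis:
    """Run the full flow pipeline on one recording.

    Downsamples to one frame per minute (when the recording is long
    enough and ``downsample`` is set), masks vessels on the
    pre-reperfusion mean map, computes the healthy-hemisphere baseline,
    builds the static core/penumbra/normal masks and tracks the ischemic
    core frame by frame.
    """
    if downsample and stack.n_frames >= 60:
        stack = downsample_to_minutes(stack)
    vessels = detect_vessels(reference_map(stack), geometry, vessel_percentile)
    baseline = compute_baseline(stack, geometry, vessels)
    masks = build_region_masks(stack, geometry, vessels, baseline,
                               theta_core, theta_normal)
    track = track_core(stack, geometry, vessels, baseline, theta_core)
    return FlowAnalysis(stack=stack, vessels=vessels, baseline=baseline,
                        masks=masks, track=track)
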