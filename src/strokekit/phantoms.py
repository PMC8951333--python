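"""Synthetic phantoms with known ground truth for every pipeline stage.

Each generator emulates one class of raw input the analysis consumes —
perfusion and hemoglobin image time series of a two-hemisphere brain
field, serial-section area tables of known-volume solids, two-channel
vessel/IgG-leak images, fluorescent whole-brain homing scans, and
behavioral trial tables — and returns the matching ground truth so that
downstream estimates can be scored against programmed values.

Phantom geometry lives entirely on the pixel grid; physical units are
attached only through pixel-size metadata. Noise is additive Gaussian,
truncated at zero for perfusion intensities. Vessels are straight bright
strips whose pixels carry ``baseline * multiplier`` regardless of the
region underneath, so vessel masking is a meaningful step. Reperfusion
recovery follows a single exponential toward a per-region plateau.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .hemodynamics import (
    BACKGROUND,
    HEALTHY,
    ISCHEMIC,
    HemisphereGeometry,
    PerfusionStack,
    THETA_CORE,
)
from .ihc import ROI, TwoChannelImage
from .stereology import SectionSeries

__all__ = [
    "VesselParams",
    "RegionKinetics",
    "PhantomSpec",
    "GroundTruth",
    "generate_perfusion_phantom",
    "generate_hemoglobin_phantom",
    "generate_section_series",
    "generate_ihc_image",
    "generate_homing_image",
    "generate_behavior_dataset",
    "semiaxes_for_core_fraction",
]

REGIONS = ("core", "penumbra", "normal")


@dataclass(frozen=True)
class VesselParams:
    """Bright-strip vessel layout: count, strip width and brightness."""

    count: int = 4
    width_px: int = 1
    multiplier: float = 3.0

    def validate(self) -> None:
        if self.count < 0 or self.width_px < 1:
            raise ValueError("vessel count must be >= 0 and width >= 1 px")
        if self.multiplier <= 1:
            raise ValueError("vessel intensity multiplier must exceed 1")


@dataclass(frozen=True)
class RegionKinetics:
    """Post-reperfusion relaxation: exponential approach to a plateau.

    ``plateau`` is expressed as a fraction of the healthy baseline for
    flow, or as a multiple of the region's pre-reperfusion level for
    hemoglobin signals. ``tau_s`` is the exponential time constant in
    seconds.
    """

    plateau: float
    tau_s: float = 40.0

    def validate(self, name: str) -> None:
        if self.tau_s <= 0:
            raise ValueError(f"{name}: tau_s must be positive")


def _default_recovery() -> dict[str, RegionKinetics]:
    return {
        "core": RegionKinetics(0.6),
        "penumbra": RegionKinetics(0.9),
        "normal": RegionKinetics(1.0),
    }


def _default_oxy() -> dict[str, RegionKinetics]:
    return {
        "core": RegionKinetics(1.5),
        "penumbra": RegionKinetics(1.2),
        "normal": RegionKinetics(1.0),
    }


def _default_deoxy() -> dict[str, RegionKinetics]:
    return {
        "core": RegionKinetics(0.5),
        "penumbra": RegionKinetics(0.8),
        "normal": RegionKinetics(1.0),
    }


@dataclass
class PhantomSpec:
    """Full description of a perfusion/hemoglobin phantom recording.

    The defaults describe the study conditions emulated throughout the
    test suite: a 96 x 128 px two-hemisphere field imaged at 1 frame/s
    for 7 min, occlusion from the start, injection at 60 s, reperfusion
    at 180 s, an elliptical ischemic core at 20 % of baseline perfusion
    surrounded by a penumbral annulus at 50 %, additive noise at 2 % of
    baseline, and exponential post-reperfusion recovery.
    """

    height: int = 96
    width: int = 128
    pixel_size_mm: float = 0.08
    midline_col: int = 64
    ischemic_side: str = "left"
    vessels: VesselParams = field(default_factory=VesselParams)
    core_center: tuple[float, float] = (48.0, 30.0)   # (row, col)
    core_semiaxes: tuple[float, float] = (14.0, 10.0)  # (row, col) px
    core_perfusion: float = 0.2
    penumbra_width_px: float = 6.0
    penumbra_perfusion: float = 0.5
    baseline: float = 100.0
    noise_sd: float = 2.0
    frame_rate_hz: float = 1.0
    duration_s: float = 420.0
    occlusion_frame: int = 0
    injection_frame: int = 60
    reperfusion_frame: int = 180
    recovery: dict[str, RegionKinetics] = field(default_factory=_default_recovery)
    oxy_kinetics: dict[str, RegionKinetics] = field(default_factory=_default_oxy)
    deoxy_kinetics: dict[str, RegionKinetics] = field(default_factory=_default_deoxy)
    hemoglobin_level: float = 1.0
    hemoglobin_noise_sd: float = 0.02
    seed: int = 0

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))

    def validate(self) -> None:
        if not 0 <= self.core_perfusion <= 1:
            raise ValueError("core perfusion fraction must lie in [0, 1]")
        if not 0 <= self.penumbra_perfusion <= 1:
            raise ValueError("penumbra perfusion fraction must lie in [0, 1]")
        if not self.core_perfusion < self.penumbra_perfusion < 1:
            raise ValueError("require core perfusion < penumbra perfusion < 1")
        if not 0 < self.midline_col < self.width:
            raise ValueError("midline column must split the field")
        if self.baseline <= 0:
            raise ValueError("baseline intensity must be positive")
        if self.noise_sd < 0 or self.hemoglobin_noise_sd < 0:
            raise ValueError("noise SD must be nonnegative")
        events = (self.occlusion_frame, self.injection_frame, self.reperfusion_frame)
        if not (events[0] < events[1] < events[2]):
            raise ValueError("event frames must be strictly increasing")
        if events[-1] >= self.n_frames:
            raise ValueError("event frames must fall within the recording")
        self.vessels.validate()
        for name, kin in (
            list(self.recovery.items())
            + list(self.oxy_kinetics.items())
            + list(self.deoxy_kinetics.items())
        ):
            kin.validate(name)
        cy, cx = self.core_center
        ay, ax = self.core_semiaxes
        ry, rx = ay + self.penumbra_width_px, ax + self.penumbra_width_px
        lo, hi = (0, self.midline_col) if self.ischemic_side == "left" else (
            self.midline_col, self.width
        )
        if cx - rx < lo or cx + rx > hi or cy - ry < 0 or cy + ry > self.height:
            raise ValueError(
                "core plus penumbra annulus must fit inside the ischemic hemisphere"
            )


@dataclass
class GroundTruth:
    """Programmed truth accompanying a generated phantom stack."""

    geometry: HemisphereGeometry
    vessel_mask: np.ndarray
    core: np.ndarray
    penumbra: np.ndarray
    normal: np.ndarray
    baseline: float
    #: noiseless per-region parenchyma value at every frame, per signal:
    #: ``region_values[signal][region]`` is a (T,) array.
    region_values: dict[str, dict[str, np.ndarray]]
    #: fraction of ischemic-hemisphere parenchyma below the core threshold
    #: at every frame, computed on the noiseless field.
    core_fraction: np.ndarray

    @property
    def parenchyma(self) -> np.ndarray:
        return self.geometry.ischemic & ~self.vessel_mask

    def region_mask(self, region: str) -> np.ndarray:
        return {"core": self.core, "penumbra": self.penumbra, "normal": self.normal}[region]

    def true_trace(self, signal: str, region: str) -> np.ndarray:
        values = self.region_values[signal][region]
        return values / values[0]


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _hemisphere_labels(spec: PhantomSpec) -> np.ndarray:
    labels = np.full((spec.height, spec.width), HEALTHY, dtype=np.int8)
    cols = np.arange(spec.width)
    on_ischemic = cols < spec.midline_col if spec.ischemic_side == "left" else (
        cols >= spec.midline_col
    )
    labels[:, on_ischemic] = ISCHEMIC
    return labels


def _vessel_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    mask = np.zeros((spec.height, spec.width), dtype=bool)
    w = spec.vessels.width_px
    for i in range(spec.vessels.count):
        if i % 4 == 3:  # every fourth vessel runs horizontally
            row = int(rng.integers(w, spec.height - w))
            mask[row : row + w, :] = True
        else:
            col = int(rng.integers(w, spec.width - w))
            mask[:, col : col + w] = True
    return mask


def _ellipse(
    shape: tuple[int, int], center: tuple[float, float], semiaxes: tuple[float, float]
) -> np.ndarray:
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    cy, cx = center
    ay, ax = semiaxes
    return ((rows - cy) / ay) ** 2 + ((cols - cx) / ax) ** 2 <= 1.0


def semiaxes_for_core_fraction(
    spec: PhantomSpec, fraction: float, aspect: float = 1.4
) -> tuple[float, float]:
    """Semi-axes so the core ellipse covers ~``fraction`` of the hemisphere.

    Sizing by continuous ellipse area against the full hemisphere pixel
    count; the exact ground-truth fraction is whatever the rasterized
    ellipse delivers and is reported in :class:`GroundTruth`.
    """
    hemisphere_px = spec.height * (
        spec.midline_col if spec.ischemic_side == "left" else spec.width - spec.midline_col
    )
    area = fraction * hemisphere_px
    ay = math.sqrt(area * aspect / math.pi)
    return (ay, ay / aspect)


# ---------------------------------------------------------------------------
# perfusion / hemoglobin phantoms
# ---------------------------------------------------------------------------


def _region_timecourses(
    spec: PhantomSpec,
    pre_levels: Mapping[str, float],
    kinetics: Mapping[str, RegionKinetics],
    plateau_mode: str,
) -> dict[str, np.ndarray]:
    """Noiseless per-region value at every frame.

    ``plateau_mode='baseline'`` reads plateaus as fractions of the healthy
    baseline (flow); ``'relative'`` as multiples of the region's own
    pre-reperfusion level (hemoglobin).
    """
    t = np.arange(spec.n_frames) / spec.frame_rate_hz
    t_rep = spec.reperfusion_frame / spec.frame_rate_hz
    out = {}
    for region, pre in pre_levels.items():
        kin = kinetics[region]
        plateau = kin.plateau * (spec.baseline if plateau_mode == "baseline" else pre)
        values = np.full(spec.n_frames, pre, dtype=float)
        post = t >= t_rep
        values[post] = plateau + (pre - plateau) * np.exp(-(t[post] - t_rep) / kin.tau_s)
        out[region] = values
    return out


def _assemble_stack(
    spec: PhantomSpec,
    geometry: HemisphereGeometry,
    vessel_mask: np.ndarray,
    masks: dict[str, np.ndarray],
    region_values: dict[str, np.ndarray],
    healthy_level: float,
    vessel_level: float | None,
    noise_sd: float,
    rng: np.random.Generator,
    signal: str,
    clip_zero: bool,
) -> PerfusionStack:
    frames = np.full((spec.n_frames, spec.height, spec.width), healthy_level)
    for region, values in region_values.items():
        frames[:, masks[region]] = values[:, None]
    if vessel_level is not None:
        frames[:, vessel_mask] = vessel_level
    if noise_sd > 0:
        frames = frames + rng.normal(0.0, noise_sd, frames.shape)
        if clip_zero:
            np.clip(frames, 0.0, None, out=frames)
    return PerfusionStack(
        frames=frames,
        timestamps=np.arange(spec.n_frames) / spec.frame_rate_hz,
        injection_frame=spec.injection_frame,
        reperfusion_frame=spec.reperfusion_frame,
        pixel_size_mm=spec.pixel_size_mm,
        signal=signal,
    )


def _phantom_geometry(
    spec: PhantomSpec, rng: np.random.Generator
) -> tuple[HemisphereGeometry, np.ndarray, dict[str, np.ndarray]]:
    geometry = HemisphereGeometry(_hemisphere_labels(spec), spec.ischemic_side)
    vessel_mask = _vessel_mask(spec, rng)
    shape = (spec.height, spec.width)
    core_full = _ellipse(shape, spec.core_center, spec.core_semiaxes)
    ay, ax = spec.core_semiaxes
    outer = _ellipse(
        shape,
        spec.core_center,
        (ay + spec.penumbra_width_px, ax + spec.penumbra_width_px),
    )
    parenchyma = geometry.ischemic & ~vessel_mask
    core = core_full & parenchyma
    penumbra = outer & ~core_full & parenchyma
    normal = parenchyma & ~core & ~penumbra
    return geometry, vessel_mask, {"core": core, "penumbra": penumbra, "normal": normal}


def _true_core_fraction(
    masks: dict[str, np.ndarray],
    region_values: dict[str, np.ndarray],
    baseline: float,
) -> np.ndarray:
    counts = {r: int(m.sum()) for r, m in masks.items()}
    total = sum(counts.values())
    n_frames = len(next(iter(region_values.values())))
    frac = np.zeros(n_frames)
    for region, values in region_values.items():
        frac += counts[region] * (values / baseline < THETA_CORE)
    return frac / total


def generate_perfusion_phantom(spec: PhantomSpec) -> tuple[PerfusionStack, GroundTruth]:
    """Generate a perfusion (flow) phantom recording plus its ground truth.

    Deterministic given ``spec.seed``. Pre-reperfusion, true-core
    parenchyma pixels sit at ``core_perfusion * baseline`` (plus noise),
    penumbra at ``penumbra_perfusion * baseline``, everything else at
    baseline; vessel pixels carry ``baseline * multiplier`` throughout.
    After the reperfusion frame each region relaxes exponentially toward
    its programmed plateau.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    geometry, vessel_mask, masks = _phantom_geometry(spec, rng)
    pre_levels = {
        "core": spec.core_perfusion * spec.baseline,
        "penumbra": spec.penumbra_perfusion * spec.baseline,
        "normal": spec.baseline,
    }
    region_values = _region_timecourses(spec, pre_levels, spec.recovery, "baseline")
    stack = _assemble_stack(
        spec, geometry, vessel_mask, masks, region_values,
        healthy_level=spec.baseline,
        vessel_level=spec.baseline * spec.vessels.multiplier,
        noise_sd=spec.noise_sd, rng=rng, signal="flow", clip_zero=True,
    )
    truth = GroundTruth(
        geometry=geometry,
        vessel_mask=vessel_mask,
        core=masks["core"],
        penumbra=masks["penumbra"],
        normal=masks["normal"],
        baseline=spec.baseline,
        region_values={"flow": region_values},
        core_fraction=_true_core_fraction(masks, region_values, spec.baseline),
    )
    return stack, truth


def generate_hemoglobin_phantom(
    spec: PhantomSpec,
) -> tuple[PerfusionStack, PerfusionStack, GroundTruth]:
    """Generate paired oxy-/deoxyhemoglobin concentration-change stacks.

    Both signals rest at ``hemoglobin_level`` before reperfusion and step
    exponentially toward per-region plateaus expressed as multiples of
    that resting level (``oxy_kinetics`` / ``deoxy_kinetics``); a mirrored
    pair (e.g. oxy 1.5x, deoxy 0.5x in the core) emulates reperfusion
    re-oxygenation. The same seed yields the same geometry as the flow
    phantom so masks transfer across signals.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    geometry, vessel_mask, masks = _phantom_geometry(spec, rng)
    pre = {r: spec.hemoglobin_level for r in REGIONS}
    oxy_values = _region_timecourses(spec, pre, spec.oxy_kinetics, "relative")
    deoxy_values = _region_timecourses(spec, pre, spec.deoxy_kinetics, "relative")
    oxy = _assemble_stack(
        spec, geometry, vessel_mask, masks, oxy_values,
        healthy_level=spec.hemoglobin_level, vessel_level=None,
        noise_sd=spec.hemoglobin_noise_sd, rng=rng, signal="oxyhb", clip_zero=False,
    )
    deoxy = _assemble_stack(
        spec, geometry, vessel_mask, masks, deoxy_values,
        healthy_level=spec.hemoglobin_level, vessel_level=None,
        noise_sd=spec.hemoglobin_noise_sd, rng=rng, signal="deoxyhb", clip_zero=False,
    )
    flow_values = _region_timecourses(
        spec,
        {
            "core": spec.core_perfusion * spec.baseline,
            "penumbra": spec.penumbra_perfusion * spec.baseline,
            "normal": spec.baseline,
        },
        spec.recovery,
        "baseline",
    )
    truth = GroundTruth(
        geometry=geometry,
        vessel_mask=vessel_mask,
        core=masks["core"],
        penumbra=masks["penumbra"],
        normal=masks["normal"],
        baseline=spec.baseline,
        region_values={"flow": flow_values, "oxyhb": oxy_values, "deoxyhb": deoxy_values},
        core_fraction=_true_core_fraction(masks, flow_values, spec.baseline),
    )
    return oxy, deoxy, truth


# ---------------------------------------------------------------------------
# stereology phantom
# ---------------------------------------------------------------------------


def generate_section_series(
    shape: str,
    d: float,
    *,
    radius: float,
    length: float | None = None,
    offset: float | None = None,
) -> tuple[SectionSeries, float]:
    """Serial analytic cross-sections of a known-volume solid.

    Sections are taken at planes ``z = z_min + offset + k*d`` (offset
    defaults to ``d/2``, the systematic midpoint design). Returns the
    section series and the analytic volume.

    Parameters
    ----------
    shape
        ``"cylinder"`` (sections perpendicular to the axis, requires
        ``length``) or ``"sphere"``.
    d
        Section spacing in mm, must be positive.
    radius, length
        Solid dimensions in mm.
    """
    if d <= 0:
        raise ValueError("section spacing d must be positive")
    if radius <= 0:
        raise ValueError("radius must be positive")
    if offset is None:
        offset = d / 2.0
    if shape == "cylinder":
        if length is None or length <= 0:
            raise ValueError("cylinder requires a positive length")
        z = np.arange(offset, length, d)
        areas = np.full(z.size, math.pi * radius**2)
        volume = math.pi * radius**2 * length
    elif shape == "sphere":
        z = np.arange(-radius + offset, radius, d)
        areas = math.pi * np.clip(radius**2 - z**2, 0.0, None)
        volume = 4.0 / 3.0 * math.pi * radius**3
    else:
        raise ValueError("shape must be 'cylinder' or 'sphere'")
    if areas.size == 0:
        raise ValueError("spacing too coarse: no section planes intersect the solid")
    return SectionSeries(areas=areas, spacing=d), volume


# ---------------------------------------------------------------------------
# IHC leak phantom
# ---------------------------------------------------------------------------

IHC_REGIONS = ("infarct", "penumbra", "healthy")


def generate_ihc_image(
    vessel_density: float = 0.05,
    leak_fractions: Mapping[str, float] | None = None,
    seed: int = 0,
    block_shape: tuple[int, int] = (120, 60),
    pixel_size_mm: float = 0.005,
    foreground: float = 255.0,
) -> tuple[TwoChannelImage, list[ROI], dict[str, float]]:
    """Two-channel vessel/IgG-leak phantom with per-region ground truth.

    The field is three side-by-side region blocks (infarct, penumbra,
    healthy). The CD31 channel marks ``vessel_density`` of each block's
    pixels; the IgG channel marks ``leak_fraction * cd31_count`` pixels,
    so the programmed IgG/CD31 area ratio per region equals the leak
    fraction (up to pixel rounding — the achieved ratio is returned).
    One ROI spans each block.
    """
    if leak_fractions is None:
        leak_fractions = {"infarct": 0.8, "penumbra": 0.4, "healthy": 0.1}
    if not 0 < vessel_density <= 1:
        raise ValueError("vessel density must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    h, w = block_shape
    cd31 = np.zeros((h, w * len(IHC_REGIONS)))
    igg = np.zeros_like(cd31)
    rois, truth = [], {}
    block_px = h * w
    for i, region in enumerate(IHC_REGIONS):
        n_vessel = int(round(vessel_density * block_px))
        n_leak = int(round(leak_fractions[region] * n_vessel))
        flat_v = rng.choice(block_px, size=n_vessel, replace=False)
        flat_l = rng.choice(block_px, size=n_leak, replace=False)
        block = slice(i * w, (i + 1) * w)
        cd31[:, block].flat[flat_v] = foreground
        igg[:, block].flat[flat_l] = foreground
        rois.append(ROI(label=region, row=0, col=i * w, height=h, width=w))
        truth[region] = n_leak / n_vessel if n_vessel else 0.0
    image = TwoChannelImage(cd31=cd31, igg=igg, pixel_size_mm=pixel_size_mm)
    return image, rois, truth


# ---------------------------------------------------------------------------
# EV homing phantom
# ---------------------------------------------------------------------------


def generate_homing_image(
    ischemic_mean: float = 200.0,
    healthy_mean: float = 100.0,
    noise_sd: float = 10.0,
    seed: int = 0,
    shape: tuple[int, int] = (100, 160),
    pixel_size_mm: float = 0.05,
    n_rois: int = 3,
    roi_area_mm2: float = 1.0,
) -> tuple[np.ndarray, list[ROI], list[ROI], dict[str, float]]:
    """Whole-brain fluorescence scan phantom for EV-homing quantification.

    Left half is the ischemic hemisphere at ``ischemic_mean``, right half
    healthy at ``healthy_mean``, with additive Gaussian noise. Equal-area
    square ROIs (default 1 mm²) are placed at mirrored positions in the
    two hemispheres. Returns the image, ischemic ROIs, paired healthy
    ROIs, and the programmed truth (means and their ratio).
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    mid = w // 2
    side = int(round(math.sqrt(roi_area_mm2) / pixel_size_mm))
    if side > min(h, mid):
        raise ValueError("ROI does not fit inside a hemisphere")
    image = np.full((h, w), healthy_mean)
    image[:, :mid] = ischemic_mean
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, image.shape)
    rows = np.linspace(0, h - side, n_rois).round().astype(int)
    col_i = (mid - side) // 2
    col_h = mid + col_i
    ischemic_rois = [
        ROI("ischemic", int(r), col_i, side, side) for r in rows
    ]
    healthy_rois = [
        ROI("healthy", int(r), col_h, side, side) for r in rows
    ]
    truth = {
        "ischemic_mean": ischemic_mean,
        "healthy_mean": healthy_mean,
        "ratio": ischemic_mean / healthy_mean,
    }
    return image, ischemic_rois, healthy_rois, truth


# ---------------------------------------------------------------------------
# behavior phantom
# ---------------------------------------------------------------------------


def generate_behavior_dataset(
    n_per_group: int = 10,
    seed: int = 0,
    groups: tuple[str, ...] = ("control", "pre_ric", "post_ric"),
    corner_right_p: Mapping[str, float] | None = None,
    hargreaves_mean_s: Mapping[str, float] | None = None,
    hargreaves_sd_s: float = 1.0,
    neuro_score_p: Mapping[str, tuple[float, ...]] | None = None,
    trials_hargreaves: int = 5,
    trials_corner: int = 10,
) -> dict[str, pd.DataFrame]:
    """Behavioral trial tables with programmable group effects.

    Emulates a post-stroke assessment session: corner-test turn records
    (Bernoulli right-turn probability per group), Hargreaves withdrawal
    latencies (normal around a per-group mean, floored at 0.5 s) for both
    hind paws, and five-point neurological scores drawn from a per-group
    categorical distribution over 0..4. Effect size 0 means identical
    distributions across groups.
    """
    if corner_right_p is None:
        corner_right_p = {"control": 0.85, "pre_ric": 0.80, "post_ric": 0.70}
    if hargreaves_mean_s is None:
        hargreaves_mean_s = {"control": 8.0, "pre_ric": 7.5, "post_ric": 6.5}
    if neuro_score_p is None:
        neuro_score_p = {
            "control": (0.0, 0.2, 0.5, 0.2, 0.1),
            "pre_ric": (0.0, 0.3, 0.5, 0.15, 0.05),
            "post_ric": (0.0, 0.4, 0.45, 0.1, 0.05),
        }
    rng = np.random.default_rng(seed)
    corner_rows, harg_rows, neuro_rows = [], [], []
    for group in groups:
        for k in range(n_per_group):
            animal = f"{group}_{k:03d}"
            turns = rng.random(trials_corner) < corner_right_p[group]
            for t, right in enumerate(turns):
                corner_rows.append(
                    {"animal": animal, "group": group, "day": 3, "trial": t,
                     "turn": "R" if right else "L"}
                )
            for paw in ("left", "right"):
                lat = rng.normal(hargreaves_mean_s[group], hargreaves_sd_s,
                                 trials_hargreaves)
                lat = np.maximum(lat, 0.5)
                for t, v in enumerate(lat):
                    harg_rows.append(
                        {"animal": animal, "group": group, "day": 7, "paw": paw,
                         "trial": t, "latency_s": float(v)}
                    )
            score = int(rng.choice(5, p=np.asarray(neuro_score_p[group])))
            neuro_rows.append(
                {"animal": animal, "group": group, "day": 1, "score": score}
            )
    return {
        "corner": pd.DataFrame(corner_rows),
        "hargreaves": pd.DataFrame(harg_rows),
        "neuroscore": pd.DataFrame(neuro_rows),
    }
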