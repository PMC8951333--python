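"""File I/O: multi-frame TIFF stacks with YAML sidecars, masks and CSV.

A recording travels as a pair of files — a multi-frame TIFF with the
image data and a YAML sidecar carrying acquisition metadata (frame
rate, event frame indices, pixel size, signal kind, ischemic side).
Masks are single-frame uint8 TIFFs; tabular results (core track,
traces, ROI tables) are tidy CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml

from .hemodynamics import HemisphereGeometry, PerfusionStack

__all__ = [
    "write_stack",
    "read_stack",
    "write_mask",
    "read_mask",
    "write_geometry",
    "read_geometry",
]


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(".yaml")


def write_stack(stack: PerfusionStack, path: str | Path,
                ischemic_side: str | None = None) -> Path:
    """Write a stack as multi-frame TIFF plus YAML sidecar; returns the TIFF path."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack.frames, dtype=np.float32))
    meta = {
        "signal": stack.signal,
        "pixel_size_mm": float(stack.pixel_size_mm),
        "injection_frame": int(stack.injection_frame),
        "reperfusion_frame": int(stack.reperfusion_frame),
        "timestamps_s": [float(t) for t in stack.timestamps],
    }
    if ischemic_side is not None:
        meta["ischemic_side"] = ischemic_side
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=False))
    return path


def read_stack(path: str | Path) -> PerfusionStack:
    """Read a stack written by :func:`write_stack`."""
    path = Path(path)
    frames = tifffile.imread(path).astype(float)
    if frames.ndim == 2:
        frames = frames[None]
    meta = yaml.safe_load(_sidecar_path(path).read_text())
    return PerfusionStack(
        frames=frames,
        timestamps=np.asarray(meta["timestamps_s"], dtype=float),
        injection_frame=int(meta["injection_frame"]),
        reperfusion_frame=int(meta["reperfusion_frame"]),
        pixel_size_mm=float(meta["pixel_size_mm"]),
        signal=meta.get("signal", "flow"),
    )


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(mask).astype(np.uint8))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(bool)


def write_geometry(geometry: HemisphereGeometry, path: str | Path) -> Path:
    """Hemisphere label map as uint8 TIFF (0 background, 1 healthy, 2 ischemic)."""
    path = Path(path)
    tifffile.imwrite(path, geometry.labels.astype(np.uint8))
    _sidecar_path(path).write_text(
        yaml.safe_dump({"ischemic_side": geometry.ischemic_side})
    )
    return path


def read_geometry(path: str | Path) -> HemisphereGeometry:
    path = Path(path)
    labels = tifffile.imread(path).astype(np.int8)
    side = "left"
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        side = yaml.safe_load(sidecar.read_text()).get("ischemic_side", "left")
    return HemisphereGeometry(labels=labels, ischemic_side=side)
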