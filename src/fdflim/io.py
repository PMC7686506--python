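"""File formats: multi-page TIFF stacks with JSON sidecars, lifetime maps, masks.

Raw stacks are plain baseline multi-page TIFF (one page per phase step,
unsigned 16-bit, page order = phase-step order) with a JSON sidecar carrying
the acquisition metadata.  Lifetime maps are single-page 32-bit float TIFF in
ns with NaN marking invalid pixels, plus a companion boolean mask TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .core import Channel, LifetimeMap, ModulationConfig, RawFrameStack

__all__ = [
    "write_stack",
    "read_stack",
    "write_lifetime_map",
    "read_lifetime_map",
    "write_mask",
    "read_mask",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(path: str | Path, stack: RawFrameStack) -> Path:
    """Write a raw frame stack as uint16 multi-page TIFF plus JSON sidecar."""
    path = Path(path)
    frames = np.clip(np.round(stack.frames), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(path, frames.astype(np.uint16))
    _sidecar(path).write_text(
        json.dumps(
            {
                "frequency_hz": stack.config.frequency_hz,
                "n_phase_steps": stack.config.n_phase_steps,
                "exposure_ms": stack.exposure_ms,
                "channel": stack.channel.value,
            },
            indent=2,
        )
    )
    return path


def read_stack(path: str | Path) -> RawFrameStack:
    """Read a raw frame stack and its JSON sidecar."""
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    frames = tifffile.imread(path).astype(float)
    if frames.ndim == 2:
        frames = frames[None]
    config = ModulationConfig(
        frequency_hz=float(meta["frequency_hz"]),
        n_phase_steps=int(meta["n_phase_steps"]),
    )
    return RawFrameStack(
        frames=frames,
        config=config,
        channel=Channel(meta["channel"]),
        exposure_ms=float(meta["exposure_ms"]),
    )


def write_lifetime_map(path: str | Path, lifetime_map: LifetimeMap) -> Path:
    """Float32 TIFF in ns (NaN = invalid) plus companion mask and dc TIFFs."""
    path = Path(path)
    tifffile.imwrite(path, lifetime_map.tau_ns.astype(np.float32))
    tifffile.imwrite(
        path.with_name(path.stem + "_valid.tif"),
        lifetime_map.valid.astype(np.uint8),
    )
    tifffile.imwrite(
        path.with_name(path.stem + "_dc.tif"),
        lifetime_map.dc.astype(np.float32),
    )
    _sidecar(path).write_text(json.dumps({"channel": lifetime_map.channel.value}))
    return path


def read_lifetime_map(path: str | Path) -> LifetimeMap:
    path = Path(path)
    tau = tifffile.imread(path).astype(float)
    valid = tifffile.imread(path.with_name(path.stem + "_valid.tif")).astype(bool)
    dc = tifffile.imread(path.with_name(path.stem + "_dc.tif")).astype(float)
    meta = json.loads(_sidecar(path).read_text())
    return LifetimeMap(tau_ns=tau, valid=valid, channel=Channel(meta["channel"]), dc=dc)


def write_mask(path: str | Path, mask: np.ndarray) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint8))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    """Boolean mask from TIFF or PNG; any nonzero value counts as inside."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr != 0
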