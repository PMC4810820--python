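"""File I/O: multi-page TIFF stacks with YAML sidecars, height maps, tables."""

from __future__ import annotations

import os

import numpy as np
import tifffile
import yaml

from .focus import HeightMap, ZStack

__all__ = [
    "write_zstack",
    "read_zstack",
    "write_heightmap",
    "read_heightmap",
]


def _sidecar(path: str) -> str:
    return os.path.splitext(path)[0] + ".yaml"


def write_zstack(path, zstack: ZStack, bits: int = 16) -> None:
    """Write a stack as a multi-page grayscale TIFF plus a YAML sidecar.

    Intensities in [0, 1] are scaled to the full 8- or 16-bit range.
    """
    if bits == 8:
        data = np.clip(zstack.slices * 255.0, 0, 255).astype(np.uint8)
    elif bits == 16:
        data = np.clip(zstack.slices * 65535.0, 0, 65535).astype(np.uint16)
    else:
        raise ValueError("bits must be 8 or 16")
    tifffile.imwrite(str(path), data, photometric="minisblack")
    with open(_sidecar(str(path)), "w") as fh:
        yaml.safe_dump({"s": zstack.s, "z_step_um": float(zstack.z_step_um),
                        "px_um": float(zstack.px_um), "bits": bits}, fh)


def read_zstack(path) -> ZStack:
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    with open(_sidecar(str(path))) as fh:
        meta = yaml.safe_load(fh)
    scale = 255.0 if meta.get("bits", 16) == 8 else 65535.0
    return ZStack(slices=data.astype(np.float32) / scale,
                  z_step_um=meta["z_step_um"], px_um=meta["px_um"])


def write_heightmap(path, hm: HeightMap) -> None:
    """Write an 8-bit height map TIFF with a YAML sidecar carrying (s, Z)."""
    tifffile.imwrite(str(path), hm.encoded.astype(np.uint8),
                     photometric="minisblack")
    with open(_sidecar(str(path)), "w") as fh:
        yaml.safe_dump({"s": hm.s, "z_step_um": float(hm.z_step_um),
                        "px_um": float(hm.px_um)}, fh)


def read_heightmap(path) -> HeightMap:
    enc = tifffile.imread(str(path)).astype(np.int32)
    with open(_sidecar(str(path))) as fh:
        meta = yaml.safe_load(fh)
    return HeightMap(encoded=enc, valid=np.ones(enc.shape, dtype=bool),
                     s=meta["s"], z_step_um=meta["z_step_um"],
                     px_um=meta["px_um"])
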