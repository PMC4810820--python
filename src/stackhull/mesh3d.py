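"""Height-map cleaning and semi-3D half-hull mesh extraction.

A decoded height map is a raster of per-pixel surface heights (µm) over an
object footprint. This module turns it into a cleaned triangle mesh of the
camera-facing surface:

1. rescale images so 1 pixel = 1 µm,
2. mask out the background using the 2D outline of the focused image,
3. optionally mask the aperture (an interior hole in the outline) so it does
   not produce spike artifacts,
4. remove outlier heights with a sliding-neighbourhood quartile filter,
5. prune sparsely populated z-levels and the bottom-most level,
6. give aperture pixels a depth equal to the lowest remaining height,
7. triangulate one vertex per valid pixel and export OBJ / OFF / CSV.
"""

from __future__ import annotations

import csv as _csv
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from ._util import boxcar_count, boxcar_sum, round_half_away
from .focus import HeightMap
from .outline2d import OutlineShape

__all__ = [
    "HeightGrid",
    "HalfHullMesh",
    "rescale_unit_pixels",
    "mask_background",
    "aperture_mask",
    "decode_grid",
    "outlier_filter",
    "prune_z_levels",
    "set_aperture_depth",
    "build_mesh",
    "write_mesh",
    "read_mesh",
]


@dataclass
class HeightGrid:
    """Per-pixel surface heights in µm with a validity mask.

    ``heights`` holds decoded heights (multiples of the z-step before
    filtering); ``valid`` marks pixels belonging to the object; ``aperture``
    marks interior-hole pixels excluded from the initial surface and filled
    in later at the object's lowest height.
    """

    heights: np.ndarray
    valid: np.ndarray
    px_um: float
    s: int
    z_step_um: float
    aperture: np.ndarray | None = None

    def __post_init__(self):
        self.heights = np.asarray(self.heights, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.heights.shape != self.valid.shape:
            raise ValueError("heights and valid must share a shape")
        if self.aperture is None:
            self.aperture = np.zeros(self.heights.shape, dtype=bool)
        else:
            self.aperture = np.asarray(self.aperture, dtype=bool)

    def replace(self, **kw) -> "HeightGrid":
        d = dict(
            heights=self.heights, valid=self.valid, px_um=self.px_um,
            s=self.s, z_step_um=self.z_step_um, aperture=self.aperture,
        )
        d.update(kw)
        return HeightGrid(**d)


@dataclass
class HalfHullMesh:
    """Triangle mesh of the camera-facing surface.

    One vertex per valid height-grid pixel (no downsampling); faces are
    index triples into ``vertices``.
    """

    vertices: np.ndarray  # (N, 3) x, y, z in µm
    faces: np.ndarray  # (M, 3) int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")


def rescale_unit_pixels(image: np.ndarray, calib_um_per_px: float = 0.975,
                        nearest: bool = False) -> np.ndarray:
    """Resample an image so that 1 pixel = 1 µm.

    ``nearest=True`` uses nearest-neighbour sampling, required for height maps
    and masks whose values are codes that must not be interpolated.
    """
    if calib_um_per_px <= 0:
        raise ValueError("calibration must be positive")
    a = np.asarray(image)
    if calib_um_per_px == 1.0:
        return a.copy()
    out_shape = (
        int(round_half_away(a.shape[0] * calib_um_per_px)),
        int(round_half_away(a.shape[1] * calib_um_per_px)),
    )
    if nearest:
        out = resize(a, out_shape, order=0, preserve_range=True,
                     anti_aliasing=False)
        return out.astype(a.dtype)
    return resize(a.astype(np.float64), out_shape, order=1,
                  preserve_range=True, anti_aliasing=calib_um_per_px < 1.0)


def mask_background(hm: HeightMap, footprint: OutlineShape) -> HeightMap:
    """Invalidate height-map pixels outside the object's filled 2D outline.

    Mirrors element-wise multiplication of the binary outline image against
    the height map; inside pixels are untouched.
    """
    if footprint.mask.shape != hm.encoded.shape:
        raise ValueError("outline and height map dims must match")
    valid = hm.valid & footprint.mask
    if not valid.any():
        raise ValueError("background masking removed every pixel")
    return HeightMap(encoded=hm.encoded, valid=valid, s=hm.s,
                     z_step_um=hm.z_step_um, px_um=hm.px_um)


def aperture_mask(filled: OutlineShape, unfilled: OutlineShape) -> np.ndarray:
    """Pixels inside the filled outline but not the unfilled one.

    The unfilled outline skips hole filling, so interior holes (the aperture
    of a foraminifer test) appear only in the filled version; the difference
    isolates them. May be empty.
    """
    if filled.mask.shape != unfilled.mask.shape:
        raise ValueError("outline dims must match")
    return filled.mask & ~unfilled.mask


def decode_grid(hm: HeightMap, aperture: np.ndarray | None = None) -> HeightGrid:
    """Decode an 8-bit height map into a µm height grid.

    Aperture pixels (if given) are excluded from the valid mask at this stage
    and re-introduced later by :func:`set_aperture_depth`.
    """
    from .focus import decode_height

    heights = decode_height(hm.encoded.astype(np.float64), hm.s, hm.z_step_um)
    valid = hm.valid.copy()
    if aperture is not None:
        valid &= ~aperture
    return HeightGrid(heights=heights, valid=valid, px_um=hm.px_um,
                      s=hm.s, z_step_um=hm.z_step_um, aperture=aperture)


def _window_quartiles(vals, valid, n):
    """Per-pixel Q1/Q3 of the valid values in each truncated n-by-n window.

    Quartiles interpolate linearly between order statistics (the same
    convention as ``numpy.percentile``). Exploits the small number of
    distinct height levels: one pass of window counts per level.
    """
    cnt = boxcar_count(valid, n).astype(np.float64)
    cnt_safe = np.maximum(cnt, 1.0)
    ranks = {
        "q1": 0.25 * (cnt - 1.0),
        "q3": 0.75 * (cnt - 1.0),
    }
    targets = {}
    for key, r in ranks.items():
        targets[key + "_lo"] = np.floor(r)
        targets[key + "_hi"] = np.ceil(r)
    levels = np.unique(vals[valid])
    cum = np.zeros(vals.shape, dtype=np.int64)
    found = {k: np.full(vals.shape, np.nan) for k in targets}
    for v in levels:
        cum += boxcar_count(valid & (vals == v), n)
        for k, karr in targets.items():
            need = np.isnan(found[k]) & (cum > karr)
            found[k][need] = v
    out = {}
    for key, r in ranks.items():
        lo, hi = found[key + "_lo"], found[key + "_hi"]
        frac = r - np.floor(r)
        out[key] = lo + frac * (hi - lo)
    return out["q1"], out["q3"], cnt_safe


def outlier_filter(grid: HeightGrid, n: int = 45) -> HeightGrid:
    """Sliding-neighbourhood quartile filter for spike and pit noise.

    For each valid pixel, the first and third quartiles of the valid pixels
    in the surrounding n-by-n window (truncated at the border, background
    excluded) are computed; a focal value outside [Q1, Q3] is replaced with
    the mean of the window's valid pixels. A single pass over a frozen copy
    of the grid: replacements never feed back into later windows.

    Aggressive by design — roughly half the pixels of a noisy surface are
    re-estimated from their neighbourhood, which both deletes height-map
    spikes and smooths the final mesh.
    """
    if n % 2 == 0 or n < 3:
        raise ValueError("n must be an odd integer >= 3")
    vals = grid.heights
    valid = grid.valid
    if not valid.any():
        raise ValueError("empty grid")
    q1, q3, cnt = _window_quartiles(vals, valid, n)
    wmean = boxcar_sum(np.where(valid, vals, 0.0), n) / cnt
    outlier = valid & ((vals < q1) | (vals > q3))
    out = vals.copy()
    out[outlier] = wmean[outlier]
    return grid.replace(heights=out)


def prune_z_levels(grid: HeightGrid, frac: float = 0.01,
                   drop_bottom: bool = True) -> HeightGrid:
    """Remove sparsely populated z-levels, then the bottom-most level.

    Heights are re-quantized to the nearest multiple of the z-step to assign
    each pixel a level; a level holding fewer than ``frac`` of the object's
    valid pixels is removed (its pixels become invalid). With
    ``drop_bottom``, the lowest remaining level is removed as well — meshes
    commonly retain a rim of background around the object at the lowest
    level, which would obscure the outline.
    """
    valid = grid.valid
    total = int(valid.sum())
    if total == 0:
        raise ValueError("empty grid")
    lev = round_half_away(grid.heights / grid.z_step_um).astype(np.int64)
    present = np.unique(lev[valid])
    if len(present) < 2:
        raise ValueError("grid must span at least 2 distinct z-levels")
    counts = {int(v): int(((lev == v) & valid).sum()) for v in present}
    keep_levels = {v for v, c in counts.items() if c >= frac * total}
    new_valid = valid & np.isin(lev, sorted(keep_levels))
    if drop_bottom and new_valid.any():
        bottom = lev[new_valid].min()
        new_valid &= lev != bottom
    if not new_valid.any():
        raise ValueError("pruning removed every pixel")
    return grid.replace(valid=new_valid)


def set_aperture_depth(grid: HeightGrid) -> HeightGrid:
    """Fill aperture pixels at the lowest height of the cleaned object.

    Semi-3D hulls only see the upper half of the shell, so apertures are
    terminated flat at the object's lowest retained height (roughly the
    mid-plane of the specimen). No-op when the aperture mask is empty.
    """
    ap = grid.aperture
    if ap is None or not ap.any():
        return grid
    if not grid.valid.any():
        raise ValueError("empty grid")
    floor_h = grid.heights[grid.valid].min()
    heights = grid.heights.copy()
    heights[ap] = floor_h
    valid = grid.valid | ap
    return grid.replace(heights=heights, valid=valid)


def build_mesh(grid: HeightGrid, provenance: dict | None = None) -> HalfHullMesh:
    """Triangulate the height grid: one vertex per valid pixel.

    Every 2x2 block of mutually valid pixels is split into two triangles
    along the NW-SE diagonal; no downsampling.
    """
    valid = grid.valid
    nv = int(valid.sum())
    if nv == 0:
        raise ValueError("empty grid")
    rows, cols = np.nonzero(valid)
    verts = np.column_stack([
        cols * grid.px_um, rows * grid.px_um, grid.heights[valid],
    ])
    index = np.full(valid.shape, -1, dtype=np.int64)
    index[valid] = np.arange(nv)
    quad = valid[:-1, :-1] & valid[:-1, 1:] & valid[1:, :-1] & valid[1:, 1:]
    qi, qj = np.nonzero(quad)
    nw = index[qi, qj]
    ne = index[qi, qj + 1]
    sw = index[qi + 1, qj]
    se = index[qi + 1, qj + 1]
    faces = np.concatenate([
        np.column_stack([nw, sw, se]),
        np.column_stack([nw, se, ne]),
    ]) if len(qi) else np.zeros((0, 3), dtype=np.int64)
    return HalfHullMesh(vertices=verts, faces=faces,
                        provenance=provenance or {})


def _downsampled(mesh: HalfHullMesh, step: int) -> HalfHullMesh:
    if step == 1:
        return mesh
    keep = np.arange(0, len(mesh.vertices), step)
    remap = -np.ones(len(mesh.vertices), dtype=np.int64)
    remap[keep] = np.arange(len(keep))
    f = remap[mesh.faces]
    f = f[(f >= 0).all(axis=1)]
    return HalfHullMesh(vertices=mesh.vertices[keep], faces=f,
                        provenance=mesh.provenance)


def write_mesh(mesh: HalfHullMesh, path, fmt: str | None = None,
               downsample: int = 1) -> None:
    """Write a mesh as OBJ, OFF, or an x/y/z CSV point list.

    ``fmt`` defaults to the file extension. ``downsample`` keeps every k-th
    vertex (1 = full mesh, the default).
    """
    if downsample < 1:
        raise ValueError("downsample must be >= 1")
    path = str(path)
    if fmt is None:
        fmt = path.rsplit(".", 1)[-1]
    fmt = fmt.lower()
    m = _downsampled(mesh, downsample)
    if fmt == "obj":
        with open(path, "w") as fh:
            for v in m.vertices:
                fh.write("v %.17g %.17g %.17g\n" % tuple(v))
            for f in m.faces:
                fh.write("f %d %d %d\n" % tuple(f + 1))
    elif fmt == "off":
        with open(path, "w") as fh:
            fh.write("OFF\n")
            fh.write("%d %d 0\n" % (len(m.vertices), len(m.faces)))
            for v in m.vertices:
                fh.write("%.17g %.17g %.17g\n" % tuple(v))
            for f in m.faces:
                fh.write("3 %d %d %d\n" % tuple(f))
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            w = _csv.writer(fh)
            w.writerow(["x_um", "y_um", "z_um"])
            for v in m.vertices:
                w.writerow(["%.17g" % c for c in v])
    else:
        raise ValueError(f"unknown mesh format: {fmt!r}")


def read_mesh(path, fmt: str | None = None) -> HalfHullMesh:
    """Read back an OBJ or OFF file written by :func:`write_mesh`."""
    path = str(path)
    if fmt is None:
        fmt = path.rsplit(".", 1)[-1]
    fmt = fmt.lower()
    verts, faces = [], []
    if fmt == "obj":
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if parts[0] == "v":
                    verts.append([float(x) for x in parts[1:4]])
                elif parts[0] == "f":
                    faces.append([int(x.split("/")[0]) - 1 for x in parts[1:4]])
    elif fmt == "off":
        with open(path) as fh:
            header = fh.readline().strip()
            if header != "OFF":
                raise ValueError("not an OFF file")
            nv, nf, _ = (int(x) for x in fh.readline().split())
            for _ in range(nv):
                verts.append([float(x) for x in fh.readline().split()[:3]])
            for _ in range(nf):
                parts = fh.readline().split()
                if int(parts[0]) != 3:
                    raise ValueError("only triangle faces are supported")
                faces.append([int(x) for x in parts[1:4]])
    else:
        raise ValueError(f"unknown mesh format: {fmt!r}")
    return HalfHullMesh(
        vertices=np.asarray(verts, dtype=np.float64),
        faces=np.asarray(faces, dtype=np.int64).reshape(-1, 3),
    )
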