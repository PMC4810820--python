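"""Object-level orchestration: z-stack in, cleaned mesh and sizes out.

``process_object`` chains the per-object stages in their canonical order:

1. height map + EDF from the stack (shape-from-focus, 11x11 kernel),
2. rescale both so 1 pixel = 1 µm,
3. 2D outline of the EDF with and without hole filling; their difference is
   the aperture mask,
4. background masking of the height map by the filled outline,
5. decode grey values to µm heights,
6. sliding quartile outlier filter (n = 45),
7. z-level pruning (1% rule) plus bottom-level removal,
8. aperture depth assignment,
9. mesh extraction and size estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import focus as _focus
from . import mesh3d, outline2d, sizevol

__all__ = ["ObjectResult", "process_object"]


@dataclass
class ObjectResult:
    """Everything the per-object pipeline produces."""

    edf: np.ndarray
    heightmap: _focus.HeightMap
    outline: outline2d.OutlineShape
    outline_unfilled: outline2d.OutlineShape | None
    aperture: np.ndarray
    grid: mesh3d.HeightGrid
    mesh: mesh3d.HalfHullMesh
    params: outline2d.Shape2DParams
    estimate: sizevol.SizeEstimate

    @property
    def max_height_um(self) -> float:
        return float(self.grid.heights[self.grid.valid].max())


def process_object(zstack: _focus.ZStack, *, threshold: float = 0.18,
                   kernel: int = 11, filter_n: int = 45,
                   prune_frac: float = 0.01, drop_bottom: bool = True,
                   detect_aperture: bool = True, n_perim: int = 100,
                   object_id: str | None = None) -> ObjectResult:
    """Run the full per-object pipeline on a single-object z-stack."""
    hm = _focus.build_height_map(zstack, kernel=kernel)
    edf = _focus.build_edf(zstack, hm)
    edf = np.clip(edf, 0.0, 1.0)

    calib = zstack.px_um
    edf1 = np.clip(mesh3d.rescale_unit_pixels(edf, calib), 0.0, 1.0)
    enc1 = mesh3d.rescale_unit_pixels(hm.encoded, calib, nearest=True)
    hm1 = _focus.HeightMap(encoded=enc1, valid=np.ones(enc1.shape, dtype=bool),
                           s=hm.s, z_step_um=hm.z_step_um, px_um=1.0)

    filled = outline2d.extract_outline(edf1, threshold, fill_holes=True,
                                       px_um=1.0)
    unfilled = None
    aperture = np.zeros(edf1.shape, dtype=bool)
    if detect_aperture:
        unfilled = outline2d.extract_outline(edf1, threshold, fill_holes=False,
                                             px_um=1.0)
        aperture = mesh3d.aperture_mask(filled, unfilled)

    hm1 = mesh3d.mask_background(hm1, filled)
    grid = mesh3d.decode_grid(hm1, aperture=aperture)
    grid = mesh3d.outlier_filter(grid, n=filter_n)
    grid = mesh3d.prune_z_levels(grid, frac=prune_frac, drop_bottom=drop_bottom)
    grid = mesh3d.set_aperture_depth(grid)

    mesh = mesh3d.build_mesh(grid, provenance={
        "object_id": object_id, "kernel": kernel, "filter_n": filter_n,
        "prune_frac": prune_frac, "threshold": threshold,
    })
    params = outline2d.shape_params(filled)
    perim_xy, _ = outline2d.resample_perimeter(filled, n=n_perim)
    est = sizevol.size_estimate(grid, params, perim_xy, mesh=mesh)
    return ObjectResult(edf=edf1, heightmap=hm1, outline=filled,
                        outline_unfilled=unfilled, aperture=aperture,
                        grid=grid, mesh=mesh, params=params, estimate=est)
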