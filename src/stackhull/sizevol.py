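"""Volume and surface area of semi-3D hulls with back-half bounds.

The imaged top hull is measured exactly: its volume is the sum of pixel
heights times pixel area, its surface area the summed area of the mesh
triangles. The un-imaged back half is bounded by three idealized base
shapes sharing the object's 2D outline and its base height H (the height of
the lowest mesh level above the slide):

- irregular cylinder:  V = A2D * H,      SA = P2D * H + A2D
- irregular cone:      V = A2D * H / 3,  SA = triangle fan from the
  perimeter to an apex at height H below the outline (lateral surface only)
- spheroidal dome: half-ellipsoid with semi-axes (major/2, minor/2, H);
  surface area from Thomsen's approximation with exponent k = 1.6.

The cylinder and cone bracket the theoretical maximum and minimum back-half
volume, and the spread between them, normalized to the intermediate dome
estimate, quantifies the uncertainty introduced by not imaging the back:

    U = 100 * (E_cyl - E_con) / E_dom   (percent, per volume and per area)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mesh3d import HalfHullMesh, HeightGrid, build_mesh
from .outline2d import Shape2DParams

__all__ = [
    "SizeEstimate",
    "mesh_surface_area",
    "top_hull_measures",
    "base_height",
    "estimate_bases",
    "cone_lateral_area",
    "thomsen_area",
    "uncertainty",
    "size_estimate",
    "size_census",
]

THOMSEN_K = 1.6


@dataclass
class SizeEstimate:
    """Exact top-hull measures plus the three completed-object estimates.

    ``cone``, ``cylinder`` and ``dome`` are (volume µm³, area µm²) pairs for
    the full object (imaged top plus estimated back). ``u_vol_pct`` and
    ``u_sa_pct`` are the cylinder-minus-cone spreads normalized to the dome
    estimate, in percent (the area spread may be negative).
    """

    v_top_um3: float
    sa_top_um2: float
    h_base_um: float
    cone: tuple
    cylinder: tuple
    dome: tuple
    u_vol_pct: float
    u_sa_pct: float


def mesh_surface_area(mesh: HalfHullMesh) -> float:
    """Total area of the mesh triangles (µm²)."""
    v = mesh.vertices
    f = mesh.faces
    if len(f) == 0:
        return 0.0
    a = v[f[:, 1]] - v[f[:, 0]]
    b = v[f[:, 2]] - v[f[:, 0]]
    return float(0.5 * np.linalg.norm(np.cross(a, b), axis=1).sum())


def top_hull_measures(grid: HeightGrid, mesh: HalfHullMesh | None = None):
    """Exact (V_top, SA_top) of the imaged half: summed pixel heights times
    pixel area, and summed triangle areas of the half-hull mesh."""
    if not grid.valid.any():
        raise ValueError("empty grid")
    v_top = float(grid.heights[grid.valid].sum()) * grid.px_um ** 2
    if mesh is None:
        mesh = build_mesh(grid)
    return v_top, mesh_surface_area(mesh)


def base_height(grid: HeightGrid) -> float:
    """Height of the lowest retained mesh level above the slide plane (µm)."""
    if not grid.valid.any():
        raise ValueError("empty grid")
    return float(grid.heights[grid.valid].min())


def cone_lateral_area(perimeter_xy: np.ndarray, centroid_xy, h: float) -> float:
    """Lateral surface of the irregular cone via a perimeter triangle fan.

    Sums the areas of the triangles formed by each adjacent pair of
    perimeter coordinates and the apex directly above (here: below, for the
    back half — the geometry is symmetric) the centroid at height ``h``.
    This is the midpoint-rule estimate of the generalized conical surface;
    for a circular outline it converges to pi*r*sqrt(r^2+h^2).
    """
    p = np.asarray(perimeter_xy, dtype=np.float64)
    apex = np.array([centroid_xy[0], centroid_xy[1], h])
    a = np.column_stack([p, np.zeros(len(p))])
    b = np.roll(a, -1, axis=0)
    cross = np.cross(a - apex, b - apex)
    return float(0.5 * np.linalg.norm(cross, axis=1).sum())


def thomsen_area(sx: float, sy: float, sz: float, k: float = THOMSEN_K) -> float:
    """Thomsen's closed-form approximation of a full ellipsoid's surface.

    Exact (k cancels) when all three semi-axes are equal.
    """
    return 4 * np.pi * (
        ((sx * sy) ** k + (sx * sz) ** k + (sy * sz) ** k) / 3.0
    ) ** (1.0 / k)


def estimate_bases(p: Shape2DParams, h_base: float,
                   perimeter_xy: np.ndarray | None = None,
                   k: float = THOMSEN_K) -> dict:
    """Back-half (volume, area) under each of the three idealized bases.

    Returns ``{"cone": (V, SA), "cylinder": (V, SA), "dome": (V, SA)}``;
    the cone area is lateral-only while the cylinder area includes the flat
    base cap (following the estimator definitions as stated). ``perimeter_xy``
    (the resampled outline, in µm) is required for the cone area.
    """
    if h_base < 0:
        raise ValueError("base height must be non-negative")
    a2d = p.area_um2
    p2d = p.perimeter_um
    v_cyl = a2d * h_base
    sa_cyl = p2d * h_base + a2d
    v_con = v_cyl / 3.0
    if perimeter_xy is not None:
        sa_con = cone_lateral_area(perimeter_xy, p.centroid_um, h_base)
    else:
        sa_con = np.nan
    sx, sy, sz = p.major_um / 2.0, p.minor_um / 2.0, h_base
    v_dom = 0.5 * (4.0 / 3.0) * np.pi * sx * sy * sz
    sa_dom = 0.5 * thomsen_area(sx, sy, sz, k)
    return {
        "cone": (v_con, sa_con),
        "cylinder": (v_cyl, sa_cyl),
        "dome": (v_dom, sa_dom),
    }


def uncertainty(est: SizeEstimate):
    """Back-half spread normalized to the dome estimate, percent.

    ``U = 100 * (E_cyl - E_con) / E_dom`` computed separately for volume and
    surface area; signed (the area spread can be negative: a cylindrical
    back can have less surface than a conical one).
    """
    for pair in (est.cone, est.cylinder, est.dome):
        if pair is None or np.any(np.isnan(pair)):
            raise ValueError("all three estimates are required")
    if est.dome[0] == 0 or est.dome[1] == 0:
        raise ValueError("dome estimate is zero; uncertainty undefined")
    u_vol = 100.0 * (est.cylinder[0] - est.cone[0]) / est.dome[0]
    u_sa = 100.0 * (est.cylinder[1] - est.cone[1]) / est.dome[1]
    return u_vol, u_sa


def size_estimate(grid: HeightGrid, params: Shape2DParams,
                  perimeter_xy: np.ndarray, mesh: HalfHullMesh | None = None,
                  k: float = THOMSEN_K) -> SizeEstimate:
    """Assemble the full per-object size record.

    Completed-object estimates add the exact top-hull measures to each
    back-half estimate.
    """
    v_top, sa_top = top_hull_measures(grid, mesh)
    h = base_height(grid)
    backs = estimate_bases(params, h, perimeter_xy, k)
    full = {name: (v_top + v, sa_top + sa) for name, (v, sa) in backs.items()}
    est = SizeEstimate(
        v_top_um3=v_top, sa_top_um2=sa_top, h_base_um=h,
        cone=full["cone"], cylinder=full["cylinder"], dome=full["dome"],
        u_vol_pct=np.nan, u_sa_pct=np.nan,
    )
    est.u_vol_pct, est.u_sa_pct = uncertainty(est)
    return est


def size_census(records, grid_points: int = 512,
                quantiles=(0.05, 0.25, 0.5, 0.75, 0.95),
                fold_quantile: float = 0.5):
    """Assemblage size distributions across sites.

    ``records`` is an iterable of ``(site, Shape2DParams, SizeEstimate)``.
    Returns ``(table, densities, summary, folds)``:

    table
        per-object DataFrame of site, 2D outline area and dome-based volume;
    densities
        site -> dict of Gaussian kernel density curves (Silverman bandwidth)
        for area and volume, each as (grid, density) arrays; sites with a
        single object get no density;
    summary
        per-site quantiles of area and volume;
    folds
        pairwise fold-differences of the chosen quantile between sites.
    """
    from scipy.stats import gaussian_kde

    rows = [
        {"site": site, "area_um2": p.area_um2, "volume_dome_um3": est.dome[0]}
        for site, p, est in records
    ]
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no objects")
    densities = {}
    for site, sub in table.groupby("site", sort=False):
        if len(sub) < 2:
            continue
        densities[site] = {}
        for col in ("area_um2", "volume_dome_um3"):
            x = sub[col].to_numpy()
            if np.ptp(x) == 0:
                continue
            kde = gaussian_kde(x, bw_method="silverman")
            bw = np.sqrt(kde.covariance[0, 0])
            grid = np.linspace(x.min() - 4 * bw, x.max() + 4 * bw, grid_points)
            densities[site][col] = (grid, kde(grid))
    summary = table.groupby("site", sort=False).quantile(list(quantiles))
    sites = list(table["site"].drop_duplicates())
    folds = pd.DataFrame(index=sites, columns=sites, dtype=float)
    med = table.groupby("site", sort=False)["volume_dome_um3"].quantile(
        fold_quantile)
    for a in sites:
        for b in sites:
            folds.loc[a, b] = med[a] / med[b]
    return table, densities, summary, folds
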