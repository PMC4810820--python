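"""Synthetic z-stacks, slides and trees with known ground truth.

Every downstream stage of the pipeline is tested against data generated
here: convex shell-like objects (light on a black slide, umbilically
oriented) rendered as 31-slice z-stacks with a 31.1 µm z-step and 1 µm
pixels, mimicking reflected-light slide scans of foraminifera.

The optical model is deliberately simple: the in-focus appearance of an
object is its base intensity modulated by a fixed speckle texture (standing
in for the wall texture of real shells — a perfectly uniform surface would
carry no focus signal at all), and slice k shows that image blurred with an
isotropic Gaussian whose spread grows linearly with the defocus distance
|h(x, y) - k*Z|. The blur is monotone in defocus, so the sharpest slice at a
pixel is the one closest to the surface height — which is exactly the
property shape-from-focus relies on. Pixels outside every object footprint
render as 0 before noise.

Optional "smear" artifacts emulate a pathology of real stack focusing:
inside a smear patch the blur is locally constant across all slices, so no
slice is sharpest and the recovered height is garbage there.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .focus import ZStack
from .mesh3d import HeightGrid

__all__ = [
    "ShapeSpec",
    "Optics",
    "GroundTruth",
    "make_heightfield",
    "render_zstack",
    "make_slide",
    "random_binary_tree",
]

KINDS = ("hemispheroid", "sphere_on_plane", "cone", "block", "terraced_block")

#: Acquisition geometry of the emulated microscope setup.
DEFAULT_SLICES = 31
DEFAULT_Z_STEP_UM = 31.1
DEFAULT_PX_UM = 0.975

_TEXTURE_AMP = 0.15  # relative speckle contrast of the in-focus surface
_TEXTURE_SIGMA = 1.0  # px; speckle correlation length


@dataclass
class ShapeSpec:
    """Analytic description of one synthetic object.

    kind
        hemispheroid: half-ellipsoid dome of relief ``relief_um``;
        sphere_on_plane: full sphere of radius ``relief_um`` resting on the
        slide (visible top hull rises to one diameter);
        cone: elliptical cone with apex height ``relief_um``;
        block: flat-topped slab of height ``relief_um``;
        terraced_block: concentric rectangular terraces stepping up to
        ``relief_um``.
    a_um, b_um
        Lateral semi-axes of the footprint (for sphere_on_plane both must
        equal the radius).
    center_um
        (x, y) position of the footprint centre on the canvas.
    intensity
        In-focus surface brightness in (0, 1]; must exceed the background (0).
    aperture_um
        Optional circular hole ``(cx, cy, radius)`` strictly interior to the
        footprint, rendered dark like the background.
    """

    kind: str
    a_um: float
    b_um: float
    relief_um: float
    center_um: tuple = (0.0, 0.0)
    intensity: float = 0.6
    aperture_um: tuple | None = None
    n_terraces: int = 4

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown shape kind: {self.kind!r}")
        if min(self.a_um, self.b_um, self.relief_um) <= 0:
            raise ValueError("all dimensions must be positive")
        if not 0 < self.intensity <= 1:
            raise ValueError("intensity must be in (0, 1]")
        if self.kind == "sphere_on_plane" and not (
            self.a_um == self.b_um == self.relief_um
        ):
            raise ValueError("sphere_on_plane requires a_um == b_um == radius")


@dataclass
class Optics:
    """Defocus blur, sensor noise and artifact injection parameters."""

    blur_coefficient: float = 0.05  # Gaussian sigma (px) per µm of defocus
    noise_sd: float = 0.01  # additive Gaussian noise, intensity units
    artifact_rate: float = 0.0  # probability of a smear patch per object

    def __post_init__(self):
        if self.blur_coefficient < 0:
            raise ValueError("blur_coefficient must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.artifact_rate <= 1:
            raise ValueError("artifact_rate must be in [0, 1]")


@dataclass
class GroundTruth:
    """What the generator knows that the pipeline must recover."""

    height_um: np.ndarray  # true height field on the pixel grid
    footprint: np.ndarray  # object footprint mask
    aperture: np.ndarray  # aperture mask (may be empty)
    volume_um3: float  # integral of height over the footprint
    surface_um2: float  # area of the triangulated true top surface


def _heights_on_grid(spec: ShapeSpec, shape_px, px_um: float):
    h, w = shape_px
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    x = xx * px_um - spec.center_um[0]
    y = yy * px_um - spec.center_um[1]
    if spec.kind in ("block", "terraced_block"):
        inside = (np.abs(x) <= spec.a_um) & (np.abs(y) <= spec.b_um)
    else:
        inside = (x / spec.a_um) ** 2 + (y / spec.b_um) ** 2 <= 1.0
    z = np.zeros((h, w))
    if spec.kind == "hemispheroid":
        rr = np.clip(1 - (x / spec.a_um) ** 2 - (y / spec.b_um) ** 2, 0, None)
        z[inside] = spec.relief_um * np.sqrt(rr[inside])
    elif spec.kind == "sphere_on_plane":
        R = spec.relief_um
        rr = np.clip(R * R - x ** 2 - y ** 2, 0, None)
        z[inside] = R + np.sqrt(rr[inside])
    elif spec.kind == "cone":
        re = np.sqrt((x / spec.a_um) ** 2 + (y / spec.b_um) ** 2)
        z[inside] = spec.relief_um * (1 - re[inside])
    elif spec.kind == "block":
        z[inside] = spec.relief_um
    elif spec.kind == "terraced_block":
        k = spec.n_terraces
        frac = np.maximum(np.abs(x) / spec.a_um, np.abs(y) / spec.b_um)
        step = np.ceil((1 - frac) * k)  # 1 .. k from rim to centre
        z[inside] = spec.relief_um * step[inside] / k
    aperture = np.zeros((h, w), dtype=bool)
    if spec.aperture_um is not None:
        acx, acy, ar = spec.aperture_um
        ax = xx * px_um - acx
        ay = yy * px_um - acy
        aperture = ax ** 2 + ay ** 2 <= ar ** 2
        # no aperture pixel may touch or cross the footprint boundary
        from scipy.ndimage import binary_erosion

        if not np.array_equal(aperture & binary_erosion(inside), aperture):
            raise ValueError("aperture must be strictly interior to the footprint")
    return z, inside, aperture


def _closed_form_volume(spec: ShapeSpec):
    a, b, c = spec.a_um, spec.b_um, spec.relief_um
    if spec.kind == "hemispheroid":
        return (2.0 / 3.0) * np.pi * a * b * c
    if spec.kind == "sphere_on_plane":
        return (5.0 / 3.0) * np.pi * c ** 3
    if spec.kind == "cone":
        return (1.0 / 3.0) * np.pi * a * b * c
    if spec.kind == "block":
        return 4.0 * a * b * c
    return None


def make_heightfield(spec: ShapeSpec, shape_px, px_um: float = 1.0):
    """Sample a shape's analytic height field on a pixel grid.

    Returns ``(HeightGrid, GroundTruth)``. The ground-truth volume comes
    from closed forms where they exist, otherwise from the grid integral;
    the ground-truth surface area is measured on the triangulated true
    surface. Raises if the footprint does not fit inside the grid.
    """
    z, inside, aperture = _heights_on_grid(spec, shape_px, px_um)
    rim = np.zeros(inside.shape, dtype=bool)
    rim[0, :] = rim[-1, :] = rim[:, 0] = rim[:, -1] = True
    if (inside & rim).any():
        raise ValueError("footprint exceeds the grid")
    if not inside.any():
        raise ValueError("footprint is empty on this grid")
    grid = HeightGrid(heights=z, valid=inside & ~aperture, px_um=px_um,
                      s=DEFAULT_SLICES, z_step_um=DEFAULT_Z_STEP_UM,
                      aperture=aperture)
    vol = _closed_form_volume(spec)
    if vol is None or aperture.any():
        vol = float(z[inside & ~aperture].sum()) * px_um * px_um
    from .mesh3d import build_mesh
    from .sizevol import mesh_surface_area

    sa = mesh_surface_area(build_mesh(grid))
    gt = GroundTruth(height_um=z, footprint=inside, aperture=aperture,
                     volume_um3=vol, surface_um2=sa)
    return grid, gt


def _sharp_image(hf: HeightGrid, intensity_map, rng) -> np.ndarray:
    texture = gaussian_filter(rng.standard_normal(hf.heights.shape),
                              _TEXTURE_SIGMA)
    texture /= max(texture.std(), 1e-12)
    img = intensity_map * (1.0 + _TEXTURE_AMP * texture)
    img[~(hf.valid | hf.aperture)] = 0.0
    img[hf.aperture] = 0.0  # apertures are dark holes, like the background
    return np.clip(img, 0.0, 1.0)


def _blur_bank_sigmas(max_sigma: float):
    sig = [0.0, 0.4, 0.8, 1.2, 1.8, 2.6, 4.0, 6.0, 9.0, 14.0, 20.0, 30.0,
           45.0, 65.0, 95.0]
    out = [s for s in sig if s < max_sigma] + [max_sigma]
    return np.asarray(out)


def render_zstack(hf: HeightGrid, optics: Optics, s: int = DEFAULT_SLICES,
                  z_step_um: float = DEFAULT_Z_STEP_UM, seed: int = 0,
                  intensity: float | np.ndarray = 0.6) -> ZStack:
    """Render a height field as a z-stack under the defocus-blur model.

    Slice k is the focal plane at height ``k * z_step_um``; at each pixel it
    shows the textured in-focus image blurred with
    ``sigma = blur_coefficient * |h - k*Z|`` (px), then additive Gaussian
    noise. Deterministic given ``seed``.
    """
    if s < 2:
        raise ValueError("s must be >= 2")
    if z_step_um <= 0:
        raise ValueError("z_step_um must be positive")
    if optics.blur_coefficient == 0:
        raise ValueError(
            "blur_coefficient must be > 0: without defocus blur the "
            "sharpest slice is undefined")
    rng = np.random.default_rng(seed)
    imap = np.broadcast_to(np.asarray(intensity, dtype=np.float64),
                           hf.heights.shape)
    sharp = _sharp_image(hf, imap, rng)
    footprint = hf.valid | hf.aperture
    h = hf.heights

    smear = np.zeros(hf.heights.shape, dtype=bool)
    if optics.artifact_rate > 0 and rng.random() < optics.artifact_rate:
        rows, cols = np.nonzero(hf.valid)
        i = rng.integers(len(rows))
        extent = np.nonzero(hf.valid.any(axis=1))[0]
        radius = max(3.0, 0.15 * (extent[-1] - extent[0]))
        yy, xx = np.indices(hf.heights.shape)
        smear = (yy - rows[i]) ** 2 + (xx - cols[i]) ** 2 <= radius ** 2
        smear &= footprint

    max_defocus = max(
        abs(float(h[footprint].max())), abs(float(h[footprint].min()) - (s - 1) * z_step_um)
    ) if footprint.any() else z_step_um
    sigmas = _blur_bank_sigmas(optics.blur_coefficient * max_defocus + 1e-9)
    bank = np.stack([
        sharp if sg == 0 else gaussian_filter(sharp, sg) for sg in sigmas
    ])

    slices = np.empty((s,) + hf.heights.shape, dtype=np.float32)
    smear_sigma = optics.blur_coefficient * 3 * z_step_um
    for k in range(s):
        sigma_map = optics.blur_coefficient * np.abs(h - k * z_step_um)
        if smear.any():
            sigma_map = np.where(smear, smear_sigma, sigma_map)
        idx = np.clip(np.searchsorted(sigmas, sigma_map), 1, len(sigmas) - 1)
        lo, hi = sigmas[idx - 1], sigmas[idx]
        w = np.clip((sigma_map - lo) / np.maximum(hi - lo, 1e-12), 0, 1)
        frame = (1 - w) * bank[idx - 1, np.arange(h.shape[0])[:, None],
                               np.arange(h.shape[1])[None, :]] + \
            w * bank[idx, np.arange(h.shape[0])[:, None],
                     np.arange(h.shape[1])[None, :]]
        frame[~footprint] = 0.0
        slices[k] = frame
    if optics.noise_sd > 0:
        slices += rng.normal(0.0, optics.noise_sd,
                             size=slices.shape).astype(np.float32)
    return ZStack(slices=slices, z_step_um=z_step_um, px_um=hf.px_um)


def make_slide(specs, canvas_px, optics: Optics, s: int = DEFAULT_SLICES,
               z_step_um: float = DEFAULT_Z_STEP_UM, seed: int = 0,
               px_um: float = 1.0):
    """Compose several objects on one canvas and render a single stack.

    Footprints must be pairwise disjoint. Returns ``(ZStack, [GroundTruth])``
    with one ground-truth record per object, in input order. An empty spec
    list yields a stack of pure background (plus noise).
    """
    h, w = canvas_px
    heights = np.zeros((h, w))
    valid = np.zeros((h, w), dtype=bool)
    aperture = np.zeros((h, w), dtype=bool)
    intensity = np.zeros((h, w))
    truths = []
    for spec in specs:
        z, inside, ap = _heights_on_grid(spec, canvas_px, px_um)
        rim = np.zeros(inside.shape, dtype=bool)
        rim[0, :] = rim[-1, :] = rim[:, 0] = rim[:, -1] = True
        if (inside & rim).any():
            raise ValueError("footprint exceeds the canvas")
        if (inside & (valid | aperture)).any():
            raise ValueError("object footprints overlap")
        heights[inside] = z[inside]
        valid |= inside & ~ap
        aperture |= ap
        intensity[inside] = spec.intensity
        vol = _closed_form_volume(spec)
        if vol is None or ap.any():
            vol = float(z[inside & ~ap].sum()) * px_um * px_um
        truths.append(GroundTruth(height_um=z, footprint=inside, aperture=ap,
                                  volume_um3=vol, surface_um2=np.nan))
    hf = HeightGrid(heights=heights, valid=valid, px_um=px_um, s=s,
                    z_step_um=z_step_um, aperture=aperture)
    stack = render_zstack(hf, optics, s=s, z_step_um=z_step_um, seed=seed,
                          intensity=intensity)
    return stack, truths


def random_binary_tree(labels, seed: int = 0):
    """Random unrooted fully bifurcating leaf-labelled tree.

    Built by random sequential addition: start from the unique 3-leaf
    topology, then attach each remaining leaf to an edge drawn uniformly at
    random. Deterministic given ``seed``. Returns a ``dendropy.Tree``.
    """
    import dendropy

    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 labels")
    if len(set(labels)) != len(labels):
        raise ValueError("labels must be distinct")
    rng = _random.Random(seed)
    # adjacency: node id -> set of neighbours; leaves are ids 0..n-1
    n = len(labels)
    centre = n
    adj = {0: {centre}, 1: {centre}, 2: {centre},
           centre: {0, 1, 2}}
    edges = [(0, centre), (1, centre), (2, centre)]
    next_id = n + 1
    for leaf in range(3, n):
        u, v = edges.pop(rng.randrange(len(edges)))
        mid = next_id
        next_id += 1
        adj[u].discard(v)
        adj[v].discard(u)
        adj[u].add(mid)
        adj[v].add(mid)
        adj[mid] = {u, v, leaf}
        adj[leaf] = {mid}
        edges.extend([(u, mid), (v, mid), (leaf, mid)])
    newick = _graph_to_newick(adj, labels, root=centre)
    return dendropy.Tree.get(data=newick, schema="newick")


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]':;,"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _graph_to_newick(adj, labels, root) -> str:
    def rec(node, parent):
        kids = [k for k in adj[node] if k != parent]
        if not kids:
            return _quote(labels[node])
        return "(" + ",".join(rec(k, node) for k in kids) + ")"

    return rec(root, None) + ";"
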