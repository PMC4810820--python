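"""Height-grid cleaning, quartile filtering, pruning and mesh export."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from stackhull import mesh3d
from stackhull.focus import HeightMap
from stackhull.mesh3d import (
    HeightGrid, aperture_mask, build_mesh, decode_grid, mask_background,
    outlier_filter, prune_z_levels, read_mesh, rescale_unit_pixels,
    set_aperture_depth, write_mesh,
)
from stackhull.outline2d import OutlineShape

Z = 31.1


def _grid(heights, valid=None, aperture=None):
    h = np.asarray(heights, dtype=float)
    v = np.ones(h.shape, bool) if valid is None else np.asarray(valid, bool)
    return HeightGrid(heights=h, valid=v, px_um=1.0, s=31, z_step_um=Z,
                      aperture=aperture)


def _outline(mask):
    return OutlineShape(mask=np.asarray(mask, bool),
                        boundary=np.zeros((1, 2)), holes_filled=True,
                        px_um=1.0)


class TestRescale:
    def test_calibration_shrinks_to_unit_pixels(self):
        out = rescale_unit_pixels(np.zeros((1000, 800)), 0.975)
        assert out.shape == (975, 780)

    def test_identity_calibration(self):
        img = np.random.default_rng(0).random((50, 60))
        assert np.array_equal(rescale_unit_pixels(img, 1.0), img)

    def test_aspect_ratio_preserved_within_one_pixel(self):
        out = rescale_unit_pixels(np.zeros((731, 293)), 0.975)
        assert abs(out.shape[0] / out.shape[1] - 731 / 293) < 1 / 293

    def test_nearest_mode_never_invents_values(self):
        enc = np.random.default_rng(1).integers(0, 256, (97, 83))
        out = rescale_unit_pixels(enc, 0.975, nearest=True)
        assert set(np.unique(out)) <= set(np.unique(enc))


class TestMasking:
    def _hm(self, n=10):
        return HeightMap(encoded=np.full((n, n), 100), valid=np.ones((n, n), bool),
                         s=31, z_step_um=Z, px_um=1.0)

    def test_outside_pixels_invalidated_inside_unchanged(self):
        hm = self._hm()
        mask = np.zeros((10, 10), bool)
        mask[2:8, 2:8] = True
        out = mask_background(hm, _outline(mask))
        assert not out.valid[0, 0]
        assert out.valid[4, 4]
        assert np.array_equal(out.encoded, hm.encoded)

    def test_full_frame_footprint_is_noop(self):
        hm = self._hm()
        out = mask_background(hm, _outline(np.ones((10, 10), bool)))
        assert out.valid.all()

    def test_empty_result_rejected(self):
        with pytest.raises(ValueError):
            mask_background(self._hm(), _outline(np.zeros((10, 10), bool)))

    def test_aperture_mask_of_annulus_is_the_hole(self):
        yy, xx = np.mgrid[0:60, 0:60]
        d2 = (yy - 30) ** 2 + (xx - 30) ** 2
        filled = d2 <= 400
        hole = d2 <= 64
        ap = aperture_mask(_outline(filled), _outline(filled & ~hole))
        assert np.array_equal(ap, hole)

    def test_no_hole_gives_empty_aperture(self):
        m = np.ones((8, 8), bool)
        assert not aperture_mask(_outline(m), _outline(m)).any()

    def test_aperture_pixels_absent_from_decoded_grid(self):
        hm = self._hm()
        ap = np.zeros((10, 10), bool)
        ap[4:6, 4:6] = True
        grid = decode_grid(hm, aperture=ap)
        assert not grid.valid[4, 4]
        mesh = build_mesh(grid)
        assert len(mesh.vertices) == 100 - 4


class TestOutlierFilter:
    def test_uniform_window_unchanged(self):
        g = _grid(np.full((9, 9), 10.0))
        out = outlier_filter(g, n=3)
        assert np.array_equal(out.heights, g.heights)

    def test_single_spike_replaced_by_window_mean(self):
        h = np.full((3, 3), 10.0)
        h[1, 1] = 100.0
        out = outlier_filter(_grid(h), n=3)
        assert out.heights[1, 1] == pytest.approx((8 * 10 + 100) / 9)
        others = np.ones((3, 3), bool)
        others[1, 1] = False
        assert np.all(out.heights[others] == 10.0)

    def test_even_or_tiny_kernel_rejected(self):
        g = _grid(np.zeros((5, 5)))
        with pytest.raises(ValueError):
            outlier_filter(g, n=4)
        with pytest.raises(ValueError):
            outlier_filter(g, n=1)

    def test_matches_brute_force_quartile_oracle(self):
        rng = np.random.default_rng(5)
        h = rng.integers(0, 8, (14, 14)).astype(float) * Z
        valid = rng.random((14, 14)) > 0.2
        g = _grid(h, valid)
        out = outlier_filter(g, n=5)
        for i in range(14):
            for j in range(14):
                if not valid[i, j]:
                    assert out.heights[i, j] == h[i, j]
                    continue
                win = h[max(0, i - 2):i + 3, max(0, j - 2):j + 3]
                wv = valid[max(0, i - 2):i + 3, max(0, j - 2):j + 3]
                vals = win[wv]
                q1, q3 = np.percentile(vals, [25, 75])
                if h[i, j] < q1 or h[i, j] > q3:
                    assert out.heights[i, j] == pytest.approx(vals.mean())
                else:
                    assert out.heights[i, j] == h[i, j]

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_output_never_exceeds_prefilter_range(self, seed):
        rng = np.random.default_rng(seed)
        h = rng.integers(0, 31, (12, 12)).astype(float) * Z
        valid = rng.random((12, 12)) > 0.3
        if not valid.any():
            return
        out = outlier_filter(_grid(h, valid), n=5)
        assert out.heights[valid].min() >= h[valid].min()
        assert out.heights[valid].max() <= h[valid].max()

    def test_seeded_spikes_removed_by_default_filter(self):
        """Single-pixel spikes of >= 5Z amplitude (aperture-artifact
        surrogates) must be pulled back to the local surface in at least
        95% of seeded trials."""
        n = 121
        yy, xx = np.mgrid[0:n, 0:n]
        c = n / 2.0
        rr = np.clip(1 - ((yy - c) ** 2 + (xx - c) ** 2) / 55**2, 0, None)
        base = np.round(150.0 * np.sqrt(rr) / Z) * Z
        valid = rr > 0
        removed = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            while True:
                i, j = rng.integers(25, n - 25, 2)
                if valid[i, j]:
                    break
            h = base.copy()
            h[i, j] += 6 * Z
            out = outlier_filter(_grid(h, valid), n=45)
            if abs(out.heights[i, j] - base[i, j]) <= 2 * Z:
                removed += 1
        assert removed >= 95


class TestPrune:
    def _levels(self, counts, z=Z):
        """1D-ish grid whose level k has exactly counts[k] pixels."""
        total = sum(counts)
        h = np.zeros(total)
        pos = 0
        for k, c in enumerate(counts):
            h[pos:pos + c] = k * z
            pos += c
        return _grid(h.reshape(1, -1))

    def test_sparse_level_removed_exactly_at_threshold(self):
        # 1000 px: level at 0.5% removed, level at 2% kept
        g = self._levels([600, 375, 5, 20])
        out = prune_z_levels(g, frac=0.01, drop_bottom=False)
        lev = np.round(out.heights / Z)
        assert not ((lev == 2) & out.valid).any()
        assert ((lev == 3) & out.valid).sum() == 20
        assert ((lev == 1) & out.valid).sum() == 375

    def test_exact_one_percent_is_kept(self):
        g = self._levels([890, 100, 10])
        out = prune_z_levels(g, frac=0.01, drop_bottom=False)
        lev = np.round(out.heights / Z)
        assert ((lev == 2) & out.valid).sum() == 10

    def test_bottom_level_dropped_regardless_of_count(self):
        g = self._levels([500, 300, 200])
        out = prune_z_levels(g, frac=0.01, drop_bottom=True)
        lev = np.round(out.heights / Z)
        assert not ((lev == 0) & out.valid).any()
        assert ((lev == 1) & out.valid).sum() == 300

    def test_single_level_grid_rejected(self):
        with pytest.raises(ValueError):
            prune_z_levels(_grid(np.full((5, 5), Z)))

    def test_pruning_everything_rejected(self):
        g = self._levels([500, 500])
        with pytest.raises(ValueError):
            prune_z_levels(g, frac=0.6, drop_bottom=True)


class TestApertureDepth:
    def test_aperture_filled_at_lowest_height(self):
        h = np.array([[3.0, 4.0, 5.0]]) * Z
        ap = np.array([[False, True, False]])
        g = _grid(h, valid=np.array([[True, False, True]]), aperture=ap)
        out = set_aperture_depth(g)
        assert out.valid.all()
        assert out.heights[0, 1] == 3 * Z

    def test_empty_aperture_is_noop(self):
        g = _grid(np.arange(9.0).reshape(3, 3))
        out = set_aperture_depth(g)
        assert np.array_equal(out.heights, g.heights)
        assert np.array_equal(out.valid, g.valid)

    def test_aperture_surface_is_flat(self):
        h = np.arange(16.0).reshape(4, 4) * Z
        ap = np.zeros((4, 4), bool)
        ap[1:3, 1:3] = True
        g = _grid(h, valid=~ap, aperture=ap)
        out = set_aperture_depth(g)
        assert len(np.unique(out.heights[ap])) == 1


class TestBuildMesh:
    def test_single_pixel_one_vertex_no_faces(self):
        v = np.zeros((3, 3), bool)
        v[1, 1] = True
        mesh = build_mesh(_grid(np.ones((3, 3)), v))
        assert len(mesh.vertices) == 1
        assert len(mesh.faces) == 0

    def test_2x2_block_two_triangles(self):
        mesh = build_mesh(_grid(np.ones((2, 2))))
        assert len(mesh.vertices) == 4
        assert len(mesh.faces) == 2

    @pytest.mark.parametrize("m", [3, 5, 8])
    def test_full_grid_face_count(self, m):
        mesh = build_mesh(_grid(np.ones((m, m))))
        assert len(mesh.vertices) == m * m
        assert len(mesh.faces) == 2 * (m - 1) ** 2

    def test_interior_pixels_belong_to_at_least_two_faces(self):
        yy, xx = np.mgrid[0:40, 0:40]
        valid = (yy - 20) ** 2 + (xx - 20) ** 2 <= 15**2
        g = _grid(np.ones((40, 40)), valid)
        mesh = build_mesh(g)
        counts = np.bincount(mesh.faces.ravel(), minlength=len(mesh.vertices))
        from scipy.ndimage import binary_erosion
        interior = binary_erosion(valid)
        index = np.full(valid.shape, -1, int)
        index[valid] = np.arange(valid.sum())
        assert np.all(counts[index[interior]] >= 2)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            build_mesh(_grid(np.ones((3, 3)), np.zeros((3, 3), bool)))


class TestMeshIO:
    @pytest.fixture()
    def mesh(self):
        h = np.arange(20.0).reshape(4, 5) * 3.7 + 0.123456789
        return build_mesh(_grid(h))

    @pytest.mark.parametrize("fmt", ["obj", "off"])
    def test_round_trip_lossless(self, mesh, fmt, tmp_path):
        path = tmp_path / f"m.{fmt}"
        write_mesh(mesh, path)
        back = read_mesh(path)
        assert np.array_equal(back.vertices, mesh.vertices)
        assert np.array_equal(back.faces, mesh.faces)

    def test_off_header_counts_match(self, mesh, tmp_path):
        path = tmp_path / "m.off"
        write_mesh(mesh, path)
        lines = path.read_text().splitlines()
        nv, nf, _ = (int(x) for x in lines[1].split())
        assert nv == len(mesh.vertices)
        assert nf == len(mesh.faces)
        assert len(lines) == 2 + nv + nf

    def test_csv_line_count(self, mesh, tmp_path):
        path = tmp_path / "m.csv"
        write_mesh(mesh, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == len(mesh.vertices) + 1

    def test_trimesh_reads_our_files(self, mesh, tmp_path):
        trimesh = pytest.importorskip("trimesh")
        for fmt in ("obj", "off"):
            path = tmp_path / f"m.{fmt}"
            write_mesh(mesh, path)
            tm = trimesh.load(str(path), process=False)
            assert np.allclose(np.asarray(tm.vertices), mesh.vertices)
            assert len(tm.faces) == len(mesh.faces)

    def test_unknown_format_rejected(self, mesh, tmp_path):
        with pytest.raises(ValueError, match="format"):
            write_mesh(mesh, tmp_path / "m.ply")

    def test_downsample_reduces_vertices(self, mesh, tmp_path):
        path = tmp_path / "m.obj"
        write_mesh(mesh, path, downsample=2)
        back = read_mesh(path)
        assert len(back.vertices) == 10
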