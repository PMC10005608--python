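import numpy as np
import pytest

import grainct as g
from grainct.meshcrop import _stitch_pair, enclosed_volume

UNIT_SQUARE = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 1.0], [1.0, 0.0]])


def regular_polygon(n, r, center=(16.0, 16.0), phase=0.0):
    ang = np.linspace(0, 2 * np.pi, n + 1)[:-1] + phase
    return np.column_stack([center[0] + r * np.sin(ang),
                            center[1] + r * np.cos(ang)])


def brute_force_min_stitch_area(P, Q):
    """Exhaustive enumeration over every acceptable stitching (all start
    correspondences, all monotone lattice paths)."""
    m, n = len(P), len(Q)
    Pn = np.vstack([P, P[:1]])

    def area(a, b, c):
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a))

    best = [np.inf]

    def walk(i, j, s, cost):
        if cost >= best[0]:
            return
        if i == m and j == n:
            best[0] = cost
            return
        if i < m:
            walk(i + 1, j, s, cost + area(Pn[i], Pn[i + 1], Q[(s + j) % n]))
        if j < n:
            walk(i, j + 1, s,
                 cost + area(Pn[i % m], Q[(s + j) % n], Q[(s + j + 1) % n]))

    for s in range(n):
        walk(0, 0, s, 0.0)
    return best[0]


def brute_force_inside(mesh, shape):
    """Independent parity oracle: rays along +z (not +x), per-voxel loop
    over all triangles."""
    eps = np.array([1.3e-5, 1.7e-5, 2.9e-5])
    V = mesh.vertices
    tris = V[mesh.triangles]  # (T, 3, 3) in (z, y, x)
    out = np.zeros(shape, dtype=bool)
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                p = np.array([z, y, x], dtype=float) + eps
                crossings = 0
                for a, b, c in tris:
                    # project on (y, x); ray along +z
                    d = (b[1] - a[1]) * (c[2] - a[2]) - (b[2] - a[2]) * (c[1] - a[1])
                    if abs(d) < 1e-15:
                        continue
                    u = ((p[1] - a[1]) * (c[2] - a[2])
                         - (p[2] - a[2]) * (c[1] - a[1])) / d
                    v = ((b[1] - a[1]) * (p[2] - a[2])
                         - (b[2] - a[2]) * (p[1] - a[1])) / d
                    if u >= 0 and v >= 0 and u + v <= 1:
                        zint = a[0] + u * (b[0] - a[0]) + v * (c[0] - a[0])
                        if zint > p[0]:
                            crossings += 1
                out[z, y, x] = crossings % 2 == 1
    return out


class TestStitchContours:
    def test_prism_band_and_volume(self):
        mesh = g.stitch_contours([(0.0, UNIT_SQUARE), (1.0, UNIT_SQUARE)])
        # 8 lateral triangles + two 4-triangle centroid-fan caps
        assert len(mesh.triangles) == 16
        assert mesh.is_closed()
        assert enclosed_volume(mesh) == pytest.approx(1.0, abs=1e-9)

    def test_optimal_versus_exhaustive_enumeration(self):
        rng = np.random.default_rng(42)
        cases = [
            (regular_polygon(6, 10), regular_polygon(6, 10, phase=np.pi / 6)),
            (regular_polygon(5, 8), regular_polygon(7, 6, phase=0.4)),
            (regular_polygon(8, 9), regular_polygon(6, 5, phase=1.1)),
        ]
        for P2, Q2 in cases:
            P = np.column_stack([np.zeros(len(P2)), P2[:, 0], P2[:, 1]])
            Q = np.column_stack([np.full(len(Q2), 4.0), Q2[:, 0], Q2[:, 1]])
            _, cost = _stitch_pair(P, Q)
            oracle = brute_force_min_stitch_area(P, Q)
            assert cost == pytest.approx(oracle, rel=1e-9)

    def test_cone_frustum_volume(self):
        hexa = regular_polygon(6, 10)
        mesh = g.stitch_contours([(0.0, hexa),
                                  (5.0, (hexa - 16.0) * 0.5 + 16.0)])
        a1 = 0.5 * 6 * 100 * np.sin(np.pi / 3)
        a2 = a1 * 0.25
        frustum = 5.0 / 3.0 * (a1 + a2 + np.sqrt(a1 * a2))
        assert enclosed_volume(mesh) == pytest.approx(frustum, rel=0.01)

    def test_cyclic_reindexing_invariance(self):
        P2 = regular_polygon(7, 9)
        Q2 = regular_polygon(9, 7, phase=0.3)
        P = np.column_stack([np.zeros(7), P2])
        Q = np.column_stack([np.full(9, 3.0), Q2])
        _, base_cost = _stitch_pair(P, Q)
        for shift in (2, 5):
            _, cost = _stitch_pair(np.roll(P, shift, axis=0),
                                   np.roll(Q, shift + 1, axis=0))
            assert cost == pytest.approx(base_cost, rel=1e-9)

    def test_single_contour_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            g.stitch_contours([(0.0, UNIT_SQUARE)])

    def test_self_intersecting_contour_rejected(self):
        bow = np.array([[0.0, 0.0], [2.0, 2.0], [0.0, 2.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="self-intersecting"):
            g.stitch_contours([(0.0, UNIT_SQUARE), (1.0, bow)])

    def test_duplicate_z_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            g.stitch_contours([(1.0, UNIT_SQUARE), (1.0, UNIT_SQUARE + 2)])


class TestVoxelsInsideMesh:
    def test_cube_half_open_count(self):
        cube = np.array([[2.0, 2.0], [2.0, 10.0], [10.0, 10.0], [10.0, 2.0]])
        mesh = g.stitch_contours([(2.0, cube), (10.0, cube)])
        inside = g.voxels_inside_mesh(mesh, (16, 16, 16))
        assert int(inside.data.sum()) == 512

    def test_outside_bounding_box_is_outside(self):
        cube = np.array([[2.0, 2.0], [2.0, 6.0], [6.0, 6.0], [6.0, 2.0]])
        mesh = g.stitch_contours([(2.0, cube), (6.0, cube)])
        inside = g.voxels_inside_mesh(mesh, (12, 12, 12))
        assert not inside.data[8:, :, :].any()
        assert not inside.data[:, 8:, :].any()

    def test_matches_brute_force_parity_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(3):
            rings = []
            for z in (5.0, 13.0, 21.0):
                n = int(rng.integers(6, 10))
                ang = np.linspace(0, 2 * np.pi, n + 1)[:-1]
                r = 9 * (1 + 0.3 * rng.standard_normal(n)).clip(0.4, 1.6)
                rings.append((z, np.column_stack([15 + r * np.sin(ang),
                                                  15 + r * np.cos(ang)])))
            mesh = g.stitch_contours(rings)
            ours = g.voxels_inside_mesh(mesh, (30, 30, 30))
            oracle = brute_force_inside(mesh, (30, 30, 30))
            assert np.array_equal(ours.data, oracle)

    def test_open_mesh_rejected(self):
        mesh = g.stitch_contours([(0.0, UNIT_SQUARE), (1.0, UNIT_SQUARE)])
        open_mesh = g.SurfaceMesh(mesh.vertices, mesh.triangles[:-1])
        with pytest.raises(ValueError, match="closed"):
            g.voxels_inside_mesh(open_mesh, (4, 4, 4))

    def test_count_converges_to_enclosed_volume(self):
        # prism at two grid refinements: count/volume ratio approaches 1
        errs = []
        for scale in (1.0, 2.0):
            sq = (UNIT_SQUARE * 8 + 2) * scale
            mesh = g.stitch_contours([(2 * scale, sq), (10 * scale, sq)])
            vol_true = enclosed_volume(mesh)
            n = int(24 * scale)
            count = int(g.voxels_inside_mesh(mesh, (n, n, n)).data.sum())
            errs.append(abs(count - vol_true) / vol_true)
        assert errs[1] <= errs[0] + 1e-12


class TestCropByMesh:
    def test_mesh_enclosing_grid_is_identity(self, rng):
        vol = g.Volume(rng.integers(0, 256, (8, 8, 8), dtype=np.uint8))
        big = np.array([[-2.0, -2.0], [-2.0, 10.0], [10.0, 10.0], [10.0, -2.0]])
        mesh = g.stitch_contours([(-2.0, big), (10.0, big)])
        assert np.array_equal(g.crop_by_mesh(vol, mesh).data, vol.data)

    def test_no_interior_centres_gives_all_zero(self, rng):
        vol = g.Volume(rng.integers(0, 256, (8, 8, 8), dtype=np.uint8))
        tiny = np.array([[3.2, 3.2], [3.2, 3.8], [3.8, 3.8], [3.8, 3.2]])
        mesh = g.stitch_contours([(3.2, tiny), (3.8, tiny)])
        assert not g.crop_by_mesh(vol, mesh).data.any()

    def test_composition_equals_apply_mask(self, rng):
        vol = g.Volume(rng.integers(0, 256, (16, 16, 16), dtype=np.uint8))
        hexa = regular_polygon(6, 5, center=(8.0, 8.0))
        mesh = g.stitch_contours([(4.0, hexa), (12.0, hexa * 0.8 + 1.6)])
        direct = g.crop_by_mesh(vol, mesh)
        composed = g.apply_mask(vol, g.voxels_inside_mesh(mesh, vol.shape))
        assert np.array_equal(direct.data, composed.data)


def test_mesh_export_off(tmp_path):
    mesh = g.stitch_contours([(0.0, UNIT_SQUARE), (1.0, UNIT_SQUARE)])
    mesh.export(tmp_path / "prism.off")
    import trimesh

    back = trimesh.load(tmp_path / "prism.off")
    assert back.volume == pytest.approx(1.0, abs=1e-6)
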