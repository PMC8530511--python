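"""Tissue metrics against analytic solids and exhaustive oracles."""

import math
from fractions import Fraction

import numpy as np
import pytest

from rpemorph import morpho
from rpemorph.errors import DegenerateGeometryError, GeometryError
from rpemorph.phantom import PhantomSpec, generate_cup_sequence, generate_shell_stack

from conftest import make_mask

PAPER_PITCH = (0.62, 0.62, 1.37)


def shell_mask(R, t, coverage, spacing=PAPER_PITCH):
    spec = PhantomSpec(
        shell_mid_radius=R,
        shell_thickness_by_frame=[t],
        angular_coverage=coverage,
        frame_times=[17.0],
        noise_sd=0.0,
        background_ramp_amplitude=0.0,
        spacing=spacing,
    )
    _, truth = generate_shell_stack(spec)
    return truth.masks[0]


class TestVoxelVolume:
    def test_empty_mask_is_zero(self):
        assert morpho.voxel_volume(make_mask(np.zeros((3, 3, 3)))) == 0.0

    def test_count_times_anisotropic_voxel_volume(self):
        vals = np.zeros((10, 10, 10), bool)
        vals.ravel()[:1000] = True
        m = make_mask(vals, spacing=PAPER_PITCH)
        assert morpho.voxel_volume(m) == pytest.approx(1000 * 0.62 * 0.62 * 1.37)

    def test_digitized_sphere_within_one_percent(self):
        """Solid sphere r=20 µm at 0.5 µm: volume within 1% of 4π/3·20³."""
        sp = 0.5
        n = 90
        c = (n - 1) / 2 * sp
        x = np.arange(n) * sp - c
        r2 = x[:, None, None] ** 2 + x[None, :, None] ** 2 + x[None, None, :] ** 2
        m = make_mask(r2 <= 20.0**2, spacing=(sp, sp, sp))
        assert morpho.voxel_volume(m) == pytest.approx(4 * math.pi / 3 * 20**3, rel=0.01)


class TestFitSurface:
    def test_flat_slab_recovers_itself(self):
        """x = c over a 40 × 60 µm footprint: area 2400 µm², no curvature terms."""
        vals = np.zeros((60, 40, 9), bool)
        vals[:, :, 4] = True
        fit, area = morpho.fit_surface(make_mask(vals))
        assert area == pytest.approx(2400.0)
        assert np.allclose(fit.coeffs[1:], 0.0, atol=1e-9)
        assert fit.coeffs[0] == pytest.approx(4.0)

    def test_tilted_plane_carries_sqrt2_slope_factor(self):
        n = 40
        vals = np.zeros((30, n, n + 2), bool)
        for iy in range(n):
            vals[:, iy, iy] = True
        _, area = morpho.fit_surface(make_mask(vals))
        assert area == pytest.approx(math.sqrt(2) * n * 30, rel=1e-6)

    def test_shallow_spherical_cap_matches_analytic_area(self):
        """Cap R=100 µm, half-angle 20°: graph area within 5% of 2πR²(1−cosθ)."""
        f = (1 - math.cos(math.radians(20))) / 2
        m = shell_mask(100.0, 4.0, f)
        _, area = morpho.fit_surface(m)
        analytic = 2 * math.pi * 100**2 * (1 - math.cos(math.radians(20)))
        assert area == pytest.approx(analytic, rel=0.05)

    def test_area_matches_triangulated_mesh_quadrature(self):
        """Column-sum area equals a fine triangulated mesh of the fitted quadratic within 1%."""
        f = (1 - math.cos(math.radians(25))) / 2
        m = shell_mask(80.0, 6.0, f)
        fit, area = morpho.fit_surface(m)
        sx, sy, sz = m.spacing
        mesh = 0.0
        k = 4  # subdivisions per column edge
        iz, iy = np.nonzero(fit.footprint)
        for zc, yc in zip(iz * sz, iy * sy):
            ys = yc - sy / 2 + sy * np.arange(k + 1) / k
            zs = zc - sz / 2 + sz * np.arange(k + 1) / k
            Y, Z = np.meshgrid(ys, zs, indexing="ij")
            X = fit.evaluate(Y, Z)
            P = np.stack([X, Y, Z], axis=-1)
            a, b, c, d = P[:-1, :-1], P[1:, :-1], P[:-1, 1:], P[1:, 1:]
            t1 = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=-1)
            t2 = 0.5 * np.linalg.norm(np.cross(b - d, c - d), axis=-1)
            mesh += float(np.sum(t1 + t2))
        assert area == pytest.approx(mesh, rel=0.01)

    def test_collinear_support_raises_rank_error(self):
        vals = np.zeros((8, 8, 8), bool)
        vals[2, :, 3] = True  # single z plane: no z² support
        with pytest.raises(DegenerateGeometryError):
            morpho.fit_surface(make_mask(vals))


class TestThickness:
    def test_ratio_definition(self):
        assert morpho.thickness(100.0, 50.0) == 2.0

    def test_zero_surface_raises(self):
        with pytest.raises(ZeroDivisionError):
            morpho.thickness(100.0, 0.0)

    @pytest.mark.parametrize("t_over_R", [0.1, 0.2])
    def test_vs_thickness_accurate_for_thin_shells(self, t_over_R):
        """V/S recovers true thickness within 10% for t/R ≤ 0.2."""
        R = 100.0
        m = shell_mask(R, t_over_R * R, 0.02)
        vol = morpho.voxel_volume(m)
        _, surf = morpho.fit_surface(m)
        assert morpho.thickness(vol, surf) == pytest.approx(t_over_R * R, rel=0.10)

    def test_invariant_under_rigid_translation(self):
        vals = np.zeros((40, 40, 30), bool)
        vals[5:25, 5:25, 4:10] = True
        a = make_mask(vals)
        b = make_mask(np.roll(np.roll(vals, 7, axis=1), 10, axis=0))
        va, (_, sa) = morpho.voxel_volume(a), morpho.fit_surface(a)
        vb, (_, sb) = morpho.voxel_volume(b), morpho.fit_surface(b)
        assert morpho.thickness(va, sa) == pytest.approx(morpho.thickness(vb, sb), rel=1e-9)


class TestBlocks:
    def test_uniform_bar_splits_into_equal_blocks(self):
        vals = np.zeros((5, 6, 70), bool)
        vals[:, :, :] = True
        _, blocks = morpho.discretize_blocks(make_mask(vals), n_blocks=7)
        vols = [morpho.voxel_volume(b) for b in blocks]
        assert len(set(vols)) == 1

    def test_block_volumes_sum_to_whole(self, rng):
        vals = rng.uniform(0, 1, (12, 15, 33)) > 0.6
        vals[3, 7, 0] = vals[3, 7, 32] = True  # pin the extent
        m = make_mask(vals, spacing=PAPER_PITCH)
        _, blocks = morpho.discretize_blocks(m, n_blocks=7)
        assert sum(morpho.voxel_volume(b) for b in blocks) == pytest.approx(
            morpho.voxel_volume(m), abs=1e-9
        )

    def test_assignment_matches_exact_rational_binning_oracle(self, rng):
        """Per-voxel binning with exact Fraction arithmetic agrees everywhere."""
        vals = rng.uniform(0, 1, (6, 9, 41)) > 0.5
        vals[0, 0, 2] = vals[0, 0, 38] = True
        m = make_mask(vals, spacing=PAPER_PITCH)
        partition, blocks = morpho.discretize_blocks(m, n_blocks=7)
        ix = np.nonzero(vals.any(axis=(0, 1)))[0]
        lo, hi = int(ix[0]), int(ix[-1])
        labels = np.zeros_like(vals, dtype=int)
        for b, bm in enumerate(blocks):
            labels[bm.values] = b
        for z, y, x in zip(*np.nonzero(vals)):
            frac = Fraction(int(x) - lo, hi - lo)  # position along the extent
            oracle = min(int(frac * 7), 6)
            assert labels[z, y, x] == oracle

    def test_too_few_columns_raises(self):
        vals = np.zeros((3, 3, 10), bool)
        vals[:, :, 2:5] = True
        with pytest.raises(GeometryError):
            morpho.discretize_blocks(make_mask(vals), n_blocks=7)

    @pytest.mark.parametrize(
        "time, retained",
        [(18.0, 7), (20.0, 6), (21.0, 5)],
        ids=["before-cmz", "at-cmz-onset", "after-cmz-onset"],
    )
    def test_cmz_exclusion_schedule(self, time, retained):
        """All blocks before 20 hpf; drop 1 at 20 hpf; drop 2 afterwards."""
        p = morpho.BlockPartition(n_blocks=7, edges_um=np.linspace(0, 70, 8))
        out = morpho.exclude_cmz_blocks(p, time, t_one=20.0)
        assert len(out.retained_blocks()) == retained

    def test_anterior_side_controls_which_blocks_drop(self):
        p = morpho.BlockPartition(n_blocks=7, edges_um=np.linspace(0, 70, 8), anterior="-x")
        out = morpho.exclude_cmz_blocks(p, 21.0)
        assert out.retained_blocks() == [3, 4, 5, 6, 7]


class TestConvexHull:
    def test_solid_box_hull_equals_box_volume(self):
        vals = np.zeros((20, 20, 20), bool)
        vals[2:12, 3:15, 4:18] = True
        m = make_mask(vals)
        assert morpho.convex_hull_volume(m) == pytest.approx(10 * 12 * 14)
        assert morpho.convex_hull_volume(m) == pytest.approx(morpho.voxel_volume(m))

    def test_voxelized_tetrahedron_within_three_percent(self):
        """Voxelized tetra vertices (0,0,0)(60,0,0)(0,60,0)(0,0,60) µm: hull
        within 3% of the analytic 36,000 µm³ (voxel-extent bias shrinks with pitch)."""
        sp = 0.15
        k = int(round(60 / sp))
        vals = np.zeros((k + 1, k + 1, k + 1), bool)
        vals[0, 0, 0] = vals[0, 0, k] = vals[0, k, 0] = vals[k, 0, 0] = True
        m = make_mask(vals, spacing=(sp, sp, sp))
        assert morpho.convex_hull_volume(m) == pytest.approx(36000.0, rel=0.03)

    def test_cup_hull_exceeds_voxel_volume(self):
        spec = PhantomSpec(
            frame_times=[17.0],
            invagination_angle_by_frame=[100.0],
            noise_sd=0.0,
            background_ramp_amplitude=0.0,
        )
        _, truth = generate_cup_sequence(spec)
        eye = truth.eye_masks[0]
        assert morpho.convex_hull_volume(eye) > morpho.voxel_volume(eye)

    def test_hull_never_below_voxel_volume_for_random_blobs(self, rng):
        for _ in range(5):
            vals = rng.uniform(0, 1, (10, 12, 14)) > 0.7
            vals[0, 0, 0] = vals[-1, -1, -1] = vals[0, -1, 0] = vals[-1, 0, -1] = True
            m = make_mask(vals, spacing=PAPER_PITCH)
            assert morpho.convex_hull_volume(m) >= morpho.voxel_volume(m) - 1e-9

    def test_coplanar_points_raise(self):
        vals = np.zeros((5, 5, 5), bool)
        vals[2, :, :] = True
        with pytest.raises(DegenerateGeometryError):
            morpho.convex_hull_volume(make_mask(vals))
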