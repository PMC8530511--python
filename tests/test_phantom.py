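"""Phantom generators against their analytic ground truth."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rpemorph.errors import GeometryError, PhantomError
from rpemorph.grid import VoxelGrid
from rpemorph.morpho import voxel_volume
from rpemorph.phantom import (
    PhantomSpec,
    add_noise_and_background,
    flattening_trajectory_spec,
    generate_cup_sequence,
    generate_nuclei_stack,
    generate_shell_stack,
    round_half_up,
)

FULL_SPHERE_ANALYTIC = 4 * math.pi / 3 * (35.0**3 - 25.0**3)  # R=30, t=10


def shell_spec(**kw) -> PhantomSpec:
    fields = dict(
        shell_mid_radius=30.0,
        shell_thickness_by_frame=[10.0],
        angular_coverage=1.0,
        frame_times=[17.0],
        noise_sd=0.0,
        background_ramp_amplitude=0.0,
    )
    fields.update(kw)
    return PhantomSpec(**fields)


class TestShellStack:
    @pytest.mark.parametrize(
        "spacing, tol",
        [((0.5, 0.5, 0.5), 0.02), ((0.62, 0.62, 1.37), 0.10)],
        ids=["isotropic-0.5um", "anisotropic-paper-pitch"],
    )
    def test_voxelized_volume_matches_analytic_shell(self, spacing, tol):
        """Full-sphere shell R=30 µm, t=10 µm: voxel count converges to 4π/3(35³−25³)."""
        _, truth = generate_shell_stack(shell_spec(spacing=spacing))
        vol = voxel_volume(truth.masks[0])
        assert vol == pytest.approx(FULL_SPHERE_ANALYTIC, rel=tol)
        assert truth.true_volume[0] == pytest.approx(FULL_SPHERE_ANALYTIC, rel=1e-12)

    def test_degenerate_zero_thickness_shell_is_empty(self):
        _, truth = generate_shell_stack(shell_spec(shell_thickness_by_frame=[0.0]))
        assert truth.true_volume[0] == 0.0
        assert not truth.masks[0].values.any()

    def test_identical_spec_and_seed_is_bit_identical(self):
        spec = shell_spec(noise_sd=5.0, background_ramp_amplitude=20.0, seed=42)
        frames_a, _ = generate_shell_stack(spec)
        frames_b, _ = generate_shell_stack(spec)
        for a, b in zip(frames_a, frames_b):
            assert np.array_equal(a.values, b.values)

    def test_shell_exceeding_image_bounds_raises(self):
        with pytest.raises(GeometryError):
            generate_shell_stack(shell_spec(image_shape=(40, 40, 40)))

    def test_truth_thickness_consistent_with_volume_over_surface(self):
        """V/S equals t up to the shell-curvature factor 1 ± (t/2R)²."""
        spec = flattening_trajectory_spec()
        _, truth = generate_shell_stack(spec)
        ratio = truth.true_volume / truth.true_surface / truth.true_thickness
        bound = (truth.true_thickness / (2 * np.asarray(spec.shell_mid_radius))) ** 2
        assert np.all(np.abs(ratio - 1.0) <= bound + 1e-12)

    def test_partial_coverage_scales_analytic_truth(self):
        _, full = generate_shell_stack(shell_spec())
        _, half = generate_shell_stack(shell_spec(angular_coverage=0.5))
        assert half.true_volume[0] == pytest.approx(0.5 * full.true_volume[0])
        assert half.true_surface[0] == pytest.approx(0.5 * full.true_surface[0])


class TestNoiseAndBackground:
    def test_zero_noise_zero_ramp_is_identity(self):
        g = VoxelGrid(np.random.default_rng(0).uniform(0, 50, (4, 5, 6)), (1, 1, 1))
        out = add_noise_and_background(g, 0.0, 0.0, seed=1)
        assert np.array_equal(out.values, g.values)

    def test_ramp_gradient_matches_prescription(self):
        """Intensity difference along x equals the prescribed linear gradient."""
        g = VoxelGrid(np.zeros((3, 4, 11)), (2.0, 1.0, 1.0))
        amp = 30.0
        out = add_noise_and_background(g, 0.0, amp, seed=0)
        expected = amp * np.arange(11) / 10.0
        assert np.allclose(out.values, expected[None, None, :])

    def test_fixed_seed_reproducible(self):
        g = VoxelGrid(np.full((4, 4, 4), 10.0), (1, 1, 1))
        a = add_noise_and_background(g, 3.0, 0.0, seed=7)
        b = add_noise_and_background(g, 3.0, 0.0, seed=7)
        c = add_noise_and_background(g, 3.0, 0.0, seed=8)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_output_clipped_at_zero(self):
        g = VoxelGrid(np.zeros((4, 4, 4)), (1, 1, 1))
        out = add_noise_and_background(g, 50.0, 0.0, seed=3)
        assert (out.values >= 0).all()

    def test_negative_parameters_rejected(self):
        g = VoxelGrid(np.zeros((2, 2, 2)), (1, 1, 1))
        with pytest.raises(PhantomError):
            add_noise_and_background(g, -1.0, 0.0)


class TestCupSequence:
    def cup_spec(self, angles, times=None, **kw):
        times = tuple(times) if times is not None else tuple(
            17.0 + np.arange(len(angles)) * 1.0
        )
        fields = dict(
            frame_times=times,
            invagination_angle_by_frame=tuple(angles),
            noise_sd=0.0,
            background_ramp_amplitude=0.0,
        )
        fields.update(kw)
        return PhantomSpec(**fields)

    def test_constant_volume_sequence_has_zero_truth_slope(self):
        _, truth = generate_cup_sequence(self.cup_spec([150, 150, 150], eye_volume_slope=0.0))
        assert np.ptp(truth.true_volume) == 0.0

    def test_truth_volumes_lie_exactly_on_prescribed_line(self):
        """Whole-eye growth at 5.54e4 µm³/hr over 17-22 hpf, exact before noise."""
        spec = self.cup_spec(
            [170, 150, 130, 110, 95, 85],
            times=np.arange(17.0, 22.01, 1.0),
            eye_volume_start=2.0e5,
            eye_volume_slope=5.54e4,
        )
        _, truth = generate_cup_sequence(spec)
        line = 2.0e5 + 5.54e4 * (truth.times - 17.0)
        assert np.allclose(truth.true_volume, line, rtol=1e-12)
        # voxelization tracks the analytic truth closely
        vox = [voxel_volume(m) for m in truth.eye_masks]
        assert np.allclose(vox, line, rtol=0.01)

    def test_flat_bilayer_at_180_degrees_has_collinear_hinges(self):
        _, truth = generate_cup_sequence(self.cup_spec([180.0, 180.0], times=[17.0, 17.5]))
        xs = [truth.vertex_points[0][0], truth.hinge_points[0, 0, 0], truth.hinge_points[0, 1, 0]]
        assert np.ptp(xs) < 1e-9

    @pytest.mark.parametrize("bad", [0.0, -10.0, 181.0, 360.0])
    def test_angle_outside_range_rejected(self, bad):
        with pytest.raises(PhantomError):
            generate_cup_sequence(self.cup_spec([bad]))


class TestNucleiStack:
    def nuclei_spec(self, n, fraction, seed=0, **kw):
        fields = dict(
            n_nuclei=n,
            labelled_fraction=fraction,
            seed=seed,
            noise_sd=0.0,
            background_ramp_amplitude=0.0,
        )
        fields.update(kw)
        return PhantomSpec(**fields)

    @pytest.mark.parametrize(
        "n, fraction, expected",
        [(200, 0.49, 98), (100, 0.70, 70), (100, 0.0, 0), (50, 1.0, 50)],
    )
    def test_labelled_count_is_exactly_rounded_fraction(self, n, fraction, expected):
        _, truth = generate_nuclei_stack(self.nuclei_spec(n, fraction))
        assert truth.n_labelled == expected
        if expected == 0:
            assert not truth.masks[1].values.any()

    def test_hard_core_separation_respected(self):
        spec = self.nuclei_spec(60, 0.5, seed=9)
        _, truth = generate_nuclei_stack(spec)
        c = truth.nuclei_centres
        d2 = np.sum((c[:, None, :] - c[None, :, :]) ** 2, axis=-1)
        d2[np.diag_indices(len(c))] = np.inf
        assert d2.min() >= (2 * spec.nucleus_radius + spec.nucleus_gap) ** 2 - 1e-9

    def test_region_too_small_raises_after_retry_budget(self):
        with pytest.raises(PhantomError):
            generate_nuclei_stack(self.nuclei_spec(100, 0.5, image_shape=(30, 30, 10)))

    @settings(deadline=None, derandomize=True, max_examples=15)
    @given(
        n=st.integers(min_value=1, max_value=25),
        fraction=st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
        seed=st.integers(min_value=0, max_value=2**20),
    )
    def test_labelled_count_exact_for_every_seed(self, n, fraction, seed):
        """round(fraction × n) labelled nuclei, whatever the seed."""
        _, truth = generate_nuclei_stack(self.nuclei_spec(n, fraction, seed=seed))
        assert truth.n_labelled == round_half_up(fraction * n)
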