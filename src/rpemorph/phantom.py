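"""Synthetic voxel phantoms with exact ground truth.

Three families of phantoms emulate the data the morphometry pipeline was
designed for:

* **shell stacks** — a partial spherical shell (a curved epithelial sheet such
  as the nascent RPE) whose mid-radius, thickness and angular coverage are
  prescribed per frame, rendered at anisotropic voxel spacing. Truth carries
  the analytic volume, mid-surface area and thickness.
* **cup sequences** — a two-channel series (whole-eye solid + its outer tissue
  shell) of a ball indented by a second sphere, with a prescribed invagination
  angle per frame and a whole-eye volume that follows an exact linear growth
  law (the indentation geometry is similar across frames, so volume scales as
  R³ and the radius solves in closed form).
* **nuclei stacks** — non-overlapping spherical nuclei inside a region, a
  prescribed fraction of which also appear in a second ("labelled") channel,
  emulating BrdU/Ki67 proliferation assays.

All generators are bit-reproducible under a fixed seed, and every stack is
accompanied by a :class:`PhantomTruth` — the oracle downstream stages are
tested against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import GeometryError, PhantomError
from .grid import SegmentationMask, Spacing, VoxelGrid

#: default voxel pitch, µm (x, y, z) — a typical confocal time-lapse setting
DEFAULT_SPACING: Spacing = (0.62, 0.62, 1.37)

#: constant foreground intensity before noise; the pipeline only thresholds,
#: so realistic texture is unnecessary
DEFAULT_AMPLITUDE = 100.0


def round_half_up(x: float) -> int:
    """round() with halves going up, so labelled counts are seed-invariant."""
    return int(math.floor(x + 0.5))


@dataclass
class PhantomSpec:
    """Parameters of a synthetic stack.

    Defaults describe an RPE-like sheet: mid-radius 60 µm with angular
    coverage 0.0243 (mid-surface ≈ 1.1 × 10³ µm²) flattening linearly from
    24 µm to 8 µm between 17 and 21 hpf, imaged every 0.5 hr at
    (0.62 × 0.62 × 1.37) µm voxels, foreground amplitude 100 with Gaussian
    noise (sd 5) and a linear background ramp (amplitude 20) along x.
    """

    image_shape: Optional[tuple[int, int, int]] = None  # voxels per axis (nx, ny, nz); None = auto-fit
    spacing: Spacing = DEFAULT_SPACING
    shell_mid_radius: float | Sequence[float] = 60.0  # µm, scalar or per frame
    shell_thickness_by_frame: Sequence[float] = tuple(np.linspace(24.0, 8.0, 9))
    angular_coverage: float | Sequence[float] = 0.0243  # fraction of the full sphere, (0, 1]; scalar or per frame
    frame_times: Sequence[float] = tuple(np.arange(17.0, 21.01, 0.5))  # hpf
    invagination_angle_by_frame: Optional[Sequence[float]] = None  # degrees, cup phantoms
    n_nuclei: int = 200
    labelled_fraction: float = 0.5
    noise_sd: float = 5.0
    background_ramp_amplitude: float = 20.0
    seed: int = 0
    # --- secondary knobs -------------------------------------------------
    amplitude: float = DEFAULT_AMPLITUDE
    margin_um: float = 3.0  # empty border around auto-fitted geometry
    eye_volume_start: float = 2.0e5  # µm³ at the first cup frame
    eye_volume_slope: float = 5.54e4  # µm³/hr, whole-eye linear growth
    rim_fraction: float = 0.8  # cup rim (hinge circle) radius / eye radius
    cup_shell_thickness: float = 8.0  # µm, tissue channel of cup phantoms
    nucleus_radius: float = 3.0  # µm
    nucleus_gap: float = 2.0  # µm of clear space between nucleus surfaces

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise PhantomError(f"spacing must be strictly positive, got {self.spacing}")
        times = np.asarray(self.frame_times, dtype=float)
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise PhantomError("frame_times must be strictly increasing")
        cov = np.atleast_1d(np.asarray(self.angular_coverage, dtype=float))
        if np.any(cov <= 0) or np.any(cov > 1):
            raise PhantomError(f"angular_coverage must lie in (0, 1], got {self.angular_coverage}")
        if not 0 <= self.labelled_fraction <= 1:
            raise PhantomError(f"labelled_fraction must lie in [0, 1], got {self.labelled_fraction}")
        thick = np.asarray(self.shell_thickness_by_frame, dtype=float)
        if np.any(thick < 0):
            raise PhantomError("shell thickness must be non-negative")
        # thickness/frame count agreement is checked by generate_shell_stack;
        # cup and nuclei phantoms do not use shell_thickness_by_frame
        if thick.size == times.size and thick.size:
            radii = np.broadcast_to(np.asarray(self.shell_mid_radius, dtype=float), times.shape)
            if np.any(thick >= radii):
                raise PhantomError("shell thickness must be smaller than the mid-radius")
        if self.noise_sd < 0 or self.background_ramp_amplitude < 0:
            raise PhantomError("noise_sd and background_ramp_amplitude must be non-negative")

    # broadcast helpers ----------------------------------------------------
    def frame_radii(self) -> np.ndarray:
        times = np.asarray(self.frame_times, dtype=float)
        return np.broadcast_to(np.asarray(self.shell_mid_radius, dtype=float), times.shape).copy()

    def frame_coverages(self) -> np.ndarray:
        times = np.asarray(self.frame_times, dtype=float)
        return np.broadcast_to(np.asarray(self.angular_coverage, dtype=float), times.shape).copy()


@dataclass
class PhantomTruth:
    """Ground truth emitted alongside every synthetic stack."""

    times: np.ndarray
    true_volume: Optional[np.ndarray] = None  # µm³ per frame
    true_surface: Optional[np.ndarray] = None  # µm², mid-surface area
    true_thickness: Optional[np.ndarray] = None  # µm
    true_angle: Optional[np.ndarray] = None  # degrees
    nuclei_centres: Optional[np.ndarray] = None  # (n, 3) physical (x, y, z) µm
    labelled_flags: Optional[np.ndarray] = None  # (n,) bool
    masks: list[SegmentationMask] = field(default_factory=list)  # exact foreground per frame
    eye_masks: list[SegmentationMask] = field(default_factory=list)  # cup phantoms only
    vertex_points: Optional[np.ndarray] = None  # (n_frames, 2) in-plane (x, y) µm
    hinge_points: Optional[np.ndarray] = None  # (n_frames, 2, 2) in-plane (x, y) µm

    @property
    def n_labelled(self) -> Optional[int]:
        return None if self.labelled_flags is None else int(np.count_nonzero(self.labelled_flags))


# ---------------------------------------------------------------------------
# noise / background
# ---------------------------------------------------------------------------

def add_noise_and_background(
    grid: VoxelGrid,
    noise_sd: float,
    ramp_amplitude: float,
    seed: int | np.random.Generator | None = 0,
) -> VoxelGrid:
    """Add a smooth linear background ramp along x plus i.i.d. Gaussian noise.

    The ramp rises from 0 at ``x = 0`` to ``ramp_amplitude`` at the far x edge
    of the frame; the noisy image is clipped at zero (intensities are
    non-negative). With ``noise_sd == 0`` and ``ramp_amplitude == 0`` the
    output values equal the input. Deterministic under a fixed seed.
    """
    if noise_sd < 0 or ramp_amplitude < 0:
        raise PhantomError("noise_sd and ramp_amplitude must be non-negative")
    values = grid.values.astype(float, copy=True)
    nz, ny, nx = values.shape
    if ramp_amplitude > 0 and nx > 1:
        ramp = ramp_amplitude * (np.arange(nx) / (nx - 1))
        values += ramp[None, None, :]
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        values += rng.normal(0.0, noise_sd, size=values.shape)
    np.clip(values, 0.0, None, out=values)
    return grid.with_values(values)


def _frame_seed(seed: int, frame: int, stream: int = 0) -> int:
    """Derive a per-frame integer seed below 2**31 from the master seed."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, frame, stream])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# spherical shell stacks
# ---------------------------------------------------------------------------

def _cap_bbox(r_out: float, r_in: float, theta: float) -> tuple[float, float, float]:
    """Physical extents of a shell cap around the -x axis, relative to centre.

    The cap opening faces +x: material lies at polar angles <= theta from -x,
    i.e. x = -r cos(theta') for theta' in [0, theta]. Returns
    ``(x_lo, x_hi, lateral_halfwidth)`` with ``x_lo <= x_hi`` (x_lo negative).
    """
    x_lo = -r_out
    if theta <= math.pi / 2:
        x_hi = -r_in * math.cos(theta)
        lateral = r_out * math.sin(theta)
    else:
        x_hi = -r_out * math.cos(theta)
        lateral = r_out
    return x_lo, x_hi, lateral


def _shell_extents(radii: np.ndarray, thick: np.ndarray, thetas: np.ndarray) -> tuple[float, float]:
    """Max extents over frames with the cap apex pinned at x = 0.

    Each frame's sphere centre sits at ``x = R + t/2`` so the deepest material
    point (the apex of the bowl) is at x = 0 for every frame — the sheet stays
    registered across the series like a stabilized time-lapse. Returns the max
    ``(x_extent, lateral_halfwidth)`` over frames.
    """
    x_ext = lateral = 0.0
    for R, t, theta in zip(radii, thick, thetas):
        if t <= 0:
            continue
        lo, hi, lat = _cap_bbox(R + t / 2.0, R - t / 2.0, theta)
        x_ext = max(x_ext, hi - lo)  # lo = -(R + t/2), apex-relative depth span
        lateral = max(lateral, lat)
    return x_ext, lateral


def _rasterize_shell(
    shape_zyx: tuple[int, int, int],
    spacing: Spacing,
    centre: tuple[float, float, float],
    r_mid: float,
    thickness: float,
    theta: float,
) -> np.ndarray:
    """Boolean cap-shell mask; opening faces +x."""
    nz, ny, nx = shape_zyx
    sx, sy, sz = spacing
    cx, cy, cz = centre
    dx = np.arange(nx) * sx - cx
    dy = np.arange(ny) * sy - cy
    dz = np.arange(nz) * sz - cz
    r2 = dz[:, None, None] ** 2 + dy[None, :, None] ** 2 + dx[None, None, :] ** 2
    r = np.sqrt(r2)
    r_in, r_out = r_mid - thickness / 2.0, r_mid + thickness / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_from_neg_x = np.where(r > 0, -dx[None, None, :] / np.where(r > 0, r, 1.0), 1.0)
    return (r >= r_in) & (r <= r_out) & (cos_from_neg_x >= math.cos(theta))


def generate_shell_stack(spec: PhantomSpec) -> tuple[list[VoxelGrid], PhantomTruth]:
    """Render a time series of partial spherical shells with analytic truth.

    Per frame the shell has mid-radius R, thickness t and solid-angle fraction
    ``angular_coverage``; truth carries volume
    ``coverage * (4π/3)((R+t/2)³ − (R−t/2)³)``, mid-surface area
    ``coverage * 4πR²`` and thickness t. A shell that would not fit inside the
    image raises :class:`GeometryError` rather than being silently clipped.
    """
    times = np.asarray(spec.frame_times, dtype=float)
    thick = np.asarray(spec.shell_thickness_by_frame, dtype=float)
    if thick.size != times.size:
        raise PhantomError(f"{thick.size} thickness values for {times.size} frames")
    radii = spec.frame_radii()
    coverages = spec.frame_coverages()
    thetas = np.arccos(1.0 - 2.0 * coverages)
    sx, sy, sz = spec.spacing
    m = spec.margin_um

    x_ext, lateral = _shell_extents(radii, thick, thetas)
    if spec.image_shape is None:
        cy = cz = m + lateral
        nx = int(math.ceil((x_ext + 2 * m) / sx)) + 1
        ny = int(math.ceil(2 * cy / sy)) + 1
        nz = int(math.ceil(2 * cz / sz)) + 1
    else:
        nx, ny, nz = spec.image_shape
        cy = (ny - 1) * sy / 2.0
        cz = (nz - 1) * sz / 2.0
        if (x_ext + 2 * m > (nx - 1) * sx
                or cy - lateral < 0 or cy + lateral > (ny - 1) * sy
                or cz - lateral < 0 or cz + lateral > (nz - 1) * sz):
            raise GeometryError(
                "shell does not fit inside the requested image shape; "
                "enlarge image_shape or leave it unset for auto-fitting"
            )
    shape_zyx = (nz, ny, nx)

    frames: list[VoxelGrid] = []
    masks: list[SegmentationMask] = []
    vol = np.zeros(times.size)
    surf = np.zeros(times.size)
    for i, (t_hpf, R, t, f, theta) in enumerate(zip(times, radii, thick, coverages, thetas)):
        if t > 0:
            centre = (m + R + t / 2.0, cy, cz)  # apex of the bowl pinned at x = margin
            mask = _rasterize_shell(shape_zyx, spec.spacing, centre, R, t, theta)
            r_out, r_in = R + t / 2.0, R - t / 2.0
            vol[i] = f * (4.0 * math.pi / 3.0) * (r_out**3 - r_in**3)
        else:
            mask = np.zeros(shape_zyx, dtype=bool)
            vol[i] = 0.0
        surf[i] = f * 4.0 * math.pi * R**2
        grid = VoxelGrid(mask.astype(float) * spec.amplitude, spec.spacing, time=float(t_hpf), channel="tissue")
        grid = add_noise_and_background(
            grid, spec.noise_sd, spec.background_ramp_amplitude, _frame_seed(spec.seed, i)
        )
        frames.append(grid)
        masks.append(SegmentationMask(mask, spec.spacing, time=float(t_hpf), channel="tissue"))

    truth = PhantomTruth(
        times=times,
        true_volume=vol,
        true_surface=surf,
        true_thickness=thick.copy(),
        masks=masks,
    )
    return frames, truth


def flattening_trajectory_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """The canonical epithelial-flattening world: thickness 24 → 8 µm, surface doubling.

    Between 17 and 22 hpf (frames every 0.5 hr) the sheet flattens linearly
    from 24 µm to 8 µm by 21 hpf and stays flat, while its mid-surface area
    doubles linearly from 1.1×10³ to 2.2×10³ µm². The optic vesicle is still
    nearly flat at 17 hpf and folds into a cup, so the mid-radius shrinks from
    200 µm (quasi-planar sheet) to 60 µm as folding proceeds; the angular
    coverage per frame is set so the mid-surface area follows the prescribed
    trajectory exactly.
    """
    times = np.arange(17.0, 22.01, 0.5)
    thick = np.interp(times, [17.0, 21.0, 22.0], [24.0, 8.0, 8.0])
    surface = np.interp(times, [17.0, 22.0], [1.1e3, 2.2e3])
    radius = np.interp(times, [17.0, 21.0, 22.0], [200.0, 60.0, 60.0])
    coverage = surface / (4.0 * math.pi * radius**2)
    fields = dict(
        frame_times=tuple(times),
        shell_thickness_by_frame=tuple(thick),
        shell_mid_radius=tuple(radius),
        angular_coverage=tuple(coverage),
        seed=seed,
    )
    fields.update(overrides)
    return PhantomSpec(**fields)


# ---------------------------------------------------------------------------
# folding cup sequences
# ---------------------------------------------------------------------------

def _cup_unit_geometry(angle_deg: float, rim_fraction: float) -> tuple[float, float, float, float]:
    """Indentation geometry for a unit-radius eye ball.

    Returns ``(h, x_v, r_ind, d)``: hinge-plane x, cavity vertex x, indenter
    radius and indenter centre x (``inf``/unused when the angle is 180°, i.e.
    no indentation). The invagination angle is the angle at the cavity vertex
    subtended by the two hinge points; smaller angles mean deeper folding.
    """
    if not 0.0 < angle_deg <= 180.0:
        raise PhantomError(f"invagination angle must lie in (0°, 180°], got {angle_deg}")
    beta = rim_fraction
    if not 0.0 < beta < 1.0:
        raise PhantomError(f"rim_fraction must lie in (0, 1), got {beta}")
    rho_h = beta
    h = math.sqrt(1.0 - beta * beta)
    if angle_deg == 180.0:
        return h, h, math.inf, math.inf
    u = rho_h / math.tan(math.radians(angle_deg) / 2.0)  # vertex depth below hinge plane
    x_v = h - u
    if x_v <= -1.0:
        raise PhantomError(
            f"invagination angle {angle_deg}° with rim fraction {beta} punches through the eye"
        )
    r_ind = (u * u + rho_h * rho_h) / (2.0 * u)
    d = x_v + r_ind
    return h, x_v, r_ind, d


def _sphere_lens_volume(r1: float, r2: float, d: float) -> float:
    """Volume of the intersection of two spheres at centre distance d."""
    if d >= r1 + r2:
        return 0.0
    if d + min(r1, r2) <= max(r1, r2):  # one inside the other
        return (4.0 * math.pi / 3.0) * min(r1, r2) ** 3
    return (
        math.pi
        * (r1 + r2 - d) ** 2
        * (d * d + 2 * d * r2 - 3 * r2 * r2 + 2 * d * r1 + 6 * r1 * r2 - 3 * r1 * r1)
        / (12.0 * d)
    )


def generate_cup_sequence(spec: PhantomSpec) -> tuple[list[tuple[VoxelGrid, VoxelGrid]], PhantomTruth]:
    """Two-channel folding-cup series with an exact linear eye-volume law.

    The whole-eye channel is a solid ball indented by a sphere whose geometry
    realizes the prescribed invagination angle; the tissue channel is the
    ball's outer shell (thickness ``cup_shell_thickness``) outside the cavity.
    Because the indentation geometry is similar across frames at fixed angle
    parameters, the eye volume scales as R³ and the radius realizing
    ``V(t) = eye_volume_start + eye_volume_slope·(t − t₀)`` is closed-form.
    Truth volumes therefore lie exactly on the prescribed line (before noise
    and voxelization). Returns frames as ``(tissue, whole-eye)`` pairs.
    """
    if spec.invagination_angle_by_frame is None:
        raise PhantomError("cup phantoms require invagination_angle_by_frame")
    times = np.asarray(spec.frame_times, dtype=float)
    angles = np.asarray(spec.invagination_angle_by_frame, dtype=float)
    if angles.size != times.size:
        raise PhantomError(f"{angles.size} angles for {times.size} frames")

    volumes = spec.eye_volume_start + spec.eye_volume_slope * (times - times[0])
    if np.any(volumes <= 0):
        raise PhantomError("prescribed eye volumes must stay positive")

    geom = [_cup_unit_geometry(a, spec.rim_fraction) for a in angles]
    radii = np.empty(times.size)
    for i, ((h, x_v, r_ind, d), V) in enumerate(zip(geom, volumes)):
        lens = 0.0 if math.isinf(r_ind) else _sphere_lens_volume(1.0, r_ind, d)
        k = 4.0 * math.pi / 3.0 - lens
        radii[i] = (V / k) ** (1.0 / 3.0)

    sx, sy, sz = spec.spacing
    m = spec.margin_um
    r_max = float(radii.max())
    if spec.image_shape is None:
        cx = cy = cz = m + r_max
        nx = int(math.ceil((2 * cx) / sx)) + 1
        ny = int(math.ceil((2 * cy) / sy)) + 1
        nz = int(math.ceil((2 * cz) / sz)) + 1
    else:
        nx, ny, nz = spec.image_shape
        cx, cy, cz = (nx - 1) * sx / 2.0, (ny - 1) * sy / 2.0, (nz - 1) * sz / 2.0
        if min(cx, cy, cz) < r_max:
            raise GeometryError("cup does not fit inside the requested image shape")

    dx = np.arange(nx) * sx - cx
    dy = np.arange(ny) * sy - cy
    dz = np.arange(nz) * sz - cz
    r2 = dz[:, None, None] ** 2 + dy[None, :, None] ** 2 + dx[None, None, :] ** 2

    frames: list[tuple[VoxelGrid, VoxelGrid]] = []
    tissue_masks: list[SegmentationMask] = []
    eye_masks: list[SegmentationMask] = []
    vertices = np.empty((times.size, 2))
    hinges = np.empty((times.size, 2, 2))
    for i, ((h, x_v, r_ind, d), R, t_hpf) in enumerate(zip(geom, radii, times)):
        eye = r2 <= R * R
        if not math.isinf(r_ind):
            ind2 = (
                dz[:, None, None] ** 2
                + dy[None, :, None] ** 2
                + (dx[None, None, :] - d * R) ** 2
            )
            cavity = ind2 < (r_ind * R) ** 2
            eye &= ~cavity
        else:
            cavity = None
        t_shell = min(spec.cup_shell_thickness, R)
        shell = eye & (r2 >= (R - t_shell) ** 2)
        rho_h = spec.rim_fraction
        vertices[i] = (cx + x_v * R, cy)
        hinges[i, 0] = (cx + h * R, cy + rho_h * R)
        hinges[i, 1] = (cx + h * R, cy - rho_h * R)

        eye_grid = VoxelGrid(eye.astype(float) * spec.amplitude, spec.spacing, time=float(t_hpf), channel="eye")
        tissue_grid = VoxelGrid(shell.astype(float) * spec.amplitude, spec.spacing, time=float(t_hpf), channel="tissue")
        eye_grid = add_noise_and_background(
            eye_grid, spec.noise_sd, spec.background_ramp_amplitude, _frame_seed(spec.seed, i, stream=1)
        )
        tissue_grid = add_noise_and_background(
            tissue_grid, spec.noise_sd, spec.background_ramp_amplitude, _frame_seed(spec.seed, i, stream=2)
        )
        frames.append((tissue_grid, eye_grid))
        tissue_masks.append(SegmentationMask(shell, spec.spacing, time=float(t_hpf), channel="tissue"))
        eye_masks.append(SegmentationMask(eye, spec.spacing, time=float(t_hpf), channel="eye"))

    truth = PhantomTruth(
        times=times,
        true_volume=volumes,
        true_angle=angles.copy(),
        masks=tissue_masks,
        eye_masks=eye_masks,
        vertex_points=vertices,
        hinge_points=hinges,
    )
    return frames, truth


# ---------------------------------------------------------------------------
# labelled-nuclei stacks
# ---------------------------------------------------------------------------

def _default_nuclei_shape(spec: PhantomSpec) -> tuple[int, int, int]:
    """Cube-ish grid sized for comfortable hard-core placement (~4% fill)."""
    pitch = 2.0 * spec.nucleus_radius + spec.nucleus_gap
    side = (2.0 * spec.n_nuclei) ** (1.0 / 3.0) * pitch + 2 * spec.nucleus_radius
    sx, sy, sz = spec.spacing
    return (int(math.ceil(side / sx)) + 1, int(math.ceil(side / sy)) + 1, int(math.ceil(side / sz)) + 1)


def generate_nuclei_stack(
    spec: PhantomSpec,
    region_mask: Optional[SegmentationMask] = None,
) -> tuple[tuple[VoxelGrid, VoxelGrid], PhantomTruth]:
    """Place non-overlapping spherical nuclei; a fixed fraction is labelled.

    Exactly ``round(labelled_fraction × n_nuclei)`` nuclei (half rounds up)
    appear in the labelled channel, so the true positive percentage is exact
    by construction for every seed. Centres keep at least
    ``2·nucleus_radius + nucleus_gap`` between them (hard core), which at the
    default 2 µm gap guarantees separate 26-connected components after
    rasterization. Raises :class:`PhantomError` when the region cannot host
    ``n_nuclei`` within the retry budget.
    """
    if spec.n_nuclei < 1:
        raise PhantomError("n_nuclei must be >= 1")
    nx, ny, nz = spec.image_shape if spec.image_shape is not None else _default_nuclei_shape(spec)
    sx, sy, sz = spec.spacing
    shape_zyx = (nz, ny, nx)
    if region_mask is not None:
        if region_mask.shape != shape_zyx or region_mask.spacing != tuple(spec.spacing):
            raise PhantomError("region_mask geometry does not match the phantom image")
        region = region_mask.values
    else:
        region = np.ones(shape_zyx, dtype=bool)

    rng = np.random.default_rng(spec.seed)
    r = spec.nucleus_radius
    min_d2 = (2.0 * r + spec.nucleus_gap) ** 2
    extent = ((nx - 1) * sx, (ny - 1) * sy, (nz - 1) * sz)
    if min(extent) < 2 * r:
        raise PhantomError("image too small for even a single nucleus")

    centres: list[tuple[float, float, float]] = []
    budget = 200 * spec.n_nuclei
    attempts = 0
    while len(centres) < spec.n_nuclei:
        if attempts >= budget:
            raise PhantomError(
                f"placed only {len(centres)}/{spec.n_nuclei} nuclei within the retry budget; "
                "the region is too small for hard-core placement"
            )
        attempts += 1
        p = (
            rng.uniform(r, extent[0] - r),
            rng.uniform(r, extent[1] - r),
            rng.uniform(r, extent[2] - r),
        )
        iz, iy, ix = int(round(p[2] / sz)), int(round(p[1] / sy)), int(round(p[0] / sx))
        if not region[iz, iy, ix]:
            continue
        ok = True
        for q in centres:
            if (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 + (p[2] - q[2]) ** 2 < min_d2:
                ok = False
                break
        if ok:
            centres.append(p)

    centres_arr = np.asarray(centres)
    n_lab = round_half_up(spec.labelled_fraction * spec.n_nuclei)
    flags = np.zeros(spec.n_nuclei, dtype=bool)
    flags[rng.permutation(spec.n_nuclei)[:n_lab]] = True

    total = np.zeros(shape_zyx, dtype=bool)
    labelled = np.zeros(shape_zyx, dtype=bool)
    for (px, py, pz), lab in zip(centres_arr, flags):
        ix0, ix1 = max(0, int((px - r) / sx) - 1), min(nx, int((px + r) / sx) + 2)
        iy0, iy1 = max(0, int((py - r) / sy) - 1), min(ny, int((py + r) / sy) + 2)
        iz0, iz1 = max(0, int((pz - r) / sz) - 1), min(nz, int((pz + r) / sz) + 2)
        ddx = np.arange(ix0, ix1) * sx - px
        ddy = np.arange(iy0, iy1) * sy - py
        ddz = np.arange(iz0, iz1) * sz - pz
        ball = (
            ddz[:, None, None] ** 2 + ddy[None, :, None] ** 2 + ddx[None, None, :] ** 2
        ) <= r * r
        total[iz0:iz1, iy0:iy1, ix0:ix1] |= ball
        if lab:
            labelled[iz0:iz1, iy0:iy1, ix0:ix1] |= ball

    t0 = float(np.asarray(spec.frame_times, dtype=float)[0]) if len(spec.frame_times) else None
    total_grid = VoxelGrid(total.astype(float) * spec.amplitude, spec.spacing, time=t0, channel="nuclei_total")
    lab_grid = VoxelGrid(labelled.astype(float) * spec.amplitude, spec.spacing, time=t0, channel="nuclei_labelled")
    total_grid = add_noise_and_background(
        total_grid, spec.noise_sd, spec.background_ramp_amplitude, _frame_seed(spec.seed, 0, stream=3)
    )
    lab_grid = add_noise_and_background(
        lab_grid, spec.noise_sd, spec.background_ramp_amplitude, _frame_seed(spec.seed, 0, stream=4)
    )

    truth = PhantomTruth(
        times=np.asarray([t0] if t0 is not None else [], dtype=float),
        nuclei_centres=centres_arr,
        labelled_flags=flags,
        masks=[
            SegmentationMask(total, spec.spacing, time=t0, channel="nuclei_total"),
            SegmentationMask(labelled, spec.spacing, time=t0, channel="nuclei_labelled"),
        ],
    )
    return (total_grid, lab_grid), truth
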