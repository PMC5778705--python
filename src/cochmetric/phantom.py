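"""Synthetic cochlea phantom: ground-truth volumes, fiducials and A-values.

The phantom is a bright tube swept along a logarithmically decaying planar
spiral with constant vertical pitch — cochlea-like (2.5 turns by default)
but chosen for analytic tractability rather than anatomical fidelity:

    r(theta) = basal_radius * exp(-radius_decay * theta / 2pi)
    p(theta) = c + (r cos(theta), r sin(theta), pitch * theta / 2pi)

The round-window fiducial sits on the outer tube wall at the spiral start
(theta = 0) and the basal-turn fiducial on the outer wall diametrically
across the basal turn (theta = pi), giving the closed-form A-value

    A = sqrt((r(0) + r(pi) + 2 * tube_radius)^2 + (pitch / 2)^2).

Fiducials are placed on the continuous spiral *before* voxelisation, so
the returned ``true_a_value`` is exact regardless of grid resolution.

Deformed "clinical-like" targets emulate a coarser scanner grid, a
different intensity transfer and blur (the modality gap between micro-CT
and clinical CT), plus a known affine + smooth non-rigid deformation that
stands in for inter-specimen anatomical variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .imaging import FiducialSet, RegionOfInterest, Volume3D
from .pipeline import AtlasBundle, compute_a_value
from .transforms import AffineTransform, BSplineTransform, TransformChain

__all__ = [
    "PhantomSpec",
    "DeformationSpec",
    "generate_phantom",
    "sample_deformation",
    "make_target",
    "phantom_atlas_bundle",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and imaging parameters of the spiral-tube phantom.

    Defaults give a human-scale cochlea (A-value ~9 mm) on an atlas-like
    0.1 mm grid; the clinical-like rendering is produced by
    :func:`make_target`.
    """

    basal_radius: float = 4.5          # mm; sets the A-value scale
    turns: float = 2.5
    tube_radius: float = 0.6           # mm
    height_pitch: float = 1.6          # mm per turn
    radius_decay: float = 0.5          # log decay per turn
    grid_shape: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (0.1, 0.1, 0.1)
    noise_sd: float = 1.5              # intensity units (tube = 100)
    blur_fwhm: float = 0.2             # mm
    intensity: float = 100.0
    seed: int = 0


@dataclass(frozen=True)
class DeformationSpec:
    """Random ground-truth deformation: affine ranges + smooth FFD field."""

    domain: RegionOfInterest
    scale_range: tuple[float, float] = (0.9, 1.1)
    rotation_range_deg: float = 10.0
    translation_range_mm: float = 5.0
    nonrigid_grid: tuple[int, int, int] = (5, 5, 5)
    max_displacement_mm: float = 2.0
    smoothness: float = 1.0            # Gaussian sigma in control-point units
    seed: int = 0


def _spiral_points(spec: PhantomSpec, n: int = 6000):
    theta = np.linspace(0.0, 2 * np.pi * spec.turns, n)
    r = spec.basal_radius * np.exp(-spec.radius_decay * theta / (2 * np.pi))
    z = spec.height_pitch * theta / (2 * np.pi)
    return theta, np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def _check_no_self_intersection(spec: PhantomSpec) -> None:
    # adjacent-turn center separation must exceed the tube diameter
    theta = np.linspace(0.0, 2 * np.pi * max(spec.turns - 1, 0.0), 200)
    if theta.size == 0 or spec.turns <= 1:
        return
    r = spec.basal_radius * np.exp(-spec.radius_decay * theta / (2 * np.pi))
    radial_gap = r * (1.0 - np.exp(-spec.radius_decay))
    sep = np.sqrt(radial_gap**2 + spec.height_pitch**2)
    if np.min(sep) < 2 * spec.tube_radius:
        raise ValueError(
            "spiral tube self-intersects: decrease tube_radius or increase "
            "pitch/decay"
        )


def analytic_a_value(spec: PhantomSpec) -> float:
    """Closed-form A-value of the phantom's outer-wall fiducial pair."""
    r0 = spec.basal_radius
    r_pi = spec.basal_radius * np.exp(-spec.radius_decay * 0.5)
    return float(
        np.hypot(r0 + r_pi + 2 * spec.tube_radius, spec.height_pitch / 2.0)
    )


def _analytic_fiducials(spec: PhantomSpec, center: np.ndarray) -> FiducialSet:
    a = spec.tube_radius
    r0 = spec.basal_radius
    r_pi = spec.basal_radius * np.exp(-spec.radius_decay * 0.5)
    pitch = spec.height_pitch
    theta_ow = 0.6
    r_ow = spec.basal_radius * np.exp(-spec.radius_decay * theta_ow / (2 * np.pi))
    theta_end = 2 * np.pi * spec.turns
    r_end = spec.basal_radius * np.exp(-spec.radius_decay * spec.turns)
    points = {
        "round_window": center + np.array([r0 + a, 0.0, 0.0]),
        "basal_turn": center + np.array([-(r_pi + a), 0.0, pitch / 2.0]),
        "apex": center
        + np.array(
            [r_end * np.cos(theta_end), r_end * np.sin(theta_end),
             pitch * spec.turns]
        ),
        "modiolus": center + np.array([0.0, 0.0, pitch * spec.turns / 2.0]),
        "oval_window": center
        + np.array(
            [(r_ow + a) * np.cos(theta_ow), (r_ow + a) * np.sin(theta_ow),
             pitch * theta_ow / (2 * np.pi) + 1.0]
        ),
    }
    return FiducialSet(points, laterality="right")


def generate_phantom(spec: PhantomSpec):
    """Voxelise the spiral-tube phantom.

    Returns ``(volume, fiducials, true_a_value)``.  The volume is a bright
    tube (intensity ``spec.intensity``) on a zero background, Gaussian
    blurred to ``blur_fwhm`` and corrupted with additive Gaussian noise;
    identical spec + seed reproduce it bitwise.
    """
    _check_no_self_intersection(spec)
    shape = np.array(spec.grid_shape, dtype=int)
    spacing = np.array(spec.spacing, dtype=float)
    extent = spacing * (shape - 1)

    _, curve_rel = _spiral_points(spec)
    lo = curve_rel.min(axis=0) - spec.tube_radius
    hi = curve_rel.max(axis=0) + spec.tube_radius
    if np.any(hi - lo > extent):
        raise ValueError(
            f"phantom tube (extent {hi - lo} mm) exceeds grid extent {extent} mm"
        )
    # place the spiral's bounding box at the grid center (origin stays at 0)
    grid_center = extent / 2.0
    center = grid_center - 0.5 * (lo + hi)
    curve = curve_rel + center

    vol = Volume3D(np.zeros(tuple(shape)), spacing, np.zeros(3))
    centers = vol.voxel_centers()
    tree = cKDTree(curve)
    dist, _ = tree.query(centers, k=1)
    tube = (dist <= spec.tube_radius).astype(np.float64).reshape(tuple(shape))
    voxels = spec.intensity * tube
    if spec.blur_fwhm > 0:
        sigma = spec.blur_fwhm / 2.3548200450309493 / spacing
        voxels = gaussian_filter(voxels, sigma=sigma)
    if spec.noise_sd > 0:
        rng = np.random.Generator(np.random.Philox(spec.seed))
        voxels = voxels + rng.normal(0.0, spec.noise_sd, size=voxels.shape)
    volume = Volume3D(voxels, spacing, np.zeros(3))
    fiducials = _analytic_fiducials(spec, center)
    true_a = compute_a_value(fiducials)
    assert abs(true_a - analytic_a_value(spec)) < 1e-9
    return volume, fiducials, true_a


def phantom_atlas_bundle(spec: PhantomSpec, laterality: str = "right"):
    """Package the phantom as an :class:`AtlasBundle` (plus its true A-value)."""
    volume, fiducials, true_a = generate_phantom(spec)
    bundle = AtlasBundle(
        volume=volume,
        aval_fiducials=fiducials.subset(["round_window", "basal_turn"]),
        init_landmarks=fiducials.subset(
            ["apex", "modiolus", "round_window", "oval_window"]
        ),
        laterality="right",
    )
    if laterality == "left":
        bundle = bundle.mirrored()
    return bundle, true_a


def sample_deformation(spec: DeformationSpec) -> TransformChain:
    """Draw a random ground-truth deformation: affine (about the domain
    center) composed with a smooth, capped B-spline displacement field.

    The non-rigid part is bounded: |T(p) - p - affine part| never exceeds
    ``max_displacement_mm`` (cubic B-spline weights are a partition of
    unity, so the field magnitude is bounded by the largest control
    displacement).  Deterministic per seed.
    """
    rng = np.random.Generator(np.random.Philox(spec.seed))
    lo, hi = spec.scale_range
    scales = rng.uniform(lo, hi, size=3)
    rot_rad = np.deg2rad(spec.rotation_range_deg)
    angles = rng.uniform(-rot_rad, rot_rad, size=3)
    trans = rng.uniform(-spec.translation_range_mm, spec.translation_range_mm, size=3)

    from scipy.spatial.transform import Rotation

    matrix = Rotation.from_euler("zyx", angles[::-1]).as_matrix() @ np.diag(scales)
    c = spec.domain.center
    affine = AffineTransform(matrix, trans + c - matrix @ c)

    grid = BSplineTransform.for_roi(spec.domain, spec.nonrigid_grid)
    disp = rng.standard_normal(grid.grid_shape + (3,))
    if spec.smoothness > 0:
        for comp in range(3):
            disp[..., comp] = gaussian_filter(disp[..., comp], spec.smoothness)
    mag = np.max(np.abs(disp))
    if spec.max_displacement_mm > 0 and mag > 0:
        disp = disp * (spec.max_displacement_mm / np.max(
            np.linalg.norm(disp, axis=-1)))
    else:
        disp = np.zeros_like(disp)
    cap = 0.4 * grid.grid_spacing  # invertibility cap, as in registration
    disp = np.clip(disp, -cap, cap)
    grid.displacements = disp
    return TransformChain([affine, grid])


def make_target(
    phantom: Volume3D,
    fiducials: FiducialSet,
    chain: TransformChain,
    target_spacing=(0.6, 0.6, 0.6),
    target_shape=(64, 64, 64),
    extra_blur_fwhm: float = 0.8,
    intensity_scale: float = 0.85,
    intensity_offset: float = 12.0,
    noise_sd: float = 1.5,
    seed: int = 0,
):
    """Render the phantom through ``chain`` onto a clinical-like grid.

    The target grid (default 64^3 at 0.6 mm) is centered on the mapped
    phantom; intensities pass through an affine transfer + extra blur to
    emulate the modality gap (NCC is invariant to the affine part).
    Returns ``(target_volume, mapped_fiducials, true_a_value)`` where the
    fiducials are the chain-mapped originals and the A-value is recomputed
    from them.
    """
    spacing = np.asarray(target_spacing, dtype=float)
    shape = np.asarray(target_shape, dtype=int)
    ext = phantom.extent_roi()
    corners = np.array(
        [[ext.lower[0] if i == 0 else ext.upper[0],
          ext.lower[1] if j == 0 else ext.upper[1],
          ext.lower[2] if k == 0 else ext.upper[2]]
         for i in (0, 1) for j in (0, 1) for k in (0, 1)]
    )
    mapped_center = chain.apply_points(corners).mean(axis=0)
    origin = mapped_center - spacing * (shape - 1) / 2.0

    target = Volume3D(np.zeros(tuple(shape)), spacing, origin)
    ycenters = target.voxel_centers()
    # 1e-3 mm inversion tolerance: negligible against the clinical voxel size
    x = chain.invert_points(ycenters, tol=1e-3, max_iter=60)
    values, _ = phantom.sample(x, order=1)
    voxels = values.reshape(tuple(shape))
    if extra_blur_fwhm > 0:
        voxels = gaussian_filter(voxels, sigma=extra_blur_fwhm / 2.3548200450309493 / spacing)
    voxels = intensity_scale * voxels + intensity_offset
    if noise_sd > 0:
        rng = np.random.Generator(np.random.Philox(seed))
        voxels = voxels + rng.normal(0.0, noise_sd, size=voxels.shape)
    target = Volume3D(voxels, spacing, origin)

    mapped = fiducials.transformed(chain.apply_points)
    extent = target.extent_roi()
    if not np.all(extent.contains(mapped.as_array())):
        raise ValueError("a mapped fiducial falls outside the target grid")
    true_a = compute_a_value(mapped) if (
        "round_window" in mapped and "basal_turn" in mapped
    ) else None
    return target, mapped, true_a
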