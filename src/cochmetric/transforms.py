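"""Spatial transforms: rigid/affine maps, cubic B-spline free-form deformation,
and their composition into the registration chain.

Conventions
-----------
All transforms map *atlas* world coordinates (LPS mm) to *target* world
coordinates.  A chain applies its stages in estimation order
(rigid -> affine -> B-spline).

The affine transform is parameterised, when estimated, as
translation (3) + Euler rotation (3, radians, applied z·y·x) +
log-scale (3) + shear (3, unit upper-triangular), composed as
``M = R @ diag(exp(s)) @ Sh``; this keeps the matrix away from reflections
during optimisation.  12 free parameters in 3D; the rigid specialisation
fixes scale and shear (6 free parameters).

The free-form deformation follows the classic control-grid construction:
a displacement vector per control point, interpolated by the cubic
B-spline tensor-product basis.  Control points act as spline
*coefficients*, not interpolated values.  Outside the grid the
displacement decays smoothly to zero (zero coefficient extension), so the
transform tends to the identity away from the region of interest; the
``strict`` evaluation mode raises instead for points beyond full cubic
support, which is what fiducial propagation uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .errors import OutOfDomainError
from .imaging import RegionOfInterest, Volume3D

__all__ = [
    "AffineTransform",
    "BSplineTransform",
    "TransformChain",
    "apply_to_point",
    "dof",
    "export_displacement_field",
]


def _euler_matrix(angles: np.ndarray) -> np.ndarray:
    return Rotation.from_euler("zyx", angles[::-1]).as_matrix()


def _shear_matrix(shear: np.ndarray) -> np.ndarray:
    sh = np.eye(3)
    sh[0, 1], sh[0, 2], sh[1, 2] = shear
    return sh


@dataclass
class AffineTransform:
    """x -> matrix @ x + translation.

    ``rigid=True`` marks the 6-DOF specialisation (matrix is a pure
    rotation); plain affine carries 12 degrees of freedom.
    """

    matrix: np.ndarray
    translation: np.ndarray
    rigid: bool = False
    #: RMS landmark residual in mm when produced by a landmark fit
    residual_rms: float | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.matrix)) <= 1e-12:
            raise ValueError("affine matrix is singular")
        if self.rigid and not np.allclose(
            self.matrix.T @ self.matrix, np.eye(3), atol=1e-8
        ):
            raise ValueError("rigid transform requires an orthonormal matrix")

    @classmethod
    def identity(cls, rigid: bool = False) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3), rigid=rigid)

    @classmethod
    def from_params(cls, params: np.ndarray, center: np.ndarray | None = None
                    ) -> "AffineTransform":
        """Build from the 12-vector [t(3), euler(3), log-scale(3), shear(3)].

        ``center`` is the fixed point about which rotation/scale/shear act
        (defaults to the origin).
        """
        p = np.asarray(params, dtype=float).reshape(12)
        m = _euler_matrix(p[3:6]) @ np.diag(np.exp(p[6:9])) @ _shear_matrix(p[9:12])
        t = p[:3].copy()
        if center is not None:
            c = np.asarray(center, dtype=float)
            t = t + c - m @ c
        return cls(m, t)

    @property
    def n_dof(self) -> int:
        return 6 if self.rigid else 12

    def apply_points(self, points: np.ndarray, strict: bool = False) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return (pts.reshape(-1, 3) @ self.matrix.T + self.translation).reshape(pts.shape)

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.translation, rigid=self.rigid)

    def invert_points(self, points: np.ndarray, **kwargs) -> np.ndarray:
        return self.inverse().apply_points(points)

    def to_dict(self) -> dict:
        return {
            "type": "rigid" if self.rigid else "affine",
            "matrix": self.matrix.tolist(),
            "translation": self.translation.tolist(),
        }


def cubic_bspline_kernel(t: np.ndarray) -> np.ndarray:
    """The centered cubic B-spline basis B3(t), support |t| < 2."""
    t = np.abs(np.asarray(t, dtype=float))
    out = np.zeros_like(t)
    near = t < 1
    mid = (t >= 1) & (t < 2)
    out[near] = (4.0 - 6.0 * t[near] ** 2 + 3.0 * t[near] ** 3) / 6.0
    out[mid] = (2.0 - t[mid]) ** 3 / 6.0
    return out


@dataclass
class BSplineTransform:
    """Cubic B-spline free-form deformation x -> x + u(x).

    ``displacements`` has shape ``(*grid_shape, 3)``: one displacement
    vector (mm) per control point.  Control point (i, j, k) sits at
    ``grid_origin + (i, j, k) * grid_spacing``.  Full cubic support (the
    region where all contributing basis functions have in-grid
    coefficients) is the index range [1, n - 2] per axis; for the default
    4x4x4 grid that is the central cell, which is sized to cover the
    registration ROI.
    """

    grid_shape: tuple[int, int, int]
    grid_origin: np.ndarray
    grid_spacing: np.ndarray
    displacements: np.ndarray | None = None

    def __post_init__(self):
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if any(n < 4 for n in self.grid_shape):
            raise ValueError("cubic FFD needs at least 4 control points per axis")
        self.grid_origin = np.asarray(self.grid_origin, dtype=float).reshape(3)
        self.grid_spacing = np.asarray(self.grid_spacing, dtype=float).reshape(3)
        if not np.all(self.grid_spacing > 0):
            raise ValueError("grid spacing must be positive")
        if self.displacements is None:
            self.displacements = np.zeros(self.grid_shape + (3,))
        self.displacements = np.asarray(self.displacements, dtype=float).reshape(
            self.grid_shape + (3,)
        )

    @classmethod
    def for_roi(cls, roi: RegionOfInterest, grid_shape=(4, 4, 4)) -> "BSplineTransform":
        """Grid whose full-support region covers ``roi``.

        The ROI is divided into ``grid_shape - 3`` cells per axis and the
        control lattice extends one cell beyond each side.
        """
        shape = tuple(int(n) for n in grid_shape)
        cells = np.array([n - 3 for n in shape], dtype=float)
        if np.any(cells < 1):
            raise ValueError("grid_shape must be >= 4 per axis")
        spacing = roi.extent / cells
        origin = roi.lower - spacing
        return cls(shape, origin, spacing)

    @property
    def n_control_points(self) -> int:
        return int(np.prod(self.grid_shape))

    @property
    def n_parameters(self) -> int:
        return 3 * self.n_control_points

    @property
    def support_roi(self) -> RegionOfInterest:
        """World box with full cubic support (index in [1, n-2] per axis)."""
        n = np.array(self.grid_shape, dtype=float)
        return RegionOfInterest(
            self.grid_origin + self.grid_spacing,
            self.grid_origin + self.grid_spacing * (n - 2),
        )

    def _continuous_index(self, points: np.ndarray) -> np.ndarray:
        return (points - self.grid_origin) / self.grid_spacing

    def displacement(self, points: np.ndarray, strict: bool = False) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = self._continuous_index(pts)
        if strict:
            n = np.array(self.grid_shape, dtype=float)
            bad = np.any((idx < 1.0 - 1e-9) | (idx > n - 2 + 1e-9), axis=1)
            if np.any(bad):
                raise OutOfDomainError(
                    f"{int(bad.sum())} point(s) outside the B-spline grid's "
                    "full-support region"
                )
        # order-3 map_coordinates with prefilter=False evaluates the cubic
        # B-spline expansion with the array entries as coefficients.  The
        # coefficient array is zero-padded by the kernel support (2) so the
        # zero-extension convention holds exactly — scipy's own 'constant'
        # mode would clip values discontinuously at the grid edge instead.
        padded = np.pad(self.displacements, ((2, 2), (2, 2), (2, 2), (0, 0)))
        coords = (idx + 2.0).T
        u = np.stack(
            [
                ndimage.map_coordinates(
                    padded[..., c], coords, order=3,
                    prefilter=False, mode="constant", cval=0.0,
                )
                for c in range(3)
            ],
            axis=1,
        )
        return u

    def apply_points(self, points: np.ndarray, strict: bool = False) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        flat = np.atleast_2d(pts)
        out = flat + self.displacement(flat, strict=strict)
        return out.reshape(pts.shape)

    def invert_points(self, points: np.ndarray, tol: float = 1e-9,
                      max_iter: int = 200, damping: float = 0.5) -> np.ndarray:
        """Solve x + u(x) = y by damped fixed-point iteration.

        Damping keeps the iteration contractive even where the field's
        Jacobian norm approaches 1 (displacements near the invertibility
        cap); converged points drop out of the active set.
        """
        y = np.atleast_2d(np.asarray(points, dtype=float))
        x = y - self.displacement(y)
        active = np.arange(x.shape[0])
        for _ in range(max_iter):
            resid = y[active] - x[active] - self.displacement(x[active])
            x[active] += damping * resid
            still = np.max(np.abs(resid), axis=1) >= tol / damping
            active = active[still]
            if active.size == 0:
                break
        return x.reshape(np.asarray(points, dtype=float).shape)

    def to_dict(self) -> dict:
        return {
            "type": "bspline",
            "grid_shape": list(self.grid_shape),
            "grid_origin": self.grid_origin.tolist(),
            "grid_spacing": self.grid_spacing.tolist(),
            "displacements": self.displacements.tolist(),
        }


@dataclass
class TransformChain:
    """Ordered composition; stages applied first-to-last (rigid, affine, FFD)."""

    transforms: list = field(default_factory=list)

    def apply_points(self, points: np.ndarray, strict: bool = False) -> np.ndarray:
        out = np.asarray(points, dtype=float)
        for t in self.transforms:
            out = t.apply_points(out, strict=strict)
        return out

    def invert_points(self, points: np.ndarray, **kwargs) -> np.ndarray:
        out = np.asarray(points, dtype=float)
        for t in reversed(self.transforms):
            out = t.invert_points(out, **kwargs)
        return out

    def extended(self, transform) -> "TransformChain":
        return TransformChain(list(self.transforms) + [transform])

    def __len__(self) -> int:
        return len(self.transforms)

    def __iter__(self):
        return iter(self.transforms)

    def to_dict(self) -> dict:
        return {"type": "chain", "stages": [t.to_dict() for t in self.transforms]}


def transform_from_dict(d: dict):
    """Inverse of the ``to_dict`` serialisations."""
    kind = d["type"]
    if kind in ("affine", "rigid"):
        return AffineTransform(
            np.array(d["matrix"]), np.array(d["translation"]), rigid=kind == "rigid"
        )
    if kind == "bspline":
        return BSplineTransform(
            tuple(d["grid_shape"]),
            np.array(d["grid_origin"]),
            np.array(d["grid_spacing"]),
            np.array(d["displacements"]),
        )
    if kind == "chain":
        return TransformChain([transform_from_dict(s) for s in d["stages"]])
    raise ValueError(f"unknown transform type {kind!r}")


def apply_to_point(transform, point: np.ndarray, strict: bool = False) -> np.ndarray:
    """Map a single world point (or array of points) through any transform."""
    return transform.apply_points(np.asarray(point, dtype=float), strict=strict)


def dof(transform) -> int:
    """Degrees of freedom, using the control-point counting convention for
    the FFD (a 4x4x4 grid counts 64; its scalar parameter count, 3x that,
    is available as ``BSplineTransform.n_parameters``)."""
    if isinstance(transform, AffineTransform):
        return transform.n_dof
    if isinstance(transform, BSplineTransform):
        return transform.n_control_points
    if isinstance(transform, TransformChain):
        return sum(dof(t) for t in transform)
    raise TypeError(f"unsupported transform {type(transform).__name__}")


def export_displacement_field(transform, roi: RegionOfInterest, grid_step: float):
    """Sample T(p) - p on a regular grid over ``roi``.

    Returns a ``Volume3D``-geometry tuple ``(origin, step, field)`` with
    ``field`` of shape (nx, ny, nz, 3) in mm, suitable for writing as a
    3-component volume (see :func:`write_displacement_field`).
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    axes = [np.arange(roi.lower[a], roi.upper[a] + 1e-9, grid_step) for a in range(3)]
    grids = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1)
    disp = transform.apply_points(pts) - pts
    field = disp.reshape(grids[0].shape + (3,))
    origin = np.array([axes[0][0], axes[1][0], axes[2][0]])
    return origin, float(grid_step), field


def write_displacement_field(origin, step, field, path: str) -> None:
    """Write a sampled displacement field as a 3-component NRRD/MetaImage."""
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(
        np.ascontiguousarray(field.transpose(2, 1, 0, 3)), isVector=True
    )
    img.SetSpacing((step, step, step))
    img.SetOrigin(tuple(np.asarray(origin, dtype=float)))
    sitk.WriteImage(img, str(path))
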