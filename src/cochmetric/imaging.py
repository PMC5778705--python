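"""3D volumes, world-coordinate geometry, fiducial points and their file formats.

Everything downstream (registration, fiducial propagation, the phantom
generator) works in a single world frame: LPS millimetres, 0-based voxel
indices, voxel-*center* convention.  The world coordinate of voxel index
``v`` is ``origin + direction @ (spacing * v)``.  All supported on-disk
formats (NIfTI, NRRD, MetaImage) are converted to this frame on read via
SimpleITK, whose native frame is already LPS.

Fiducial files come in two dialects: a plain CSV ``label,x,y,z`` in LPS mm,
and the 3D Slicer FCSV markup format, which stores RAS coordinates unless
its header says otherwise (RAS -> LPS: negate x and y).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .errors import (
    DimensionalityError,
    EmptyRegionError,
    FiducialParseError,
    MissingLabelError,
    VolumeFormatError,
)

__all__ = [
    "Volume3D",
    "FiducialSet",
    "RegionOfInterest",
    "read_volume",
    "write_volume",
    "crop_to_roi",
    "mirror_volume",
    "mirror_points",
    "read_fiducials",
    "write_fiducials",
]

#: labels with fixed anatomical meaning
AVAL_LABELS = ("round_window", "basal_turn")
INIT_LANDMARK_LABELS = ("apex", "modiolus", "round_window", "oval_window")

_VOLUME_EXTENSIONS = (".nii", ".nii.gz", ".nrrd", ".nhdr", ".mha", ".mhd")


@dataclass(frozen=True)
class RegionOfInterest:
    """Axis-aligned box in world millimetres."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "lower", np.asarray(self.lower, dtype=float))
        object.__setattr__(self, "upper", np.asarray(self.upper, dtype=float))
        if self.lower.shape != (3,) or self.upper.shape != (3,):
            raise ValueError("ROI bounds must be 3-vectors")
        if not np.all(self.lower < self.upper):
            raise ValueError("ROI lower bound must be strictly below upper bound")

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.lower + self.upper)

    @property
    def extent(self) -> np.ndarray:
        return self.upper - self.lower

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.all((pts >= self.lower) & (pts <= self.upper), axis=1)

    def padded(self, margin: float) -> "RegionOfInterest":
        return RegionOfInterest(self.lower - margin, self.upper + margin)

    @staticmethod
    def around_points(points: np.ndarray, margin: float) -> "RegionOfInterest":
        """Bounding box of ``points`` grown by ``margin`` mm on every side."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return RegionOfInterest(pts.min(axis=0) - margin, pts.max(axis=0) + margin)


@dataclass
class Volume3D:
    """A scalar voxel grid with world geometry.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Intensities, stored as float64 regardless of the on-disk type.
    spacing : 3-vector, mm per voxel, strictly positive.
    origin : 3-vector, mm; world coordinate of voxel (0, 0, 0).
    direction : 3x3 orthonormal direction-cosine matrix.
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D scalar array, got ndim={self.voxels.ndim}"
            )
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if not np.all(self.spacing > 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if abs(abs(np.linalg.det(self.direction)) - 1.0) > 1e-6 or not np.allclose(
            self.direction.T @ self.direction, np.eye(3), atol=1e-6
        ):
            raise ValueError("direction matrix must be orthonormal")

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def index_to_world(self, index) -> np.ndarray:
        """World mm coordinates of (possibly fractional) voxel indices."""
        idx = np.asarray(index, dtype=float)
        return (self.direction @ (self.spacing * idx).reshape(-1, 3).T).T.reshape(
            idx.shape
        ) + self.origin

    def world_to_index(self, world) -> np.ndarray:
        """Continuous voxel indices of world mm coordinates."""
        pts = np.asarray(world, dtype=float)
        rel = (self.direction.T @ (pts.reshape(-1, 3) - self.origin).T).T
        return (rel / self.spacing).reshape(pts.shape)

    @property
    def world_center(self) -> np.ndarray:
        """World coordinate of the grid's geometric center."""
        return self.index_to_world((np.array(self.shape, dtype=float) - 1) / 2)

    def extent_roi(self) -> RegionOfInterest:
        """Axis-aligned world bounding box of all voxel centers."""
        n = np.array(self.shape, dtype=float) - 1
        corners = np.array(
            [[i * n[0], j * n[1], k * n[2]] for i in (0, 1) for j in (0, 1) for k in (0, 1)]
        )
        world = self.index_to_world(corners)
        return RegionOfInterest(world.min(axis=0), world.max(axis=0))

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel center, shape (n_voxels, 3)."""
        grids = np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij")
        idx = np.stack([g.ravel() for g in grids], axis=1).astype(float)
        return self.index_to_world(idx)

    # -- interpolation ----------------------------------------------------

    def sample(self, points: np.ndarray, order: int = 1):
        """Interpolate intensities at world points.

        Returns ``(values, inside)`` where ``inside`` flags points whose
        continuous index lies within the grid; outside values are 0.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = self.world_to_index(pts)
        n = np.array(self.shape, dtype=float)
        inside = np.all((idx >= 0.0) & (idx <= n - 1), axis=1)
        values = ndimage.map_coordinates(
            self.voxels, idx.T, order=order, mode="constant", cval=0.0
        )
        return values, inside

    def gradient_volumes(self) -> list["Volume3D"]:
        """Per-axis intensity gradient volumes in world units (intensity/mm).

        Only valid for signed-permutation direction matrices (sufficient for
        all CT-style axis-aligned data this package handles).
        """
        perm, sign = _signed_permutation(self.direction)
        index_grads = np.gradient(self.voxels, *self.spacing)
        out: list[Volume3D | None] = [None, None, None]
        for j in range(3):  # index axis j -> world axis perm[j]
            g = index_grads[j] * sign[j]
            out[perm[j]] = Volume3D(g, self.spacing, self.origin, self.direction)
        return out  # type: ignore[return-value]


def _signed_permutation(direction: np.ndarray):
    """Decompose a direction matrix into (perm, sign) if axis-aligned.

    ``direction[:, j]`` must be ±e_{perm[j]}; raises otherwise.
    """
    perm = np.empty(3, dtype=int)
    sign = np.empty(3)
    for j in range(3):
        col = direction[:, j]
        i = int(np.argmax(np.abs(col)))
        if abs(abs(col[i]) - 1.0) > 1e-9 or np.sum(np.abs(col) > 1e-9) != 1:
            raise ValueError(
                "operation requires an axis-aligned (signed-permutation) "
                "direction matrix"
            )
        perm[j] = i
        sign[j] = np.sign(col[i])
    return perm, sign


# -- volume I/O -----------------------------------------------------------


def _check_extension(path: str) -> None:
    lower = path.lower()
    if not any(lower.endswith(ext) for ext in _VOLUME_EXTENSIONS):
        raise VolumeFormatError(
            f"unsupported volume format for '{path}'; "
            f"expected one of {', '.join(_VOLUME_EXTENSIONS)}"
        )


def read_volume(path: str) -> Volume3D:
    """Read a NIfTI / NRRD / MetaImage volume into the internal LPS frame."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    _check_extension(str(path))
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - SimpleITK error text varies
        raise VolumeFormatError(f"could not read '{path}': {exc}") from exc
    if img.GetDimension() != 3:
        raise DimensionalityError(
            f"'{path}' is {img.GetDimension()}-dimensional; expected 3"
        )
    if img.GetNumberOfComponentsPerPixel() != 1:
        raise DimensionalityError(f"'{path}' is not a scalar volume")
    # SimpleITK arrays are indexed (z, y, x); transpose to (x, y, z).
    voxels = sitk.GetArrayFromImage(img).astype(np.float64).transpose(2, 1, 0)
    return Volume3D(
        voxels=voxels,
        spacing=np.array(img.GetSpacing()),
        origin=np.array(img.GetOrigin()),
        direction=np.array(img.GetDirection()).reshape(3, 3),
    )


def write_volume(volume: Volume3D, path: str) -> None:
    """Write a volume; format chosen by extension (.nii/.nii.gz/.nrrd/.mha/.mhd)."""
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise IOError(f"parent directory does not exist: {parent}")
    _check_extension(str(path))
    img = sitk.GetImageFromArray(volume.voxels.transpose(2, 1, 0))
    img.SetSpacing(tuple(volume.spacing))
    img.SetOrigin(tuple(volume.origin))
    img.SetDirection(tuple(volume.direction.ravel()))
    sitk.WriteImage(img, str(path))


# -- cropping and mirroring ----------------------------------------------


def crop_to_roi(volume: Volume3D, roi: RegionOfInterest) -> Volume3D:
    """Keep exactly the voxels whose centers fall inside ``roi``.

    World coordinates of retained voxels are unchanged: the origin shifts,
    spacing and direction are preserved.
    """
    perm, sign = _signed_permutation(volume.direction)
    slices = []
    for j in range(3):
        w = perm[j]
        coords = volume.origin[w] + sign[j] * volume.spacing[j] * np.arange(
            volume.shape[j]
        )
        keep = np.nonzero((coords >= roi.lower[w]) & (coords <= roi.upper[w]))[0]
        if keep.size == 0:
            raise EmptyRegionError(
                f"ROI does not contain any voxel centers along index axis {j}"
            )
        slices.append(slice(int(keep[0]), int(keep[-1]) + 1))
    start = np.array([s.start for s in slices], dtype=float)
    new_origin = volume.index_to_world(start)
    return Volume3D(
        voxels=volume.voxels[tuple(slices)].copy(),
        spacing=volume.spacing.copy(),
        origin=new_origin,
        direction=volume.direction.copy(),
    )


def mirror_volume(volume: Volume3D, plane_axis: int) -> Volume3D:
    """Reflect about the plane through the volume's world center.

    The plane normal is the world direction of index axis ``plane_axis``.
    Flipping the voxel array along that axis while keeping the geometry is
    exactly this reflection, so the mirrored volume occupies the same world
    extent as the original (an isometry and an involution).
    """
    if plane_axis not in (0, 1, 2):
        raise ValueError(f"plane_axis must be 0, 1 or 2, got {plane_axis}")
    return Volume3D(
        voxels=np.flip(volume.voxels, axis=plane_axis).copy(),
        spacing=volume.spacing.copy(),
        origin=volume.origin.copy(),
        direction=volume.direction.copy(),
    )


def mirror_points(points: np.ndarray, volume: Volume3D, plane_axis: int) -> np.ndarray:
    """Reflect world points about the same center plane as :func:`mirror_volume`."""
    if plane_axis not in (0, 1, 2):
        raise ValueError(f"plane_axis must be 0, 1 or 2, got {plane_axis}")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    normal = volume.direction[:, plane_axis]
    center = volume.world_center
    d = (pts - center) @ normal
    out = pts - 2.0 * d[:, None] * normal[None, :]
    return out.reshape(np.asarray(points, dtype=float).shape)


# -- fiducials ------------------------------------------------------------


@dataclass
class FiducialSet:
    """Named 3D points in world (LPS) millimetres."""

    points: dict[str, np.ndarray]
    laterality: str | None = None

    def __post_init__(self):
        clean = {}
        for label, p in self.points.items():
            p = np.asarray(p, dtype=float).reshape(3)
            if label in clean:
                raise FiducialParseError(f"duplicate fiducial label '{label}'")
            clean[label] = p
        self.points = clean
        if self.laterality is not None and self.laterality not in ("left", "right"):
            raise ValueError(f"laterality must be 'left' or 'right', got {self.laterality!r}")

    def __contains__(self, label: str) -> bool:
        return label in self.points

    def __len__(self) -> int:
        return len(self.points)

    def __getitem__(self, label: str) -> np.ndarray:
        return self.require(label)

    @property
    def labels(self) -> list[str]:
        return list(self.points)

    def require(self, label: str) -> np.ndarray:
        if label not in self.points:
            raise MissingLabelError(
                f"fiducial '{label}' missing; available: {sorted(self.points)}"
            )
        return self.points[label]

    def subset(self, labels) -> "FiducialSet":
        return FiducialSet({l: self.require(l) for l in labels}, self.laterality)

    def as_array(self, labels=None) -> np.ndarray:
        labels = list(labels) if labels is not None else self.labels
        return np.array([self.require(l) for l in labels])

    def transformed(self, func) -> "FiducialSet":
        """Apply ``func`` (array of points -> array of points) to every point."""
        labels = self.labels
        moved = np.atleast_2d(func(self.as_array(labels)))
        return FiducialSet(dict(zip(labels, moved)), self.laterality)

    def mirrored(self, volume: Volume3D, plane_axis: int) -> "FiducialSet":
        flipped = self.transformed(lambda p: mirror_points(p, volume, plane_axis))
        if self.laterality is not None:
            flipped = replace(
                flipped, laterality="left" if self.laterality == "right" else "right"
            )
        return flipped


def _parse_float3(fields, line_no):
    try:
        return np.array([float(fields[0]), float(fields[1]), float(fields[2])])
    except (ValueError, IndexError) as exc:
        raise FiducialParseError(f"could not parse coordinates: {exc}", line_no)


def read_fiducials(path: str, laterality: str | None = None) -> FiducialSet:
    """Read a fiducial file (plain CSV ``label,x,y,z`` or Slicer FCSV).

    FCSV is detected by its ``# Markups fiducial`` header; FCSV coordinates
    are RAS by default and converted to LPS (negate x, y) unless a
    ``# CoordinateSystem = LPS`` header line says they already are LPS.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    is_fcsv = any(l.lstrip().startswith("#") and "Markups fiducial" in l for l in lines[:3])
    if is_fcsv:
        return _read_fcsv(lines, laterality)
    return _read_csv(lines, laterality)


def _read_csv(lines, laterality):
    points: dict[str, np.ndarray] = {}
    file_laterality = laterality
    header: list[str] | None = None
    for line_no, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = [f.strip() for f in line.split(",")]
        if header is None:
            if [f.lower() for f in fields[:4]] != ["label", "x", "y", "z"]:
                raise FiducialParseError(
                    "expected header 'label,x,y,z'", line_no
                )
            header = [f.lower() for f in fields]
            continue
        if len(fields) < 4:
            raise FiducialParseError("expected at least 4 comma-separated fields", line_no)
        label = fields[0]
        if label in points:
            raise FiducialParseError(f"duplicate fiducial label '{label}'", line_no)
        points[label] = _parse_float3(fields[1:4], line_no)
        if "laterality" in header and len(fields) > header.index("laterality"):
            value = fields[header.index("laterality")].lower()
            if value:
                if value not in ("left", "right"):
                    raise FiducialParseError(f"bad laterality {value!r}", line_no)
                file_laterality = value
    if header is None:
        raise FiducialParseError("empty fiducial file", None)
    return FiducialSet(points, file_laterality)


def _read_fcsv(lines, laterality):
    coordinate_system = "RAS"
    points: dict[str, np.ndarray] = {}
    for line_no, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("coordinatesystem"):
                coordinate_system = body.split("=")[-1].strip().upper()
                # Slicer also writes numeric codes: 0 = RAS, 1 = LPS
                coordinate_system = {"0": "RAS", "1": "LPS"}.get(
                    coordinate_system, coordinate_system
                )
            continue
        fields = [f.strip() for f in line.split(",")]
        # id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID
        if len(fields) < 12:
            raise FiducialParseError("FCSV row has fewer than 12 fields", line_no)
        label = fields[11] or fields[0]
        if label in points:
            raise FiducialParseError(f"duplicate fiducial label '{label}'", line_no)
        p = _parse_float3(fields[1:4], line_no)
        if coordinate_system == "RAS":
            p = np.array([-p[0], -p[1], p[2]])
        elif coordinate_system != "LPS":
            raise FiducialParseError(
                f"unknown FCSV coordinate system {coordinate_system!r}", line_no
            )
        points[label] = p
    return FiducialSet(points, laterality)


def write_fiducials(fiducials: FiducialSet, path: str, fmt: str | None = None) -> None:
    """Write fiducials as plain CSV (LPS) or Slicer FCSV (RAS).

    ``fmt`` is 'csv' or 'fcsv'; inferred from the extension when omitted.
    """
    if fmt is None:
        fmt = "fcsv" if str(path).lower().endswith(".fcsv") else "csv"
    with open(path, "w", encoding="utf-8") as fh:
        if fmt == "csv":
            has_lat = fiducials.laterality is not None
            fh.write("label,x,y,z" + (",laterality" if has_lat else "") + "\n")
            for label, p in fiducials.points.items():
                row = f"{label},{p[0]:.9g},{p[1]:.9g},{p[2]:.9g}"
                if has_lat:
                    row += f",{fiducials.laterality}"
                fh.write(row + "\n")
        elif fmt == "fcsv":
            fh.write("# Markups fiducial file version = 4.11\n")
            fh.write("# CoordinateSystem = RAS\n")
            fh.write("# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID\n")
            for i, (label, p) in enumerate(fiducials.points.items(), start=1):
                ras = (-p[0], -p[1], p[2])
                fh.write(
                    f"F{i},{ras[0]:.9g},{ras[1]:.9g},{ras[2]:.9g},"
                    f"0,0,0,1,1,1,0,{label},,\n"
                )
        else:
            raise ValueError(f"unknown fiducial format {fmt!r}")
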