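"""Intensity-based registration: NCC metric, sparse sampling, and the
three-stage cascade (closed-form landmark rigid, 12-DOF affine, 4x4x4
cubic-FFD B-spline).

The estimated chain maps atlas coordinates to target coordinates, so the
A-value fiducials placed on the atlas are propagated by direct application
of the chain.  Metric sampling consequently draws voxel-center points from
the atlas ROI and probes the target (trilinear) at transformed positions.

Defaults mirror the published parameter table: NCC objective throughout,
0.1% sampling for the affine stage, 100% (dense) for the B-spline stage,
least-squares landmark initialisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial.transform import Rotation

from .errors import (
    ConfigurationError,
    DegenerateLandmarksError,
    DegenerateMetricError,
    InsufficientOverlapError,
)
from .imaging import FiducialSet, RegionOfInterest, Volume3D, crop_to_roi
from .transforms import (
    AffineTransform,
    BSplineTransform,
    TransformChain,
    cubic_bspline_kernel,
)

__all__ = [
    "RegistrationConfig",
    "ncc",
    "sample_points",
    "evaluate_metric",
    "register_landmarks",
    "register_affine",
    "register_bspline",
]


@dataclass(frozen=True)
class RegistrationConfig:
    """Cascade parameters.

    ``affine_sample_fraction`` / ``bspline_sample_fraction`` are fractions
    of the voxel centers in the atlas ROI (published defaults 0.001 and
    1.0).  ``max_samples_bspline`` caps the dense stage at a seeded uniform
    subsample; the cap is a computational ceiling only — 2e4 points
    over-determine 192 scalar parameters by two orders of magnitude.
    """

    metric: str = "NCC"
    affine_sample_fraction: float = 0.001
    bspline_sample_fraction: float = 1.0
    max_iterations_affine: int = 200
    max_iterations_bspline: int = 100
    convergence_tol: float = 1e-5
    convergence_window: int = 5
    multiresolution_levels: int = 3
    rng_seed: int = 20180122
    grid_shape: tuple[int, int, int] = (4, 4, 4)
    displacement_cap_factor: float = 0.4
    max_samples_bspline: int = 20000
    n_starts_affine: int = 1
    min_overlap: float = 0.5
    ncc_floor: float = 0.3
    histogram_match: bool = False

    def __post_init__(self):
        if self.metric != "NCC":
            raise ConfigurationError(f"unsupported metric {self.metric!r}")
        for frac in (self.affine_sample_fraction, self.bspline_sample_fraction):
            if not 0 < frac <= 1:
                raise ConfigurationError("sample fractions must lie in (0, 1]")


# -- similarity metric ----------------------------------------------------


def ncc(fixed_samples: np.ndarray, moving_samples: np.ndarray) -> float:
    """Pearson-form normalized cross-correlation in [-1, 1].

    Invariant to positive affine rescaling of either intensity vector;
    raises for vectors of length < 2 or zero variance.
    """
    a = np.asarray(fixed_samples, dtype=float).ravel()
    b = np.asarray(moving_samples, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("sample vectors must have equal length")
    if a.size < 2:
        raise DegenerateMetricError("need at least 2 samples for NCC")
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0.0:
        raise DegenerateMetricError("zero intensity variance; NCC undefined")
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


def sample_points(
    volume: Volume3D,
    roi: RegionOfInterest,
    fraction: float,
    seed: int,
) -> np.ndarray:
    """Uniform sample (without replacement) of voxel centers inside ``roi``.

    Size is ``round(fraction * count)``; fraction 1 returns every center.
    Counter-based Philox generator makes the draw reproducible per seed.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    sub = crop_to_roi(volume, roi)
    centers = sub.voxel_centers()
    keep = roi.contains(centers)
    centers = centers[keep]
    n = centers.shape[0]
    k = int(round(fraction * n))
    if k < 10:
        raise ValueError(
            f"sample of {k} points from {n} voxel centers is too small; "
            "increase the sampling fraction"
        )
    if k >= n:
        return centers
    rng = np.random.Generator(np.random.Philox(seed))
    idx = rng.choice(n, size=k, replace=False)
    return centers[np.sort(idx)]


def evaluate_metric(
    atlas: Volume3D,
    target: Volume3D,
    transform,
    points: np.ndarray,
    min_overlap: float = 0.5,
) -> float:
    """NCC between atlas intensities at ``points`` and target intensities
    (trilinear) at the transformed points; out-of-target points are
    excluded pairwise.  Raises if fewer than ``min_overlap`` remain."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    fixed, _ = atlas.sample(pts, order=1)
    mapped = transform.apply_points(pts)
    moving, inside = target.sample(mapped, order=1)
    frac = inside.mean() if inside.size else 0.0
    if frac < min_overlap:
        raise InsufficientOverlapError(
            f"only {100 * frac:.1f}% of sample points map inside the target "
            f"(need >= {100 * min_overlap:.0f}%)"
        )
    return ncc(fixed[inside], moving[inside])


# -- landmark stage -------------------------------------------------------


def register_landmarks(
    atlas_landmarks: FiducialSet, target_landmarks: FiducialSet
) -> AffineTransform:
    """Closed-form least-squares rigid fit (Kabsch) on matching labels.

    Minimises the sum of squared distances from transformed atlas
    landmarks to their target counterparts over rotation + translation
    (6 DOF, no scaling).  The RMS residual is attached to the result.
    """
    common = [l for l in atlas_landmarks.labels if l in target_landmarks]
    missing = [l for l in atlas_landmarks.labels if l not in target_landmarks]
    if len(common) < 3:
        raise DegenerateLandmarksError(
            f"need >= 3 corresponding landmarks, found {len(common)}"
            + (f"; target is missing {missing}" if missing else "")
        )
    a = atlas_landmarks.as_array(common)
    b = target_landmarks.as_array(common)
    a_c, b_c = a - a.mean(axis=0), b - b.mean(axis=0)
    sv = np.linalg.svd(a_c, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateLandmarksError("landmarks are collinear")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # align_vectors warns on exact fits
        rot, _ = Rotation.align_vectors(b_c, a_c)
    matrix = rot.as_matrix()
    translation = b.mean(axis=0) - matrix @ a.mean(axis=0)
    out = AffineTransform(matrix, translation, rigid=True)
    resid = out.apply_points(a) - b
    out.residual_rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return out


# -- optimizer ------------------------------------------------------------


def _adaptive_ascent(
    objective,
    gradient,
    x0: np.ndarray,
    step_init: float,
    step_min: float,
    max_iterations: int,
    tol: float,
    window: int,
    project=None,
    trace: list | None = None,
):
    """Monotone adaptive gradient ascent (regular-step style).

    Moves a normalised gradient step; accepted steps grow the step length,
    rejected ones halve it.  Never returns a point worse than its start.
    Converged when ``window`` consecutive accepted improvements fall below
    ``tol``, or the step collapses below ``step_min``.
    """
    x = np.asarray(x0, dtype=float).copy()
    f = objective(x)
    best_x, best_f = x.copy(), f
    step = step_init
    small_gains = 0
    if trace is not None:
        trace.append(best_f)
    for _ in range(max_iterations):
        g = gradient(x)
        gnorm = np.linalg.norm(g)
        if gnorm == 0.0:
            break
        accepted = False
        while step >= step_min:
            x_new = x + step * g / gnorm
            if project is not None:
                x_new = project(x_new)
            f_new = objective(x_new)
            if f_new > f:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        gain = f_new - f
        x, f = x_new, f_new
        if f > best_f:
            best_x, best_f = x.copy(), f
        if trace is not None:
            trace.append(best_f)
        step = min(step * 1.2, step_init)
        small_gains = small_gains + 1 if gain < tol else 0
        if small_gains >= window:
            break
    return best_x, best_f


def _smoothed(volume: Volume3D, sigma_mm: float) -> Volume3D:
    if sigma_mm <= 0:
        return volume
    sig = sigma_mm / volume.spacing
    return Volume3D(
        gaussian_filter(volume.voxels, sigma=sig),
        volume.spacing,
        volume.origin,
        volume.direction,
    )


def _match_histogram(target: Volume3D, atlas: Volume3D) -> Volume3D:
    """Monotone intensity remap of target onto the atlas histogram."""
    t = target.voxels.ravel()
    q = np.linspace(0, 1, 257)
    src = np.quantile(t, q)
    dst = np.quantile(atlas.voxels.ravel(), q)
    mapped = np.interp(target.voxels, src, dst)
    return Volume3D(mapped, target.spacing, target.origin, target.direction)


# -- affine stage ---------------------------------------------------------

#: step scales per affine parameter block: translation mm, rotation rad,
#: log-scale, shear — one optimizer unit moves ~1 mm or ~1 degree.
_AFFINE_SCALES = np.array([1.0] * 3 + [0.02] * 3 + [0.02] * 3 + [0.02] * 3)


def register_affine(
    atlas: Volume3D,
    target: Volume3D,
    init: TransformChain,
    config: RegistrationConfig | None = None,
    roi: RegionOfInterest | None = None,
    points: np.ndarray | None = None,
) -> AffineTransform:
    """12-DOF affine stage: maximise NCC over a sparse atlas-ROI sample.

    The returned transform composes *after* ``init`` (chain = init +
    affine).  Multi-resolution via Gaussian scale-space smoothing of both
    images (factors 4x, 2x, 1x of the target voxel size).  The final NCC
    on the optimisation sample never falls below the initial value.
    """
    config = config or RegistrationConfig()
    if roi is None:
        roi = atlas.extent_roi()
    if points is None:
        points = sample_points(atlas, roi, config.affine_sample_fraction,
                               config.rng_seed)
    if config.histogram_match:
        target = _match_histogram(target, atlas)
    warped0 = init.apply_points(points)
    center = warped0.mean(axis=0)
    coarse = float(np.max(target.spacing))

    levels = [4.0, 2.0, 1.0][-config.multiresolution_levels:]
    params = np.zeros(12)
    rng = np.random.Generator(np.random.Philox(config.rng_seed + 1))
    traces: list[list[float]] = []
    for li, level in enumerate(levels):
        sigma = 0.5 * (level - 1.0) * coarse
        atlas_l = _smoothed(atlas, sigma)
        target_l = _smoothed(target, sigma)
        fixed, _ = atlas_l.sample(points, order=1)
        if np.std(fixed) == 0:
            raise DegenerateMetricError("atlas sample has zero variance")

        def objective(z, _t=target_l, _f=fixed):
            aff = AffineTransform.from_params(z * _AFFINE_SCALES, center=center)
            moving, inside = _t.sample(aff.apply_points(warped0), order=1)
            if inside.mean() < config.min_overlap:
                return -np.inf
            try:
                return ncc(_f[inside], moving[inside])
            except DegenerateMetricError:
                return -np.inf

        def gradient(z, _obj=objective):
            h = 0.05
            g = np.empty(12)
            for i in range(12):
                e = np.zeros(12)
                e[i] = h
                g[i] = (_obj(z + e) - _obj(z - e)) / (2 * h)
            return np.nan_to_num(g, nan=0.0, posinf=0.0, neginf=0.0)

        z0 = params / _AFFINE_SCALES
        if objective(z0) == -np.inf:
            raise InsufficientOverlapError(
                "initial transform leaves insufficient atlas/target overlap"
            )
        starts = [z0]
        if li == 0 and config.n_starts_affine > 1:
            for _ in range(config.n_starts_affine - 1):
                starts.append(z0 + rng.uniform(-1.0, 1.0, size=12))
        best = None
        level_trace: list[float] = []
        for s in starts:
            zb, fb = _adaptive_ascent(
                objective,
                gradient,
                s,
                step_init=2.0,
                step_min=0.005,
                max_iterations=config.max_iterations_affine,
                tol=config.convergence_tol,
                window=config.convergence_window,
                trace=level_trace if s is starts[0] else None,
            )
            if best is None or fb > best[1]:
                best = (zb, fb)
        traces.append(level_trace)
        params = best[0] * _AFFINE_SCALES

    out = AffineTransform.from_params(params, center=center)
    # best-so-far NCC per multiresolution level; non-decreasing within each
    # level (each level optimises against its own smoothed images)
    out.metric_traces = traces
    out.metric_trace = traces[-1]
    final = evaluate_metric(atlas, target, init.extended(out), points,
                            config.min_overlap)
    initial = evaluate_metric(atlas, target, init, points, config.min_overlap)
    if final < initial - 1e-12:  # optimizer contract: never worse than start
        out = AffineTransform.identity()
        out.metric_traces = traces
        out.metric_trace = traces[-1]
        final = initial
    out.final_ncc = final
    return out


# -- B-spline stage -------------------------------------------------------


def _bspline_weights(transform: BSplineTransform, points: np.ndarray):
    """Sparse-as-dense basis weight matrix W: W[i, j] = product of cubic
    B3 factors linking sample point i to control point j (flattened)."""
    idx = (np.atleast_2d(points) - transform.grid_origin) / transform.grid_spacing
    n = points.shape[0]
    shape = transform.grid_shape
    w_axis = []
    for a in range(3):
        centers = np.arange(shape[a])
        w = cubic_bspline_kernel(idx[:, a][:, None] - centers[None, :])
        w_axis.append(w)
    W = (
        w_axis[0][:, :, None, None]
        * w_axis[1][:, None, :, None]
        * w_axis[2][:, None, None, :]
    ).reshape(n, -1)
    return W


def register_bspline(
    atlas: Volume3D,
    target: Volume3D,
    init: TransformChain,
    config: RegistrationConfig | None = None,
    roi: RegionOfInterest | None = None,
    points: np.ndarray | None = None,
) -> BSplineTransform:
    """Cubic-FFD stage: control-point displacements maximising NCC over a
    dense atlas-ROI sample (default fraction 1.0, capped).

    The control grid spans the image of the atlas ROI under ``init`` (the
    FFD acts on post-affine coordinates).  Displacements are projected
    onto a cap of ``displacement_cap_factor x grid_spacing`` each step to
    preserve invertibility.  Ascent uses the analytic NCC gradient with
    respect to the control displacements.  Final NCC on the sample never
    falls below the value at the affine initialisation.
    """
    config = config or RegistrationConfig()
    if len(init) == 0:
        raise ConfigurationError("B-spline stage requires the affine init chain")
    if roi is None:
        roi = atlas.extent_roi()
    if points is None:
        points = sample_points(atlas, roi, config.bspline_sample_fraction,
                               config.rng_seed + 2)
    if points.shape[0] > config.max_samples_bspline:
        rng = np.random.Generator(np.random.Philox(config.rng_seed + 3))
        sel = rng.choice(points.shape[0], size=config.max_samples_bspline,
                         replace=False)
        points = points[np.sort(sel)]
    if config.histogram_match:
        target = _match_histogram(target, atlas)

    fixed, _ = atlas.sample(points, order=1)
    warped = init.apply_points(points)  # FFD domain = post-affine coordinates
    mapped_roi = RegionOfInterest.around_points(warped, margin=1e-6)
    pad = 0.02 * mapped_roi.extent
    grid = BSplineTransform.for_roi(
        RegionOfInterest(mapped_roi.lower - pad, mapped_roi.upper + pad),
        config.grid_shape,
    )
    if not np.all(grid.support_roi.contains(warped)):
        raise ConfigurationError("B-spline grid does not cover the mapped ROI")

    W = _bspline_weights(grid, warped)  # (n, n_cp), constant over iterations
    grad_vols = target.gradient_volumes()
    cap = config.displacement_cap_factor * grid.grid_spacing
    n_cp = grid.n_control_points
    a_c = fixed - fixed.mean()
    var_a = float(a_c @ a_c)
    if var_a == 0:
        raise DegenerateMetricError("atlas sample has zero variance")

    def warp(d_flat):
        u = W @ d_flat.reshape(n_cp, 3)
        return warped + u

    def objective(d_flat):
        moving, inside = target.sample(warp(d_flat), order=1)
        if inside.mean() < config.min_overlap:
            return -np.inf
        try:
            return ncc(fixed[inside], moving[inside])
        except DegenerateMetricError:
            return -np.inf

    def gradient(d_flat):
        x = warp(d_flat)
        g, inside = target.sample(x, order=1)
        a = np.where(inside, a_c, 0.0)
        gm = np.where(inside, g, 0.0)
        gm = gm - (gm[inside].mean() if inside.any() else 0.0)
        gm = np.where(inside, gm, 0.0)
        sa = np.sqrt(float(a @ a))
        sg = np.sqrt(float(gm @ gm))
        if sa == 0 or sg == 0:
            return np.zeros(n_cp * 3)
        corr = float(a @ gm) / (sa * sg)
        # dNCC/dg_i for the masked Pearson form
        q = a / (sa * sg) - corr * gm / (sg * sg)
        q = np.where(inside, q, 0.0)
        grad = np.empty((n_cp, 3))
        for c in range(3):
            gc, _ = grad_vols[c].sample(x, order=1)
            grad[:, c] = W.T @ (q * gc)
        return grad.ravel()

    def project(d_flat):
        d = d_flat.reshape(n_cp, 3)
        return np.clip(d, -cap, cap).ravel()

    trace: list[float] = []
    step_init = 0.25 * float(np.min(target.spacing))
    d_best, f_best = _adaptive_ascent(
        objective,
        gradient,
        np.zeros(n_cp * 3),
        step_init=step_init,
        step_min=1e-4 * step_init,
        max_iterations=config.max_iterations_bspline,
        tol=config.convergence_tol,
        window=config.convergence_window,
        project=project,
        trace=trace,
    )
    grid.displacements = d_best.reshape(grid.grid_shape + (3,))
    grid.metric_trace = trace
    grid.final_ncc = f_best
    return grid
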