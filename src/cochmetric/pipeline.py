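"""End-to-end A-value measurement: laterality-aware atlas selection, ROI
cropping, the landmark -> affine -> B-spline cascade, fiducial
propagation, and cochlear duct length (CDL) estimation.

The A-value is the straight-line distance (mm) between the center of the
round window and the furthest point on the basal turn; CDL at the lateral
wall or Organ of Corti is estimated from it by linear equations of the
form ``CDL = slope * A + intercept``.  Published coefficient sets exist
in the otology literature; because they are transcription-sensitive they
ship here as *configuration data* (named presets registered at run time
or loaded from a config file), not hard-coded constants.

The statsmodels-style surface is :class:`AValueModel` (data + config) and
:class:`AValueResults` (estimates, per-stage diagnostics, summary table).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import CochmetricError, ConfigurationError
from .imaging import (
    AVAL_LABELS,
    INIT_LANDMARK_LABELS,
    FiducialSet,
    RegionOfInterest,
    Volume3D,
    crop_to_roi,
    mirror_volume,
)
from .registration import (
    RegistrationConfig,
    evaluate_metric,
    register_affine,
    register_bspline,
    register_landmarks,
    sample_points,
)
from .transforms import AffineTransform, BSplineTransform, TransformChain, dof

__all__ = [
    "AtlasBundle",
    "AValueModel",
    "AValueResults",
    "CDLEquation",
    "select_atlas",
    "measure_a_value",
    "compute_a_value",
    "estimate_cdl",
]

logger = logging.getLogger("cochmetric.pipeline")

#: default margin (mm) of the automatic ROI box around the init landmarks
DEFAULT_ROI_MARGIN_MM = 10.0


# -- CDL equations --------------------------------------------------------


@dataclass(frozen=True)
class CDLEquation:
    """Linear A-value -> CDL mapping, ``CDL = slope * A + intercept``."""

    name: str
    slope: float
    intercept: float
    site: str = "lateral_wall"  # or "organ_of_corti"
    source: str = ""

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("CDL equation slope must be positive (CDL increases with A)")
        if self.site not in ("lateral_wall", "organ_of_corti"):
            raise ValueError(f"unknown measurement site {self.site!r}")

    def __call__(self, a_value: float) -> float:
        return estimate_cdl(a_value, self)


#: named presets; empty by default — coefficients are user/packager-supplied
#: configuration transcribed from the cited primary sources.
CDL_PRESETS: dict[str, CDLEquation] = {}


def register_cdl_preset(equation: CDLEquation) -> None:
    CDL_PRESETS[equation.name] = equation


def get_cdl_preset(name: str) -> CDLEquation:
    if name not in CDL_PRESETS:
        available = sorted(CDL_PRESETS) or ["<none registered>"]
        raise ConfigurationError(
            f"unknown CDL preset {name!r}; available presets: {', '.join(available)}"
        )
    return CDL_PRESETS[name]


def estimate_cdl(a_value: float, equation: CDLEquation) -> float:
    """CDL (mm) from the A-value via a linear equation."""
    if a_value <= 0:
        raise ValueError(f"A-value must be positive, got {a_value}")
    return equation.slope * a_value + equation.intercept


def compute_a_value(fiducials: FiducialSet) -> float:
    """Euclidean distance (mm) between round_window and basal_turn."""
    rw = fiducials.require("round_window")
    bt = fiducials.require("basal_turn")
    return float(np.linalg.norm(bt - rw))


# -- atlas bundle ---------------------------------------------------------


@dataclass
class AtlasBundle:
    """A reference volume with its measurement and initialisation fiducials.

    ``aval_fiducials`` carries round_window and basal_turn (the measured
    pair); ``init_landmarks`` carries apex, modiolus, round_window and
    oval_window (the landmark-registration quadruple).  Both live in the
    volume's world frame.
    """

    volume: Volume3D
    aval_fiducials: FiducialSet
    init_landmarks: FiducialSet
    laterality: str

    def __post_init__(self):
        if self.laterality not in ("left", "right"):
            raise ValueError(
                "atlas laterality must be 'left' or 'right' — pass the flag "
                "explicitly"
            )
        for label in AVAL_LABELS:
            self.aval_fiducials.require(label)
        for label in INIT_LANDMARK_LABELS:
            self.init_landmarks.require(label)

    @property
    def a_value(self) -> float:
        return compute_a_value(self.aval_fiducials)

    def mirrored(self, plane_axis: int = 0) -> "AtlasBundle":
        """The opposite-laterality bundle (volume and fiducials reflected
        consistently about the volume's center plane)."""
        vol = mirror_volume(self.volume, plane_axis)
        return AtlasBundle(
            volume=vol,
            aval_fiducials=self.aval_fiducials.mirrored(self.volume, plane_axis),
            init_landmarks=self.init_landmarks.mirrored(self.volume, plane_axis),
            laterality="left" if self.laterality == "right" else "right",
        )


def select_atlas(bundle: AtlasBundle, target_laterality: str) -> AtlasBundle:
    """Return the bundle matching ``target_laterality``, mirroring if needed."""
    if target_laterality not in ("left", "right"):
        raise ValueError(
            f"target laterality must be 'left' or 'right', got {target_laterality!r}"
        )
    if bundle.laterality == target_laterality:
        return bundle
    return bundle.mirrored()


# -- results --------------------------------------------------------------


@dataclass
class AValueResults:
    """Fitted measurement: the A-value, its provenance, and diagnostics."""

    a_value: float
    propagated_fiducials: FiducialSet
    transform_chain: TransformChain
    stage_metrics: dict[str, float]
    cdl_estimates: dict[str, float] = field(default_factory=dict)
    atlas_a_value: float | None = None
    landmark_residual_rms: float | None = None
    low_confidence: bool = False
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.a_value <= 0:
            self.warnings.append("non-positive A-value: coincident fiducials")

    def summary(self) -> str:
        lines = ["A-value measurement", "=" * 44]
        lines.append(f"{'A-value (mm)':<32}{self.a_value:>10.2f}")
        if self.atlas_a_value is not None:
            lines.append(f"{'Atlas A-value (mm)':<32}{self.atlas_a_value:>10.2f}")
        for name, cdl in self.cdl_estimates.items():
            lines.append(f"{'CDL ' + name + ' (mm)':<32}{cdl:>10.2f}")
        lines.append("-" * 44)
        for stage, value in self.stage_metrics.items():
            lines.append(f"{'NCC after ' + stage:<32}{value:>10.4f}")
        if self.landmark_residual_rms is not None:
            lines.append(
                f"{'Landmark residual RMS (mm)':<32}{self.landmark_residual_rms:>10.4f}"
            )
        stages = [type(t).__name__ for t in self.transform_chain]
        lines.append(f"stages: {' -> '.join(stages)} "
                     f"({dof(self.transform_chain)} DOF total)")
        if self.low_confidence:
            lines.append("WARNING: final NCC below confidence floor")
        for w in self.warnings:
            lines.append(f"WARNING: {w}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "a_value_mm": round(self.a_value, 2),
            "a_value_mm_full": self.a_value,
            "atlas_a_value_mm": self.atlas_a_value,
            "propagated_fiducials": {
                k: list(v) for k, v in self.propagated_fiducials.points.items()
            },
            "cdl_estimates_mm": {k: round(v, 2) for k, v in self.cdl_estimates.items()},
            "stage_metrics_ncc": self.stage_metrics,
            "landmark_residual_rms_mm": self.landmark_residual_rms,
            "low_confidence": self.low_confidence,
            "warnings": self.warnings,
            "transform_chain": self.transform_chain.to_dict(),
        }

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# -- the measurement itself ----------------------------------------------


def measure_a_value(
    atlas: AtlasBundle,
    target: Volume3D,
    target_landmarks: FiducialSet,
    roi: RegionOfInterest | None = None,
    config: RegistrationConfig | None = None,
    cdl_equations: list[CDLEquation] | None = None,
    roi_margin_mm: float = DEFAULT_ROI_MARGIN_MM,
) -> AValueResults:
    """Run the full cascade and propagate the atlas A-value fiducials.

    Stages: landmark rigid fit -> target ROI crop -> affine -> B-spline;
    the composed chain maps the atlas fiducials into the target, and the
    distance between the propagated round-window and basal-turn points is
    the target's A-value.  Per-stage NCC (evaluated on a common dense
    sample) is reported for diagnostics.
    """
    config = config or RegistrationConfig()
    for label in INIT_LANDMARK_LABELS:
        target_landmarks.require(label)
    warnings_list: list[str] = []

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except CochmetricError as exc:
            raise type(exc)(f"[stage: {name}] {exc}") from exc

    # 1. landmark initialisation
    rigid = _stage("landmark", register_landmarks, atlas.init_landmarks,
                   target_landmarks.subset(INIT_LANDMARK_LABELS))
    chain = TransformChain([rigid])
    logger.info("landmark stage: residual RMS %.3f mm", rigid.residual_rms)

    # 2. ROI cropping (world-mm boxes apply across resolutions)
    if roi is None:
        roi = RegionOfInterest.around_points(
            target_landmarks.subset(INIT_LANDMARK_LABELS).as_array(), roi_margin_mm
        )
    target_roi = crop_to_roi(target, roi)
    atlas_roi_box = RegionOfInterest.around_points(
        atlas.init_landmarks.as_array(), roi_margin_mm
    )
    ext = atlas.volume.extent_roi()
    atlas_roi_box = RegionOfInterest(
        np.maximum(atlas_roi_box.lower, ext.lower),
        np.minimum(atlas_roi_box.upper, ext.upper),
    )

    # common dense sample for comparable per-stage metrics
    dense_points = sample_points(
        atlas.volume, atlas_roi_box, config.bspline_sample_fraction, config.rng_seed + 2
    )
    if dense_points.shape[0] > config.max_samples_bspline:
        rng = np.random.Generator(np.random.Philox(config.rng_seed + 3))
        sel = rng.choice(dense_points.shape[0], size=config.max_samples_bspline,
                         replace=False)
        dense_points = dense_points[np.sort(sel)]

    stage_metrics: dict[str, float] = {}
    stage_metrics["landmark"] = _stage(
        "landmark", evaluate_metric, atlas.volume, target_roi, chain, dense_points,
        config.min_overlap,
    )
    logger.info("NCC after landmark: %.4f", stage_metrics["landmark"])

    # 3. affine
    affine = _stage("affine", register_affine, atlas.volume, target_roi, chain,
                    config, atlas_roi_box)
    ncc_affine = _stage(
        "affine", evaluate_metric, atlas.volume, target_roi,
        chain.extended(affine), dense_points, config.min_overlap,
    )
    if ncc_affine < stage_metrics["landmark"]:
        # cascade contract: a stage that does not improve the common-sample
        # NCC (its own sparse objective can disagree marginally) is skipped
        warnings_list.append(
            "affine stage did not improve the dense-sample NCC "
            f"({ncc_affine:.4f} < {stage_metrics['landmark']:.4f}); skipped"
        )
        affine = AffineTransform.identity()
        ncc_affine = stage_metrics["landmark"]
    chain = chain.extended(affine)
    stage_metrics["affine"] = ncc_affine
    logger.info("NCC after affine: %.4f", stage_metrics["affine"])

    # 4. B-spline (optimised on the same dense sample it is reported on)
    ffd = _stage("bspline", register_bspline, atlas.volume, target_roi, chain,
                 config, atlas_roi_box, dense_points)
    ncc_ffd = _stage(
        "bspline", evaluate_metric, atlas.volume, target_roi,
        chain.extended(ffd), dense_points, config.min_overlap,
    )
    if ncc_ffd < stage_metrics["affine"]:
        warnings_list.append(
            "B-spline stage did not improve the dense-sample NCC "
            f"({ncc_ffd:.4f} < {stage_metrics['affine']:.4f}); skipped"
        )
        ffd = BSplineTransform(ffd.grid_shape, ffd.grid_origin, ffd.grid_spacing)
        ncc_ffd = stage_metrics["affine"]
    chain = chain.extended(ffd)
    stage_metrics["bspline"] = ncc_ffd
    logger.info("NCC after B-spline: %.4f", stage_metrics["bspline"])

    # 5. fiducial propagation and the A-value
    propagated = atlas.aval_fiducials.transformed(
        lambda p: chain.apply_points(p, strict=True)
    )
    propagated = replace(propagated, laterality=atlas.laterality)
    a_value = compute_a_value(propagated)

    cdl = {}
    for eq in cdl_equations or []:
        cdl[eq.name] = estimate_cdl(a_value, eq)

    low_conf = stage_metrics["bspline"] < config.ncc_floor
    if low_conf:
        warnings_list.append(
            f"final NCC {stage_metrics['bspline']:.3f} below floor "
            f"{config.ncc_floor:.2f}"
        )
    return AValueResults(
        a_value=a_value,
        propagated_fiducials=propagated,
        transform_chain=chain,
        stage_metrics=stage_metrics,
        cdl_estimates=cdl,
        atlas_a_value=atlas.a_value,
        landmark_residual_rms=rigid.residual_rms,
        low_confidence=low_conf,
        warnings=warnings_list,
    )


# -- model object ---------------------------------------------------------


class AValueModel:
    """Automated A-value measurement model.

    Parameters
    ----------
    atlas : AtlasBundle
        Reference volume with fiducials; mirrored automatically when its
        laterality differs from the target's.
    target : Volume3D
        The clinical-resolution volume to be measured.
    target_landmarks : FiducialSet
        User-placed apex/modiolus/round_window/oval_window points.
    target_laterality : str
        'left' or 'right'.
    roi : RegionOfInterest, optional
        Cochlear region in the target; derived from the landmarks
        (10 mm margin box) when omitted.
    config : RegistrationConfig, optional
    cdl_equations : list of CDLEquation, optional

    ``fit()`` runs the cascade and returns :class:`AValueResults`.
    """

    def __init__(
        self,
        atlas: AtlasBundle,
        target: Volume3D,
        target_landmarks: FiducialSet,
        target_laterality: str | None = None,
        roi: RegionOfInterest | None = None,
        config: RegistrationConfig | None = None,
        cdl_equations: list[CDLEquation] | None = None,
        roi_margin_mm: float = DEFAULT_ROI_MARGIN_MM,
    ):
        laterality = target_laterality or target_landmarks.laterality
        if laterality is None:
            raise ValueError(
                "target laterality unknown: pass target_laterality='left'/'right'"
            )
        self.atlas = select_atlas(atlas, laterality)
        self.target = target
        self.target_landmarks = target_landmarks
        self.target_laterality = laterality
        self.roi = roi
        self.config = config or RegistrationConfig()
        self.cdl_equations = cdl_equations or []
        self.roi_margin_mm = roi_margin_mm

    def fit(self) -> AValueResults:
        return measure_a_value(
            self.atlas,
            self.target,
            self.target_landmarks,
            roi=self.roi,
            config=self.config,
            cdl_equations=self.cdl_equations,
            roi_margin_mm=self.roi_margin_mm,
        )
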