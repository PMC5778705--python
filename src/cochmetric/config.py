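"""TOML configuration: registration parameters, ROI, and CDL presets.

Schema (all keys optional)::

    [registration]
    affine_sample_fraction = 0.001
    bspline_sample_fraction = 1.0
    max_iterations_affine = 200
    max_iterations_bspline = 100
    convergence_tol = 1e-5
    multiresolution_levels = 3
    rng_seed = 20180122
    grid_shape = [4, 4, 4]
    displacement_cap_factor = 0.4
    max_samples_bspline = 20000
    histogram_match = false

    [pipeline]
    roi_margin_mm = 10.0
    ncc_floor = 0.3

    [roi]                      # optional explicit target ROI, world mm
    lower = [x, y, z]
    upper = [x, y, z]

    [[cdl_equations]]          # CDL = slope * A + intercept, per preset
    name = "..."
    slope = 4.0
    intercept = -5.0
    site = "lateral_wall"      # or "organ_of_corti"
    source = "citation"
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields

from .errors import ConfigurationError
from .imaging import RegionOfInterest
from .pipeline import DEFAULT_ROI_MARGIN_MM, CDLEquation
from .registration import RegistrationConfig

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    roi: RegionOfInterest | None = None
    roi_margin_mm: float = DEFAULT_ROI_MARGIN_MM
    cdl_equations: list[CDLEquation] = field(default_factory=list)


def load_config(path: str) -> PipelineConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)

    reg_kwargs = dict(raw.get("registration", {}))
    if "grid_shape" in reg_kwargs:
        reg_kwargs["grid_shape"] = tuple(reg_kwargs["grid_shape"])
    pipe = raw.get("pipeline", {})
    if "ncc_floor" in pipe:
        reg_kwargs["ncc_floor"] = pipe["ncc_floor"]
    valid = {f.name for f in fields(RegistrationConfig)}
    unknown = set(reg_kwargs) - valid
    if unknown:
        raise ConfigurationError(f"unknown [registration] keys: {sorted(unknown)}")
    try:
        reg = RegistrationConfig(**reg_kwargs)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc

    roi = None
    if "roi" in raw:
        try:
            roi = RegionOfInterest(raw["roi"]["lower"], raw["roi"]["upper"])
        except (KeyError, ValueError) as exc:
            raise ConfigurationError(f"bad [roi] section: {exc}") from exc

    equations = []
    for entry in raw.get("cdl_equations", []):
        try:
            equations.append(
                CDLEquation(
                    name=entry["name"],
                    slope=float(entry["slope"]),
                    intercept=float(entry["intercept"]),
                    site=entry.get("site", "lateral_wall"),
                    source=entry.get("source", ""),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ConfigurationError(f"bad [[cdl_equations]] entry: {exc}") from exc

    return PipelineConfig(
        registration=reg,
        roi=roi,
        roi_margin_mm=float(pipe.get("roi_margin_mm", DEFAULT_ROI_MARGIN_MM)),
        cdl_equations=equations,
    )
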