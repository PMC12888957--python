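"""Run configuration: every analysis threshold in one schema-versioned
structure, loadable from YAML.

Defaults encode the standard readout and analysis protocol: 11 slices from
2 um depth in 2 um steps; delta stubs span at most 4 slices; the alpha
reference range is 16 um; dose estimation requires particles able to reach
10 um depth (5 slices); the LET split threshold is 25 keV/um; angle
histograms use 1-degree bins and intensity histograms 100 a.u. bins.
Unknown keys in a YAML file raise a configuration error naming the key.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields

import numpy as np
import yaml

from .calibrate import AngleCorrectionModel, LETCalibration
from .detect import ClassificationParams, DetectionParams, LinkingParams
from .errors import ConfigurationError

__all__ = ["CalibrationConfig", "AnalysisConfig", "load_config", "dump_config"]

SCHEMA_VERSION = 1


@dataclass
class CalibrationConfig:
    """Angle-correction parameters, LET calibration and sensitivity options."""

    angle_a: float = 0.79
    angle_b: float = 0.15           # 1/degree
    angle_c: float = 15.0           # degrees
    let_form: str = "log_linear"
    let_params: tuple = (-13.8155, 2.0)   # ln LET = p0 + p1 ln I
    let_intensity_range: tuple = (200.0, 30000.0)
    let_knots: list | None = None
    sensitivity: float = 1.0
    min_alpha_tracks: int = 200
    alpha_nominal_let: float = 100.0

    def angle_model(self) -> AngleCorrectionModel:
        return AngleCorrectionModel(self.angle_a, self.angle_b, self.angle_c)

    def let_calibration(self) -> LETCalibration:
        knots = None if self.let_knots is None else np.asarray(self.let_knots)
        return LETCalibration(form=self.let_form,
                              params=tuple(self.let_params),
                              knots=knots,
                              intensity_range=tuple(self.let_intensity_range))


@dataclass
class AnalysisConfig:
    """Complete parameter block of the image-analysis pipeline."""

    schema_version: int = SCHEMA_VERSION
    # readout geometry
    n_slices: int = 11
    slice_start_um: float = 2.0
    slice_step_um: float = 2.0
    # stage parameters
    detection: DetectionParams = field(default_factory=DetectionParams)
    linking: LinkingParams = field(default_factory=LinkingParams)
    classify: ClassificationParams = field(default_factory=ClassificationParams)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    # dosimetry thresholds (measurement-protocol defaults)
    delta_max_slices: int = 4
    alpha_max_range_um: float = 16.0
    min_depth_um: float = 10.0
    min_slices: int = 5
    let_threshold_kev_um: float = 25.0
    angle_bin_deg: float = 1.0
    intensity_bin_au: float = 100.0
    rho_g_cm3: float = 1.0          # water, matching the quality factor
    target_dose_gy: float = 1.0
    count_rejected_in_fluence: bool = False
    n_bootstrap: int = 1000
    seed: int = 0

    def __post_init__(self):
        # keep the classification block in sync with the top-level thresholds
        self.classify.delta_max_slices = self.delta_max_slices
        self.classify.alpha_max_range_um = self.alpha_max_range_um

    @property
    def slice_depths_um(self) -> np.ndarray:
        return self.slice_start_um + self.slice_step_um * np.arange(self.n_slices)


def _build(cls, data: dict, path: str):
    known = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in known:
            raise ConfigurationError(
                f"unknown configuration key {path}{key!r}")
        ftype = known[key].type
        if isinstance(value, dict) and ftype in (
                "DetectionParams", "LinkingParams", "ClassificationParams",
                "CalibrationConfig"):
            sub_cls = {"DetectionParams": DetectionParams,
                       "LinkingParams": LinkingParams,
                       "ClassificationParams": ClassificationParams,
                       "CalibrationConfig": CalibrationConfig}[ftype]
            value = _build(sub_cls, value, path=f"{path}{key}.")
        elif isinstance(value, list) and key in ("let_params",
                                                 "let_intensity_range"):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from YAML, validating all keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"configuration file {path} must be a mapping")
    return _build(AnalysisConfig, data, path="")


def dump_config(config: AnalysisConfig, path=None) -> str:
    """Serialise a configuration to YAML."""
    def _clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: _clean(getattr(obj, f.name))
                    for f in fields(obj)}
        if isinstance(obj, tuple):
            return list(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    text = yaml.safe_dump(_clean(config), sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
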