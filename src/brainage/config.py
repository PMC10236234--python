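"""Simulation and pipeline configuration.

:class:`SimConfig` holds every knob of the synthetic cohort generator; its
defaults reproduce the structure of the study design it emulates — a study
arm of 416 middle-aged/older adults (ages 44–74) scanned on 24 scanners, 99
demographically similar controls, a large lifespan reference cohort with an
additional AD-pattern class, and ~145 anatomical ROIs.  Site-effect and
noise magnitudes are exposed here rather than hard-coded because no
published per-ROI values exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class SimConfig:
    """Parameters of the synthetic multi-scanner cohort generator.

    All counts are subjects, ages in years, volumes/shifts in mm^3,
    ``site_scale_sd`` is the SD of per-scanner log multiplicative noise
    scale, ``ad_effect_sd`` is in units of the residual noise SD.
    """

    n_study: int = 416
    n_control: int = 99
    n_reference: int = 600
    n_ad_cases: int = 221
    n_rois: int = 145
    n_scanners: int = 24
    age_range: tuple[float, float] = (44.0, 74.0)
    reference_age_range: tuple[float, float] = (20.0, 90.0)
    site_shift_sd: float = 80.0
    site_scale_sd: float = 0.15
    aging_offset_years: float = 6.0
    ad_effect_sd: float = 1.5
    noise_sd: float = 150.0
    affected_roi_fraction: float = 0.6
    ad_signature_fraction: float = 0.2
    cohort_shift_sd: float = 50.0
    followup_years: float = 32.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.age_range = tuple(self.age_range)  # type: ignore[assignment]
        self.reference_age_range = tuple(self.reference_age_range)  # type: ignore[assignment]
        self.validate()

    def validate(self) -> None:
        for name in ("n_study", "n_control", "n_reference", "n_ad_cases",
                     "n_rois", "n_scanners"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v <= 0:
                raise ConfigurationError(f"{name} must be a positive integer, got {v!r}")
        for name in ("age_range", "reference_age_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ConfigurationError(f"{name} must satisfy min < max, got ({lo}, {hi})")
        for name in ("site_shift_sd", "site_scale_sd", "noise_sd",
                     "cohort_shift_sd", "followup_years"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not 0.0 <= self.affected_roi_fraction <= 1.0:
            raise ConfigurationError(
                f"affected_roi_fraction must lie in [0, 1], got {self.affected_roi_fraction}")
        if not 0.0 <= self.ad_signature_fraction <= 1.0:
            raise ConfigurationError(
                f"ad_signature_fraction must lie in [0, 1], got {self.ad_signature_fraction}")
        if self.affected_roi_fraction + self.ad_signature_fraction > 1.0:
            raise ConfigurationError(
                "affected_roi_fraction + ad_signature_fraction must not exceed 1 "
                "(age-sensitive and AD-signature ROI sets are disjoint)")
        if not isinstance(self.seed, int):
            raise ConfigurationError(f"seed must be an integer, got {self.seed!r}")

    def replace(self, **kw) -> "SimConfig":
        d = asdict(self)
        d.update(kw)
        return SimConfig(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_range"] = list(self.age_range)
        d["reference_age_range"] = list(self.reference_age_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown SimConfig fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class PipelineConfig:
    """End-to-end pipeline run configuration (see ``brainage run``)."""

    out_dir: str = "run"
    seed: int = 0
    simulate: SimConfig | None = field(default_factory=SimConfig)
    #: harmonization covariates used in the within-study step
    step1_covariates: tuple[str, ...] = ("age", "sex", "icv", "diagnosis")
    #: harmonization covariates used in the study-to-reference step
    step2_covariates: tuple[str, ...] = ("age", "sex", "diagnosis")
    spare_c_grid: tuple[float, ...] = tuple(10.0 ** k for k in range(-3, 4))
    spare_epsilon: float = 0.1
    run_roi_scan: bool = True
    run_cognition: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "simulate" in d and d["simulate"] is not None:
            d["simulate"] = SimConfig.from_dict(d["simulate"])
        for key in ("step1_covariates", "step2_covariates", "spare_c_grid"):
            if key in d:
                d[key] = tuple(d[key])
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown PipelineConfig fields: {sorted(unknown)}")
        return cls(**d)
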