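"""Simulation configuration for the TCGS-like longitudinal data generator.

The generator emulates a six-wave cardiometabolic cohort: Bernoulli sex,
truncated-normal baseline age with 3-year wave spacing, BMI as a linear
function of age and sex with a subject-level random intercept, and DBP as a
linear function of age, sex and BMI with its own random intercept.  MAR
missingness is injected per cell through wave-specific logistic models that
depend on age and on the *other* outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import yaml

__all__ = ["SimulationConfig", "ConfigurationError"]


class ConfigurationError(ValueError):
    """Raised when a SimulationConfig violates its invariants."""


# Wave-specific intercepts of the logistic missingness models, one per wave.
_BETA0 = (-2.646, -2.634, -3.047, -3.271, -2.872, -2.440)  # BMI
_PHI0 = (-1.701, -1.815, -2.091, -2.386, -2.104, -1.522)   # DBP


@dataclass(frozen=True)
class SimulationConfig:
    """Every generative and amputation parameter of the simulated cohort.

    Scale parameters (``*_re_scale``, ``*_resid_scale``) are interpreted
    according to ``scale_interpretation``: as standard deviations (default)
    or as variances of the corresponding normal draws.  The default was
    fixed by calibration against the reference missing-data proportions and
    the trajectory-mean BMI coefficient (see docs/methods.md).
    """

    n_subjects: int = 1000
    n_waves: int = 6
    p_sex: float = 0.5

    # Baseline age: truncated normal on [age_min, age_max].
    age_mean: float = 39.34
    age_sd: float = 16.23
    age_min: float = 1.0
    age_max: float = 84.0
    wave_spacing_years: float = 3.0

    # BMI_ij = b0 + b_age * Age_ij + b_sex * Sex_i + u_i + e_ij
    bmi_coef: tuple[float, float, float] = (19.86, 0.136, 2.360)
    bmi_re_scale: float = 4.50
    bmi_resid_scale: float = 1.57

    # DBP_ij = d0 + d_age * Age_ij + d_sex * Sex_i + d_bmi * BMI_ij + u_i + e_ij
    dbp_coef: tuple[float, float, float, float] = (55.03, 0.098, -3.434, 0.707)
    dbp_re_scale: float = 6.35
    dbp_resid_scale: float = 6.88

    scale_interpretation: Literal["sd", "variance"] = "sd"

    # logit P(BMI_ij missing) = beta0[j] + beta1 * Age_ij + beta2 * DBP_ij
    # logit P(DBP_ij missing) = phi0[j] + phi1 * Age_ij + phi2 * BMI_ij
    beta0: tuple[float, ...] = _BETA0
    phi0: tuple[float, ...] = _PHI0
    beta1: float = 0.002
    beta2: float = 0.02
    phi1: float = 0.002
    phi2: float = 0.02

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ConfigurationError("n_subjects must be positive")
        if self.n_waves != 6:
            raise ConfigurationError("n_waves is fixed at 6")
        if not 0.0 <= self.p_sex <= 1.0:
            raise ConfigurationError("p_sex must lie in [0, 1]")
        if not self.age_min < self.age_max:
            raise ConfigurationError("age_min must be < age_max")
        for name in ("bmi_re_scale", "bmi_resid_scale",
                     "dbp_re_scale", "dbp_resid_scale"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.scale_interpretation not in ("sd", "variance"):
            raise ConfigurationError(
                "scale_interpretation must be 'sd' or 'variance'")
        if len(self.beta0) != self.n_waves:
            raise ConfigurationError("beta0 must have one entry per wave")
        if len(self.phi0) != self.n_waves:
            raise ConfigurationError("phi0 must have one entry per wave")

    def sd(self, scale: float) -> float:
        """Return ``scale`` as a standard deviation under the configured
        interpretation."""
        return scale if self.scale_interpretation == "sd" else scale ** 0.5

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for k in ("bmi_coef", "dbp_coef", "beta0", "phi0"):
            if k in d and isinstance(d[k], list):
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
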