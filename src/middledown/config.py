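"""Validated suite configuration (YAML in, YAML out, lossless round trip).

Defaults encode the acquisition geometry of the targeted assay: the
retention-time window per acetyl degree, the 585-640 Th MS1 scan range, the
470-530 Th narrow ion-trap MS2 range, and the analysis tolerances.  Unknown
keys are rejected outright so a typo in a config never silently falls back
to a default.
"""

from __future__ import annotations

import hashlib
from typing import Dict, List, Literal, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator

from .simulate import DEFAULT_RT_WINDOWS, AcquisitionConfig


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class AcquisitionSection(_Strict):
    rt_windows: Dict[int, Tuple[float, float]] = dict(DEFAULT_RT_WINDOWS)
    ms1_range: Tuple[float, float] = (585.0, 640.0)
    ms2_range: Tuple[float, float] = (470.0, 530.0)
    scan_interval_s: float = 2.0
    peak_width_min: float = 1.0
    noise_cv: float = 0.0
    baseline: float = 0.0
    n_baseline_peaks: int = 12
    isotope_envelope: bool = False
    charge: int = 9

    @field_validator("rt_windows")
    @classmethod
    def _windows_ordered(cls, v):
        for a, (lo, hi) in v.items():
            if lo >= hi:
                raise ValueError(f"RT window for degree {a} has start >= end")
        return v

    @field_validator("ms1_range", "ms2_range")
    @classmethod
    def _ranges_ordered(cls, v):
        if v[0] <= 0 or v[0] >= v[1]:
            raise ValueError(f"scan range {v} must be positive and ordered")
        return v

    def to_acquisition(self) -> AcquisitionConfig:
        return AcquisitionConfig(**self.model_dump())


class QuantSection(_Strict):
    precursor_tol: float = 0.05
    fragment_tol: float = 0.3
    snr_min: float = 3.0
    bin_width: float = 0.1
    intensity_mode: Literal["max", "sum"] = "max"
    ttest: Literal["student", "welch"] = "student"
    fdr: bool = False


class KineticsSection(_Strict):
    enzyme_nM: float = 4.0
    alpha: float = 0.05
    specific_activity: float = 1.0
    time_min: float = 1.0


class DoseResponseSection(_Strict):
    hook_frac: float = 0.1
    f_list: List[float] = [80.0]
    noise_floor: float = 0.0


class SuiteConfig(_Strict):
    acquisition: AcquisitionSection = AcquisitionSection()
    quant: QuantSection = QuantSection()
    kinetics: KineticsSection = KineticsSection()
    dose_response: DoseResponseSection = DoseResponseSection()
    seed: int = 0
    outdir: str = "."

    def dump_yaml(self) -> str:
        return yaml.safe_dump(_plain(self.model_dump()), sort_keys=True)

    def sha256(self) -> str:
        return hashlib.sha256(self.dump_yaml().encode()).hexdigest()


def _plain(obj):
    """YAML-safe plain types (tuples -> lists, int keys -> str)."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(x) for x in obj]
    return obj


def load_config(path: Optional[str] = None) -> SuiteConfig:
    """Load and validate a YAML config; an empty/absent file means all defaults."""
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    try:
        return SuiteConfig.model_validate(data)
    except ValidationError as exc:
        offenders = ", ".join(
            "->".join(str(p) for p in err["loc"]) or "<root>" for err in exc.errors()
        )
        raise ConfigError(f"invalid config ({offenders}): {exc}") from exc
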