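"""Validated run configuration (YAML file + CLI overrides)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .errors import ConfigError

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class WindowSettings(_Strict):
    test_duration_s: float = 20.0
    analysis_start_s: float = 10.0
    analysis_end_s: float | None = None

    @model_validator(mode="after")
    def _check(self):
        end = self.analysis_end_s if self.analysis_end_s is not None else self.test_duration_s
        if not (0 <= self.analysis_start_s < end <= self.test_duration_s):
            raise ValueError(
                f"analysis window invalid: start={self.analysis_start_s}, end={end}, "
                f"duration={self.test_duration_s}"
            )
        return self


class CohortSettings(_Strict):
    n_patients: int = 16
    n_controls: int = 10
    severity_lo: float = 0.4
    severity_hi: float = 1.0


class SimulationSettings(_Strict):
    drift_max_deg: float = 30.0
    pron_max_deg: float = 60.0
    drift_tau_s: float = 4.0
    osc_amp_deg: float = 5.0
    osc_freq_hz: float = 3.0
    counter_coupling: float = 0.3
    accel_noise_sd_g: float = 0.02
    traj_noise_deg: float = 0.5
    rate_hz: float = 50.0
    duration_s: float = 20.0
    initial_dip_deg: float = 8.0
    dip_recovery_s: float = 3.0


class ClassifierSettings(_Strict):
    svm_degree: int = 2
    svm_C: float = 1.0
    rbfn_clusters_selected: int = 2  # with feature selection
    rbfn_clusters_full: int = 4  # without feature selection
    rf_trees: int = 100


class SelectionSettings(_Strict):
    patience: int = 5
    direction: str = "bidirectional"
    merit: str = "auto"
    placement: str = "pooled"  # pooled | nested


class RunConfig(_Strict):
    """Everything a full pipeline run needs; unknown keys are rejected."""

    seed: int = 0
    units: str = "g"
    filter_cutoff_hz: float = 5.0
    osc_method: str = "rms_detrend"
    window: WindowSettings = WindowSettings()
    cohort: CohortSettings = CohortSettings()
    simulation: SimulationSettings = SimulationSettings()
    classifiers: ClassifierSettings = ClassifierSettings()
    selection: SelectionSettings = SelectionSettings()

    @model_validator(mode="after")
    def _check(self):
        if self.units not in ("g", "ms2"):
            raise ValueError(f"units must be g|ms2, got {self.units!r}")
        if self.selection.placement not in ("pooled", "nested"):
            raise ValueError("selection.placement must be pooled|nested")
        if self.simulation.duration_s < (
            self.window.analysis_end_s
            if self.window.analysis_end_s is not None
            else self.window.test_duration_s
        ):
            raise ValueError("simulation duration shorter than the analysis window end")
        return self

    def config_hash(self) -> str:
        """Stable digest of the full configuration (for run manifests)."""
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML configuration file and apply keyword overrides.

    Overrides use dotted keys for nested sections (``selection.patience=3``).
    Any schema violation raises :class:`ConfigError` before a stage runs.
    """
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: configuration must be a mapping")
        data = raw
    for key, value in overrides.items():
        if value is None:
            continue
        parts = key.split(".")
        node = data
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = value
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc
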