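"""Validated run configuration for the analysis pipeline.

A single YAML (or dict) config drives the whole pipeline: simulation (when
used in place of instrument data), population splitting, digitization and
estimation.  Unknown keys are rejected so typos fail loudly before any stage
runs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from .core import RHO_CELLS_PER_OD_DEFAULT

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulationConfig(_Strict):
    n_droplets: int = 100_000
    alpha_mode: Literal["fixed", "discrete_set", "continuous_uniform"] = "fixed"
    alpha: Optional[float] = 0.5
    alpha_set: Optional[list[tuple[float, float]]] = None  # (alpha, weight)
    alpha_range: Optional[tuple[float, float]] = None
    volume_modes: list[tuple[float, float]] = [(50.0, 1.0)]  # (pL, weight)
    c_p: float = 1e8
    c_b_nominal: float = 1.83e9
    c_b_effective: Optional[float] = None
    k_cb_per_min: Optional[float] = None
    tau_min: Optional[float] = None
    per_droplet_kinetics: bool = False
    incubation_min: float = 1e9
    times_min: Optional[list[float]] = None
    # fluorescence overrides (None -> FluorescenceModel defaults)
    green_log_mean_neg: Optional[float] = None
    green_log_sd: Optional[float] = None
    green_log_shift: Optional[float] = None
    spontaneous_lysis_prob: Optional[float] = None
    red_gain: Optional[float] = None
    red_offset: Optional[float] = None
    red_noise_sd: Optional[float] = None
    coalescence_prob: Optional[float] = None

    @model_validator(mode="after")
    def _alpha_spec_present(self):
        need = {"fixed": self.alpha is not None,
                "discrete_set": bool(self.alpha_set),
                "continuous_uniform": self.alpha_range is not None}
        if not need[self.alpha_mode]:
            raise ValueError(f"alpha_mode={self.alpha_mode!r} lacks its value spec")
        return self


class CalibrationConfig(_Strict):
    red_low: float
    alpha_min: float
    red_high: float
    alpha_max: float
    red_encodes: Literal["phage", "bacteria"] = "phage"


class PopulationsConfig(_Strict):
    mode: Literal["none", "discrete", "continuous", "size"] = "none"
    n_groups: int = 2
    n_bins: int = 300
    min_bin_count: int = 50
    n_size_modes: int = 2
    coalescence_z: float = 4.0
    posterior_floor: Optional[float] = None


class DigitizationConfig(_Strict):
    k_max: int = 4
    method: Literal["weights", "hard", "posterior"] = "weights"
    compute_silhouette: bool = False
    silhouette_cap: int = 10_000


class EstimationConfig(_Strict):
    rho_cells_per_od: float = RHO_CELLS_PER_OD_DEFAULT
    effective_fraction_for_k: Optional[float] = None
    fit_alpha_curve: bool = False
    fit_kinetics: bool = False


class RunConfig(_Strict):
    """Top-level validated pipeline configuration."""

    seed: int = 0
    simulation: Optional[SimulationConfig] = None
    events_path: Optional[str] = None
    calibration: Optional[CalibrationConfig] = None
    populations: PopulationsConfig = PopulationsConfig()
    digitization: DigitizationConfig = DigitizationConfig()
    estimation: EstimationConfig = EstimationConfig()
    out_dir: Optional[str] = None

    @model_validator(mode="after")
    def _has_source(self):
        if self.simulation is None and self.events_path is None:
            raise ValueError("config needs either a simulation block or events_path")
        if self.populations.mode == "continuous" and self.calibration is None:
            raise ValueError("continuous-alpha mode requires a calibration block")
        return self


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(Path(path)) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)
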