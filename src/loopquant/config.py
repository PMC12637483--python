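"""Validated configuration objects for simulation and analysis.

Two configs drive the package: :class:`SimulationConfig` parameterizes the
synthetic-data generator (ground-truth looping, distance laws, detection
noise, transcriptional repression), and :class:`AnalysisConfig` holds the
quantification thresholds (nucleus QC, the 2 um pairing cap and the 0.27 um
contact threshold, ploidy, binning).
"""

from __future__ import annotations

from typing import Literal, Optional, Tuple

from pydantic import BaseModel, Field, model_validator


class SimulationConfig(BaseModel):
    """Parameters of the synthetic FISH dataset generator.

    Distances are in micrometers, areas in square micrometers, intensities in
    arbitrary units. The distance law is a two-component mixture: looped
    allele pairs draw their separation from a half-normal law, unlooped pairs
    from a Rayleigh law (the 2D-projected separation of isotropically
    diffusing loci). Defaults put ~9% of unlooped pairs below the 0.27 um
    contact threshold, in the range of dark-condition baselines.
    """

    n_cells: int = Field(1000, gt=0)
    ploidy: int = Field(2, ge=2, le=4)
    p_loop: float = Field(0.1, ge=0.0, le=1.0)
    allele_coupling: float = Field(0.0, ge=0.0, lt=1.0)
    looped_distance_params: Tuple[float, float] = (0.10, 0.05)
    free_distance_params: Tuple[float, ...] = (0.6,)
    spot_detection_prob: float = Field(1.0, ge=0.0, le=1.0)
    false_spot_rate: float = Field(0.0, ge=0.0)
    nucleus_area_params: Tuple[float, float] = (180.0, 40.0)
    nucleus_solidity_params: Tuple[float, float] = (60.0, 3.0)
    expression_params: Tuple[float, float] = (7.0, 0.5)
    expression_effect: float = 0.0
    rna_p_on: float = Field(0.3, ge=0.0, le=1.0)
    repression_effect: float = Field(0.0, ge=0.0, le=1.0)
    ts_intensity_params: Tuple[float, float] = (5.0, 0.4)
    seed: int = 0

    @model_validator(mode="after")
    def _check_scales(self) -> "SimulationConfig":
        loc, scale = self.looped_distance_params
        if not (loc >= 0):
            raise ValueError("looped_distance_params: location must be >= 0")
        if not (scale > 0):
            raise ValueError("looped_distance_params: scale must be > 0")
        if not (self.free_distance_params[0] > 0):
            raise ValueError("free_distance_params: scale must be > 0")
        mean, sd = self.nucleus_area_params
        if not (mean > 0 and sd > 0):
            raise ValueError("nucleus_area_params: mean and sd must be > 0")
        a, b = self.nucleus_solidity_params
        if not (a > 0 and b > 0):
            raise ValueError("nucleus_solidity_params: alpha and beta must be > 0")
        if not (self.expression_params[1] > 0):
            raise ValueError("expression_params: log-sd must be > 0")
        if not (self.ts_intensity_params[1] > 0):
            raise ValueError("ts_intensity_params: log-sd must be > 0")
        return self


class AnalysisConfig(BaseModel):
    """Quantification thresholds and conventions.

    ``min_area`` defaults to the U2OS value (90 um^2); use 50 for HeLa.
    ``contact_threshold`` (0.27 um) classifies a matched allele pair as a DNA
    contact; ``max_pair_distance`` (2 um) caps cross-channel matching.
    """

    min_area: float = Field(90.0, gt=0)
    min_solidity: float = Field(0.9, ge=0.0, le=1.0)
    max_pair_distance: float = Field(2.0, gt=0)
    contact_threshold: float = Field(0.27, gt=0)
    ploidy: int = Field(2, ge=1)
    n_bins: int = Field(4, ge=1)
    pixel_size: float = Field(0.108, gt=0)
    match_mode: Literal["one_to_one", "per_spot_min"] = "one_to_one"
    control_condition: Optional[str] = None

    @model_validator(mode="after")
    def _check_thresholds(self) -> "AnalysisConfig":
        if not (self.contact_threshold < self.max_pair_distance):
            raise ValueError(
                "contact_threshold must be smaller than max_pair_distance"
            )
        return self
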