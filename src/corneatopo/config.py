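"""Pipeline configuration.

Every numeric constant of the method lives here with its published default:
the 10x60 px closing element and 1/3 area ratio of the artifact filter, the
0.1 phase-map threshold, the degree-5 boundary polynomial, the 27 px
curvature half-window, the 0.016 mm pixel pitch, and the 21 px fusion strip.
Unknown keys are rejected so a typo in a JSON config fails loudly.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, model_validator


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class PhaseConfig(_StrictModel):
    """Log-Gabor filter-bank parameters for the phase symmetry/asymmetry maps."""

    n_scales: int = Field(4, ge=2)
    n_orientations: int = Field(6, ge=2)
    min_wavelength: float = Field(4.0, ge=2.0)
    scale_multiplier: float = Field(2.1, gt=1.0)
    sigma_on_f: float = Field(0.55, gt=0.0, lt=1.0)
    noise_k: float = Field(2.0, ge=0.0)
    epsilon: float = Field(1e-4, gt=0.0)


class PreprocessConfig(_StrictModel):
    """Artifact-removal parameters (closing + connected-component area filter)."""

    se_rows: int = Field(10, ge=1)
    se_cols: int = Field(60, ge=1)
    area_ratio: float = Field(1.0 / 3.0, gt=0.0, le=1.0)
    binarization: str = "otsu"
    grayscale_closing: bool = False


class SegmentationConfig(_StrictModel):
    tau_sym: float = Field(0.1, gt=0.0, lt=1.0)
    tau_asym: float = Field(0.1, gt=0.0, lt=1.0)
    poly_degree: int = Field(5, ge=1)
    weight_center_fit: bool = True  # use the symmetry intensity as LSQ weight
    band_search_factor: float = Field(0.75, gt=0.0)
    end_flag_fraction: float = Field(1.0 / 6.0, ge=0.0, lt=0.5)


class CurvatureConfig(_StrictModel):
    half_width: int = Field(27, ge=3)
    pixel_pitch: float = Field(0.016, gt=0.0)
    use_fitted_boundary: bool = True


class ViewingConditions(_StrictModel):
    """CIECAM02 viewing conditions (D65 white, average surround by default)."""

    white_xyz: tuple[float, float, float] = (95.047, 100.0, 108.883)
    adapting_luminance: float = Field(60.0, gt=0.0)  # cd/m^2
    background_luminance: float = Field(20.0, gt=0.0)  # Y_b, relative
    surround: str = "average"  # average | dim | dark
    # display-referred input: treat the display white as fully adapted, so
    # neutral grays come out exactly achromatic (D = 1)
    discount_illuminant: bool = True


class FusionConfig(_StrictModel):
    strip_width: int = Field(21, ge=3)
    palette: str = "rainbow"
    continuous_normalization: bool = False  # smooth variant of the piecewise map
    use_chroma: bool = False  # fuse chroma C instead of saturation s
    viewing_conditions: ViewingConditions = ViewingConditions()

    @model_validator(mode="after")
    def _odd_strip(self) -> "FusionConfig":
        if self.strip_width % 2 == 0:
            raise ValueError("strip_width must be odd")
        return self


class MetricsConfig(_StrictModel):
    stage_threshold_mm: float = Field(0.05, gt=0.0)
    apex_prominence_px: float = Field(1.0, ge=0.0)


class IOConfig(_StrictModel):
    bit_depth: int = Field(16, ge=8, le=16)
    frame_rate: float = Field(30.0, gt=0.0)


class PipelineConfig(_StrictModel):
    """Nested configuration for the whole topography pipeline."""

    io: IOConfig = IOConfig()
    phase: PhaseConfig = PhaseConfig()
    preprocess: PreprocessConfig = PreprocessConfig()
    segmentation: SegmentationConfig = SegmentationConfig()
    curvature: CurvatureConfig = CurvatureConfig()
    fusion: FusionConfig = FusionConfig()
    metrics: MetricsConfig = MetricsConfig()
    synthetic: dict = Field(default_factory=dict)  # forwarded to SyntheticConfig

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(self.model_dump_json(indent=2))
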