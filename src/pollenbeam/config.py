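"""Validated configuration models for the virtual isolation pipeline.

Every tunable of the pipeline lives in one of the pydantic models below so
that a single JSON/YAML document can describe a full run (synthesis,
imaging, detection, masking, laser settings, disruption model).  Defaults
encode the study conditions of the automated pollen-isolation workflow:
pollen densities of tens of cells per mm^2, ~77 % viability, a few percent
of fluorescently labelled target grains, 16-bit camera counts, an FDA
positivity threshold of 9,600 counts, a 12 um dust filter, a 60 um-diameter
exclusion mask around each target, and a 145 mW / 10 ms operating point for
the infrared laser.
"""

from __future__ import annotations

from typing import Literal

from pydantic import BaseModel, Field, model_validator

#: Full-scale value of the 16-bit camera; also the saturation level used to
#: recognise tdTomato-positive (target) regions.
FULL_SCALE = 65535

CHANNELS = ("green", "red", "brightfield")


class IntensityModel(BaseModel):
    """Per-channel intensity levels used when rendering a field (16-bit counts).

    ``viable_fda_mean``/``sd`` describe the per-grain fluorescein brightness of
    living (FDA-positive) pollen; per-grain draws are clipped to
    ``viable_fda_mean - 3 * viable_fda_sd`` so every viable grain clears the
    default 9,600-count positivity threshold by construction.
    ``autofluorescence_level`` is the faint residual green signal of
    FDA-negative grains (what threshold calibration samples), and
    ``target_red_level`` defaults to camera saturation because the nuclear
    tdTomato signal is recognised by the presence of saturated red pixels.
    """

    model_config = {"frozen": True}

    background_mean: float = Field(default=1000.0, ge=0, le=FULL_SCALE)
    background_sd: float = Field(default=100.0, ge=0)
    viable_fda_mean: float = Field(default=20000.0, ge=0, le=FULL_SCALE)
    viable_fda_sd: float = Field(default=2000.0, ge=0)
    autofluorescence_level: float = Field(default=3000.0, ge=0, le=FULL_SCALE)
    target_red_level: float = Field(default=float(FULL_SCALE), ge=0, le=FULL_SCALE)
    dust_green_level: float = Field(default=12000.0, ge=0, le=FULL_SCALE)
    brightfield_cell_level: float = Field(default=10000.0, ge=0, le=FULL_SCALE)


class FieldConfig(BaseModel):
    """Ground-truth pollen-field statistics.

    Defaults are the reference sample of the workflow: one-sixth of an anther
    (~2,119 grains) suspended over 25 mm^2, i.e. 84.8 cells/mm^2, with 77 %
    viability and 5.8 % tdTomato-expressing targets among viable grains.
    ``target_attrition_prob`` models spontaneous FDA loss of protected targets
    (developmental arrest / bombardment damage), disabled by default.
    """

    model_config = {"frozen": True}

    area_width_um: float = Field(default=5000.0, gt=0)
    area_height_um: float = Field(default=5000.0, gt=0)
    density_per_mm2: float = Field(default=84.8, ge=0)
    viability_fraction: float = Field(default=0.77, ge=0, le=1)
    target_fraction_of_viable: float = Field(default=0.058, ge=0, le=1)
    clump_fraction: float = Field(default=0.0, ge=0, le=1)
    min_separation_um: float = Field(default=40.0, ge=0)
    diameter_mean_um: float = Field(default=30.0, gt=12.0)
    diameter_sd_um: float = Field(default=2.5, ge=0)
    dust_per_mm2: float = Field(default=5.0, ge=0)
    dust_diameter_um: tuple[float, float] = (4.0, 10.0)
    intensity: IntensityModel = Field(default_factory=IntensityModel)
    target_attrition_prob: float = Field(default=0.0, ge=0, le=1)
    rng_seed: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _check_dust(self) -> "FieldConfig":
        lo, hi = self.dust_diameter_um
        if not (0 < lo <= hi <= 12.0):
            raise ValueError("dust diameters must lie in (0, 12] um")
        return self

    @property
    def area_mm2(self) -> float:
        return self.area_width_um * self.area_height_um / 1e6


class ImagingConfig(BaseModel):
    """Virtual camera/stage geometry.

    The instrument description gives no pixel scale or tile size, so both are
    explicit choices: 0.5 um/px keeps a 30 um grain ~60 px across, and
    0.5 x 0.5 mm tiles give the 80-120-tile counts of a >=20 mm^2 run.  Tiles
    are half-open ``[x0, x0 + w)`` and must cover the field area exactly.
    """

    model_config = {"frozen": True}

    pixel_size_um: float = Field(default=0.5, gt=0)
    tile_width_px: int = Field(default=1000, gt=0)
    tile_height_px: int = Field(default=1000, gt=0)
    channels: tuple[str, ...] = CHANNELS
    noise_sd: dict[str, float] = Field(
        default_factory=lambda: {"green": 100.0, "red": 100.0, "brightfield": 100.0}
    )
    bit_depth: Literal[16] = 16

    @property
    def tile_width_um(self) -> float:
        return self.tile_width_px * self.pixel_size_um

    @property
    def tile_height_um(self) -> float:
        return self.tile_height_px * self.pixel_size_um


class DetectionParams(BaseModel):
    """Thresholds and filters for region detection.

    ``fda_threshold`` (strictly-greater, 9,600 counts) defines FDA positivity;
    ``target_threshold`` defaults to the 16-bit full scale and a region is a
    target when it contains red pixels at or above it, i.e. saturated pixels
    (a printed threshold of ">65,535" is unattainable on 16-bit data, so it is
    read as saturation).  Components with equivalent diameter <= 12 um are
    discarded as dust (strict ``>``).
    """

    model_config = {"frozen": True}

    fda_threshold: float = Field(default=9600.0, ge=0, le=FULL_SCALE)
    target_threshold: float = Field(default=float(FULL_SCALE), ge=0, le=FULL_SCALE)
    brightfield_threshold: float = Field(default=5000.0, ge=0, le=FULL_SCALE)
    min_diameter_um: float = Field(default=12.0, gt=0)
    clump_area_factor: float = Field(default=1.5, gt=0)
    connectivity: Literal[1, 2] = 2  # skimage convention: 1 = 4-conn, 2 = 8-conn


class LaserSettings(BaseModel):
    """Infrared-laser operating point.

    Default is the condition chosen for isolation runs: 300 mW at the source
    delivering 145 mW in the focal plane, 10 ms exposure per shot.  Exposure
    is bounded to the 1-20 ms range that was characterised.
    """

    model_config = {"frozen": True}

    source_power_mw: float = Field(default=300.0, gt=0)
    focal_power_mw: float = Field(default=145.0, gt=0)
    exposure_ms: float = Field(default=10.0, ge=1.0, le=20.0)

    @model_validator(mode="after")
    def _check_power(self) -> "LaserSettings":
        if self.focal_power_mw > self.source_power_mw:
            raise ValueError("focal-plane power cannot exceed source power")
        return self


class DisruptionModel(BaseModel):
    """Empirical FDA-decay response of pollen to focal-plane laser power.

    Breakpoints (characterised powers):

    * 24 mW  - FDA signal never disappears (any exposure 1-20 ms);
    * 48 mW  - fluorescence lost after a uniform 165-225 s;
    * 96 mW  - lost after a short period (default 10 s, not quantified);
    * 145 mW - lost within 42.5 s (draw uniform in (0, min(42.5, t96)]);
    * 194 mW - lost instantly, and the grain is physically displaced.

    Between breakpoints decay time is interpolated log-linearly in power;
    below 48 mW the model returns "never" (no disappearance was observed
    there).  ``exposure_exponent`` scales time by ``(10 ms / exposure)^g``;
    the default 0 reflects the weak observed exposure dependence while
    keeping decay time (weakly) non-increasing in exposure.
    ``success_prob`` models per-shot failure (empirical disruption rates of
    65.7-87.2 % on hardware) without claiming a mechanism.
    """

    model_config = {"frozen": True}

    never_below_mw: float = 48.0
    t48_range_s: tuple[float, float] = (165.0, 225.0)
    t96_s: float = Field(default=10.0, gt=0)
    t145_max_s: float = Field(default=42.5, gt=0)
    displace_at_mw: float = 194.0
    power_range_mw: tuple[float, float] = (24.0, 194.0)
    exposure_range_ms: tuple[float, float] = (1.0, 20.0)
    exposure_exponent: float = Field(default=0.0, ge=0)
    success_prob: float = Field(default=1.0, ge=0, le=1)
    shrink_factor: float = Field(default=0.7, gt=0, le=1)
    rng_seed: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _check_ranges(self) -> "DisruptionModel":
        lo, hi = self.t48_range_s
        if not (0 < lo <= hi):
            raise ValueError("t48_range_s must be an increasing positive interval")
        if self.t96_s > lo:
            raise ValueError("t96_s must not exceed the lower 48 mW decay time")
        return self


class PipelineConfig(BaseModel):
    """Top-level configuration binding all stages of one virtual run."""

    model_config = {"frozen": True}

    field: FieldConfig = Field(default_factory=FieldConfig)
    imaging: ImagingConfig = Field(default_factory=ImagingConfig)
    detection: DetectionParams = Field(default_factory=DetectionParams)
    mask_diameter_um: float = Field(default=60.0, gt=0)
    laser: LaserSettings = Field(default_factory=LaserSettings)
    disruption: DisruptionModel = Field(default_factory=DisruptionModel)
    elapsed_s: float = Field(default=300.0, ge=0)
    calibrate_fda_threshold: bool = False
    calibrate_n_dim: int = Field(default=10, gt=0)
    seed: int = Field(default=0, ge=0)
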