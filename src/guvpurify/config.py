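"""Validated run configuration (YAML/JSON) for the end-to-end pipeline."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .device import (
    BRANCH_LENGTHS_UM,
    BRANCH_WIDTH_UM,
    ChannelSegment,
    DeviceNetwork,
    calibrate_to_thresholds,
)
from .synthetic import MixtureSpec, OpticsSpec, VesiclePopulationSpec


class DeviceConfig(BaseModel):
    """Geometry of the purification module (defaults: the published chip)."""

    pinch_width_um: float = 20.0
    pinch_length_um: float = 80.0
    pinch_height_um: float = 40.0
    branch_width_um: float = BRANCH_WIDTH_UM
    branch_lengths_um: list[float] = Field(default_factory=lambda: list(BRANCH_LENGTHS_UM))
    branch_height_um: float = 40.0
    viscosity_pa_s: float = 1.25e-3
    calibrate_thresholds: bool = False  # fit branch I/II windows to solute observations

    @field_validator("branch_lengths_um")
    @classmethod
    def _five_branches(cls, v: list[float]) -> list[float]:
        if len(v) != 5:
            raise ValueError("exactly 5 branch lengths required (outlets I..V)")
        return v

    def to_network(self) -> DeviceNetwork:
        net = DeviceNetwork(
            pinch=ChannelSegment(
                "pinch", self.pinch_length_um, self.pinch_width_um, self.pinch_height_um
            ),
            branches=tuple(
                ChannelSegment(f"branch_{i}", L, self.branch_width_um, self.branch_height_um)
                for i, L in enumerate(self.branch_lengths_um)
            ),
            viscosity_pa_s=self.viscosity_pa_s,
        )
        if self.calibrate_thresholds:
            net = calibrate_to_thresholds(net)
        return net


class PhysicsConfig(BaseModel):
    """Fluid and membrane constants for the mechanics stage."""

    eta_continuous_pa_s: float = 1.25e-3  # 15% v/v glycerol buffer
    eta_droplet_pa_s: float = 9.375e-3  # octanol: lambda = 7.5
    stretch_modulus_n_per_m: float = 0.25  # kappa_A of DOPC
    ca_critical: float = 1e-3
    profile_factor: float = 1.0


class SyntheticConfig(BaseModel):
    """Stated world of the synthetic purification scenario."""

    guv_count: int = 30
    guv_diameter_mean_um: float = 20.6
    guv_diameter_sd_um: float = 2.2
    droplet_count: int = 12
    droplet_median_um: float = 3.0
    droplet_sigma_ln: float = 1.0
    droplet_diameter_large_um: float = 30.0  # representative oversized droplet
    viscosity_ratio: float = 7.5
    free_dye_level: float = 3200.0
    lumen_intensity: float = 2500.0
    image_size_px: int = 512
    pixel_size_um: float = 0.5
    ring_width_px: float = 4.0
    psf_sigma_px: float = 1.0
    noise_sd: float = 15.0
    background_mean: float = 48.0
    out_of_focus_fraction: float = 0.1

    def optics(self) -> OpticsSpec:
        return OpticsSpec(
            image_shape=(self.image_size_px, self.image_size_px),
            pixel_size_um=self.pixel_size_um,
            ring_width_px=self.ring_width_px,
            psf_sigma_px=self.psf_sigma_px,
            noise_sd=self.noise_sd,
            background_mean=self.background_mean,
            out_of_focus_fraction=self.out_of_focus_fraction,
        )

    def guv_population(self) -> VesiclePopulationSpec:
        return VesiclePopulationSpec(
            count=self.guv_count,
            diameter_mean_um=self.guv_diameter_mean_um,
            diameter_sd_um=self.guv_diameter_sd_um,
        )

    def mixture(self) -> MixtureSpec:
        return MixtureSpec(
            vesicles=self.guv_population(),
            droplet_count=self.droplet_count,
            droplet_median_um=self.droplet_median_um,
            droplet_sigma_ln=self.droplet_sigma_ln,
            viscosity_ratio=self.viscosity_ratio,
            free_dye_level=self.free_dye_level,
        )


class ImagingConfig(BaseModel):
    """Detection and measurement parameters."""

    radius_min_px: int = 14
    radius_max_px: int = 30
    canny_sigma: float = 2.0
    accumulator_threshold: float = 0.45
    annulus_halfwidth_px: float = 2.0
    refine_mode: str = "disk"  # outlet images show lumen-dye disks
    background_margin_px: float = 4.0
    blur_quantile: float = 0.2
    histogram_bins: int = 64

    @property
    def radius_range(self) -> tuple[int, int]:
        return self.radius_min_px, self.radius_max_px


class FretConfig(BaseModel):
    """Fusion-assay simulation and analysis parameters."""

    enabled: bool = True
    x_transfer_true_mol_percent: float = 0.073
    suv_label_mol_percent: float = 0.1
    calibration_baseline: float = 0.25
    calibration_slope: float = 0.26
    calibration_levels: list[float] = Field(
        default_factory=lambda: [0.0, 0.1, 0.2, 0.3, 0.4, 0.5]
    )
    calibration_noise_sd: float = 0.0
    n_images: int = 1
    guv_count_per_image: int = 10
    R_guv_um: float = 10.0
    r_suv_um: float = 0.065


class RunConfig(BaseModel):
    """Complete, schema-validated pipeline configuration.

    All five stage blocks are required keys when loading from a mapping or
    file (``RunConfig.default()`` builds one with every default in place).
    """

    device: DeviceConfig
    physics: PhysicsConfig
    synthetic: SyntheticConfig
    imaging: ImagingConfig
    fret: FretConfig
    seed: int = 0
    ratio: float = 1.6  # Q_ws / Q_GUVs
    Q_guv_ul_per_h: float = 33.4
    out_dir: str | None = None

    @classmethod
    def default(cls, **overrides) -> "RunConfig":
        return cls(
            device=DeviceConfig(),
            physics=PhysicsConfig(),
            synthetic=SyntheticConfig(),
            imaging=ImagingConfig(),
            fret=FretConfig(),
            **overrides,
        )

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return cls.model_validate(data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))
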