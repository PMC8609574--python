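"""Scalar vesicle/droplet mechanics for the pinched segment.

Covers the flow velocity in the pinch, the membrane capillary number built
on the area-stretching modulus, the rupture velocity bound, motion-blur
velocimetry, and the reduced volume (asphericity) of a vesicle.

Units follow microfluidics practice at the interface (uL/h, um, nm, fps)
and SI internally (m/s, Pa*s, N/m).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

UL_PER_H_TO_M3_PER_S = 1e-9 / 3600.0

#: critical membrane capillary number below which DOPC GUVs stay intact
CA_CRITICAL = 1e-3
#: area-stretching modulus of a DOPC bilayer, N/m
KAPPA_A_DOPC = 0.25
#: viscosity of the 15% v/v glycerol working buffer, Pa*s
ETA_GLYCEROL_BUFFER = 1.25e-3


@dataclass(frozen=True)
class FluidSpec:
    """Continuous (suspending) and droplet-phase viscosities, Pa*s."""

    eta_continuous: float = ETA_GLYCEROL_BUFFER
    eta_droplet: float = 7.5 * ETA_GLYCEROL_BUFFER  # octanol, lambda ~ 7.5

    def __post_init__(self) -> None:
        if self.eta_continuous <= 0 or self.eta_droplet <= 0:
            raise ValueError("viscosities must be > 0")

    @property
    def viscosity_ratio(self) -> float:
        return self.eta_droplet / self.eta_continuous


@dataclass(frozen=True)
class StabilityReport:
    """Outcome of the capillary-number stability check for one vesicle size."""

    capillary_number: float
    threshold: float
    velocity_m_per_s: float
    rupture_velocity_m_per_s: float

    @property
    def stable(self) -> bool:
        return self.capillary_number < self.threshold


def mean_velocity(
    Q_total_ul_per_h: float,
    width_um: float,
    height_um: float,
    profile_factor: float = 1.0,
) -> float:
    """Characteristic flow velocity (m/s) in a rectangular channel.

    ``profile_factor = 1`` returns the cross-section mean Q/(w*h); larger
    factors give a characteristic peak velocity of the laminar profile.
    """
    if Q_total_ul_per_h <= 0:
        raise ValueError("total flow rate must be > 0")
    if width_um <= 0 or height_um <= 0:
        raise ValueError("channel dimensions must be > 0")
    if profile_factor <= 0:
        raise ValueError("profile_factor must be > 0")
    area_m2 = (width_um * 1e-6) * (height_um * 1e-6)
    return profile_factor * Q_total_ul_per_h * UL_PER_H_TO_M3_PER_S / area_m2


def capillary_number(
    fluid: FluidSpec,
    velocity_m_per_s: float,
    radius_um: float,
    stretch_modulus_n_per_m: float = KAPPA_A_DOPC,
    pinch_width_um: float = 20.0,
) -> float:
    """Membrane capillary number Ca = eta_c * v * R / (kappa_A * w).

    Ratio of the viscous stress scale eta_c*v*R/w acting over the vesicle to
    the membrane's area-stretching resistance kappa_A.  Small Ca means the
    membrane tension stays far below the lysis tension.
    """
    if velocity_m_per_s < 0:
        raise ValueError("velocity must be >= 0")
    if radius_um <= 0 or stretch_modulus_n_per_m <= 0 or pinch_width_um <= 0:
        raise ValueError("radius, stretch modulus and width must be > 0")
    return (
        fluid.eta_continuous
        * velocity_m_per_s
        * (radius_um * 1e-6)
        / (stretch_modulus_n_per_m * pinch_width_um * 1e-6)
    )


def rupture_velocity_bound(
    fluid: FluidSpec,
    radius_um: float,
    stretch_modulus_n_per_m: float = KAPPA_A_DOPC,
    pinch_width_um: float = 20.0,
    ca_critical: float = CA_CRITICAL,
) -> float:
    """Flow velocity (m/s) at which the capillary number reaches ``ca_critical``.

    Exact inverse of :func:`capillary_number`; decreases with vesicle radius.
    """
    if ca_critical <= 0:
        raise ValueError("critical capillary number must be > 0")
    return (
        ca_critical
        * stretch_modulus_n_per_m
        * (pinch_width_um * 1e-6)
        / (fluid.eta_continuous * radius_um * 1e-6)
    )


def stability_report(
    fluid: FluidSpec,
    velocity_m_per_s: float,
    radius_um: float,
    stretch_modulus_n_per_m: float = KAPPA_A_DOPC,
    pinch_width_um: float = 20.0,
    ca_critical: float = CA_CRITICAL,
) -> StabilityReport:
    """Assemble a :class:`StabilityReport` for one vesicle size and velocity."""
    ca = capillary_number(
        fluid, velocity_m_per_s, radius_um, stretch_modulus_n_per_m, pinch_width_um
    )
    v_max = rupture_velocity_bound(
        fluid, radius_um, stretch_modulus_n_per_m, pinch_width_um, ca_critical
    )
    return StabilityReport(
        capillary_number=ca,
        threshold=ca_critical,
        velocity_m_per_s=velocity_m_per_s,
        rupture_velocity_m_per_s=v_max,
    )


def velocity_from_blur(displacement_um: float, fps: float) -> float:
    """Vesicle speed (m/s) from motion blur: u = delta_d / delta_t, delta_t = 1/fps.

    The displacement is the distance between the centers of the two circles
    that bound a blurred vesicle streak within a single exposure.
    """
    if fps <= 0:
        raise ValueError("frame rate must be > 0")
    if displacement_um < 0:
        raise ValueError("displacement must be >= 0")
    return displacement_um * 1e-6 * fps


def reduced_volume(volume_um3: float, radius_um: float) -> float:
    """Reduced volume V = V_vesicle / V_sphere(R); 1 for a sphere, <1 if deflated."""
    if radius_um <= 0:
        raise ValueError("radius must be > 0")
    if volume_um3 < 0:
        raise ValueError("volume must be >= 0")
    return volume_um3 / ((4.0 / 3.0) * np.pi * radius_um**3)
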