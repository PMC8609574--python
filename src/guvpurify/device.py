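"""Lumped hydraulic model of the pinched-flow-fractionation (PFF) purification chip.

The device is a Y-junction feeding a narrow pinched segment (width ``w``) that
opens into a broadened section drained by five branch channels (outlets I-V,
outlet I adjacent to the GUV-mixture sidewall).  All outlets sit at a common
pressure, so with imposed inlet flow rates the flow split among branches is a
pure resistor-divider problem; the lateral structure of the laminar flow in
the pinch then decides which outlet window a given component class reaches.

Replaces a finite-element laminar-flow simulation with:

* exact series solution for rectangular-duct hydraulic resistance,
* Kirchhoff solution of the branch network,
* an analytic streamline coordinate (plug or parabolic flux inversion)
  across the pinch width,
* a one-sided-fan construction for the separation angle theta.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from scipy.optimize import brentq

OUTLET_LABELS = ("I", "II", "III", "IV", "V")

#: width (um) of each of the five branch channels
BRANCH_WIDTH_UM = 300.0
#: branch lengths (um); II and IV are longer so that the short branches
#: I, III, V draw slightly more flow, widening outlet III's streamline window
BRANCH_LENGTHS_UM = (4150.0, 4700.0, 4150.0, 4700.0, 4150.0)


@dataclass(frozen=True)
class ChannelSegment:
    """A straight rectangular microchannel segment.

    All dimensions in micrometres.  The resistance formula uses the smaller
    cross-sectional dimension cubed, so width/height order does not matter.
    """

    name: str
    length_um: float
    width_um: float
    height_um: float

    def __post_init__(self) -> None:
        for attr in ("length_um", "width_um", "height_um"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{self.name}: {attr} must be > 0")


def channel_resistance(
    seg: ChannelSegment,
    viscosity_pa_s: float,
    *,
    method: str = "series",
    n_terms: int = 50,
) -> float:
    """Hydraulic resistance (Pa*s/m^3) of a rectangular duct.

    ``method="series"`` evaluates the exact Fourier-series solution for
    pressure-driven flow in a rectangular cross-section truncated at
    ``n_terms`` odd terms; ``method="approx"`` uses the familiar one-term
    approximation ``12 mu L / (w h^3 (1 - 0.63 h/w))`` (h = smaller side).
    """
    if viscosity_pa_s <= 0:
        raise ValueError("viscosity must be > 0")
    w = max(seg.width_um, seg.height_um) * 1e-6
    h = min(seg.width_um, seg.height_um) * 1e-6
    length = seg.length_um * 1e-6
    if method == "approx":
        correction = 1.0 - 0.63 * h / w
    elif method == "series":
        n = np.arange(1, 2 * n_terms, 2, dtype=float)  # odd terms
        correction = 1.0 - (192.0 * h / (np.pi**5 * w)) * np.sum(
            np.tanh(n * np.pi * w / (2.0 * h)) / n**5
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return 12.0 * viscosity_pa_s * length / (w * h**3 * correction)


def _default_branches() -> tuple[ChannelSegment, ...]:
    return tuple(
        ChannelSegment(f"branch_{lab}", L, BRANCH_WIDTH_UM, 40.0)
        for lab, L in zip(OUTLET_LABELS, BRANCH_LENGTHS_UM)
    )


@dataclass(frozen=True)
class DeviceNetwork:
    """Geometry of the purification module.

    Defaults are the published chip: pinch w = 20 um, l = 80 um, h = 40 um;
    five 300 um-wide branches, lengths 4150 um (I, III, V) and 4700 um
    (II, IV).  Inlet segments only set absolute pressures, not the split,
    and carry nominal dimensions.  ``branch_resistance_scale`` holds optional
    per-branch calibration factors (see :func:`calibrate_to_thresholds`).
    """

    inlet_ws: ChannelSegment = ChannelSegment("inlet_ws", 5000.0, 100.0, 40.0)
    inlet_guv: ChannelSegment = ChannelSegment("inlet_guv", 5000.0, 100.0, 40.0)
    pinch: ChannelSegment = ChannelSegment("pinch", 80.0, 20.0, 40.0)
    branches: tuple[ChannelSegment, ...] = field(default_factory=_default_branches)
    outlet_pressure_pa: float = 1e5
    viscosity_pa_s: float = 1.25e-3  # 15% v/v glycerol buffer
    branch_resistance_scale: tuple[float, ...] = (1.0,) * 5

    def __post_init__(self) -> None:
        if len(self.branches) != 5:
            raise ValueError("DeviceNetwork requires exactly 5 branches (I..V)")
        if len(self.branch_resistance_scale) != 5:
            raise ValueError("branch_resistance_scale must have 5 entries")
        if any(s <= 0 for s in self.branch_resistance_scale):
            raise ValueError("branch resistance scales must be > 0")

    def branch_resistances(self) -> np.ndarray:
        return np.array(
            [
                channel_resistance(seg, self.viscosity_pa_s) * s
                for seg, s in zip(self.branches, self.branch_resistance_scale)
            ]
        )

    @property
    def broadened_width_um(self) -> float:
        return float(sum(b.width_um for b in self.branches))


@dataclass(frozen=True)
class FlowState:
    """Solved flow configuration at given inlet rates (uL/h)."""

    Q_ws: float
    Q_guv: float
    outlet_fractions: tuple[float, ...]
    pinched_fraction: float
    theta_deg: float
    junction_pressure_pa: float
    manifold_pressure_pa: float

    @property
    def Q_total(self) -> float:
        return self.Q_ws + self.Q_guv

    @property
    def ratio(self) -> float:
        """Flow-rate ratio Q_ws / Q_guv."""
        return self.Q_ws / self.Q_guv if self.Q_guv > 0 else np.inf

    @property
    def mixture_fraction(self) -> float:
        """Fraction of total volumetric flow carried by the GUV-mixture stream."""
        return self.Q_guv / self.Q_total

    def outlet_flows(self) -> np.ndarray:
        """Volumetric flow (uL/h) through each outlet I..V."""
        return self.Q_total * np.asarray(self.outlet_fractions)

    def cumulative_fractions(self) -> np.ndarray:
        return np.cumsum(self.outlet_fractions)


class ComponentKind(str, Enum):
    SOLUTE = "solute"
    SUV = "suv"
    RIGID_PARTICLE = "rigid_particle"
    GUV = "guv"
    DROPLET = "droplet"


@dataclass(frozen=True)
class ComponentSpec:
    """A filterable object entering the pinch with the GUV-mixture stream."""

    kind: ComponentKind
    diameter_um: float = 0.0
    viscosity_ratio: float | None = None  # lambda = eta_d / eta_c, droplets
    stretch_modulus_n_per_m: float | None = None  # kappa_A, vesicles
    reduced_volume: float = 1.0  # V = V_GUV / V_sphere
    surfactant_stabilized: bool = False
    interfacial_tension_n_per_m: float | None = None  # annotation only

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", ComponentKind(self.kind))
        if self.diameter_um < 0:
            raise ValueError("diameter must be >= 0")
        if self.kind is ComponentKind.DROPLET:
            if self.viscosity_ratio is None or self.viscosity_ratio <= 0:
                raise ValueError("droplets require viscosity_ratio > 0")
        if not (0.0 < self.reduced_volume <= 1.0):
            raise ValueError("reduced_volume must lie in (0, 1]")


def solve_flow_split(
    net: DeviceNetwork,
    Q_ws: float,
    Q_guv: float,
    *,
    profile: str = "parabolic",
) -> FlowState:
    """Kirchhoff solution of the outlet network for imposed inlet flows (uL/h).

    All five branches connect the broadened-section manifold to a common
    outlet pressure, so outlet flow fractions are proportional to branch
    conductance; node pressures follow from the total flow through the pinch.
    """
    if Q_ws < 0 or Q_guv < 0:
        raise ValueError("flow rates must be >= 0")
    if Q_ws == 0 and Q_guv == 0:
        raise ValueError("at least one inlet flow must be positive")
    R_branch = net.branch_resistances()
    if not np.all(np.isfinite(R_branch)) or np.any(R_branch <= 0):
        raise ValueError("network is disconnected or has non-physical resistances")
    g = 1.0 / R_branch
    fractions = g / g.sum()
    Q_total_si = (Q_ws + Q_guv) * 1e-9 / 3600.0  # uL/h -> m^3/s
    p_manifold = net.outlet_pressure_pa + Q_total_si / g.sum()
    p_junction = p_manifold + Q_total_si * channel_resistance(
        net.pinch, net.viscosity_pa_s
    )
    y_star = pinched_stream_fraction(Q_guv, Q_ws, profile=profile)
    state = FlowState(
        Q_ws=Q_ws,
        Q_guv=Q_guv,
        outlet_fractions=tuple(fractions),
        pinched_fraction=y_star,
        theta_deg=0.0,
        junction_pressure_pa=p_junction,
        manifold_pressure_pa=p_manifold,
    )
    return replace(state, theta_deg=bifurcation_angle(state, net))


def cumulative_flux_fraction(t: float | np.ndarray, profile: str = "parabolic"):
    """Fraction of total flux carried between the wall (t=0) and width fraction t.

    ``plug``: uniform velocity, F = t.  ``parabolic``: 2D Poiseuille profile
    u(t) ~ t(1-t), F = 3t^2 - 2t^3.
    """
    t = np.clip(t, 0.0, 1.0)
    if profile == "plug":
        return t
    if profile == "parabolic":
        return 3.0 * t**2 - 2.0 * t**3
    raise ValueError(f"unknown profile {profile!r}")


def invert_flux_fraction(F: float, profile: str = "parabolic") -> float:
    """Width fraction t such that cumulative_flux_fraction(t) = F."""
    if not 0.0 <= F <= 1.0:
        raise ValueError("flux fraction must lie in [0, 1]")
    if profile == "plug":
        return F
    if F in (0.0, 1.0):
        return F
    return brentq(
        lambda t: cumulative_flux_fraction(t, profile) - F,
        0.0,
        1.0,
        xtol=1e-12,
        rtol=4 * np.finfo(float).eps,
    )


def pinched_stream_fraction(
    Q_guv: float, Q_ws: float, profile: str = "parabolic"
) -> float:
    """Width fraction of the pinch occupied by the focused GUV-mixture stream.

    The mixture is pressed against one sidewall by the washing stream; its
    boundary sits at the lateral position where the integrated flux from the
    wall equals the mixture's share of the total flow rate.
    """
    if Q_guv < 0 or Q_ws < 0:
        raise ValueError("flow rates must be >= 0")
    if Q_guv == 0 and Q_ws == 0:
        raise ValueError("at least one flow must be positive")
    F_mix = Q_guv / (Q_guv + Q_ws)
    return invert_flux_fraction(F_mix, profile)


def bifurcation_angle(
    state: FlowState,
    net: DeviceNetwork,
    *,
    reference_distance_um: float | None = None,
    fan_tangent: float = 1.1,
) -> float:
    """Separation angle theta (degrees) between the two bifurcating streams.

    The pinch's mixture-side wall continues straight into the broadened
    section while the opposite wall steps away; near the expansion the
    washing stream fans into the widening channel.  The local width at
    downstream distance d is modelled as ``w + d*fan_tangent`` (capped at
    the full broadened width), and the mixture-stream boundary at distance
    d sits at the same flux fraction of the local width as in the pinch.
    theta is the angle of that boundary streamline relative to the fanning
    washing-side wall, evaluated at d = one pinch width by default.
    ``fan_tangent = 1.1`` reproduces the potential-flow (Laplace
    streamfunction) spreading of a several-fold one-sided sudden expansion
    at that reference distance.

    theta -> 0 as Q_ws -> 0 (no focusing, no bifurcation) and increases
    strictly with Q_ws/Q_guv.
    """
    w = net.pinch.width_um
    d = reference_distance_um if reference_distance_um is not None else w
    if d <= 0:
        raise ValueError("reference distance must be > 0")
    W_local = min(w + d * fan_tangent, net.broadened_width_um)
    y_star = state.pinched_fraction
    lateral = (1.0 - y_star) * (W_local - w)
    return float(np.degrees(np.arctan2(lateral, d)))


@dataclass(frozen=True)
class OutletAssignment:
    """Where a component class exits the device."""

    outlets: tuple[str, ...]
    principal: str
    flux_fraction: float
    ruptured: bool = False
    follows_mixture: bool = False


def _outlet_of_flux(F: float, cum: np.ndarray) -> int:
    """Index of the outlet whose cumulative flow window contains F."""
    idx = int(np.searchsorted(cum, F, side="left"))
    return min(idx, len(cum) - 1)


def assign_outlet(
    comp: ComponentSpec,
    state: FlowState,
    net: DeviceNetwork,
    *,
    profile: str = "parabolic",
    confinement_tolerance: float = 0.5,
) -> OutletAssignment:
    """Assign a component class to outlet(s) I..V.

    Rules:

    * solutes and SUVs co-flow with the mixture stream and exit through
      every outlet whose flow window overlaps the mixture's flux share;
    * deformable droplets (viscosity ratio > 1 or surfactant-stabilized)
      elongate in the pinch, so their center of mass is carried with the
      mixture stream regardless of diameter — same rule as solutes;
    * rigid particles ride the streamline through their center of mass,
      a/2 from the focusing sidewall (classic PFF);
    * GUVs ride the streamline through min(a, w)/2 — vesicles wider than
      the pinch deform to fit and center on the pinch centerline; those
      exceeding w by more than ``confinement_tolerance * w`` are flagged
      as likely ruptured.
    """
    cum = state.cumulative_fractions()
    w = net.pinch.width_um
    kind = comp.kind

    mixture_like = kind in (ComponentKind.SOLUTE, ComponentKind.SUV) or (
        kind is ComponentKind.DROPLET
        and ((comp.viscosity_ratio or 0.0) > 1.0 or comp.surfactant_stabilized)
    )
    if mixture_like:
        F_mix = state.mixture_fraction
        starts = np.concatenate(([0.0], cum[:-1]))
        hit = np.flatnonzero(starts < F_mix)
        outlets = tuple(OUTLET_LABELS[i] for i in hit)
        return OutletAssignment(
            outlets=outlets,
            principal=outlets[0],
            flux_fraction=F_mix,
            follows_mixture=True,
        )

    if kind is ComponentKind.RIGID_PARTICLE:
        t = min(comp.diameter_um, w) / (2.0 * w)
        F = float(cumulative_flux_fraction(t, profile))
        idx = _outlet_of_flux(F, cum)
        return OutletAssignment(
            outlets=(OUTLET_LABELS[idx],),
            principal=OUTLET_LABELS[idx],
            flux_fraction=F,
        )

    if kind is ComponentKind.GUV:
        t = min(comp.diameter_um, w) / (2.0 * w)
        F = float(cumulative_flux_fraction(t, profile))
        idx = _outlet_of_flux(F, cum)
        ruptured = comp.diameter_um > (1.0 + confinement_tolerance) * w
        return OutletAssignment(
            outlets=(OUTLET_LABELS[idx],),
            principal=OUTLET_LABELS[idx],
            flux_fraction=F,
            ruptured=ruptured,
        )

    if kind is ComponentKind.DROPLET:
        # non-deforming droplet (lambda <= 1, no surfactant): behaves rigidly
        t = min(comp.diameter_um, w) / (2.0 * w)
        F = float(cumulative_flux_fraction(t, profile))
        idx = _outlet_of_flux(F, cum)
        return OutletAssignment(
            outlets=(OUTLET_LABELS[idx],),
            principal=OUTLET_LABELS[idx],
            flux_fraction=F,
        )

    raise ValueError(f"unknown component kind {kind!r}")


def calibrate_to_thresholds(
    net: DeviceNetwork,
    ratio_I_and_II: float = 1.3,
    ratio_I_only: float = 2.4,
) -> DeviceNetwork:
    """Scale branch I and II resistances so solute thresholds match observation.

    The pure-geometry network under-sizes outlets I and II: a solute stream
    is observed to fit within outlets I+II at flow ratio ``ratio_I_and_II``
    and within outlet I alone above ``ratio_I_only``.  Those two conditions
    fix the cumulative windows c1 = 1/(1+ratio_I_only) and
    c2 = 1/(1+ratio_I_and_II); branches III-V keep their geometric
    proportions.  Returns a new network with per-branch resistance scales.

    (A single shared factor cannot satisfy both thresholds, hence the
    two-factor fit.)
    """
    if not ratio_I_only > ratio_I_and_II > 0:
        raise ValueError("require ratio_I_only > ratio_I_and_II > 0")
    f_I = 1.0 / (1.0 + ratio_I_only)
    c2 = 1.0 / (1.0 + ratio_I_and_II)
    f_II = c2 - f_I
    R_geom = np.array(
        [channel_resistance(seg, net.viscosity_pa_s) for seg in net.branches]
    )
    g_geom = 1.0 / R_geom
    G_rest = g_geom[2:].sum()
    G_total = G_rest / (1.0 - c2)
    g_target = g_geom.copy()
    g_target[0] = f_I * G_total
    g_target[1] = f_II * G_total
    scale = tuple(float(s) for s in (g_geom / g_target))
    return dataclasses.replace(net, branch_resistance_scale=scale)
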