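"""FRET lipid-mixing analysis and SUV-GUV fusion stoichiometry.

The lipid-mixing readout is the relative FRET efficiency
``E_FRET = I_Rh / (I_Rh + I_NBD)`` between a donor (DOPE-NBD, fixed in the
GUV membrane) and an acceptor (DOPE-Rh, delivered by fusing SUVs).  A
calibration of E against known acceptor mole percentages converts the
measured shift after fusion into the transferred acceptor fraction, which a
geometric lipid count turns into the number of fused SUVs per GUV and a
charge balance.  A dithionite-bleaching model classifies lamellarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

#: mean membrane area occupied by one lipid, Angstrom^2
AREA_PER_LIPID_A2 = 68.0


def fret_efficiency(I_rh: float, I_nbd: float) -> float:
    """Relative FRET efficiency E = I_Rh / (I_Rh + I_NBD), in [0, 1]."""
    if I_rh < 0 or I_nbd < 0:
        raise ValueError("intensities must be >= 0")
    total = I_rh + I_nbd
    if total == 0:
        raise ValueError("both intensities are zero")
    return I_rh / total


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FretCalibration:
    """Fitted monotone map acceptor mol% -> E_FRET with its valid range."""

    levels: pd.DataFrame  # columns mol_percent, E_mean[, E_sd]
    model: str  # "linear" | "monotone_spline"
    intercept: float
    slope: float
    interpolator: PchipInterpolator | None
    monotone: bool

    @property
    def valid_range(self) -> tuple[float, float]:
        x = self.levels["mol_percent"]
        return float(x.min()), float(x.max())

    def predict(self, mol_percent):
        x = np.asarray(mol_percent, dtype=float)
        if self.model == "linear":
            return self.intercept + self.slope * x
        return self.interpolator(x)

    @property
    def baseline(self) -> float:
        """Donor-only apparent efficiency E(0)."""
        return float(self.predict(0.0))


def fit_calibration(table: pd.DataFrame, model: str = "linear") -> FretCalibration:
    """Fit the E_FRET(x) calibration from (mol%, E) level pairs.

    Requires at least two distinct acceptor levels including x = 0 (the
    donor-only baseline).  ``linear`` fits by least squares;
    ``monotone_spline`` uses a shape-preserving (PCHIP) interpolant, exact
    on the knots.  Non-monotone data under the linear model still fit, but
    the violation is flagged on the result.
    """
    table = pd.DataFrame(table).sort_values("mol_percent").reset_index(drop=True)
    x = table["mol_percent"].to_numpy(dtype=float)
    y = table["E_mean"].to_numpy(dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("calibration needs >= 2 distinct acceptor levels")
    if x.min() > 1e-12:
        raise ValueError("calibration must include the zero-acceptor baseline")
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("E values must lie in (0, 1)")
    monotone = bool(np.all(np.diff(y) >= 0))
    if model == "linear":
        slope, intercept = np.polyfit(x, y, 1)
        if not monotone:
            warnings.warn("calibration data are not monotone in mol%", stacklevel=2)
        return FretCalibration(
            levels=table,
            model="linear",
            intercept=float(intercept),
            slope=float(slope),
            interpolator=None,
            monotone=monotone,
        )
    if model == "monotone_spline":
        if not monotone:
            raise ValueError("monotone_spline requires non-decreasing E levels")
        interp = PchipInterpolator(x, y)
        return FretCalibration(
            levels=table,
            model="monotone_spline",
            intercept=float(y[0]),
            slope=float(np.polyfit(x, y, 1)[0]),
            interpolator=interp,
            monotone=True,
        )
    raise ValueError(f"unknown calibration model {model!r}")


def invert_calibration(
    cal: FretCalibration,
    E_measured: float,
    *,
    baseline_tolerance: float = 0.05,
) -> float:
    """Acceptor mol% in the GUV membrane giving the measured E_FRET.

    Monotone inversion by bisection to 1e-10 mol%.  E below the
    donor-only baseline (within ``baseline_tolerance``) returns 0 with a
    warning; E above the calibrated range raises (no extrapolation).
    """
    lo, hi = cal.valid_range
    E_lo = float(cal.predict(lo))
    E_hi = float(cal.predict(hi))
    if E_measured > E_hi:
        raise ValueError(
            f"E = {E_measured:.4f} above calibration range (max {E_hi:.4f}); "
            "extrapolation refused"
        )
    if E_measured < E_lo:
        if E_measured < E_lo - baseline_tolerance:
            raise ValueError(
                f"E = {E_measured:.4f} far below the donor-only baseline {E_lo:.4f}"
            )
        warnings.warn(
            "measured E below the donor-only baseline; returning 0 mol%",
            stacklevel=2,
        )
        return 0.0
    return brentq(
        lambda x: float(cal.predict(x)) - E_measured, lo, hi, xtol=1e-10
    )


# ---------------------------------------------------------------------------
# geometric lipid counting
# ---------------------------------------------------------------------------


def lipid_count(
    radius_um: float,
    area_per_lipid_a2: float = AREA_PER_LIPID_A2,
    layers: int = 1,
) -> float:
    """Number of lipids on a sphere of the given radius.

    ``layers * 4 pi R^2 / A_lipid``; the single-layer convention
    (``layers=1``) is the default counting convention used throughout the
    stoichiometry (both leaflets would double every count and cancel in the
    SUV-per-GUV ratio anyway).
    """
    if radius_um <= 0:
        raise ValueError("radius must be > 0")
    if area_per_lipid_a2 <= 0:
        raise ValueError("area per lipid must be > 0")
    if layers < 1:
        raise ValueError("layers must be >= 1")
    radius_a = radius_um * 1e4  # um -> Angstrom
    return layers * 4.0 * np.pi * radius_a**2 / area_per_lipid_a2


def fused_suv_count(
    x_transferred_mol_percent: float,
    x_acceptor_suv_mol_percent: float,
    R_guv_um: float,
    r_suv_um: float,
) -> float:
    """Number of SUVs fused per GUV from the transferred acceptor fraction.

    n = (x_transferred * N_GUV) / (x_SUV * N_SUV)
      = (x_transferred / x_SUV) * (R_GUV / r_SUV)^2 —
    the area per lipid and the leaflet convention cancel.
    """
    if x_acceptor_suv_mol_percent <= 0:
        raise ValueError("SUV acceptor label fraction must be > 0")
    if x_transferred_mol_percent < 0:
        raise ValueError("transferred fraction must be >= 0")
    if R_guv_um <= 0 or r_suv_um <= 0:
        raise ValueError("radii must be > 0")
    return (
        x_transferred_mol_percent
        / x_acceptor_suv_mol_percent
        * (R_guv_um / r_suv_um) ** 2
    )


@dataclass(frozen=True)
class MembraneComposition:
    """Membrane mole fractions plus fluorescent-label content (mol%)."""

    fractions: dict[str, float]
    donor_mol_percent: float = 0.0
    acceptor_mol_percent: float = 0.0

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mole fractions must sum to 1, got {total!r}")
        if any(v < 0 for v in self.fractions.values()):
            raise ValueError("mole fractions must be >= 0")
        for label, value in (
            ("donor", self.donor_mol_percent),
            ("acceptor", self.acceptor_mol_percent),
        ):
            if not 0.0 <= value <= 100.0:
                raise ValueError(f"{label} label must be a mol% in [0, 100]")

    def fraction(self, lipid: str) -> float:
        return self.fractions.get(lipid, 0.0)


def guv_composition() -> MembraneComposition:
    """Negatively charged GUV membrane: DOPC:DOPG 3:1 with 1 mol% DOPE-NBD."""
    return MembraneComposition(
        fractions={"DOPC": 0.7425, "DOPG": 0.2475, "DOPE-NBD": 0.01},
        donor_mol_percent=1.0,
    )


def suv_composition() -> MembraneComposition:
    """Positively charged SUV membrane: DOPE:DOTAP 4:1 with 0.1 mol% DOPE-Rh."""
    return MembraneComposition(
        fractions={"DOPE": 0.7992, "DOTAP": 0.1998, "DOPE-Rh": 0.001},
        acceptor_mol_percent=0.1,
    )


def charge_balance(
    n_suvs: float,
    suv_comp: MembraneComposition,
    guv_comp: MembraneComposition,
    R_guv_um: float,
    r_suv_um: float,
    area_per_lipid_a2: float = AREA_PER_LIPID_A2,
) -> tuple[float, float]:
    """(n_DOTAP transferred from SUVs, n_DOPG resident in the GUV membrane).

    Both counts use the single-layer lipid count; comparable magnitudes
    indicate that fusion proceeded long enough to neutralise the GUV's
    negative surface charge.
    """
    if n_suvs < 0:
        raise ValueError("n_suvs must be >= 0")
    N_suv = lipid_count(r_suv_um, area_per_lipid_a2)
    N_guv = lipid_count(R_guv_um, area_per_lipid_a2)
    n_dotap = n_suvs * suv_comp.fraction("DOTAP") * N_suv
    n_dopg = guv_comp.fraction("DOPG") * N_guv
    return n_dotap, n_dopg


@dataclass(frozen=True)
class FusionStoichiometry:
    """Full stoichiometric account of an SUV-GUV fusion experiment."""

    x_transferred_mol_percent: float
    x_acceptor_suv_mol_percent: float
    R_guv_um: float
    r_suv_um: float
    area_per_lipid_a2: float
    n_guv_lipids: float
    n_suv_lipids: float
    n_suvs: float
    n_dotap: float
    n_dopg: float


def fusion_stoichiometry(
    x_transferred_mol_percent: float,
    *,
    suv_comp: MembraneComposition | None = None,
    guv_comp: MembraneComposition | None = None,
    R_guv_um: float = 10.0,
    r_suv_um: float = 0.065,
    area_per_lipid_a2: float = AREA_PER_LIPID_A2,
) -> FusionStoichiometry:
    """Assemble the complete stoichiometry report for a measured transfer."""
    suv_comp = suv_comp if suv_comp is not None else suv_composition()
    guv_comp = guv_comp if guv_comp is not None else guv_composition()
    n = fused_suv_count(
        x_transferred_mol_percent,
        suv_comp.acceptor_mol_percent,
        R_guv_um,
        r_suv_um,
    )
    n_dotap, n_dopg = charge_balance(
        n, suv_comp, guv_comp, R_guv_um, r_suv_um, area_per_lipid_a2
    )
    return FusionStoichiometry(
        x_transferred_mol_percent=x_transferred_mol_percent,
        x_acceptor_suv_mol_percent=suv_comp.acceptor_mol_percent,
        R_guv_um=R_guv_um,
        r_suv_um=r_suv_um,
        area_per_lipid_a2=area_per_lipid_a2,
        n_guv_lipids=lipid_count(R_guv_um, area_per_lipid_a2),
        n_suv_lipids=lipid_count(r_suv_um, area_per_lipid_a2),
        n_suvs=n,
        n_dotap=n_dotap,
        n_dopg=n_dopg,
    )


# ---------------------------------------------------------------------------
# dithionite lamellarity assay
# ---------------------------------------------------------------------------


class Lamellarity(str, Enum):
    UNILAMELLAR = "unilamellar"
    MULTILAMELLAR = "multilamellar"
    INCONCLUSIVE = "inconclusive"


def dithionite_expected_fraction(bilayers: int) -> float:
    """Fluorescence remaining after dithionite reduces the outermost leaflet.

    With the NBD label distributed equally over all ``2 * bilayers``
    leaflets and only the outermost accessible, the surviving fraction is
    ``(2 b - 1) / (2 b)``: 0.5 for a unilamellar membrane, approaching 1 as
    the number of bilayers grows.
    """
    if bilayers < 1:
        raise ValueError("bilayers must be >= 1")
    return (2.0 * bilayers - 1.0) / (2.0 * bilayers)


def dithionite_classify(
    measured_fraction: float,
    measured_sd: float,
    k: float = 1.0,
) -> Lamellarity:
    """Classify lamellarity from the post-dithionite fluorescence fraction.

    Unilamellar if the measurement lies within ``k`` sd of the unilamellar
    expectation (0.5) and more than ``k`` sd from the two-bilayer
    expectation (0.75); multilamellar in the reverse case; otherwise
    inconclusive.
    """
    if not 0.0 <= measured_fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if measured_sd <= 0:
        raise ValueError("measurement sd must be > 0")
    near_uni = abs(measured_fraction - dithionite_expected_fraction(1)) <= k * measured_sd
    near_multi = abs(measured_fraction - dithionite_expected_fraction(2)) <= k * measured_sd
    if near_uni and not near_multi:
        return Lamellarity.UNILAMELLAR
    if near_multi and not near_uni:
        return Lamellarity.MULTILAMELLAR
    return Lamellarity.INCONCLUSIVE


# ---------------------------------------------------------------------------
# image-based recovery
# ---------------------------------------------------------------------------


def efficiency_from_images(
    stack: np.ndarray,
    channels: tuple[str, str],
    radius_range: tuple[int, int],
    *,
    annulus_halfwidth: float = 2.0,
    detect_channel: int = 0,
    subtract_background: bool = True,
    **detect_kwargs,
) -> pd.DataFrame:
    """Per-vesicle E_FRET from a two-channel (donor, acceptor) image stack.

    Detects vesicles on the donor channel, measures equatorial intensities
    in both channels (background-subtracted by default, using the Gaussian
    background fit of each channel), and returns one row per vesicle with
    the two intensities and E_FRET.
    """
    from . import imaging

    donor_name, acceptor_name = channels
    detections = imaging.detect_vesicles(stack[detect_channel], radius_range, **detect_kwargs)
    imaging.measure_channels(stack, list(channels), detections, annulus_halfwidth)
    bg = {name: 0.0 for name in channels}
    if subtract_background:
        for ci, name in enumerate(channels):
            bg[name] = imaging.background_distribution(stack[ci], detections).fit_mean
    rows = []
    for det in detections:
        I_nbd = max(det.channel_intensities[donor_name] - bg[donor_name], 0.0)
        I_rh = max(det.channel_intensities[acceptor_name] - bg[acceptor_name], 0.0)
        if I_nbd + I_rh == 0:
            continue
        rows.append(
            {
                "x_px": det.x_px,
                "y_px": det.y_px,
                "r_px": det.r_px,
                "I_nbd": I_nbd,
                "I_rh": I_rh,
                "E_fret": fret_efficiency(I_rh, I_nbd),
            }
        )
    return pd.DataFrame(rows)


def recover_transfer(
    images_after: list[np.ndarray],
    channels: tuple[str, str],
    cal: FretCalibration,
    radius_range: tuple[int, int],
    **kwargs,
) -> tuple[float, pd.DataFrame]:
    """Invert the calibration on the population-mean E_FRET after fusion.

    Per-vesicle efficiencies are averaged over all images (mean of
    per-vesicle E, then one inversion), matching how a population-level
    transferred fraction is quoted.  Returns (x_transferred mol%, table).
    """
    tables = [
        efficiency_from_images(stack, channels, radius_range, **kwargs)
        for stack in images_after
    ]
    table = pd.concat(tables, ignore_index=True)
    if table.empty:
        raise ValueError("no vesicles detected in the after-fusion images")
    E_mean = float(table["E_fret"].mean())
    return invert_calibration(cal, E_mean), table
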