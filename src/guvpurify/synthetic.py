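"""Seeded synthetic-data generator with per-object ground truth.

Emulates the statistical structure of the study's raw data — GUV populations
(monodisperse, from droplet-microfluidic assembly, and polydisperse, from
electroformation), octanol droplets, free-dye background and two-channel
fluorescence micrographs with ring-shaped membrane signatures — so that every
analysis stage can be tested against known truth without any downloads.

Image convention: 0-based indices, pixel-center coordinates, row-major
arrays ``(channel, y, x)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

logger = logging.getLogger(__name__)

GROUND_TRUTH_COLUMNS = (
    "id",
    "x_px",
    "y_px",
    "r_px",
    "channel",
    "ring_intensity",
    "in_focus",
)


# ---------------------------------------------------------------------------
# population specs
# ---------------------------------------------------------------------------


def _validate_fractions(composition: dict[str, float] | None) -> None:
    if composition:
        total = sum(composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mole fractions must sum to 1, got {total!r}")
        if any(v < 0 for v in composition.values()):
            raise ValueError("mole fractions must be >= 0")


@dataclass(frozen=True)
class VesiclePopulationSpec:
    """Gaussian-diameter vesicle population with membrane composition."""

    count: int
    diameter_mean_um: float
    diameter_sd_um: float
    composition: dict[str, float] | None = None
    label_channels: dict[str, float] | None = None  # channel -> labeled mol%

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if self.diameter_sd_um < 0:
            raise ValueError("diameter sd must be >= 0")
        if self.diameter_mean_um <= 0:
            raise ValueError("diameter mean must be > 0")
        _validate_fractions(self.composition)


def ola_population(count: int = 100) -> VesiclePopulationSpec:
    """Monodisperse GUVs from on-chip assembly: diameter 20.6 +/- 2.2 um (R = 10.3 +/- 1.1)."""
    return VesiclePopulationSpec(
        count=count,
        diameter_mean_um=20.6,
        diameter_sd_um=2.2,
        composition={"DOPC": 0.7425, "DOPG": 0.2475, "DOPE-NBD": 0.01},
        label_channels={"nbd": 1.0},
    )


def electroformed_population(count: int = 300) -> VesiclePopulationSpec:
    """Polydisperse electroformed giant vesicles: diameter 15 +/- 9 um."""
    return VesiclePopulationSpec(
        count=count,
        diameter_mean_um=15.0,
        diameter_sd_um=9.0,
        composition={"DPhPC": 0.9962, "Liss-Rhod-PE": 0.0038},
        label_channels={"rh": 0.38},
    )


def suv_population(count: int = 1000) -> VesiclePopulationSpec:
    """Positively charged SUVs (r = 65 nm) carrying the FRET acceptor label."""
    return VesiclePopulationSpec(
        count=count,
        diameter_mean_um=0.13,
        diameter_sd_um=0.013,
        composition={"DOPE": 0.7992, "DOTAP": 0.1998, "DOPE-Rh": 0.001},
        label_channels={"rh": 0.1},
    )


@dataclass(frozen=True)
class MixtureSpec:
    """The unpurified product stream: GUVs + octanol droplets + free dye (+ SUVs)."""

    vesicles: VesiclePopulationSpec = field(default_factory=ola_population)
    droplet_count: int = 150
    droplet_median_um: float = 3.0  # log-normal median
    droplet_sigma_ln: float = 1.0  # broad: nm to tens of um
    viscosity_ratio: float = 7.5  # octanol in aqueous buffer
    free_dye_level: float = 3200.0  # counts added to background where dye present
    suvs: VesiclePopulationSpec | None = None

    def __post_init__(self) -> None:
        if self.viscosity_ratio <= 0:
            raise ValueError("viscosity ratio must be > 0")
        if self.free_dye_level < 0:
            raise ValueError("free dye level must be >= 0")
        if self.droplet_count < 0:
            raise ValueError("droplet count must be >= 0")


@dataclass(frozen=True)
class OpticsSpec:
    """Imaging model: geometry, PSF, noise and focus behaviour."""

    image_shape: tuple[int, int] = (512, 512)  # (ny, nx)
    pixel_size_um: float = 0.5
    ring_width_px: float = 4.0
    psf_sigma_px: float = 1.0
    noise_sd: float = 15.0
    background_mean: float = 48.0
    out_of_focus_fraction: float = 0.1
    bit_depth: int = 16
    defocus_sigma_factor: float = 5.0  # PSF inflation for out-of-focus objects
    quantize: bool = True  # round to integer counts (camera ADC)

    def __post_init__(self) -> None:
        positives = (
            self.pixel_size_um,
            self.ring_width_px,
            self.bit_depth,
        )
        if any(v <= 0 for v in positives) or any(s <= 0 for s in self.image_shape):
            raise ValueError("optics dimensions must be strictly positive")
        if self.psf_sigma_px < 0 or self.noise_sd < 0 or self.background_mean < 0:
            raise ValueError("psf sigma, noise sd and background must be >= 0")
        if not 0.0 <= self.out_of_focus_fraction <= 1.0:
            raise ValueError("out_of_focus_fraction must lie in [0, 1]")

    @property
    def max_count(self) -> int:
        return 2**self.bit_depth - 1


@dataclass(frozen=True)
class SceneObject:
    """One renderable object with its per-channel truth."""

    id: int
    x_px: float
    y_px: float
    r_px: float
    intensities: dict[str, float]  # channel -> true amplitude
    appearance: dict[str, str]  # channel -> "ring" | "disk"
    in_focus: bool = True


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def sample_population(spec: VesiclePopulationSpec, seed: int) -> pd.DataFrame:
    """Draw vesicle diameters ~ N(mean, sd); non-positive draws are resampled.

    Returns a frame with columns ``id, diameter_um, radius_um``.
    """
    rng = np.random.default_rng(seed)
    if spec.count == 0:
        return pd.DataFrame(columns=["id", "diameter_um", "radius_um"])
    d = rng.normal(spec.diameter_mean_um, spec.diameter_sd_um, size=spec.count)
    while np.any(d <= 0):
        bad = d <= 0
        d[bad] = rng.normal(spec.diameter_mean_um, spec.diameter_sd_um, bad.sum())
    return pd.DataFrame(
        {"id": np.arange(spec.count), "diameter_um": d, "radius_um": d / 2.0}
    )


def sample_droplets(mix: MixtureSpec, seed: int) -> pd.DataFrame:
    """Log-normal octanol-droplet diameters (um)."""
    rng = np.random.default_rng(seed)
    d = rng.lognormal(math.log(mix.droplet_median_um), mix.droplet_sigma_ln, mix.droplet_count)
    return pd.DataFrame(
        {"id": np.arange(mix.droplet_count), "diameter_um": d, "radius_um": d / 2.0}
    )


def place_objects(
    diameters_um: np.ndarray,
    optics: OpticsSpec,
    intensities: dict[str, float],
    appearance: dict[str, str],
    seed: int,
    *,
    intensity_cv: float = 0.1,
    min_gap_px: float = 4.0,
    existing: list[SceneObject] = (),
    id_offset: int = 0,
    max_tries: int = 2000,
) -> list[SceneObject]:
    """Scatter objects at random non-overlapping positions inside the frame.

    Per-object brightness varies log-normally with coefficient of variation
    ``intensity_cv`` (applied jointly to all channels, so intensity ratios —
    hence FRET efficiencies — are preserved).  Raises if an object cannot be
    placed without overlap after ``max_tries`` attempts.
    """
    rng = np.random.default_rng(seed)
    ny, nx = optics.image_shape
    placed: list[SceneObject] = list(existing)
    out: list[SceneObject] = []
    diameters_um = np.asarray(diameters_um, dtype=float)
    n_defocus = int(round(optics.out_of_focus_fraction * len(diameters_um)))
    focus_flags = np.ones(len(diameters_um), dtype=bool)
    if n_defocus:
        focus_flags[rng.choice(len(diameters_um), n_defocus, replace=False)] = False
    for i, d_um in enumerate(diameters_um):
        r_px = d_um / 2.0 / optics.pixel_size_um
        margin = r_px + optics.ring_width_px + 2.0 * optics.psf_sigma_px + 2.0
        if 2 * margin >= min(ny, nx):
            raise ValueError(f"object of radius {r_px:.1f} px does not fit the frame")
        for _ in range(max_tries):
            x = rng.uniform(margin, nx - 1 - margin)
            y = rng.uniform(margin, ny - 1 - margin)
            if all(
                math.hypot(x - o.x_px, y - o.y_px) >= r_px + o.r_px + min_gap_px
                for o in placed
            ):
                break
        else:
            raise ValueError("could not place all objects without overlap")
        brightness = rng.lognormal(0.0, intensity_cv) if intensity_cv > 0 else 1.0
        obj = SceneObject(
            id=id_offset + i,
            x_px=x,
            y_px=y,
            r_px=r_px,
            intensities={c: v * brightness for c, v in intensities.items()},
            appearance=dict(appearance),
            in_focus=bool(focus_flags[i]),
        )
        placed.append(obj)
        out.append(obj)
    return out


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _ring_attenuation(ring_width_px: float, psf_sigma_px: float) -> float:
    """Mean of a PSF-blurred unit annulus profile over the annulus footprint.

    1D radial model: a box of width ``ring_width_px`` convolved with a
    Gaussian of ``psf_sigma_px``, averaged over ``|u| <= ring_width/2``.
    The renderer divides ring amplitudes by this factor so that the
    ground-truth ``ring_intensity`` equals the in-focus equatorial mean an
    ideal measurement recovers.  Equals 1 when the PSF is a delta.
    """
    if psf_sigma_px <= 0:
        return 1.0
    from scipy.stats import norm

    half = ring_width_px / 2.0
    u = np.linspace(-half, half, 257)
    profile = norm.cdf((u + half) / psf_sigma_px) - norm.cdf((u - half) / psf_sigma_px)
    return float(np.trapezoid(profile, u) / ring_width_px)


def _draw(
    canvas: np.ndarray,
    obj: SceneObject,
    channel: str,
    ring_width_px: float,
    ring_scale: float = 1.0,
) -> None:
    amp = obj.intensities.get(channel)
    if amp is None:
        return
    shape = obj.appearance.get(channel, "ring")
    ny, nx = canvas.shape
    half = ring_width_px / 2.0
    extent = int(math.ceil(obj.r_px + half + 1))
    x0 = max(int(obj.x_px) - extent, 0)
    x1 = min(int(obj.x_px) + extent + 1, nx)
    y0 = max(int(obj.y_px) - extent, 0)
    y1 = min(int(obj.y_px) + extent + 1, ny)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(yy - obj.y_px, xx - obj.x_px)
    if shape == "ring":
        mask = np.abs(dist - obj.r_px) <= half
        amp = amp * ring_scale
    elif shape == "disk":
        mask = dist <= obj.r_px
    else:
        raise ValueError(f"unknown appearance {shape!r}")
    canvas[y0:y1, x0:x1][mask] += amp


def render_micrograph(
    objects: list[SceneObject],
    optics: OpticsSpec,
    channels: list[str],
    seed: int,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a multi-channel micrograph and its ground-truth table.

    Each in-focus object is drawn as an annulus (or filled disk) of its true
    amplitude, the channel is convolved with a Gaussian PSF, out-of-focus
    objects get an inflated PSF, Gaussian read noise is added, and pixel
    values are rounded and clipped to the configured bit depth.

    Returns ``(image, ground_truth)`` with ``image`` of shape
    ``(n_channels, ny, nx)`` (uint16 for bit depths <= 16) and one
    ground-truth row per (object, channel).
    """
    for obj in objects:
        if obj.r_px < 2.0:
            raise ValueError(
                f"object {obj.id}: radius {obj.r_px:.2f} px is unresolvable (< 2 px)"
            )
    rng = np.random.default_rng(seed)
    ny, nx = optics.image_shape
    # pre-compensate ring amplitudes for PSF attenuation so that the
    # ground-truth ring_intensity is the in-focus equatorial mean
    ring_scale = 1.0 / _ring_attenuation(optics.ring_width_px, optics.psf_sigma_px)
    stack = np.empty((len(channels), ny, nx), dtype=np.float64)
    for ci, channel in enumerate(channels):
        focused = np.zeros((ny, nx))
        blurred = np.zeros((ny, nx))
        for obj in objects:
            _draw(
                focused if obj.in_focus else blurred,
                obj,
                channel,
                optics.ring_width_px,
                ring_scale,
            )
        if optics.psf_sigma_px > 0:
            focused = gaussian_filter(focused, optics.psf_sigma_px)
        if blurred.any():
            blurred = gaussian_filter(
                blurred, max(optics.psf_sigma_px, 0.5) * optics.defocus_sigma_factor
            )
        img = optics.background_mean + focused + blurred
        if optics.noise_sd > 0:
            img = img + rng.normal(0.0, optics.noise_sd, size=img.shape)
        stack[ci] = img
    clipped = np.count_nonzero((stack < 0) | (stack > optics.max_count))
    if clipped:
        logger.warning("%d pixel values clipped to [0, %d]", clipped, optics.max_count)
    stack = np.clip(stack, 0, optics.max_count)
    if not optics.quantize:
        rows = [
            (obj.id, obj.x_px, obj.y_px, obj.r_px, ch, obj.intensities[ch], obj.in_focus)
            for obj in objects
            for ch in channels
            if ch in obj.intensities
        ]
        truth = pd.DataFrame(rows, columns=list(GROUND_TRUTH_COLUMNS))
        return stack, truth
    stack = np.rint(stack)
    dtype = np.uint16 if optics.bit_depth <= 16 else np.uint32
    rows = [
        (obj.id, obj.x_px, obj.y_px, obj.r_px, ch, obj.intensities[ch], obj.in_focus)
        for obj in objects
        for ch in channels
        if ch in obj.intensities
    ]
    truth = pd.DataFrame(rows, columns=list(GROUND_TRUTH_COLUMNS))
    return stack.astype(dtype), truth


def write_micrograph(path, image: np.ndarray, channels: list[str] | None = None) -> None:
    """Write a multi-page TIFF, one page per channel."""
    import tifffile

    tifffile.imwrite(path, image, metadata={"channels": channels} if channels else None)


def write_preview(path, image: np.ndarray, channel: int = 0) -> None:
    """Write an 8-bit PNG preview of one channel."""
    import imageio.v3 as iio

    chan = image[channel].astype(float)
    lo, hi = chan.min(), chan.max()
    scaled = np.zeros_like(chan) if hi == lo else (chan - lo) / (hi - lo) * 255
    iio.imwrite(path, scaled.astype(np.uint8))


# ---------------------------------------------------------------------------
# FRET forward models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LinearFretRelation:
    """True acceptor-density -> E_FRET map used by the forward simulations.

    ``E(x) = baseline + slope * x`` with x the acceptor (DOPE-Rh) mole
    percentage in the GUV membrane.  The baseline is the donor-only apparent
    efficiency (spectral bleed-through), 0.25 by default.
    """

    baseline: float = 0.25
    slope: float = 0.26  # per mol%

    def __call__(self, mol_percent):
        return self.baseline + self.slope * np.asarray(mol_percent, dtype=float)


def make_calibration_table(
    mol_percents,
    relation=LinearFretRelation(),
    noise_sd: float = 0.0,
    seed: int = 0,
    level_sd: float = 0.02,
) -> pd.DataFrame:
    """Tabulate (acceptor mol%, E_FRET) calibration pairs.

    ``noise_sd`` perturbs the measured mean E at each level; ``level_sd``
    is the recorded per-level measurement scatter.  Values are kept inside
    (0, 1).
    """
    mol_percents = np.asarray(mol_percents, dtype=float)
    if np.any(mol_percents < 0):
        raise ValueError("acceptor mol% must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    rng = np.random.default_rng(seed)
    E = relation(mol_percents).astype(float)
    if noise_sd > 0:
        E = E + rng.normal(0.0, noise_sd, size=E.shape)
    E = np.clip(E, 1e-6, 1.0 - 1e-6)
    return pd.DataFrame(
        {"mol_percent": mol_percents, "E_mean": E, "E_sd": np.full_like(E, level_sd)}
    )


@dataclass(frozen=True)
class FusionExperiment:
    """Before/after image sets from a simulated SUV-GUV fusion assay."""

    images_before: list[np.ndarray]
    images_after: list[np.ndarray]
    truth_before: pd.DataFrame
    truth_after: pd.DataFrame
    channels: tuple[str, str]
    x_transfer_true: float
    relation: LinearFretRelation


def simulate_fusion_experiment(
    x_transfer_true: float,
    guv_spec: VesiclePopulationSpec | None = None,
    optics: OpticsSpec | None = None,
    seed: int = 0,
    *,
    relation: LinearFretRelation = LinearFretRelation(),
    suv_label_mol_percent: float = 0.1,
    total_ring_intensity: float = 3000.0,
    n_images: int = 1,
    intensity_cv: float = 0.1,
) -> FusionExperiment:
    """Forward-model a lipid-mixing FRET experiment.

    GUV membranes carry a fixed donor (NBD) label; fusion transfers
    ``x_transfer_true`` mol% of acceptor (Rh) into the membrane, raising the
    apparent FRET efficiency through ``relation``.  Per-vesicle donor and
    acceptor ring amplitudes split a common intensity budget as
    ``I_rh = E * I_tot`` and ``I_nbd = (1 - E) * I_tot``, so the measured
    per-vesicle ``E_FRET = I_rh / (I_rh + I_nbd)`` recovers E exactly in the
    noiseless limit.
    """
    if x_transfer_true < 0:
        raise ValueError("transferred fraction must be >= 0")
    if x_transfer_true > suv_label_mol_percent:
        raise ValueError(
            "transferred acceptor fraction exceeds the SUV label budget "
            f"({suv_label_mol_percent} mol%)"
        )
    guv_spec = guv_spec if guv_spec is not None else ola_population(count=12)
    optics = optics if optics is not None else OpticsSpec()
    channels = ("nbd", "rh")
    E_before = float(relation(0.0))
    E_after = float(relation(x_transfer_true))
    rng = np.random.default_rng(seed)

    def _render_set(E: float) -> tuple[list[np.ndarray], pd.DataFrame]:
        images, truths = [], []
        for k in range(n_images):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            pop = sample_population(guv_spec, sub_seed)
            objs = place_objects(
                pop["diameter_um"].to_numpy(),
                optics,
                intensities={
                    "nbd": (1.0 - E) * total_ring_intensity,
                    "rh": E * total_ring_intensity,
                },
                appearance={"nbd": "ring", "rh": "ring"},
                seed=sub_seed + 1,
                intensity_cv=intensity_cv,
            )
            img, truth = render_micrograph(objs, optics, list(channels), sub_seed + 2)
            truth["image"] = k
            images.append(img)
            truths.append(truth)
        return images, pd.concat(truths, ignore_index=True)

    images_before, truth_before = _render_set(E_before)
    images_after, truth_after = _render_set(E_after)
    return FusionExperiment(
        images_before=images_before,
        images_after=images_after,
        truth_before=truth_before,
        truth_after=truth_after,
        channels=channels,
        x_transfer_true=x_transfer_true,
        relation=relation,
    )
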