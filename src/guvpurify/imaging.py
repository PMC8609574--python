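"""Micrograph analysis: GUV detection, intensity measurement, statistics.

Vesicles appear as bright rings (membrane label) or disks (lumen dye) on a
noisy background.  Detection runs a circular Hough transform on Canny edges;
per-vesicle intensities are read on the equatorial annulus; the free-dye
background of an outlet image is summarised by a Gaussian fit to the
intensity histogram of all non-vesicle pixels; the purification-efficiency
statistic compares those background levels between outlets.

Image convention matches the synthetic renderer: 0-based indices,
pixel-center coordinates, row-major ``(y, x)`` arrays.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from skimage.feature import canny
from skimage.filters import sobel
from skimage.transform import hough_circle, hough_circle_peaks

logger = logging.getLogger(__name__)


@dataclass
class DetectedVesicle:
    """One detected circle with its per-channel equatorial intensities."""

    x_px: float
    y_px: float
    r_px: float
    r_um: float | None = None
    channel_intensities: dict[str, float] = field(default_factory=dict)
    focus_score: float = 0.0
    accumulator: float = 0.0

    def __post_init__(self) -> None:
        if self.r_px <= 0:
            raise ValueError("radius must be > 0")


@dataclass(frozen=True)
class IntensityHistogram:
    """Histogram of background pixel intensities with a Gaussian fit."""

    bin_edges: np.ndarray
    pixel_counts: np.ndarray
    fit_mean: float
    fit_sd: float
    fit_amplitude: float
    fit_ok: bool
    n_pixels: int
    masked_fraction: float


@dataclass(frozen=True)
class SizeDistribution:
    """Detected vesicle diameters with Gaussian summary statistics."""

    diameters_um: np.ndarray
    mean_um: float
    sd_um: float
    n: int


@dataclass(frozen=True)
class Efficiency:
    """Purification efficiency e = 1 - f(III)/f(I)."""

    value: float
    rounded: float
    outlet_iii_brighter: bool


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def detect_vesicles(
    image: np.ndarray,
    radius_range: tuple[int, int],
    *,
    canny_sigma: float = 2.0,
    accumulator_threshold: float = 0.45,
    min_center_distance_px: int | None = None,
    max_detections: int | None = None,
    pixel_size_um: float | None = None,
    refine: str | None = "ring",
    refine_window_px: float = 5.0,
) -> list[DetectedVesicle]:
    """Detect circular vesicles in a single-channel image.

    Canny edges feed a circular Hough transform over integer radii in
    ``radius_range`` (inclusive); peaks above ``accumulator_threshold``
    (fraction of the circle perimeter supported by edges) become detections.
    Non-maximum suppression forbids centers closer than the smallest search
    radius.  Each detection carries a ``focus_score`` — the mean Sobel
    gradient magnitude on its equatorial annulus — used downstream to flag
    out-of-focus vesicles.

    The Hough vote locks onto a ring's outer edge, overestimating the
    radius by about the ring half-width plus the PSF spread, so radii are
    refined to sub-pixel precision on the radial intensity profile:
    ``refine="ring"`` moves the radius to the intensity peak (membrane
    label), ``refine="disk"`` to the steepest descent of the profile (lumen
    dye boundary), ``refine=None`` keeps the raw Hough radius.
    """
    if image.ndim != 2:
        raise ValueError("detect_vesicles expects a single-channel 2D image")
    r_min, r_max = int(radius_range[0]), int(radius_range[1])
    if r_min < 2 or r_max < r_min:
        raise ValueError("radius range must satisfy 2 <= r_min <= r_max")
    img = np.asarray(image, dtype=float)
    span = img.max() - img.min()
    norm = (img - img.min()) / span if span > 0 else np.zeros_like(img)
    edges = canny(norm, sigma=canny_sigma)
    radii = np.arange(r_min, r_max + 1)
    spaces = hough_circle(edges, radii)
    min_dist = min_center_distance_px if min_center_distance_px is not None else r_min
    accums, cx, cy, rad = hough_circle_peaks(
        spaces,
        radii,
        min_xdistance=min_dist,
        min_ydistance=min_dist,
        threshold=accumulator_threshold,
        total_num_peaks=max_detections if max_detections is not None else np.inf,
    )
    grad = sobel(norm)
    detections = []
    for a, x, y, r in zip(accums, cx, cy, rad):
        r_fit = float(r)
        if refine is not None:
            r_fit = _refine_radius(
                norm, float(x), float(y), r_fit, refine, refine_window_px
            )
        det = DetectedVesicle(
            x_px=float(x),
            y_px=float(y),
            r_px=r_fit,
            r_um=r_fit * pixel_size_um if pixel_size_um else None,
            focus_score=_annulus_mean(grad, float(x), float(y), r_fit, 2.0),
            accumulator=float(a),
        )
        detections.append(det)
    return detections


def _refine_radius(
    image: np.ndarray,
    x: float,
    y: float,
    r0: float,
    mode: str,
    window: float,
    step: float = 0.25,
) -> float:
    """Sub-pixel radius from the radial intensity profile around (x, y)."""
    if mode not in ("ring", "disk"):
        raise ValueError(f"unknown refine mode {mode!r}")
    radii = np.arange(max(2.0, r0 - window), r0 + window + step / 2, step)
    profile = np.array([_annulus_mean(image, x, y, r, 0.5) for r in radii])
    if mode == "ring":
        score = profile
    else:  # disk boundary: steepest radial decrease
        score = -np.gradient(profile, step)
    i = int(np.argmax(score))
    if 0 < i < len(radii) - 1:  # parabolic sub-step interpolation
        denom = score[i - 1] - 2 * score[i] + score[i + 1]
        if denom != 0:
            i_frac = 0.5 * (score[i - 1] - score[i + 1]) / denom
            return float(radii[i] + np.clip(i_frac, -1, 1) * step)
    return float(radii[i])


def _annulus_mean(
    image: np.ndarray, x: float, y: float, r: float, halfwidth: float
) -> float:
    ny, nx = image.shape
    extent = int(np.ceil(r + halfwidth + 1))
    x0, x1 = max(int(x) - extent, 0), min(int(x) + extent + 1, nx)
    y0, y1 = max(int(y) - extent, 0), min(int(y) + extent + 1, ny)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(yy - y, xx - x)
    mask = np.abs(dist - r) <= halfwidth
    if not mask.any():
        raise ValueError("annulus contains no pixels")
    return float(image[y0:y1, x0:x1][mask].mean())


def equatorial_intensity(
    image: np.ndarray,
    det: DetectedVesicle,
    annulus_halfwidth: float = 2.0,
    *,
    on_border: str = "raise",
) -> float:
    """Mean intensity over the equatorial annulus |dist - r| <= halfwidth.

    The annulus must lie fully inside the image; ``on_border="partial"``
    instead averages over the visible part of a clipped annulus.
    """
    ny, nx = image.shape
    reach = det.r_px + annulus_halfwidth
    inside = (
        det.x_px - reach >= -0.5
        and det.y_px - reach >= -0.5
        and det.x_px + reach <= nx - 0.5
        and det.y_px + reach <= ny - 0.5
    )
    if not inside:
        if on_border == "raise":
            raise ValueError("equatorial annulus is clipped by the image border")
        if on_border != "partial":
            raise ValueError(f"unknown on_border mode {on_border!r}")
    return _annulus_mean(image, det.x_px, det.y_px, det.r_px, annulus_halfwidth)


def measure_channels(
    stack: np.ndarray,
    channels: list[str],
    detections: list[DetectedVesicle],
    annulus_halfwidth: float = 2.0,
) -> list[DetectedVesicle]:
    """Fill ``channel_intensities`` of each detection from a (C, ny, nx) stack."""
    if stack.ndim != 3 or stack.shape[0] != len(channels):
        raise ValueError("stack must be (n_channels, ny, nx) matching `channels`")
    for det in detections:
        for ci, channel in enumerate(channels):
            det.channel_intensities[channel] = equatorial_intensity(
                stack[ci], det, annulus_halfwidth
            )
    return detections


def detections_to_frame(detections: list[DetectedVesicle]) -> pd.DataFrame:
    """Tabulate detections (one row each; channel intensities as columns)."""
    rows = []
    for i, det in enumerate(detections):
        row = {
            "id": i,
            "x_px": det.x_px,
            "y_px": det.y_px,
            "r_px": det.r_px,
            "r_um": det.r_um,
            "focus_score": det.focus_score,
            "accumulator": det.accumulator,
        }
        for channel, value in det.channel_intensities.items():
            row[f"I_{channel}"] = value
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# background statistics and the efficiency statistic
# ---------------------------------------------------------------------------


def _gaussian(x, amplitude, mean, sd):
    return amplitude * np.exp(-0.5 * ((x - mean) / sd) ** 2)


def background_distribution(
    image: np.ndarray,
    detections: list[DetectedVesicle] = (),
    *,
    margin_px: float = 4.0,
    blur_quantile: float = 0.2,
    bins: int = 64,
    max_pixels: int | None = None,
    max_masked_fraction: float = 0.95,
) -> IntensityHistogram:
    """Histogram + Gaussian fit of the background (non-vesicle) intensity.

    Every detection's disk, dilated by ``margin_px``, is masked out;
    detections whose focus score falls below the ``blur_quantile`` quantile
    are treated as out-of-focus and masked with a doubled margin.  The
    Gaussian is fitted to the histogram counts by least squares, falling
    back to robust sample moments if the fit fails.  ``max_pixels`` caps the
    number of background pixels used (deterministically), so comparable
    pixel areas can be enforced across outlet images.
    """
    if image.ndim != 2:
        raise ValueError("expects a single-channel 2D image")
    ny, nx = image.shape
    mask = np.zeros(image.shape, dtype=bool)
    if detections:
        scores = np.array([d.focus_score for d in detections])
        cutoff = np.quantile(scores, blur_quantile) if len(detections) > 1 else -np.inf
        yy, xx = np.mgrid[0:ny, 0:nx]
        for det in detections:
            margin = margin_px * (2.0 if det.focus_score < cutoff else 1.0)
            mask |= np.hypot(yy - det.y_px, xx - det.x_px) <= det.r_px + margin
    masked_fraction = mask.mean()
    if masked_fraction > max_masked_fraction:
        raise ValueError(
            f"masked fraction {masked_fraction:.2f} leaves too little background"
        )
    pixels = np.asarray(image, dtype=float)[~mask]
    if max_pixels is not None and pixels.size > max_pixels:
        pixels = pixels[:max_pixels]
    logger.info("background area: %d px (%.1f%% masked)", pixels.size, 100 * masked_fraction)
    counts, edges = np.histogram(pixels, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mean0, sd0 = float(pixels.mean()), float(pixels.std())
    fit_ok = True
    if sd0 == 0 or len(centers) < 4:
        amplitude, mean, sd = float(counts.max()), mean0, max(sd0, 0.0)
        fit_ok = False
    else:
        try:
            popt, _ = curve_fit(
                _gaussian,
                centers,
                counts.astype(float),
                p0=(float(counts.max()), mean0, sd0),
                maxfev=10000,
            )
            amplitude, mean, sd = float(popt[0]), float(popt[1]), abs(float(popt[2]))
        except RuntimeError:
            amplitude, mean, sd = float(counts.max()), mean0, sd0
            fit_ok = False
    return IntensityHistogram(
        bin_edges=edges,
        pixel_counts=counts,
        fit_mean=mean,
        fit_sd=sd,
        fit_amplitude=amplitude,
        fit_ok=fit_ok,
        n_pixels=int(pixels.size),
        masked_fraction=float(masked_fraction),
    )


def purification_efficiency(f_outlet_I: float, f_outlet_III: float) -> Efficiency:
    """Separation efficiency e = 1 - f(III)/f(I) from outlet background levels.

    ``f(I)`` reflects the free-dye concentration in the unpurified mixture,
    ``f(III)`` the residual dye level co-collected with the purified GUVs.
    Reported at two decimals alongside full precision; a negative value
    (outlet III brighter than outlet I) is flagged.
    """
    if f_outlet_I <= 0:
        raise ValueError("f(I) must be > 0")
    if f_outlet_III < 0:
        raise ValueError("f(III) must be >= 0")
    e = 1.0 - f_outlet_III / f_outlet_I
    brighter = e < 0
    if brighter:
        warnings.warn("outlet III is brighter than outlet I (e < 0)", stacklevel=2)
    return Efficiency(value=e, rounded=round(e, 2), outlet_iii_brighter=brighter)


def size_distribution(
    detections: list[DetectedVesicle] | np.ndarray,
    pixel_size_um: float,
) -> SizeDistribution:
    """Vesicle diameter distribution (um) with Gaussian mean +/- sd summary."""
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be > 0")
    if isinstance(detections, np.ndarray):
        radii_px = detections.astype(float)
    else:
        radii_px = np.array([d.r_px for d in detections], dtype=float)
    if radii_px.size == 0:
        raise ValueError("no detections given")
    diameters = 2.0 * radii_px * pixel_size_um
    sd = float(diameters.std(ddof=1)) if diameters.size > 1 else 0.0
    return SizeDistribution(
        diameters_um=diameters,
        mean_um=float(diameters.mean()),
        sd_um=sd,
        n=int(diameters.size),
    )
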