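# Methods

## Hydraulic network model

The purification module is reduced to a lumped resistor network: two inlet
segments meet at a Y-junction, a pinched segment (w = 20 µm, l = 80 µm,
h = 40 µm) feeds a broadened section drained by five branch channels
(width 300 µm, height 40 µm; lengths 4150 µm for branches I, III, V and
4700 µm for II, IV) that share one outlet pressure. Segment resistance uses
the exact Fourier-series solution for pressure-driven flow in a rectangular
duct, truncated at 50 odd terms (the familiar `12µL/(wh³(1−0.63 h/w))`
approximation is provided for cross-checks and agrees to <1% at the device
aspect ratios; note that the naive "halving the height multiplies resistance
by 8" rule holds only in the thin-slit limit — the side-wall correction
gives ≈7.7 at 300×40 µm). With imposed inlet flow rates the outlet split
depends only on branch conductances; inlet and pinch resistances set
absolute pressures only.

Because the flow is laminar and inertialess, a streamline at wall-side
width fraction *t* of the pinch carries cumulative flux `F(t) = 3t² − 2t³`
(2D Poiseuille; a plug profile `F(t) = t` is available for classic-PFF
algebra). The mixture-stream boundary *y\** solves `F(y*) = Q_GUVs/Q_total`
by bisection to 1e−10.

### Separation angle

The angle θ between the bifurcating streams is not uniquely defined by a
lumped model; we construct it as follows. The pinch's mixture-side wall
continues straight into the broadened section; near the expansion the local
channel width is modelled as `W(d) = min(w + t_fan·d, W_broad)` at
downstream distance *d*, and the stream boundary sits at the same flux
fraction of `W(d)` as in the pinch. θ is the angle of that boundary
relative to the fanning washing-side wall, evaluated at `d = w`:

    θ = atan[ (1 − y*) · (W(d) − w) / d ]

The fan tangent `t_fan = 1.1` was fixed by matching the spreading of a
potential-flow (Laplace streamfunction) solution of a several-fold
one-sided sudden expansion at the same reference distance; the same
finite-difference solution serves as an independent oracle in the test
suite (5% agreement on the symmetric equal-flow case). The construction
satisfies θ → 0 as Q_ws → 0, strict monotonicity in Q_ws/Q_GUVs, and
θ < 90°. Absolute θ values are model-specific; only their ordering and
limits are used downstream.

### Outlet assignment and calibration

Outlet windows are the cumulative flow fractions of branches I→V (I
adjacent to the mixture wall). Solutes and SUVs exit through every window
overlapping the mixture's flux share; rigid particles ride the streamline
through a/2 from the wall; GUVs through min(a, w)/2 (vesicles wider than
the pinch deform and center); droplets with viscosity ratio λ > 1 or
surfactant stabilization elongate and are carried with the mixture stream
regardless of size. GUVs wider than (1 + 0.5)·w are flagged as likely
ruptured (the 0.5 confinement tolerance reflects the stated operating
envelope a ≈ w ± 0.5w).

Pure geometry puts the outlet-I and I+II cumulative windows at 0.210 and
0.395 — too small to reproduce the observed solute routing thresholds
(mixture confined to I+II at flow ratio 1.3, to I alone above 2.4, which
require 0.294 and 0.435). A single shared resistance factor cannot satisfy
both, so the optional calibration scales branches I and II individually to
hit the two thresholds exactly, leaving III–V at their geometric
proportions. Default is pure geometry; `DeviceConfig.calibrate_thresholds`
switches the fitted windows on.

## Mechanics

Scalar models only: mean pinch velocity `v = Q/(w·h)` (a configurable
profile factor > 1 yields a characteristic peak velocity; the default is 1
and printed literature pinch velocities ~30% above Q/(w·h) are treated as
order-of-magnitude context, not targets); membrane capillary number
`Ca = η_c v R/(κ_A w)` — the published form is not recoverable from the
source text, and this reconstruction is validated against the single
printed rupture bound (0.4 m/s), hence the generous 25% acceptance
tolerance on that number; it is implemented as a plain function so an
alternative exponent structure can be swapped in. Default continuous-phase
viscosity is 1.25 mPa·s (15% v/v glycerol buffer); pure water would raise
the bound to 0.5 m/s. Blur velocimetry is `u = Δd·fps`; reduced volume is
`V_vesicle / (4/3 π R³)`.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes:

* **Populations.** Gaussian diameters, resampled on non-positive draws.
  Presets: OLA-GUVs 20.6 ± 2.2 µm (the production route), electroformed
  GUVs 15 ± 9 µm (the polydisperse route), SUVs r = 65 nm. Octanol
  droplets are log-normal (median 3 µm, σ_ln = 1 — spanning nanometric to
  tens-of-microns, as the byproduct population does).
* **Rendering.** Membrane label → annulus of width 4 px; lumen dye and
  droplets → filled disks. Channels are convolved with a Gaussian PSF
  (σ = 1 px); a configurable fraction of objects (default 10%) is rendered
  with a 5× inflated PSF to emulate out-of-focus vesicles. Gaussian read
  noise is added, and pixels are rounded and clipped to 16 bits (clipping
  is logged; `quantize=False` disables rounding for exactness tests). Ring
  amplitudes are pre-compensated for the 1D PSF attenuation of the annulus
  profile, so the ground-truth `ring_intensity` *is* the in-focus
  equatorial mean an ideal measurement recovers — without this the
  blurred-annulus mean would sit ~20% below the drawn amplitude and no
  image-side estimator could be checked against truth at the percent level.
* **Scene statistics.** Placement is rejection-sampled with no overlaps
  (a gap of ≥4 px); per-object brightness varies log-normally (CV 0.1)
  jointly across channels so intensity ratios — hence FRET efficiencies —
  are exact per object.
* **Imaging constants.** Pixel size 0.5 µm, 512² frames, background offset
  48 counts, noise σ = 15 counts. The pixel size and noise level are not
  published; they are configurable defaults chosen to match a 10×/EMCCD
  setup, and the default background/free-dye levels (48 / 3200 counts)
  reproduce the printed outlet intensity scale. None of these affect the
  scale-invariant efficiency statistic.
* **FRET forward model.** The acceptor-density → E map defaults to
  `E(x) = 0.25 + 0.26·x` (x in mol%): baseline 0.25 is the donor-only
  apparent efficiency; the slope keeps E within (0, 1) over the 0–0.5 mol%
  calibration range. Per-vesicle donor/acceptor amplitudes split a fixed
  budget as `I_Rh = E·I_tot`, `I_NBD = (1−E)·I_tot`, so measured
  `E_FRET` equals E in the noiseless limit and the inversion is exact.

What a green test does **not** establish: the generator has no diffraction
model beyond a Gaussian PSF, no spectral bleed-through or detector shot
noise (noise is additive, intensity-independent), no vesicle clustering or
partial occlusion, and droplets/vesicles never overlap. Detection recall
and intensity-recovery figures therefore bound performance on well-spread
fields, not on crowded micrographs.

## Image analysis

Detection is Canny edges + circular Hough transform over integer radii,
with non-maximum suppression at the smallest search radius and an
accumulator threshold of 0.45 (fraction of perimeter supported by edges;
0.35 suffices for sparse fields but admits arc artefacts in dense ones).
The Hough peak locks onto a ring's outer edge, so radii are refined on the
radial intensity profile — peak position for membrane rings, steepest
descent for lumen disks — with parabolic sub-pixel interpolation (typical
residual <0.1 px). The focus score is the mean Sobel gradient on the
equatorial annulus; detections below the 0.2 focus quantile are treated as
out-of-focus and masked with a doubled margin in the background step.

Background statistics use a least-squares Gaussian fit to the histogram of
non-vesicle pixels (64 bins), falling back to sample moments for
degenerate histograms; `max_pixels` caps the pixel count so outlet images
are compared over similar areas (the pipeline matches outlet I to outlet
III's background area exactly). Efficiency is reported at full precision
and rounded to two decimals (1 − 48/3250 = 0.985 → 0.99).

## FRET analysis

Calibration fits are linear by default (the published calibration curve is
not tabulated; a monotone PCHIP spline is available and exact on its
knots) and must include the zero-acceptor baseline. Inversion is bisection
to 1e−10 mol%; measurements below baseline return 0 with a warning,
measurements above the calibrated range refuse to extrapolate. The
population transferred fraction uses the mean of per-vesicle E followed by
one inversion (mean-then-invert; for a linear calibration this equals
invert-then-mean). Lipid counts use the single-layer convention
`N = 4πR²/A` with A = 68 Å² — this convention, not the two-leaflet count,
reproduces the printed charge-balance magnitudes, and the SUV-per-GUV
ratio is invariant to both the convention and A. Dithionite
classification uses k = 1 standard deviation around the unilamellar (0.5)
and two-bilayer (0.75) expectations.

## Pipeline

`run_pipeline` executes device → mechanics → synthetic rendering →
imaging → FRET in order; any stage failure aborts with a stage-tagged
error, and outputs are written atomically (temp file + rename). The global
seed is fanned out to stages via `numpy.random.SeedSequence` spawn keys,
so re-running a stage alone reproduces its exact output; reports are JSON
with sorted keys and are byte-identical for identical (config, seed).
Wall-clock timings are kept on the report object but excluded from the
serialized JSON so determinism is testable. `sweep` re-runs the cheap
device/mechanics stages per parameter value by default; full-pipeline
sweeps (with imaging) are opt-in via `stages=`.

## Known limitations

* No finite-element flow field: θ and the outlet windows ignore the 2D
  entry flow of the broadened section; the threshold calibration absorbs
  part of this error but is fitted to two observations only.
* Droplet deformation is categorical (λ > 1 ⇒ co-flows with the mixture),
  not a shape computation.
* The capillary-number formula is a reconstruction; only its printed bound
  is validated.
* Detection assumes circular cross-sections; touching or strongly
  defocused vesicles can be missed (by design they are excluded from
  background statistics rather than segmented).
* The dithionite model assumes label equipartition across leaflets and no
  dithionite permeation on the assay timescale.
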