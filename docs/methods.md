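# Methods

`shadowcyte` simulates and analyses lens-free shadow images: the
diffraction patterns that micro-objects (polystyrene beads, leukocytes)
cast on a bare CMOS sensor when illuminated by semi-coherent light from an
LED behind a pinhole aperture. This note records the optical model, the
feature definitions, the synthetic-phantom conditions, and the numerical
choices that an informed user needs in order to interpret results.

## Optical forward model

Each channel is modelled as: LED die (spatially incoherent disc, default
150 µm) → circular pinhole (default 300 µm) → sample plane → sensor.
All lengths in the code are micrometres.

**Propagation.** Free-space propagation uses the band-limited
angular-spectrum method: the transfer function is evaluated on the exact
non-paraxial dispersion relation and spatial frequencies whose phase would
alias on the finite grid are suppressed, which keeps periodic wrap-around
out of the observation window. Distance 0 is the identity; interior energy
is conserved to well under 0.5 % at the configured distances.

**Illumination.** The field a single LED-die point produces behind the
pinhole is a spherical wave clipped by the aperture. By the Fresnel
scaling theorem this equals a plane wave diffracted over the reduced
distance `z1·L0/(L0+z1)` and observed on a grid magnified by
`(L0+z1)/L0`; off-axis die points shift the same pattern laterally by
`-s·z1/L0`. Partial coherence is therefore computed as an incoherent
average of shifted copies of one coherent diffraction pattern (a single
Fourier-domain kernel), with `n_source_points = 1` degenerating exactly to
fully coherent illumination. This reproduces the two experimentally
reported behaviours of the pinhole sweep: transmitted power grows
monotonically with aperture area, while the *central* irradiance rises
steeply only until the aperture leaves the diffraction-dominated regime
(Fresnel number ≈ 1, here between 100 µm and 250 µm) and then saturates at
the radiance limit. The plateau carries deterministic Fresnel-ripple
structure of a few percent, so the calibration curve is "rising, then
flat within ripple", not strictly monotone — matching how such curves are
described empirically.

**Object rendering.** Scenes are thin transmission objects on an
oversampled grid (default 2× the pixel pitch): each phantom is an
elliptical footprint with a smooth (sigmoid) edge, uniform amplitude
transmittance and phase shift, plus an optional band-limited random phase
texture inside the footprint ("granularity") standing in for internal
structure. The scene is propagated `sample_to_sensor`, the intensity is
blurred by the pinhole partial-coherence kernel (pattern displacements
`p·z2/z1` for points `p` across the aperture), box-integrated to the pixel
pitch, and degraded by Poisson shot noise (`photon_scale` photons per unit
relative intensity), additive Gaussian read noise, and quantization to 8
or 16 bits.

**Rough (drilled) apertures.** Rim irregularity is a smooth random
Fourier perturbation of the boundary radius with a given amplitude and
angular correlation scale. Optically, a rough rim scatters a fraction of
the light (≈ perturbed rim area / aperture area = `2a/R`) into angles of
order wavelength / rim-correlation-length; at the sensor this adds a
diffuse halo, modelled as Gaussian blurring of that intensity fraction.
This is what makes drilled apertures measurably less sharp than etched
ones while leaving ring positions (PPD/MMD) nearly unchanged.

**Geometry defaults.** The device's internal distances and pixel pitch
are not public. The defaults — source→pinhole 10 mm, pinhole→sample
20 mm, sample→sensor 150 µm, pixel pitch 2.2 µm, 470 nm — were chosen so
the configuration is physically coherent for shadow imaging: the lateral
coherence width at the sample (λ·z1/D ≈ 31 µm) exceeds the pattern size,
the source blur at the sensor (D·z2/z1 ≈ 2.3 µm) stays near one pixel,
and cells sit close enough to the sensor that pattern size grows with
object size (Fresnel number ≳ 1 for 10–25 µm objects). With a
millimetre-scale sample-to-sensor distance those conditions fail — the
pinhole blur alone (60 µm at z2 = 1 mm, z1 = 5 mm) erases all structure —
so this geometry should be treated as a representative stand-in, not a
measurement of the instrument. All values are configurable.

## Shadow parameters

Patterns are located by a polarity-rectified multi-scale
Laplacian-of-Gaussian blob detector with a robust (MAD-based) score
threshold and non-maximum suppression; windows that exit the frame are
dropped. Sub-pixel centres exploit the centro-symmetry of diffraction
patterns: the autoconvolution of the window (correlation with its own
180° rotation) peaks at twice the symmetry centre, and a parabolic fit on
that peak gives ≈ 0.05 px accuracy on isolated patterns regardless of
whether the pattern core is bright or dark. (A centroid-plus-quadratic
refinement on the raw intensity, tried first, lands 2–4 px off on weak
dark-core phase patterns.) Refinement is bounded to ±3 px; windows
without a significant symmetry peak keep the centroid estimate and are
flagged degenerate.

Each pattern is resampled bilinearly along 36 equally spaced rays
(0.5 px radial step), smoothed with a 5-sample local quadratic
(Savitzky–Golay) filter, and alternating extrema are found by
sign-changes of the first differences with parabolic sub-sample
refinement; adjacent max/min pairs whose contrast falls below 3× the
per-profile noise MAD are cancelled.

- **PPD** (peak-to-peak distance): per diameter (pair of opposite rays),
  the sum of the two *principal* peak radii — the highest-intensity
  maximum beyond 2 px — averaged over diameters and converted to µm. The
  principal peak is the dominant bright ring flanking the pattern core;
  using the literal first local maximum instead (available as
  `peak_mode="first"`) breaks the size correlation at Fresnel numbers ≳ 1,
  where interior Fresnel wiggles precede the ring.
- **MMD** (maxima-to-minima distance): per ray, the radial distance from
  the principal peak to the adjacent outward minimum, searched within
  4 px (≈ two fringe periods at the default geometry); when no prominent
  minimum survives the noise filter, the lowest point of the smoothed
  segment is used. The bounded search matters: unbounded "next minimum"
  adjacency occasionally jumps several fringes and the resulting outliers
  dominate MMD-SD. Measuring from the pattern centre instead is exposed
  as `mmd_reference="center"`.
- **MMD-SD**: the sample standard deviation of per-ray MMD across
  directions — near zero for circular patterns, elevated for elongated or
  internally structured ones. A cell needs a quorum (default 8) of valid
  rays, else its parameters are flagged invalid.
- **Sharpness**: Tenengrad (mean squared Sobel gradient) of the window
  after normalizing by the full gray scale of the sensor. Normalizing by
  the window min-max instead would cancel precisely the contrast loss
  that distinguishes aperture qualities.

Rotation behaviour: PPD and mean MMD are rotation-invariant to ≈ 0.1 %
under interpolating rotations; MMD-SD of a circular pattern is a
dispersion of noise around zero, for which a relative tolerance is not
meaningful — the tests check it stays small in absolute terms and that
90° rotations (interpolation-free) reproduce all parameters exactly.

## LAP

The instrument's composite activation score is not published. The
default here is the control-anchored ratio

    LAP = (PPD / median_ctrl PPD) / (MMD-SD / median_ctrl MMD-SD)

which is dimensionless, equals 1 at the control medians, rises strictly
with PPD, falls strictly with MMD-SD, and amplifies the joint effect of
swelling plus degranulation relative to either alone. Control locations
are medians (robust to heavy-tailed per-cell distributions); a z-score
variant `z(PPD) − z(MMD-SD)` is available behind `variant="zscore"`.
Cells with undefined LAP (MMD-SD ≤ 0 or invalid parameters) are excluded
listwise from LAP summaries but retained for PPD/MMD-SD. Cohort means are
normalized by the control mean, so the control maps to 1 and the
normalization is idempotent and scale-invariant. Absolute LAP magnitudes
are not comparable to the instrument's (unknown formula); only
directions and orderings are meaningful.

## Synthetic phantoms as study conditions

- **Beads**: circular thin-object surrogates (amplitude transmittance
  0.55, phase 1.8 rad), no texture, diameters as stated per experiment
  (10/20 µm for calibration and reproducibility runs, 5–25 µm for the
  linearity ladder).
- **Resting leukocytes**: diameter 9.0 µm ± 6 %, aspect ratio
  1 + |N(0.15, 0.10)|, phase 1.2 rad, transmittance 0.85, granularity
  0.50 rad RMS at 1.2 µm correlation length.
- **Activated leukocytes**: diameter +20 % (10.8 µm), granularity −50 %
  (0.25 rad), aspect → 1 + |N(0, 0.05)| — the morphological triad of
  activation (swelling, degranulation, rounding). The absolute
  granularity levels were placed in the responsive part of the MMD-SD
  dose–response (the response saturates above ≈ 0.35 rad); the relative
  −50 % change is the study condition.
- **Channel perturbations**: per-channel illumination gain ±2 % and
  sample-to-sensor distance ±5 %, drawn uniformly once per channel —
  the documented default manufacturing tolerances for the four-channel
  reproducibility check (CoV threshold 10 %).

What the generator does *not* emulate: overlapping/clumped cells (the
detector excludes rather than de-clumps), sub-cellular organelle optics
(granularity is a statistical texture, not organelles), polychromatic LED
spectra, sensor fixed-pattern noise and saturation blooming, and debris.
Passing tests therefore demonstrate internal consistency of the method
under realistic geometry and noise, not instrument-grade accuracy on
clinical samples.

## Statistics

Group comparisons use the two-sided Mann–Whitney U test (exact null by
enumeration when min(n) ≤ 8 and the data are tie-free, else the normal
approximation with tie and continuity corrections; `U = min(U1, U2)`),
with significance stars at the strict thresholds * p<0.05, ** p<0.01,
*** p<0.001, **** p<0.0001. The continuity-corrected approximation
tracks the exact p to within ≈ 0.011 at n1 = n2 = 8. Reproducibility is
summarised as CoV = 100·SD/mean across channel means. Bivariate
PPD × MMD-SD populations are summarised as 2D histograms with a
mean/covariance concentration ellipse at 2σ (the ≈ 86 % contour of a
bivariate normal).

## Problem sizes

Default experiment sizes are chosen to give comfortable statistical
margins at interactive runtimes: 384×384 px frames (≈ 0.85 mm field)
holding 25–50 phantoms, 20 phantoms per diameter for the linearity
ladder, 50 cells per group for shape comparisons, 200 cells per cohort
and 20 seeded replicates for activation-direction recovery, and
4 channels × 3 replicates × 50 beads for the CoV check. Every stochastic
step is reproducible from a single seed.

## Known limitations

- The geometry is a physically consistent placeholder; absolute PPD/MMD
  values scale with the (unpublished) sample-to-sensor distance.
- The thin-object approximation ignores multiple scattering inside
  cells; large high-contrast objects are rendered less faithfully.
- MMD-SD for elongated patterns is sensitive to resampling/interpolation
  at the single-cell level; cohort-level comparisons are robust.
- Overlapping diffraction patterns are excluded, biasing dense fields
  toward isolated cells.
- The LAP formula is this package's policy choice, not the instrument's.
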