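# Methods

This note documents the models implemented in `camoquant`, the
conventions and defaults chosen where the underlying methods admit more
than one, and what the synthetic data do and do not emulate.

## Receptor-noise-limited discrimination

Quantum catches are trapezoidal integrals Q_i = ∫R·I·S_i dλ on a common
1-nm grid (both operands linearly resampled; extrapolation outside a
spectrum's measured support is an error).  Von Kries adaptation divides
each catch by the catch of a perfect white reflector under the same
illuminant; this makes catches — and everything downstream — exactly
invariant to rescaling the illuminant, which the tests assert to 1e-12.

Chromatic distance uses the log form of the receptor-noise-limited
model.  Rather than the separate published quotient formulas for di-,
tri- and tetrachromats, we implement the single equivalent variational
form

    ΔS² = min_c Σ_i (Δf_i − c)²/ω_i²,   Δf_i = ln(Qa_i/Qb_i),

whose minimiser is the noise-weighted mean of the contrasts.  This is
algebraically identical to the quotient forms for any channel count
(the test suite verifies agreement with both the quotient formulas and
a numerical minimisation to 1e-9 over thousands of random cases) and is
symmetric, nonnegative, and invariant to adding a constant to all
contrasts (intensity changes do not change chromaticity in log space).

Achromatic distance is ΔL = |ln(Qa_D/Qb_D)|/ω_D on the designated
luminance (double-cone) channel.  RNL luminance discrimination lacks
strong behavioural validation; `JNDResult` carries that caveat
explicitly.

**Noise parameters.**  Weber fractions follow the abundance scaling
ω_i = ν·√(η_max/η_i) with reference ν = 0.05 on the most abundant cone.
The bundled receptor fixture uses Gaussian sensitivities at 372, 449,
502 and 563 nm (widths 28–40 nm), abundances 1 : 1.92 : 2.68 : 2.7, and
a broad double cone at 560 nm — a blue-tit-*like* stand-in, because
measured sensitivity curves, abundances and Weber fractions are species
data the package does not ship.  Every operation accepts an arbitrary
`ReceptorSet`, and absolute JND values on real data depend strongly on
this choice; only within-receptor-set comparisons are meaningful.

Image-level JNDs take the mean catch per channel over each ROI of the
acuity-controlled image, giving one chromatic and one achromatic value
per animal/background pair.

## Acuity control

MRA = 1/acuity degrees; its object-plane span is 2d·tan(MRA/2) and its
pixel span follows from the image scale.  Each channel is blurred with
a Gaussian of FWHM = 1 MRA (σ = MRA_px/2.3548, boundary mode `reflect`,
which conserves the image mean), then bilinearly rescaled so one MRA
spans 5 px (masks: nearest-neighbour, so labels stay integers).  The
whole image is processed, not individual ROIs.  The exact blur kernel
used by comparable image-analysis toolboxes is not published; FWHM = 1
MRA is our documented convention and both the kernel width and the
px/MRA target are parameters.  If the image is already below receiver
resolution (MRA < 2 px) a minimal 2-px blur is applied with a warning.

## Granularity analysis

Bands are octave-spaced: scales 2, 4, 8, … px, capped at 1200 px or the
largest image dimension, whichever is smaller.  Each band is an
isotropic radial filter applied in the frequency domain; the default
kernel is Gaussian in log spatial frequency,

    H_s(f) = exp(−(ln(f·s))²/(2τ²)),   τ = ln(m)/2   (m = scale multiplier),

chosen because it peaks exactly at period s — a sinusoid of period s
always localises in the band labelled s — and neighbouring octave bands
hand over half-way between scales.  The bank is then *tile-normalised*:
transfer functions are divided by √(Σ_s H_s²) wherever the bank has
support, so the squared transfers partition the frequency plane and, by
Parseval, the band variances partition the total non-DC variance of the
image (white-noise band energies² sum to the image variance; the test
allows 15% for DC and discretisation).  This makes energies comparable
across bands, image sizes and viewing distances.  A difference-of-
Gaussian low-pass variant (`kind="dog"`, FWHM s and s/m) is available;
we did not make it the default because its bands peak roughly a
half-octave below their nominal scale and overlap too broadly to
partition variance.

Energy per scale is the standard deviation of the band-filtered values
over the ROI pixels only, but filtering always runs on the full image
(ignore-labelled pixels are replaced by the mean of the labelled region
before the FFT) to avoid ROI-edge artefacts.

**PED.**  The `ped` operation defaults to the summed absolute
difference of unit-sum-normalized spectra (a total-variation-style
metric, maximum 2); raw-energy and mean-per-scale variants are
selectable, and mismatched scale grids or normalization states are
errors.  The *pipeline* default is different: raw energies with the
mean absolute difference per scale.  The reason is empirical and
documented here deliberately: after acuity control the animal ROI may
be only tens of pixels across, and unit-sum normalization of a spectrum
estimated from so few effective samples is dominated by estimation
noise — enough to reverse the expected effect of viewing distance.
Raw band energies, by contrast, genuinely shrink as blur removes
pattern information, so raw-energy PED decreases with distance and
preserves the lichen-vs-bark ordering; both behaviours are asserted in
the acceptance suite.  Whether a given study's PED used normalized or
raw spectra, and sum or mean aggregation, is often unreported — results
tables therefore record the variant used.

## Survival analysis

Kaplan–Meier is the plain product-limit estimator with Greenwood
variance S(t)²Σ d_j/(n_j(n_j−d_j)).  When censoring occurs only at the
study end, S(end) telescopes to 1 − d/n and the Greenwood SE to
√(p(1−p)/n) exactly, independent of how events split across check
times — the property that lets study-end survival be reproduced from
design counts alone.

Cox regression maximises the Efron (default) or Breslow partial
likelihood by Newton–Raphson with step-halving, to gradient norm
< 1e-8 within 100 iterations.  Efron is the default because check-time
data are heavily tied; the two methods agree exactly on tie-free data.
Categorical covariates are dummy-coded against a reference level
(alphabetically first unless configured; always reported).  The overall
Wald statistic is β′Iβ with the observed information.  Attack time is
the check time at which damage was observed; interval-censored
likelihoods are out of scope.  Pairwise log-rank tests delegate to
`lifelines` with Benjamini–Hochberg adjustment.

## Synthetic data

Textures are thresholded Gaussian random fields: white noise smoothed
with σ = scale/2π (anisotropically for bark, σ_vertical = anisotropy·σ),
cut at the median into tones 0.5 ± contrast/2, plus residual speckle
proportional to contrast (so zero contrast is exactly constant).  The
σ–scale mapping is calibrated so that the thresholded field's octave
pattern spectrum peaks at the nominal characteristic scale, which the
tests check across seeds.  Defaults encode the study conditions:
lichen — coarse (32 px = 3.2 mm at the default 10 px/mm) high-contrast
blotches; moth — the same class at contrast 0.9 (a high-contrast
lichen-like wing pattern); bark — finer (12 px), low-contrast (0.3),
vertically striated (anisotropy 4).

Scenes composite an elliptical moth patch (22 mm wingspan × 0.55 aspect
at 10 px/mm — so the default 6 cpd / 500–1000 mm geometry produces
non-trivial rescaling) onto a background texture, with labels 1 = moth,
2 = background.  Channels are *multiplicative* per-receptor maps of the
grey texture, so with zero offsets every channel is the same function
of grey and the chromatic signal is exactly zero; colour and luminance
mismatch are injected explicitly (moth region scaled by 1 ± offset,
alternating sign across chromatic channels).  When the moth and
background texture configurations coincide, the moth patch reuses the
background realization — a perfectly pattern-matched target.  Even
then, measured PED has a small positive floor (~0.01 with the pipeline
defaults) because the two ROIs are finite disjoint samples of one
stochastic texture; tests bound the mean across seeds rather than
asserting zero.

Predation data are exponential attack times per treatment, recorded at
the first 24/48/72 h check at or after the true time and right-censored
at 72 h, 100 replicates per treatment by default.  Helper
`hazard_for_event_fraction` converts a target 72-h attack fraction into
a rate.

**What the synthetics do not emulate:** real reflectance spectra or
camera responses (scenes are generated directly as catch-like stacks;
the camera-to-catch step is exercised separately by `image_to_catch`
with user-supplied mappings), photorealistic lichen geometry, spatially
correlated predator behaviour, and non-proportional hazards.  Passing
tests therefore demonstrate the correctness and qualitative behaviour
of the measurement chain, not quantitative agreement with any real
animal's measurements.

## Problem sizes and determinism

All stochastic tests run with fixed seeds (hypothesis in derandomised
mode).  The synthetic camouflage suites use 20 replicate scenes of
384×384 px at two distances, Cox recovery uses 2,000 subjects per group,
and the null-calibration checks use 100–200 simulation replicates —
sizes at which the observed statistics are stable to well within the
asserted margins.  The acceptance script's survival targets are exact
by construction (invariance of S(end) to the event-time split), so its
output is identical for every seed.
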