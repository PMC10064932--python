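# Methods

## Model overview

`acuitysim` implements an image-computable ideal-observer-style model of
letter acuity. The observer stores one noiseless neural template per Sloan
letter and size, formed by passing the rendered letter through the eye's
habitual optics (higher-order aberrations only) and a neural low-pass
filter. On each trial a test letter passes through the same pipeline plus
the induced defocus and additive neural noise, and is identified by the
template with the highest sliding normalized cross-correlation. Acuity
emerges from a simulated method-of-constant-stimuli session and a
psychometric fit, exactly as a human observer's acuity would be measured.

The model's purpose is to reproduce *trends* of acuity loss across defocus
amplitude, temporal frequency, and decision strategy — not to fit individual
observers. No parameter is optimized against empirical acuity data; the
neural noise variance (0.144) is a fixed constant inherited from the parent
template-matching acuity model in the literature.

## Optotypes

Letters are drawn from geometric primitives (rectangles, rings, elliptical
hooks, diagonal slabs, capsules) on the canonical Sloan 5×5 grid: letter
width = letter height, stroke width = height/5. Geometric rendering, rather
than a system font, makes the bank bit-reproducible across platforms. The
letterforms are faithful Sloan approximations, not glyph-exact copies of the
commercial font; since templates and test stimuli come from the same bank,
the observer is self-consistent. The S uses a rectilinear middle stroke
joining two elliptical hooks — the one visible stylization.

Frame: 255×255 px at 92 dpi viewed from 2 m, i.e.
atan(25.4/92 mm / 2 m) = 0.4746 arcmin/px, field 2.02°. Sizes −0.5 … +1.3
logMAR in 0.1 steps (19 levels × 10 letters = 190 images). A letter at
−0.5 logMAR is ~3.3 px tall and is rendered anti-aliased (4×4 supersampled
coverage); matching still operates on such sub-resolution stimuli because
the psychometric range must include sizes the observer cannot resolve.
Letters are dark (0) on a white field (1), chart convention, full contrast.

## Wave optics

Aberrations are OSA-indexed Zernike coefficients in µm over a 5-mm pupil.
Spherical defocus converts as c₂⁰ = D·R²/(4√3) with R the pupil radius in
mm (0.9021 µm per diopter at 5 mm). The monochromatic wavelength is 555 nm
(photopic peak; the choice only scales the phase per µm of wavefront and the
diffraction cutoff).

The OTF is the normalized autocorrelation of the generalized pupil
P = A(x)·exp(i·2π/λ·W(x)). The pupil plane is sampled with pitch λ·Δν,
where Δν is the image's frequency resolution in cycles/radian, so the
discrete autocorrelation lattice lands exactly on the image DFT
frequencies; a 512² grid holds the 317-sample pupil plus the largest needed
shift without circular aliasing. This band-limited route is used instead of
rendering a PSF at the image pixel pitch because the 5-mm pupil's incoherent
cutoff (157 cyc/deg) exceeds the image Nyquist frequency (63 cyc/deg): a
PSF on the image grid would alias, and the conjugate pupil grid could not
even contain the aperture. `psf()` therefore returns the point spread
function on its own finer pupil-conjugate grid, while filtering always goes
through the image-grid OTF.

Two numerical details keep the unaberrated MTF within ~1e-3 of the
closed-form diffraction limit: the aperture edge is anti-aliased by 8×8
subpixel coverage, and the pixel-box smoothing this introduces is
deconvolved from the pupil spectrum (division by the box sinc) before the
autocorrelation. Frequencies above the cutoff are identically zero by
construction.

Templates are filtered with the higher-order-aberration OTF only; test
images with higher-order aberrations plus the induced defocus. The
higher-order coefficients ship in `data/hoa_population_5mm.json`: a
documented, literature-representative stand-in for adult population means
at 5 mm (dominant positive spherical aberration 0.062 µm, small mean
coma/trefoil terms). Population *means* of most higher-order terms are near
zero even though individual eyes carry larger magnitudes; the fixture
follows the means. Filtering is linear end to end — no intensity clipping,
real part taken after the inverse FFT, mean luminance preserved.

## Neural stage

Both template and test images are low-pass filtered by a radially symmetric
neural transfer function representing post-retinal contrast attenuation for
a 25-year-old observer at 1100 trolands. The gain is log-linear in spatial
frequency, NTF(f) = exp(−f/f₀) — the standard straight-line fall-off of
photopic contrast sensitivity on a log-sensitivity axis. The scale constant
is **f₀ = 12.0 cyc/deg**, the single calibrated constant of the build: the
published parameterization the model family uses is not reproduced here, so
f₀ was fixed once by requiring the complete observer (diffraction + 5-mm
higher-order optics + NTF + 0.144 noise + 51.9% criterion) to sit at the
parent model's no-defocus operating point of −0.03 logMAR, estimated over
20 seeded sessions. It was not adjusted afterwards; every other result is a
prediction given that operating point.

Noise: zero-mean white Gaussian, variance 0.144 in squared normalized
intensity units, added to the test image only, after filtering, one draw per
trial. The template is the stored, noiseless neural representation. Noise is
not clipped — the decision variable is a correlation, not a display.

## Template matching

Sliding zero-mean normalized cross-correlation of each same-size template
against the test image, restricted to the region containing the optotype:
the template is cropped to the letter's bounding box and the search area to
that box dilated by 10%, which excludes spurious peaks in blank field
areas. Scores ≥ 0.95 are candidate matches; the candidate with the highest
peak is the response; peaks equal after rounding to three decimals are
resolved by a seeded random pick; if no template reaches 0.95 the observer
answers with the global argmax (a forced-choice task always has a
response). The engine evaluates all 10 templates in one batched FFT
correlation with shared window statistics; a test asserts bit-level
agreement with the reference per-template sliding NCC.

The model's chance level is 1/10 (ten templates). The human task it
parallels was 26-alternative (chance 3.85%); the threshold criterion
(51.9%) and free 0-to-1 cumulative-Gaussian fit are kept identical for the
model data. An optional guess-rate-corrected fit (γ = 1/26) is exposed but
off by default.

## Temporal defocus and strategies

d(t) = DC + A·sin(2πft + φ). A 300-ms epoch is sampled at 1 ms (300
samples) with onset drawn uniformly over one period per trial —
presentation and fluctuation are unsynchronized. Strategies select which
samples form the effective image: all 300 (average); the six 50-ms bins'
best bin (least); first or last 100 (early/late); or a per-trial
equiprobable draw among the four (mixed). "Best" bin = smallest mean
*absolute* defocus, the sign-ambivalent quantity that governs blur (a
signed mean could cancel through a zero crossing). The lone mention of a
500-ms duration in the source literature's discussion is treated as a slip;
300 ms is used throughout.

Because filtering is linear, the mean of N defocused images equals the
image filtered by the mean of the N OTFs; the engine averages OTFs (cached
on a 0.01-D quantized defocus grid — two orders of magnitude below the
eye's depth of focus) and performs a single inverse FFT per trial. The
equivalence with explicit image averaging is tested to 1e-10 in the
float64 reference path; the complex64 cache tracks it to ~1e-5, far below
the noise floor (SD 0.38).

Zero crossings: a uniformly placed window of duration d contains a zero of
the zero-mean sinusoid with probability min(1, 2fd) (zeros every
half-period); with 0 < |DC| < A the two zeros per period split the cycle
into unequal gaps g and T−g and the probability is
(min(g,d) + min(T−g,d))/T; with |DC| ≥ A there are no zeros. Monte-Carlo
agreement is tested at 10⁵ draws.

## Psychophysical procedure

Eleven sizes, 0.1 logMAR apart, 10 presentations each in random order (110
trials); random letter each trial. The window center starts at the
clinically expected acuity for the condition's effective defocus
(0.35 logMAR/D × (|DC| + A/2)), clipped so the window stays inside the
19-level bank. If the first 28 trials (25%) are all correct or all
incorrect the session aborts and recenters by ∓0.2 logMAR (max 5 restarts;
exhaustion raises an error rather than returning a censored threshold).

Fit: binomial maximum likelihood of Φ((s−µ)/σ) via Nelder-Mead from a grid
of starts, parameterized in (µ, log σ) to keep σ positive. Threshold
= µ + σ·Φ⁻¹(0.519). Sessions with all-extreme data are flagged degenerate.
Within-session uncertainty: per-size counts resampled as Binomial(n, p̂)
and refitted 100 times (Monte Carlo); condition-level uncertainty: the
across-replicate SEM over (by default) 10 independently seeded sessions.
Table-1-style regressions are ordinary least squares of mean acuity on
amplitude over the four amplitude conditions only — the baseline is not a
regression point, consistent with intercepts that sit below the baseline
acuity.

Because the unconstrained 0-to-1 Gaussian must also absorb the 10% chance
floor at unresolvable sizes, fitted σ values run larger than the
"true" transition width and session-to-session threshold scatter is a few
hundredths of a logMAR — both features the source protocol shares.

## Seeding and reproducibility

Every stochastic step draws from a `numpy` Generator. Condition seeds
derive from (master seed, crc32 of a condition tag, replicate index), so a
condition's result is independent of the order in which conditions run and
a master seed reproduces the entire study bit for bit.

## Problem sizes and runtime choices

Default study sizes follow the protocol: 110 trials per session, 10
replicate sessions per condition, 100 Monte-Carlo refits. The qualitative
trend checks in the test suite (strategy orderings, offset experiment,
static-versus-temporal potency) use 3 replicate sessions per condition —
enough to order effects separated by ≥0.1 logMAR — while all numeric
operating-point checks keep the full 10. With the OTF cache warm a trial
costs ~10 ms, a session ~1.5 s.

## What the simulation does and does not show

The generator reproduces the study's stimulus conditions: sinusoidal,
monochromatic, single-aberration-profile defocus with an unsynchronized
300-ms epoch. It does not model chromatic aberration, Stiles–Crawford
apodization, pupil-size variation, non-sinusoidal (broadband) fluctuation
spectra, crowding, or human lapses and biases; the empirical human values
(e.g. the 0.12 logMAR cyclopleged baseline) are therefore outside its
scope, and agreement with the model-side operating points does not imply
the human data would be reproduced. Known limitations: the 10-template
chance floor inflates fitted σ relative to a 26-alternative task; the
higher-order-aberration fixture is a population-mean stand-in, so absolute
acuities carry that uncertainty even though amplitude/frequency trends are
robust to it.
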