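# Methods

This note records the models implemented in `canopyocc`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices a maintainer would want to know about.

## Waveform model and processing

A large-footprint waveform is modelled as a sum of Gaussian energy
components in height — one per vegetation stratum plus a ground return at
0 m — sampled as exact per-bin integrals on 0.15 m bins, so the noise-free
profile integrates to the configured total energy (100 arbitrary units) to
machine precision. Each component's width is broadened in quadrature by
the transmitted pulse (`pulse_sigma`, default 0.35 m, a typical ~5 ns
near-infrared altimeter pulse expressed as a Gaussian sd) and by terrain
slope. Slope broadening uses (footprint relief)/4 added in quadrature,
where relief = 2a·tan(slope) along the footprint's major axis (length 2a);
the divisor 4 makes the ±2σ extent of the added spread match the relief,
which reproduces the qualitative waveform stretching that motivates
relief-corrected canopy heights while staying analytically checkable.
Detector noise is additive i.i.d. Gaussian about a configurable noise
floor, floored at zero.

Processing follows the standard altimetry chain. Noise statistics default
to the 50 lowest plus 50 highest bins (assumed signal-free, the usual
leading/trailing noise windows); the simulator pads ≥10 m (or 9
component-sigmas) on both sides so these windows exist. Denoising zeroes
bins at or below mean + 4·sd and subtracts the mean from survivors. The
60 cm smoothing filter is interpreted as the Gaussian **sd** (an FWHM
interpretation is selectable); the kernel is truncated at 6σ,
unit-normalized, and applied by zero-padded convolution, conserving energy
to better than 1e-9 for signals away from the array ends. Decomposition
initialises at the profile's local maxima (largest first, at most six) and
refines all components jointly by bounded least squares, accepting the fit
only if it does not worsen the initialisation's residual; components are
returned sorted by height. Ground is the larger-amplitude of the two
lowest components, ties breaking toward the lower one.

Metric conventions: heights are re-expressed relative to the fitted ground
centre; the vegetation profile is the smoothed amplitude minus the fitted
ground Gaussian, floored at zero, above ground only. HOME uses cumulative
**total** (vegetation + ground) energy from the signal end, the
established datum for height-of-median-energy; a vegetation-only variant
is reported alongside because the field usage is ambiguous. FHD bins are
half-open [b, b+1) metres above ground. Canopy height subtracts the full
footprint relief from the waveform extent and floors at zero; the relief
coefficient is configurable because published relief corrections are
described only qualitatively and the exact formula differs between
sensors. Bare footprints (no vegetation energy) report zero metrics with a
flag; VDR is undefined (missing) when canopy height is zero.

## Point-cloud metrics

Vegetation returns are those above the 1 m cutoff; stratum fractions use
left-open/right-closed intervals (1,3], (3,10], (10,∞) as fractions of all
returns, which makes p.lower + p.mid + p.upper = density an exact
identity. Height statistics are over vegetation returns only; kurtosis is
reported as excess kurtosis (symmetric-normal → 0) for testability. Mode
metrics use raw 1 m-bin counts without smoothing (the simplest
reproducible rule; a smoothing window could be added): modes are strict
local maxima, a plateau counts once at its lowest bin, the dominant mode
is the highest-count mode (ties toward the lower bin), and the mode range
is the height difference between the highest- and lowest-elevation modes.
Footprint aggregation replicates each 20 m cell to 1 m cells and averages
the cells whose centres fall inside the ellipse, which avoids biasing the
mean by partial cells at the footprint perimeter.

## Terrain covariates

Slope and aspect use Horn's 3×3 finite differences. Aspect is reported as
the compass bearing of steepest **ascent** (a plane rising due south has
aspect 180°); this is the convention the rest of the package, including
the heat-load folding, is written against. The heat load index folds
aspect about the NE–SW axis, A_f = |180° − |aspect − 225°||, and evaluates
the McCune–Keon regression; the three published equation variants live in
`HLI_EQUATIONS` with citation strings, eq. 1 (exponentiated form, broadest
slope/latitude range) being the default. With these coefficients the index
peaks on south-southwest aspects and is minimal on the northeast, which the
tests check as properties (aspect invariance at zero slope, SW > NE,
folding symmetry, warmest aspect in the S–W quadrant). Site elevation is
bilinear interpolation at the footprint centre; footprint relief is
max − min elevation over DEM cell centres inside the ellipse.

## Occupancy model

The likelihood is the standard single-season zero-inflated form with logit
links; missing visits drop out of the within-site product. The
implementation evaluates per-site log-likelihoods with `log_expit` and
`logaddexp` (no overflow for extreme linear predictors) and supplies the
analytic gradient (posterior occupancy weights times score residuals) to
L-BFGS-B. Fits start from the zero vector plus four seeded N(0, 0.5)
perturbations; convergence uses |Δnll| ≤ 1e-12 and gradient norm ≤ 1e-8.
Standard errors come from the inverse observed information, computed by
central finite differences of the analytic gradient; non-invertible
information (near-separation, boundary estimates) yields infinite SEs
rather than failure. Covariates are standardized (mean 0, sd 1) before
fitting — with strongly intercorrelated structure covariates the
likelihood is near-separable and coefficient magnitudes of order 10² on
the standardized scale are expected; standardization keeps the
optimisation stable. AICc uses n = number of sites.

## Selection, averaging, diagnostics

Candidate models are all non-empty site-covariate subsets crossed with all
detection-covariate subsets (detection-only models are ecologically
irrelevant and excluded); the intercept-only null is appended for
reference. The retained set is ΔAICc ≤ 6 — deliberately more conservative
than the common ΔAICc ≤ 2 — and Akaike weights are renormalized to sum to
1 over that set. Both averaging modes are implemented: full (absent terms
contribute zero) and conditional (weights renormalized over models
containing the term), with the algebraic identity
full = conditional × RVI asserted exactly in tests. Unconditional standard
errors follow Burnham & Anderson: √(Σ w_i (se_i² + (β_i − β̄)²)).
Conditional averaging is the default reporting mode; the mode is always
recorded in output.

Belsley screening scales columns to unit length, computes condition
indices (max singular value over each singular value) and
variance-decomposition proportions, flags components with CI > 30 in which
two or more covariates carry VDP ≥ 0.5, and greedily drops the flagged
covariate with the largest VDP until clean. Thresholds 30/0.5 are
Belsley's canonical guidance. The pipeline screens the **standardized**
covariates: screening raw ecological covariates (which share location and
scale structure) mostly flags the common "intercept-like" component rather
than true near-dependencies.

The overdispersion statistic is ĉ = deviance/(n − p) with
deviance = 2(logL_sat − logL_model). The default saturated model gives
every site free (ψ_i, p_i): a pure history (all zeros or all ones) has
saturated likelihood 1 and a mixed history with d detections in J visits
has (d/J)^d (1 − d/J)^(J−d). This dominates every covariate model, so the
deviance is non-negative, and its magnitude is of the order of published
global-model deviances for two-visit designs. A pooled-pattern multinomial
alternative is available but can produce negative deviances against
covariate models (site-specific probabilities can beat any exchangeable
pattern distribution) and is only appropriate for covariate-free
comparisons; the definition used is recorded in the diagnostics output.
Note that ĉ is not calibrated to 1 under a well-specified model — its
expectation depends on (ψ, p, J); the tests verify it against the
closed-form expectation at the simulation's true parameters.

## Validation

ROC labels default to the observed any-detection indicator, since true
occupancy is latent in real surveys; on synthetic data the latent state
can be supplied. Cutoffs are the midpoint of the two 1-D k-means centres
(best of 10 seeded restarts); AUC is the rank statistic with ties counting
one half. LOOCV refits warm-start at the full-data optimum, which makes
the n refits cheap and (empirically) lands on the same optimum; refit
failures are counted and skipped. LOOCV AUC with an uninformative
covariate is mildly pessimistic (below 0.5) at small n — removing a
detected site lowers its own held-out prediction — which the tests treat
as expected behaviour of the estimator, not a defect.

## Synthetic study design

The end-to-end pipeline emulates a two-platform LiDAR occupancy survey:
sites on a 340 m grid (the home-range spacing used in woodpecker surveys)
over smooth synthetic montane terrain (gentle trend plus long-wavelength
undulations, relief ~100 m, slopes of a few degrees at 10 m resolution);
one ~64 m elliptical waveform footprint and one ~12 pt/m² point cloud per
site; canopies with a shrub stratum (1–4 m), optional sub-canopy, and a
main canopy stratum (12–35 m), ground energy 5–30 % — loosely matching
montane mixed-conifer stands with ~30 m canopies and high canopy density.
Truth for the detection histories is a logit-linear model on the
standardized **measured** covariates (elev, HLI, FHD, p.mid, mode range)
with moderate effects (ψ intercept −0.2; slopes 0.3, 0.25, 0.9, −0.4,
0.6) and detection intercept 0.6 with wind effect −0.35 — about 45 %
occupancy and 65 % per-visit detection, typical of playback surveys for a
moderately detectable woodpecker. Defaults use 80 sites and 2 visits.

What the generator does **not** emulate: radiometric detail (gain,
saturation physics — saturation is approximated by a consecutive-bins-at-
ceiling flag), atmospheric/cloud contamination, geolocation error,
footprint-to-footprint overlap, spatial autocorrelation in occupancy, and
real ground-finding from unclassified point clouds (synthetic clouds are
born height-normalized). Passing tests therefore demonstrate correctness
of the estimators under the stated generative model, not robustness to
those real-data artefacts.

## Problem sizes

Test and acceptance runs use sizes chosen to exercise the asymptotics
while staying light: the pipeline runs 80 sites × 63 candidate models;
parameter recovery uses n = 500 sites × 3 visits; Wald coverage uses
300–500 replicates; the denoising tail rate uses 10⁶ bins; LOOCV
optimism checks use a dozen replicates of n = 60. These are the package's
own defaults for a convincing-but-quick demonstration; all are parameters.

## Known limitations

* Decomposition is a local optimiser seeded at profile maxima; heavily
  overlapping strata (closer than ~2 combined sigmas) merge, and the
  ground rule then attributes merged low strata to ground. This mirrors
  the physical resolution limit of smoothed waveforms.
* The Wald intervals rely on the observed information; under separation
  they are infinite and model averaging inherits the corresponding
  uncertainty.
* The Belsley greedy drop removes one covariate per pass; with more than
  one simultaneous near-dependency the drop order can matter.
* `hli` equation choice and the relief coefficient in canopy height are
  study-level conventions; change them in `RunConfig`, not in code.
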