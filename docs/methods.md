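# Methods

This note documents the models, parameters and design decisions behind
`qustex`: what the pipeline computes, what the simulator emulates, and what
passing tests do and do not demonstrate about real clinical data.

## Spectral analysis

**Acquisition model.**  RF frames are 2-D arrays (axial fast-time sample ×
scan line) with metadata: sampling frequency 40 MHz, pulse centre frequency
7 MHz with −6 dB fractional bandwidth 0.6, speed of sound fixed at
1540 m/s, so the axial pitch is c/(2·fs) ≈ 19.3 µm/sample.  Lateral line
pitch defaults to 0.2 mm.

**Windows.**  The sliding analysis window spans 10 wavelengths axially
(2·10·fs/fc = 114 samples at the defaults) — long enough that the fitted
parameters are insensitive to the exact length (the suite checks < 0.5 dBr
mean-MBF movement for ±20% length changes) — and the same physical extent
laterally, rounded to whole lines.  Windows step at 50% overlap in both
directions (configurable; the overlap, the Hann axial taper and the
averaging order are not dictated by the method itself, so they are echoed
into every output's metadata).  Per-line periodograms are averaged in
linear power across the window's lines before any log is taken.

**Normalisation and fit.**  Each window's spectrum is divided by the
spectrum of the same window location in the reference-phantom frame
acquired with the same settings; 10·log10 of the ratio is the normalised
spectrum in dBr.  Reference bins below 10⁻¹² of the reference maximum, and
sample bins with non-positive power, are masked rather than producing
±infinite dBr.  Ordinary least squares over the −6 dB band of the
calibration pulse (≈ 4.9–9.1 MHz at the defaults; band edges located by
dB-linear interpolation between spectrum bins) yields slope, 0-MHz
intercept, and mid-band fit = fitted value at the band centre; the identity
`MBF = slope·f_c + I0` holds exactly by construction.  Windows with fewer
than 3 usable band bins are flagged invalid (NaN + mask), never zero.

Two exact invariants pin the implementation down: a frame normalised
against itself gives identically zero maps, and scaling the RF by `a`
shifts MBF and intercept maps by exactly +20·log10(a) dBr while leaving the
slope untouched (gain cancellation).

## Texture analysis

Maps are quantised to 16 gray levels (uniform bins; ties on an edge fall to
the lower bin, the maximum to the top level).  The default range policy is
per-map min–max over the ROI, which makes the features exactly invariant to
affine intensity changes; a fixed global range is available for analyses
that compare absolute texture across maps — the patch-size sensitivity
property is checked under the fixed-range policy, because per-map scaling
confounds cross-map contrast comparisons with dynamic-range differences.
Symmetric GLCMs are accumulated at distances {1} pixel (configurable) and
angles 0°/45°/90°/135° (opposite directions are covered by symmetry; pairs
with either pixel outside the ROI are dropped, no padding).  Contrast,
correlation and homogeneity are the standard sums over the normalised
matrix; correlation is reported as undefined (NaN, with a reason) when a
marginal variance is zero, and undefined values propagate as undefined only
when every angle/distance is undefined.  Features are averaged over angles,
then distances.

## ROI and biomarkers

The per-plane ROI is the central part of the clinician-drawn (here:
simulator-provided) tumour mask: the pixels nearest to the point (focal
depth row, tumour lateral centroid), grown to cover 2/3 of the tumour area
(for a circular tumour this is the concentric disc of radius √(2/3)·R).
Mean and texture features are computed per plane, averaged (unweighted)
across scan planes into per-visit tumour-volumetric values, and converted
to baseline-relative biomarkers: `100·(v_t − v_0)/|v_0|` percent alongside
the absolute change `v_t − v_0`.  Whether a percent or an absolute change
is the right longitudinal contrast is genuinely ambiguous for dB-valued
quantities, so both are emitted; a stability guard (|baseline| ≥ 0.5 dBr
for means, ≥ 0.05 for dimensionless textures) flags percent changes with
near-zero denominators, and any biomarker where a patient trips the guard
is analysed on the absolute scale for the whole cohort (one scale per
column).

## Statistics

* **Group comparison:** each group is screened with a one-sample KS test of
  the standardised values against N(0,1) at α = 0.05 (estimated mean/SD —
  the Lilliefors caveat applies, making the gate conservative, i.e. quick
  to fall back to the distribution-free branch).  Both groups normal →
  pooled-variance two-sided t-test; otherwise a two-sample KS test with the
  exact small-sample p-value for groups of ≤ 25.
* **Classification:** pooled-covariance (equal-covariance Gaussian) LDA,
  `w = Σ⁻¹(μ₁−μ₀)`, threshold at equal posterior with empirical priors;
  positive class = non-responder (the clinically costly miss).  A ridge
  `1e-6·mean(diag)` is added only when the pooled covariance is singular.
  Sensitivity/specificity are computed from leave-one-out predictions by
  default (resubstitution on ~20 patients is optimistic; both modes are
  supported and reported).  The ROC and its AUC use the full-fit
  discriminant scores: pooled held-out scores from refitted models are not
  on a common scale and exhibit the known LOO score-reversal artifact that
  drives AUC far below 1/2 under weak signal; for a single biomarker the
  full-fit score is a monotone transform of the biomarker itself, so the
  AUC is the biomarker's own ROC area.  AUC is computed by threshold sweep
  with trapezoidal (half-credit) tie handling and equals the Mann–Whitney
  U/(n₁n₂) identity to machine precision.
* **Survival:** Kaplan–Meier product-limit curves per group (events before
  censorings at tied times) and the standard O−E/hypergeometric-variance
  log-rank test, via lifelines.  No multiple-testing correction is applied
  anywhere — biomarkers are reported one by one — and this is deliberate;
  treat the per-biomarker p-values accordingly.

## The simulator

**Tissue and echo model.**  Tissue is a 2-D Poisson field of point
scatterers (default ≈ 103/mm², i.e. ~5 per λ² resolution cell — fully
developed speckle) with zero-mean Gaussian amplitudes.  The RF frame is the
linear convolution of a Gaussian-envelope tone burst with the reflectivity
grid (nearest line laterally, linear interpolation between axial samples),
plus white noise (σ = 0.01, essentially negligible); no nonlinear
propagation, no elevational beam, no explicit frequency-dependent
attenuation (the method cancels attenuation by normalisation, so the
simulator does not model what the pipeline would remove).  The model is
exactly linear in scatterer amplitudes; superposition and the
2·depth/c echo delay are verified against closed forms.

**Geometry (desk scale).**  Frames are 20×20 mm with 3 parallel planes
5 mm apart; tumours are spheres of radius 6.5–9 mm centred at the 10 mm
focal depth, hypoechoic by −3 dB (which also keeps the baseline MBF
biomarker clear of the percent-change guard); per-patient gain varies
×0.7–1.4 and is applied to patient and phantom alike (the pipeline must
cancel it, and a dedicated invariant checks that it does).  These sizes are
the package's own choice of a compact study geometry; the clinical setting
has centimetre-scale plane spacing and 3–13 cm tumours, with everything
else proportional.

**Response model.**  Per visit and patient, tumour-mean target shifts are
drawn as `Δ_MBF ~ N(m, s)` and `Δ_I0 ~ N(m', s')` with group means taken
from the clinical trajectories the simulator is calibrated to (responders
+3.7/+6.8 dBr MBF and +1.9/+2.3 dBr intercept at weeks 1/4; non-responders
−2.1/−4.9 and −1.8/−0.4) and patient-level SDs equal to the reported
standard errors times √n (n = 15/5) — the published ± values are standard
errors of group means, and patient-level spread at that scale is also what
makes the week-1 mean-value biomarker an imperfect classifier (AUC ≈ 0.84)
while texture discriminates almost perfectly, the ordering the analysis is
about.  The drawn mean shift is delivered as a flat dB gain over the whole
tumour.  Heterogeneity is separate: circular patches (radius 2 mm,
Poisson-placed centres at the intensity that covers 75% of the tumour in
expectation, persisted across visits within a patient) carry zero-mean
patch-to-patch dB contrast — 4 dB (week 1) and 5 dB (week 4) for
responders, 1 dB for non-responders.  The paper quantifies no texture
effect size, so these are simulator choices: heterogeneous early cell death
in responders is given patch contrast on the scale of the eventual mean
shifts, non-responders only mild remodelling.  Patch fields get diffuse
~1 mm Gaussian margins (mask-normalised smoothing, so a constant field is
preserved exactly).

**Calibration.**  The dB-domain ROI mean of a spatially heterogeneous power
field overstates the scatterer-level mean (windows average power before the
log — Jensen's inequality), so the generator predicts the window-averaged
dB mean of its own shift field (masked box filter at the window scale) and
absorbs the difference into a flat in-tumour offset; the measured
tumour-mean shift then recovers the drawn target.  A residual +0.1–0.3 dBr
second-order speckle effect remains and is accepted (the recovery criterion
is 1 dBr; the acceptance probe lands within ~0.1 dBr of the programmed
means because the offsets partially cancel between baseline and follow-up).
The intercept/MBF difference is a flat spectral tilt
`b = (Δ_MBF − Δ_I0)/f_c` dB/MHz applied to tumour scatterers through a
31-tap linear-phase FIR with gain `10^{b(f−f_c)/20}` (unity at f_c);
measured intercept shifts track the drawn targets with correlation > 0.99
and < 0.1 dBr bias.

**Survival.**  Recurrence times are exponential with median 48 months
(responders) vs 12 months (non-responders) — a hazard ratio of 4, chosen as
simulator values, not published ones — with administrative censoring at
50 months.

**What the simulator does not emulate.**  Real breast RF data has depth-
and tissue-dependent attenuation, elevational beam width, heterogeneous
normal tissue, operator-dependent ROI placement, missing visits and
pathology-label noise.  Passing tests therefore demonstrate that the
*pipeline* is correct and that the *designed* effect structure is
recovered; they do not validate the clinical effect sizes themselves.

## Problem sizes and determinism

Every random quantity descends from a single integer seed through
`numpy.random.SeedSequence` spawning; identical (config, seed) reproduce
every output byte (CSV floats are written with a fixed format).  The test
suite uses 20 default cohorts (15/5 patients, 3 visits × ≤3 planes) for the
end-to-end recovery and AUC-ordering checks, 20 seeds for the Monte-Carlo
property checks, and 100 replicates for the power simulations; the
acceptance script uses 3 zero-variance probe cohorts for the calibration
readout and 12 default cohorts for the classification study.  One known
red mark: the log-rank power requirement of ≥80% rejection at hazard ratio
4 with n = 15/5 exceeds the analytic (Schoenfeld) power of that design,
log(4)·√(20·0.75·0.25) ≈ 2.68σ ⇒ ~72% two-sided — the corresponding test
reports the shortfall rather than hiding it.
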