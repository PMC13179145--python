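# Methods

`ivdquant` quantifies lumbar intervertebral disc (IVD) health from
sagittal multi-echo MRI and relates it to a lifetime physical-loading
exposure score. Because no imaging data ship with the package, a phantom
module generates every input the pipeline consumes; this note describes
the models, the conventions chosen where several were defensible, and
what the synthetic data do and do not establish about real acquisitions.

## Signal model and T2 estimation

Transverse relaxation is modelled as mono-exponential,

    S(TE) = S0 · exp(−TE / T2),

so ordinary least squares of ln S on echo time gives `T2 = −1/slope` and
`S0 = exp(intercept)`. The default echo times are the eight of the
emulated sagittal spin-echo multi-echo sequence (15.75 … 162.75 ms in
21 ms steps). All echoes enter the fit — there is no stimulated-echo
suppression or correction — and an echo subset (e.g. dropping the first
echo) is available as a configuration option for sensitivity checks.
Echoes with non-positive signal have no logarithm and are dropped; a fit
needs at least three usable echoes and a strictly negative slope,
otherwise it is reported missing with a reason code rather than a value.

Regional T2 uses a *fit-on-mean* convention: the signal is averaged over
the region's pixels at each echo, then one line is fitted. The
alternative (fit every voxel, average the T2 estimates) is available via
`fit_mode="voxel"`. Fit-on-mean is the default because averaging before
the logarithm suppresses the noise-induced bias of log-linear fitting;
with 1 % Gaussian noise the mean fitted T2 is within 1 % of truth
(verified over 10⁴ fits). On a disc whose regions hold different true
T2s, the *whole-disc* value fits a sum of exponentials with a single
line; the result is systematically a few milliseconds above the
arithmetic mean of the region T2s (longer-T2 tissue dominates late
echoes). This is inherent to the estimator, affects synthetic and real
data alike, and shifts baselines rather than association slopes.

## Geometry conventions

Pixels are addressed `(row, col)`, 0-based, with centers at integer
coordinates; millimetre conversions always use per-axis spacing. The
anatomical anterior direction is metadata: the phantom writes anterior =
increasing column, and real data must supply an orientation; measures
are invariant under in-plane rotation only when the orientation rotates
with the image.

*Boundary traces* (ordered point lists around a disc or vertebral body)
are connected linearly — not splined — and closed; self-intersecting or
collinear traces are rejected, naming the offending segment pair.
*Rasterization* includes a pixel iff its center lies inside the polygon,
with centers exactly on an edge counted inside. This pixel-center rule
is a declared convention of this package, chosen so that a brute-force
even-odd point-in-polygon oracle can verify every mask exactly.

The *anterior–posterior (AP) axis* of a mask is the chord through its
anterior-most and posterior-most pixel centers (projection onto the
anterior vector; ties broken to the smallest row, then column, so
symmetric shapes get an axis-aligned chord). The five regional bands —
1 anterior annulus, 2 anterior nucleus, 3 central nucleus, 4 posterior
nucleus, 5 posterior annulus — are equal-length intervals of this chord.
Band boundaries are half-open with ties to the more anterior band, and
pixels projecting beyond the chord ends fall into the end bands. Masks
narrower than five pixels along the axis are flagged unpartitionable.
(Region 2 is "anterior nucleus" throughout; published tabulations of
this layout sometimes label it "posterior nucleus" in footnotes — a
discrepancy we surface here rather than resolve silently.)

## Morphometry

* **Height** is the mean perpendicular chord between the superior and
  inferior boundary chains, measured at `K = 50` equally spaced stations
  along the AP axis excluding a 5 % tail at each extreme (chords
  degenerate at the AP tips). Both `K` and the tail fraction are
  configuration keys; for an ellipse the station mean matches the
  analytic chord integral to the Riemann error.
* **Width** is the straight-line distance between the anterior-most and
  posterior-most boundary points.
* **Area** is pixel count × pixel area per traced slice; **volume** is
  the sum of slice areas times the effective slice spacing — slice
  thickness plus interslice gap, 3.5 mm + 1.0 mm = 4.5 mm for the
  emulated sequence — divided by 1000 to give cm³.
* **Vertebral-body height** uses the same chord-mean rule, and the
  height-to-vertebral-body ratio divides the disc height by the height
  of the vertebra *inferior* to the disc (T11/T12 → T12, …, L5/S1 → S1).
  Whether a single vertebra or an average of the adjacent pair should
  normalise each disc is not settled; the single-vertebra convention is
  used and recorded here.

## Nucleus-to-annulus ratio

From the single-echo T2-weighted stack, the mean signal of regions 2, 3
and 4 (nucleus) is divided by the mean of regions 1 and 5 (annulus).
Region means are averaged across slices *first* and one ratio is formed
per level (ratio-of-averages); the average-of-ratios alternative exists
behind `ratio_mode` for sensitivity analysis, and a constructed
counterexample in the tests shows the two genuinely differ. The three
nucleus region means enter unweighted even though their pixel counts
differ. The ratio is scale-invariant by construction.

## Phantom

Discs are superellipse cross-sections (exponent 2.5; smooth, simple
polygons with analytic area `4ab·Γ(1+1/n)²/Γ(1+2/n)`), replicated over a
slice extent (slices 2–9 of 12 by default); vertebral bodies are
near-rectangular superellipses (exponent 6). The default grid is a
cropped sagittal lumbar window of 384 × 160 pixels at 0.90 × 0.95 mm —
the acquisition FOV/matrix constants (which give 0.86, 0.27 and
0.61 mm²/pixel for the three emulated sequences) are retained separately
for the analytic geometry checks. Noise is additive Gaussian on the
magnitude by default (the log-linear fit's bias is then analysable),
with a Rician option; phantom noise levels are configurable and default
to σ = 5 (multi-echo S0 = 1000) in the phantom and σ = 2 in the
end-to-end pipeline. Seeds are explicit arguments everywhere; a fixed
spec + seed reproduces stacks bit-for-bit.

Because the measured height is a chord mean, a superellipse of nominal
height h measures `factor(h)` with an analytic factor (< 1); when the
pipeline builds a phantom to realise planted truth values it divides by
this factor so that measured values center on the planted ones.

The phantom does **not** model B0/B1 inhomogeneity, stimulated echoes,
partial-volume effects beyond rasterization, multi-component T2, or
anatomical shape variability. Passing recovery tests therefore
establishes the correctness of the estimators and their conventions, not
robustness to those physical confounds.

## Pfirrmann surrogate

Visual degeneration grading is out of scope; grades are inputs. For
synthetic cohorts a surrogate maps central-nucleus T2 through ordered
thresholds (110, 95, 80, 60 ms separating grades 1|2|3|4|5, roughly
quintiles of the plausible nucleus-T2 range, configurable) to an ordinal
grade, so lower nucleus T2 never yields a lower grade. A regression
slope on these grades is monotone-associative, not a planted linear
coefficient.

## Synthetic cohorts

The cohort generator draws, per sex, BPAQ total scores from a
zero-truncated normal (male 16.97 ± 17.66, female 12.00 ± 13.39), age
(35.15 ± 5.85 / 30.55 ± 5.43), BMI (28.67 ± 4.33 / 29.90 ± 8.95) and
four occupational loading scores. The reported male *current sitting*
location of 770.95 is internally inconsistent with both its own SD and
the female value and is treated as a typographical artefact; the
generator defaults to 30.0 ± 30.65 for that parameter, which remains
configurable. Disc outcomes obey

    y = α(level, outcome) + β·BPAQ + Σ γ_k·(covariate_k − center_k) + ε,

with baselines α derived from the default phantom so the imaging
pipeline can realise them. T2 noise has a shared per-disc component
(SD 10 ms) plus an independent per-region component (SD 6 ms). Residual
SDs (height ratio 0.033, volume 1.2 cm³, nucleus/annulus ratio 0.45)
were chosen to reproduce the confidence-interval scale of per-level
regressions at n = 40 with this exposure spread; pain (VAS) and
disability (ODI) use their descriptive SDs (20 and 9 points), which
makes their intervals somewhat wider than a strict CI-matching choice
would. Default planted effects are confined to L5/S1 (whole-disc T2
β = −0.30 ms per BPAQ unit across all five regions, nucleus-to-annulus
ratio β = −0.02) with a single covariate effect (age on T2, −0.3 ms per
year); all of these are arguments, not constants.

## Statistics

Associations are estimated by OLS (statsmodels) with t-based two-sided
p-values and 95 % CIs; α = 0.05 throughout. The battery mirrors the
analysis design: per-level simple regressions for five outcomes;
covariate screening in which each candidate (age, BMI, current/past
occupational sitting and labour; sex is handled by stratification, never
as a regressor) is kept if its univariate regression against *any* MR
outcome reaches p < 0.05, producing one global covariate set for all
final models (a per-outcome mode is available, since the screening scope
is ambiguous in this design); covariate-adjusted models; average-spine
models on the per-participant mean of the seven levels; sex-stratified
pooled-disc models with exposure and outcome z-scored within stratum
(the standardized slope of a simple model equals Pearson r, checked
numerically); per-level regional-T2 models; and simple pain/disability
models. Pfirrmann grade enters OLS as a continuous outcome; in the
pooled sex-stratified output its sign is inverted by default so that
higher values mean better disc health, matching the presentation
convention of the per-level tables (raw scale) versus pooled figures
(inverse scale).

Pooled-disc models ignore within-participant correlation across the
seven levels by design — a documented limitation of the mirrored
analysis; cluster-robust standard errors by participant are available
behind `cluster_robust_pooled` but off by default. Note that in pooled
strata all covariates are participant-constant, so the design matrix
rank is bounded by the number of participants: sex strata need more
participants than regressors.

Benjamini–Hochberg adjustment (statsmodels `fdr_bh`) is applied as a
sensitivity analysis within declared families: each level's five
outcomes, the five average-spine outcomes, each level's five regions,
and each sex stratum's five pooled outcomes. The family boundaries are
configurable since they are a design choice. Missing data are handled by
listwise deletion and reflected in each model's n (the synthetic cohorts
are complete; this path exists for real tables).

## Problem sizes and numerical tolerances

Noiseless phantoms recover region T2 to ≤ 1e-9 relative error and
nucleus-to-annulus ratios exactly; rasterized areas agree with analytic
polygon areas within one boundary row of pixels. Simulation-based checks
use 10⁴ replicates for the type-I error (tolerance ±0.01 around 0.05),
2000 synthetic cohorts of n = 40 for CI coverage (±2 % around 95 %), and
100 random disc shapes for the partition oracle. The end-to-end
determinism check runs the full pipeline twice on a coarsened
(1.8 × 1.9 mm) grid with 16 participants and compares result CSVs
byte-for-byte; the headline end-to-end run uses the full-resolution grid
with 40 participants. These sizes are the package's defaults for its own
verification and scale linearly if larger runs are wanted.

## Known limitations

* Mono-exponential T2 only; no multi-component or EPG modelling.
* The whole-disc T2 of a regionally heterogeneous disc is an
  estimator-specific quantity (see above), so planted whole-disc effects
  are recovered approximately, not exactly, end-to-end.
* Grade associations are monotone by construction of the surrogate, not
  linear.
* Pooled-disc inference is anti-conservative in principle (repeated
  discs per participant); mirrored intentionally, with a robust-SE
  escape hatch.
* The ROI rasterization rule of the original tracing software is
  unknown; the pixel-center rule here is a convention, and sub-pixel
  disagreements with other tools are expected at boundaries.
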