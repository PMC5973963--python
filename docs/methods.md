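# Methods

## Structural model

Drug disposition follows a two-compartment linear model with first-order
elimination from the central compartment, parameterised as apparent
(oral-bioavailability-scaled) clearance CL/F (L/h), central volume Vc/F (L),
inter-compartmental flow Q/F (L/h) and peripheral volume Vp/F (L).  The
micro rate constants are k10 = CL/Vc, k12 = Q/Vc, k21 = Q/Vp; the hybrid
constants α, β are the roots of s² − (k10+k12+k21)s + k10·k21, computed with
the numerically stable form β = (k10·k21)/α to avoid cancellation when
α ≫ β.  As Q → 0 the peripheral compartment disconnects and the surviving
elimination root tends to k10; `terminal_half_life` accepts Q = 0 explicitly
as the one-compartment reduction ln2·Vc/CL.

Oral input is dual: a fraction F1 of the bioavailable dose enters a
first-order depot (rate constant Ka, lag ALAG1) and the complement 1 − F1
enters the central compartment as a zero-order infusion of duration D2
starting at the dose time.  The lag applies to the first-order route only;
the source analysis attaches the lag to the first-order process and gives
none for the zero-order process, so the zero-order input starting at dose
time is the parsimonious reading (this was a genuinely open point; the
choice is isolated in one code path should the alternative be preferred).

All solutions are closed-form (sums of exponentials; the zero-order route
has during-/post-infusion branches).  Multiple dosing uses superposition;
steady state sums each exponential term's geometric series analytically,
with the first few intervals summed explicitly whenever the dosing interval
is shorter than max(ALAG1, D2), so short intervals are handled by
bookkeeping rather than rejection.  Units are fixed: mg (free-base
equivalents), L, h, ng/mL (mg/L × 1000).

Degenerate Ka (within 1e-8 relative of α or β) is perturbed by 1e-7
relative — deterministic, documented, and far below fitting precision —
instead of switching to separate limit formulas.  Cmax,ss is located by a
0.05-h grid over one interval refined by bounded scalar minimisation
(xatol 1e-6); Cmin,ss is the pre-dose trough; AUC_τ,ss is the exact mass
balance 1000·Frel·dose/CL.

## Covariate model

Continuous covariates use power models θ·(x/x_REF)^θx; categorical
covariates multiply by exp(θx) where θx is the log fractional change, so a
printed fractional change fc maps to the multiplier 1 + fc.  Reference
levels: healthy volunteer, male, White, tablet.  Reference covariate values
are age 60 y and weight 80 kg (the reference-subject definition used for
covariate-impact contrasts) and dose 60 mg for the dose-on-Ka power model
(the modal tablet dose); the analysis from which the coefficients come
states only that approximate medians were used without printing them, so
these anchors are explicit, overridable fields of `ThetaVector`.

Three presets carry the published fixed-effect sets (final model FM, the
variant without cancer-type effects FMECT, and the covariate-free BASE
structure).  F1 carries no covariates; the capsule effect on bioavailability
acts as an overall multiplier Frel on the dose before the F1 split.  The
population level OTH ("other malignancies") covers the mixed-malignancy
phase-1 cohort.

## Variability model

IIV is log-normal on Ka, CL/F and Vc/F (θ_i = θ_T·e^η) and logit-scale on
F1 (so individual F1 stays in (0,1); exp-scale IIV could exceed 1).  The
four published variances are ω²_Ka 2.063, ω²_CL 0.202, ω²_Vc 0.233,
ω²_F1 0.466.  The published CL–Vc off-diagonal term (2.475) exceeds the
Cauchy–Schwarz bound √(0.202·0.233) ≈ 0.217 and cannot be a covariance of a
valid matrix; it is stored as metadata (`PRINTED_CL_VC_TERM`) and never used.
`default_omega(cl_vc_corr=0.5)` builds the diagonal matrix plus a
configurable CL–Vc correlation; the 0.5 default encodes the qualitative
information that the two were estimated with substantial positive
association while keeping Ω valid.  Residual error is additive on the log
scale with σ² = 0.118.

## Synthetic multi-study data

`default_study_suite()` encodes nine virtual studies totalling 1534
subjects: two rich single-dose healthy-volunteer studies (one a
tablet/capsule crossover, encoded as a second dose after a 672-h washout;
one a 20/40/60-mg tablet dose escalation), a phase-1 mixed-malignancy
multiple-dose study (140 or 200 mg capsule, rich days 1 and 19), and phase
2/3 studies in glioblastoma, prostate cancer (three studies, including a
randomized-discontinuation arm sampled pre-dose at even weeks 14–24),
medullary thyroid cancer (day-1 and day-29 serial sampling) and renal cell
carcinoma (samples ~12 h after the preceding daily dose on days 29/57).
Demographics are drawn per study: sex and race multinomial at the observed
proportions (race renormalized over the four known levels where the source
tables carry a not-available category), age and weight truncated-normal at
the observed mean/SD clipped to the observed range.

Deliberate simplifications: sampling at nominal times (optional uniform
relative jitter, off by default); no dropout or dose modification (optional
exponential dropout hazard, off by default); complete covariates; arm
assignment deterministic (arms filled in order).  Planned schedules omit the
pre-first-dose baseline sample: a baseline record is structurally zero drug
and would be a guaranteed below-LLOQ row, whereas the pooled analysis
dataset reported < 1% below-LLOQ records — only consistent with baselines
being absent.  With that convention the simulated BLQ fraction under the
final-model preset is ≈ 0.3%.  Values below 0.5 ng/mL are flagged BLQ and
MDV = 1: retained in the file, excluded from the estimation view (no
M3-type BLQ likelihood).

Because the generator simulates from the same model family that the
estimator fits, passing recovery/detection tests demonstrates correctness of
the machinery, not adequacy of the model for real cabozantinib data —
model misspecification, actual-time deviations, dose reductions and
enterohepatic recirculation are all absent by construction.

## Estimation

The marginal likelihood is approximated Laplace-style.  Per subject, the
joint −2 log density g(η) (log-residual term plus N(0, Ω) prior restricted
to the active random effects — those with positive Ω diagonal) is minimised
over η by a damped Gauss–Newton iteration: the Jacobian J of log-predictions
with respect to η is taken by forward differences (step 1e-5), the curvature
H = 2JᵀJ/σ² + 2Ω⁻¹ drives the Newton step (Levenberg damping, up to 50
iterations, convergence at 1e-8 relative objective change), and the same
interaction-style expected curvature enters the Laplace determinant:

    OFV_i = g(η̂) + log det(H/(4π)).

Using the expected (Gauss–Newton) rather than exact Hessian is the classic
first-order-conditional-with-interaction family choice; it is positive
definite by construction and, on the rich-data toy used in the tests, agrees
with 21-node adaptive Gauss–Hermite quadrature of the exact marginal to
within 0.1.  The named production algorithms of pharmacometric practice
(FOCEI/ITS/SAEM/importance sampling) are not re-implemented; this single
Laplace-family engine stands in for them and every comparison in the package
uses it consistently.  Non-converged subjects are retried from three fixed
jittered starts.  Predictions that are non-positive at an observation time
contribute a large finite penalty, never NaN.

The outer problem optimises transformed parameters — log for positive
structural values and variances, logit for F1, log(1+fc) for categorical
coefficients, identity for exponents — by Nelder–Mead simplex (adaptive for
more than two parameters, xatol 1e-4, fatol 0.05), warm-starting every
subject's inner MAP from the previous outer evaluation.  Identifiability is
declared per configuration: sparse-only datasets should fix ALAG1, D2 and
the dose exponent at preset values (absorption constants need rich early
sampling to be identified).  The parameter covariance, when requested, is
2·H⁻¹ of the OFV's central-difference Hessian on the transformed scale,
symmetrised and ridged to positive definiteness if needed; it feeds the
smoothed parametric bootstrap of the predictive check.

Nested models are compared by ΔOFV against the χ² upper tail with df equal
to the difference in estimated-parameter counts.

## Predictive check

500 replicates by default.  Parameter vectors are drawn multivariate-normal
on the transformed scale around the estimates; draws violating any parameter
invariant are rejected and redrawn with the count reported (drawing on the
transformed scale makes rejections rare).  Each replicate re-simulates the
observed dataset's own design and covariates (resampling covariates is the
documented alternative); the median and 10th/90th percentiles of
concentration per study and nominal time are summarised across replicates by
their 5th/95th percentiles.  Nominal-time binning uses the design's
scheduled times.

## Experiment sizes used in the test suite

Oracle and recovery experiments are sized for a single-CPU desk run: the
ODE cross-check uses 50 random parameter sets × 20 times; the quadrature
comparison 5 subjects × 33 samples; parameter recovery 150 rich-sampled
reference-covariate subjects estimating (CL, Vc, Ka, F1, ω²_CL, σ²); the
covariate-detection experiment 10 replicates of 150 subjects (20% MTC) with
IIV on CL, comparing fits with and without the MTC clearance coefficient
(Ω and σ² fixed at their generating values, so the likelihood-ratio test has
one degree of freedom); PPC calibration 120 subjects over two studies, 100
replicates, with parameter uncertainty set from the log-scale standard
errors implied by the published 90% confidence intervals for CL/F, Vc/F and
Ka.  The recovery experiment uses demographically homogeneous
reference-covariate volunteers so the estimated structural references
correspond exactly to the generating values.

## Known limitations

- Absolute OFV values are comparable only within this engine; they differ
  from other implementations by approximation-family constants.  ΔOFV
  between nested fits is the meaningful quantity.
- No inter-occasion variability, no time-varying covariates, no
  enterohepatic-recirculation or transit-compartment absorption variants.
- The estimator's outer search is derivative-free; very ill-conditioned
  configurations (e.g. near-noiseless data) may need tighter simplex
  tolerances or a restart from the first optimum.
- BLQ records are excluded from the likelihood rather than modelled.
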