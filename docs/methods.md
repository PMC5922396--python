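# Methods

`ctcev` re-implements, as a tested pipeline on synthetic data, the automated
enumeration of circulating tumor cells (CTCs) and tumor-derived extracellular
vesicles (tdEVs) from CellSearch-style 4-channel fluorescence image archives,
together with the downstream biostatistics used to evaluate such counts as
prognostic biomarkers: ROC-based dichotomization against survival,
Kaplan-Meier / log-rank comparisons, Cox proportional-hazards regression with
a shared frailty per dataset, forward stepwise model selection, and Uno's
truncated C-index with bootstrap model comparison. No clinical data ship with
the package; every analysis runs on generated data with known ground truth,
which is what makes each stage falsifiable.

## Image model and simulator

A cartridge is a stack of frames, each with four channels in fixed order:
DNA (DAPI), Marker1 (FITC), CK (cytokeratin-PE), CD45 (APC). The sample-plane
pixel size defaults to 0.67 µm/pixel — a 6.7 µm camera pixel behind a 10×
objective. The simulator plants five object classes as uniform disks:

| class | channels | diameter (µm) | role |
|---|---|---|---|
| `ctc` | CK disk + concentric DNA disk (0.7× diameter) | 6–12 | target cell |
| `tdev` | CK only | 2.0–3.6 | anucleated vesicle |
| `leukocyte` | CD45 + DNA | 7–12 | main confounder |
| `bare_nucleus` | DNA only | 6–10 | distractor |
| `debris` | dim CK (mean 30) | 1.5–3 | distractor |

Disks are blurred with a Gaussian PSF (σ = 0.25 µm by default, the
diffraction-limited width of a 0.45 NA objective at ~550 nm emission), offset
by a constant background (default 5), and degraded with Poisson shot noise
plus additive Gaussian read noise (default SD 2) — the standard CCD model.
Setting `noise_sd = 0` disables the noise model entirely so that planted
intensities and geometry are analytically exact; several tests rely on this.
Default class intensities (CK 140–150, DNA 120, CD45 150 on the 0–255-like
scale the gates assume) place each class clearly on its side of the gate
thresholds. The true instrument's intensity calibration is not public, so
these are nominal values, not a claim about CellSearch photometry; everything
is configurable.

Object placement rejects positions closer than the two radii plus PSF
support, so planted objects never merge. This is a deliberate simplification:
real cartridges contain touching cells and under-segmentation, which the
simulator does not emulate. Passing recovery tests therefore demonstrate
correctness of the segmentation/gating logic, not robustness to clustered
cells.

What the simulator does not model: optical aberrations, cartridge edge
artifacts, non-uniform illumination, channel crosstalk, autofluorescence, and
the immunomagnetic enrichment step.

## Segmentation and features

The original analysis software identifies objects with a multiscale
segmentation whose details are not public. The substitute here is per-channel
median-background subtraction followed by a fixed threshold (default 20
intensity units above background; a triangle-threshold mode is available),
8-connected labeling, and a minimum area of 2 pixels. It sits behind the
`segment_channel` contract so it can be swapped without touching anything
downstream.

Objects are connected components of the union of the per-channel masks within
a frame. Per-channel mean intensity is the background-subtracted mean inside
that channel's own mask restricted to the object, 0 when the channel shows no
contour there. `size_ck` is the CK-contour area in pixels: with 0.67 µm
pixels, the CTC gate's 16–400 pixel window corresponds to ≈3.6–18 µm
equivalent diameter, consistent with cells > 4 µm. `dna_overlay_ck` is
|DNA ∩ CK| / |CK| (a DNA-mask denominator is available by configuration).
Stacks without a Marker2 channel report `mean_marker2 = 0`, which trivially
satisfies "≤ 5" predicates — the 4-layer archives carry no second marker.

## Gates

The CTC gate is the quantitative definition: CD45 ≤ 5, DNA > 45, CK > 60,
Marker1 ≤ 5, Marker2 ≤ 5, 16 ≤ size_ck ≤ 400, overlay > 0.2, with strict and
non-strict comparators exactly as written. The tdEV gate keeps the
CK/CD45/marker predicates, widens the size window to [3, 400] pixels, and
replaces the nuclear requirement with its complement (DNA ≤ 45 **or**
overlay ≤ 0.2): a tdEV is a CK-positive, CD45-negative particle without a
nucleus. The published tdEV gate is in supplementary material that is not
redistributable, so these thresholds are explicitly provisional defaults;
gates serialize to JSON so a replacement drops in. With the defaults the two
gates are provably disjoint (a nucleated object cannot satisfy the tdEV
gate's anti-nuclear clause), and counts are per cartridge — one 7.5 mL blood
draw — with no volume normalization.

## Cohort simulator

Each patient carries negative-binomial CTC and tdEV counts (tdEV mean
defaulting to 20× the CTC mean, the frequency ratio at which these vesicles
outnumber intact tumor cells in the same archives), coupled through a
Gaussian copula with latent correlation 0.8 by default; lognormal CK18,
ccCK18, PSA, LDH, ALP; normal albumin, hemoglobin, age; a dataset label; and
survival from

    h_i(t) = z_g · λ0 · exp(x_i'β),   z_g ~ Gamma(1/θ, θ),  E z = 1, Var z = θ

with exponential baseline (λ0 = 0.05 /month, median ≈ 14 months for a median
patient), per-dataset frailty, and independent exponential censoring whose
rate is solved numerically (Brent) so the realized censoring fraction matches
the configured rate in expectation. Hazard covariates are the same
shifted-log transforms the Cox module applies — counts as
ln(0.0001 + count/1000), enzymes as ln(0.001 + U/L/100) — centered at their
sample means, so generative coefficients are directly comparable to fitted
ones. Default sample sizes (84 + 45) mirror a retrospective plus a
prospective cohort; the demonstration config enlarges them to 200 + 200 so
the qualitative pattern it illustrates is stable across seeds. Times are
continuous months; month-rounded data (heavy ties) are supported by the
fitting code but not generated by default.

## Statistics

- **Quantiles** use linear interpolation between order statistics.
- **Mann-Whitney** uses the exact null distribution when both groups have
  ≤ 25 observations and no ties, otherwise the tie-corrected normal
  approximation. The reported U counts pairs with x < y plus half-ties, so
  U_x + U_y = nm.
- **ROC cut-off**: classes come from the cohort's Kaplan-Meier median
  overall survival. Patients with follow-up ≥ median are long survivors
  regardless of event status; patients who died before the median are short
  (the positive class); patients censored before the median are excluded —
  their class is unknowable, and the source description does not say how such
  patients were handled. Candidate thresholds are the distinct observed
  values; positive means value ≥ threshold (high = unfavorable). The chosen
  cut-off minimizes |sensitivity − specificity|, with ties broken by maximal
  sensitivity + specificity and then by the smallest threshold — a
  deterministic rule that favors discrimination. AUC is the trapezoid area
  under the empirical ROC closed at (0,0) and (1,1). Per-dataset cut-offs
  (needed when plasma collection differs between cohorts) are obtained by
  running the procedure per dataset label.
- **ELISA**: all wells are blank-corrected; a 4-parameter logistic is fitted
  to the 7 standards (log-linear interpolation is the fallback when the fit
  fails — the kit's true curve model is not stated, and 4PL is standard
  immunoassay practice); duplicates are averaged before conversion; samples
  outside the standards' absorbance range are flagged, never extrapolated;
  QC wells outside their declared range abort the plate.

## Survival machinery

Kaplan-Meier and the log-rank test delegate to lifelines; a median that is
never reached is the value ∞, not an exception. The Cox machinery is written
here because no installed Python package fits a gamma shared-frailty model:

- **Plain Cox**: Newton-Raphson on the Efron-approximation partial
  likelihood (Efron rather than Breslow because month-resolution follow-up
  implies heavy ties), with step-halving so the likelihood never decreases,
  convergence at |Δll| < 1e-9 with gradient below 1e-6, Wald CIs and
  p-values from the observed information. Zero-variance or collinear designs
  raise a singular-design error; non-convergence raises an error carrying the
  iteration trace.
- **Gamma shared frailty**: for fixed variance θ the penalized partial
  likelihood PL(β, ω) + (1/θ)Σ(ω_g − e^{ω_g}) is maximized jointly over β and
  the per-group log-frailties ω by Newton; its stationary point satisfies the
  closed-form gamma E-step z_g = (1/θ + d_g)/(1/θ + A_g), so this is the EM
  fixed point with quadratic convergence. θ is then chosen by maximizing the
  integrated (marginal) likelihood — gamma frailty integrates out
  analytically against the Breslow baseline — profiled on a coarse log-grid
  and refined by bounded 1-D search. When the profile optimum is at the
  boundary the model is reported as collapsed to the plain fit with
  frailty variance 0 (with only two dataset labels the variance is barely
  identified, and collapse is the expected outcome for weak heterogeneity).
  β standard errors come from the (β, β) block of the inverse penalized
  information; they do not propagate uncertainty in θ.
- **Stepwise selection** (p_in = 0.05, p_out = 0.10) uses likelihood-ratio
  entry/exit tests — more stable than Wald in small samples; the source does
  not state which its software used. An empty final model is a valid outcome,
  and the add/drop trace is returned.
- **Uno's C** (default τ = 24 months) delegates to scikit-survival's IPCW
  estimator; brute-force pair enumeration is the independent oracle in tests.
- **Bootstrap model comparison** (default 1000 replicates) resamples
  patients with replacement, refits both models per replicate and recomputes
  both C-indices; it reports the full-sample delta, the percentile 95% CI and
  a two-sided normal p-value from delta / bootstrap SE. Replicates that fail
  to fit are skipped and counted. Inside replicates the models are refit
  *without* the frailty term by default: the frailty fit costs ~100× a plain
  fit, and the C-index ranks the linear predictor x'β, which the frailty term
  (a per-dataset constant affecting calibration, not within-model ranking)
  leaves essentially unchanged. The headline models are still fit with
  frailty.

## Problem sizes

Defaults were chosen so a full validation run (test suite plus the
demonstration) completes comfortably on one CPU: 16-frame 256×256 cartridges
(scalable to the archival 144–180 frames), 20-cartridge enumeration studies,
cohorts of 400–500 patients, 100–500 replicate Monte-Carlo studies, and the
demonstration's 1000 bootstrap replicates.

## Known limitations

- The segmentation substitute is not the original multiscale algorithm; on
  real archives its absolute counts would differ even though the gate logic
  is identical.
- The tdEV gate thresholds are provisional (see above).
- Simulated objects never touch; no claim is made about clustered-cell
  performance.
- The frailty fit assumes gamma frailty; the original software's frailty
  family and penalization details are not stated, so the family is isolated
  behind the fitting routine rather than guessed at elsewhere.
- CK18/ccCK18 interaction terms with dataset (used in the source analysis to
  absorb collection-protocol differences) are not built; the simulator
  generates both datasets from one plasma-marker law, so the demonstration
  does not need them.
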