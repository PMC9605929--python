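# Methods

`gliodx` implements a quantitative pipeline for distinguishing recurrent
high-grade glioma from treatment-related change using two simultaneously
acquired modalities: dynamic contrast-enhanced (DCE) T1 MRI analysed with a
two-compartment exchange model (2CXM), and amino-acid PET analysed with
tumour-to-background isocontour metrics. This note documents the models, the
numerical choices, and what the synthetic data can and cannot establish.

## Kinetic model and unit conventions

The 2CXM describes gadolinium exchange between an intravascular compartment
and the extravascular-extracellular space (EES):

```
v_b dC_b/dt = f (C_a - C_b) + ps (C_e - C_b)
v_e dC_e/dt = ps (C_b - C_e)
C_t = v_b C_b + v_e C_e
```

Parameters are carried in reported units — blood flow `F` (mL/100 g/min),
blood volume `BV` (mL/100 g), unidirectional clearance `Ki` (mL/100 g/min,
the Patlak slope, with `ps = Ki f / (f - Ki)`), and EES volume `Ve`
(mL/100 g) — with tissue density 1 g/mL so that mL/100 g and mL/100 mL
coincide. The kinetics are written directly on the blood-equivalent scale:
hematocrit enters only (a) when converting the plasma arterial concentration
to the whole-blood input driving the tissue (`1 - Hct_large`, default 0.45),
and (b) in the optional mapping to plasma-referenced parameters
(`F_p = F (1 - Hct_small)`, `v_p = BV (1 - Hct_small)/100`, default
`Hct_small` 0.25; `to_plasma_parameters`). Under this convention the tissue
impulse response `h` satisfies exactly: `h(0) = F/6000` per second, and
`∫h dt = (BV + Ve)/100` whenever `Ki > 0` (with `Ki = 0` the EES is
unreachable and the area is `BV/100`). `Ki = F` is handled as the exact
flow-limited limit (one well-mixed compartment); `Ki > F` is rejected
(extraction cannot exceed delivery).

The forward model decomposes `h` into its exponential modes (eigen-solution
of the 2×2 rate matrix) and convolves each mode with the piecewise-linear
arterial input *exactly*, via a first-order recurrence evaluated as an IIR
filter. The forward curve therefore has no quadrature error beyond the
piecewise-linear representation of the AIF itself, and the same code path is
used for synthesis and fitting.

## Arterial input function

A population-style analytic AIF: gamma-variate first pass
`A (τ/αθ)^α exp(α - τ/θ)` (defaults: peak amplitude 5 mM plasma, shape 3,
scale 4 s, bolus arrival 30 s) plus a slower recirculation/washout term
(fraction 0.25, rise 25 s, decay 220 s). Clinical practice measures the AIF
from an arterial voxel; the analytic form is the phantom's known ground
truth and is configurable throughout.

## T1 mapping and concentration conversion

Variable-flip-angle (VFA) spoiled-gradient-echo volumes (≥ 4 distinct
angles — fewer is rejected, mirroring a common exclusion rule) are fitted
per voxel with the linearised DESPOT1 regression as initialiser and bounded
nonlinear refinement (T1 ∈ [50, 8000] ms). Degenerate voxels are flagged
invalid, never raised. The SPGR model assumes perfect spoiling and ignores
T2* decay (reasonable at the short echo times of DCE protocols).

Dynamic frames are inverted analytically for T1(t) and converted as
`C(t) = (1/T1(t) - 1/T1(0)) / r1`, default relaxivity `r1` = 3.6 s⁻¹mM⁻¹ at
3 T (configurable; protocols differ). The dynamic series' effective M0 is
re-scaled from the pre-contrast baseline frames because dynamic and VFA
acquisitions may differ in gain (configurable off). Signals above the
theoretical SPGR saturation value are flagged and clamped (or set NaN).

## Tikhonov deconvolution and flow read-out

Blood flow is estimated model-free by solving

```
min_h ||A h - c||² + λ² ||L h||²,    h ≥ 0,
```

with `A` the convolution matrix of the whole-blood input and `L` a
second-difference operator (identity available). Two numerical choices
matter and were validated against the phantom:

* **Quadrature.** `A` is built from exact hat-function (piecewise-linear)
  quadrature, so the unknowns are the response values *at the grid nodes*.
  A rectangle rule instead recovers interval averages, which at 1 s sampling
  biases the flow read-out (the response maximum) ≈ 13% low for typical
  tissue transit times — larger than the recovery tolerance this package
  tests for.
* **λ selection.** Default is the Morozov discrepancy principle: the noise
  level is estimated per voxel from the pre-bolus frames and λ is the
  largest grid value whose residual stays within it. On noiseless data this
  degenerates to minimal smoothing (sub-1% flow error); at realistic noise
  it buys exactly as much smoothing as the noise demands. The L-curve corner
  (the textbook default, also implemented) under-regularises this system
  catastrophically at realistic noise and over-smooths noiseless data; GCV
  is stable but over-smooths the peak (flow ≈ −30% at SNR 20). Solutions
  with material negative excursions are refined under a non-negativity
  constraint (`h ≥ 0` is physiology, and the flow read-out is `max h`).

`F = 6000 × max h`. No bolus-delay correction is applied: phantom AIF and
tissue curves share one clock. Real data with arterial-to-tissue delay would
need an alignment step this package does not provide.

At SNR 20 the deconvolved flow is noisy and, depending on the selection
rule, biased (discrepancy: roughly +20% median; GCV: −30%); the downstream
BV fit is insensitive to this (a ±20% flow error moves fitted BV by ∓≈7%),
which is why the noisy-chain acceptance criterion is stated on BV.

## 2CXM fitting

With flow held at the deconvolved value (a joint-fit flag re-estimates it),
`(BV, Ki, Ve)` are fitted by bounded nonlinear least squares (default bounds
BV ∈ [0, 20], Ki ∈ [0, F], Ve ∈ [0, 60] mL/100 g(/min)); the initialiser
takes BV from the early-phase area ratio, Ki from the late Patlak slope, and
Ve = 20. The fit is exposed statsmodels-style:
`TwoCompartmentExchangeModel(curve, aif, f).fit()` returns a results object
with estimates, asymptotic standard errors from the Gauss–Newton
approximation, the fitted curve and a `summary()` table. Non-convergent
voxels are flagged invalid with the residual recorded.

## Lesion delineation and metrics

* `VOL_FET`: PET uptake > 1.6 × the mean of a contralateral-cortex
  background VOI, restricted to 26-connected components intersecting a
  lesion seed mask (the seed stands in for report-guided reading).
* `VOL_BV`: BV > factor × a ~1 mL normal-appearing white-matter (NAWM)
  reference mean, default factor 2.0 — a *surrogate* for the visual
  delineation used clinically; the downstream diagnostics consume
  `BV_max`/`nBV_max` regardless of the factor. A vessel-exclusion mask
  removes macrovascular signal; its absence warns (the manual step has no
  automatic equivalent).
* Metrics: `TBR_max` (max uptake in VOL_FET / background mean), `BV_max`
  (max BV in VOL_BV), `nBV_max = BV_max / NAWM mean`, and medians
  (`TBR_med`, `F_med`, `BV_med`, `Ki_med`) over the contrast-enhancing
  volume. Fallbacks when VOL_BV is empty: enhancing lesions use VOL_CE,
  non-enhancing use VOL_FET, and if that is also empty, a 1 mL sphere at the
  FLAIR lesion centre; an empty VOL_FET mirrors the same chain for uptake.
  If every region is empty the metric is NaN (missing), never zero. Metrics
  are reported at full precision; 1-decimal rounding is presentation only.

## Outcome adjudication

A deterministic reduction of modified-RANO response assessment to a pure
function: histology (tumour/no-tumour, any day — late confirmatory surgery
counts) takes precedence over MRI (≥ 25% increase of the bidimensional
diameter product at a follow-up ≥ 4 weeks later and within 6 months ±
2 weeks → progression; > 50% reduction → regression; otherwise stable; any
new enhancing lesion or flagged non-enhancing progression → progression)
over a clinical-deterioration flag. "Significant non-enhancing progression"
and "clinical deterioration" are boolean inputs — no quantitative rule
exists for them. A no-tumour histology combined with a clinical progression
flag is returned non-evaluable ("conflicting; clinical decision required")
rather than auto-resolved. Patient outcome: progressive if any lesion is,
non-progressive if all evaluable lesions are, else non-evaluable.

## Diagnostics

ROC AUC is the rank (Mann–Whitney) statistic with tie correction; multiple
covariates are combined through a maximum-likelihood logistic fit whose
linear predictor feeds the same ROC machinery (on perfect separation the
implementation warns and falls back to the best single covariate's rank
AUC). Paired AUCs are compared with the DeLong placement-value test.
Empirical cut-offs maximise Youden's J over the observed values under a
strict "value > cut-off is positive" convention, ties broken toward the
lower cut-off (favouring sensitivity; the convention is not derivable from
published tables). Proportion CIs are exact Clopper–Pearson; the odds-ratio
CI is the exact conditional (Fisher noncentral hypergeometric) interval,
with unbounded limits rendered "n.a."; normal approximations are available.
Combination rules: concordant-AND (positive only if positive on both
modalities) and sequential-BV-first (PET required only when BV is negative),
the latter also reporting the fraction of lesions spared the second test.
Patient-wise analysis takes the maximum metric across all of a patient's
lesions, including lesions without a lesion-wise outcome. Subgroup analyses
are row filters feeding the same operations. No multiplicity adjustment is
applied (two-tailed 0.05 convention).

## Synthetic data: what it emulates, what it does not

The DCE phantom drives known parameter maps through the same 2CXM + SPGR
equations the pipeline inverts, with seeded Gaussian noise; the PET phantom
places smooth raised-cosine spheres of configurable peak-to-background ratio
(profile `bg (1 + (ratio-1) cos²(πr/2R))`) over a uniform background, which
makes the supra-threshold sub-volume analytically countable. The cohort
generator draws `TBR_max`/`BV_max`/`nBV_max` log-normally per outcome group
(medians 1.7/2.8, 3.4/14.7, 4.9/20.5 matching published lesion summary
statistics; log-sigmas 0.30/1.1/1.1 calibrated once to the published ranges,
giving the PET metric the larger standardized separation), correlated
through a shared latent factor (weight √0.5 by default; the true correlation
is not published and is exposed as a parameter).

A green phantom test establishes that the *inverse chain is consistent with
the forward model* — not that the model describes tissue. The phantoms have
no anatomy, motion, B1 inhomogeneity, k-space artefacts, partial-volume
mixture, water-exchange effects, arterial delay/dispersion, or PET scanner
physics; cohort draws are exchangeable across lesions within a group
(no within-patient correlation of metrics). Published AUCs and cut-offs
depend on the unavailable patient data and are deliberately not asserted;
the cohort tests check structural properties (counts, calibration, the
FET > BV ordering on average) instead.

## Numerical defaults

| Quantity | Default | Why |
| --- | --- | --- |
| Hct large / small | 0.45 / 0.25 | standard large-/small-vessel values |
| r1 relaxivity | 3.6 s⁻¹mM⁻¹ | gadobutrol-class at 3 T; configurable |
| TR / dynamic flip | 5 ms / 15° | typical 3-T DCE protocol placeholders |
| VFA angles | 2, 5, 10, 15° | ≥ 4 distinct angles required |
| frame spacing / duration | 1 s / 300 s | high-temporal-resolution DCE |
| λ grid | 10⁻⁶…10⁰ × σ_max, 25 points | spans under- to over-smoothing |
| FET isocontour | 1.6 × background mean | established delineation threshold |
| BV isocontour factor | 2.0 × NAWM mean | surrogate for visual reading |
| T1 bounds | [50, 8000] ms | physiological range |
| evaluation window | 182 ± 14 days | 6-month follow-up convention |
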