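# Methods

This note records the statistical model, the algorithmic choices, and the
limits of what the test suite demonstrates.

## Data model

The unit of analysis is a (chemical, endpoint) **group**: per
concentration *d* (µM), binomial counts (*x* affected of *n* observed),
optionally resolved by plate. Binary per-well observations aggregate to
these counts with NA wells excluded from both numerator and denominator.
Pre-computed proportions are accepted; when they come without
affected/total counts, each row enters the likelihood with unit weight
(the group is flagged `unit_totals`), which preserves the point estimates
but understates the information content — supplying counts is always
preferable.

Value parsing is deliberately tolerant of CSV dialects (numeric and
textual 0/1; empty string, `NA`, `NaN`, `null` → missing), but duplicated
(chemical, concentration, plate, well, endpoint) keys are a hard error:
they almost always indicate a double upload, and silent deduplication
would bias the denominators. Concentrations are compared by exact
equality after float parsing; no binning of near-equal doses is
attempted.

## LPR transform

Continuous larval photomotor response traces are reduced to two per-well
scores against a cycle plan (phase length L, inter-phase gap G, first
phase, number of cycles; phases are half-open intervals [start,
start+L), gap timepoints belong to neither phase):

- **AUC** — trapezoidal area under the movement trace in the dark phase
  minus the light phase, summed over cycles. Trapezoids on the observed
  timepoints make no assumption about uniform sampling.
- **MOV** — movement at the first dark timepoint minus the last light
  timepoint of each cycle, summed over cycles.

Missing values propagate: any NA among the points a cycle needs makes
that score NA, and wells whose traces cannot cover a full cycle (fewer
than two samples in either phase) are NA with a logged reason.

Dichotomization is referenced to same-chemical controls: a well is
abnormal (1) when its score falls strictly outside the inclusive
2.5th–97.5th percentile band (linear interpolation) of the chemical's
non-NA control scores; at least 10 usable control scores are required or
the endpoint is skipped for that chemical. Percentile bounds, the
minimum control count, and per-cycle summation (vs averaging) are
configurable — the dichotomization rule is this package's declared
default, chosen so that by construction about 5% of control wells are
called abnormal.

## Eligibility filters

Three filters run in a fixed order; a removed group is attributed to the
first filter that fails it, so `kept + Σ removals = input` always holds.

1. **Negative control** (default threshold 0.50): the control
   (0 µM) response of each plate is computed per chemical, pooled across
   endpoints, and plates with response strictly above the threshold are
   dropped from every group of that chemical; groups re-aggregate from
   surviving plates and the later filters see the re-aggregated counts.
   Pooling the plate statistic across endpoints makes the action genuinely
   plate-level — a plate with sick controls is distrusted for all of that
   chemical's endpoints, not selectively. Groups without plate resolution
   or without control data pass with a flag.
2. **Minimum concentrations** (default 3): a group must retain at least
   3 distinct non-zero concentrations with observed wells.
3. **Correlation** (default ρ ≥ 0.2): Spearman rank correlation (average
   ranks for ties, NA pairs removed) between pooled concentration and
   response; groups below the threshold, or with an undefined ρ (fewer
   than 3 usable dose points, or zero variance), are removed. A ρ equal
   to the threshold is kept; the comparison carries a 1e-12 slack so a
   rho that equals the threshold up to float rounding is not removed.

Boundary semantics (strict `>` for the control filter, `≥` keeps for the
other two) are fixed and recorded in the report. Spearman ρ is recorded
for every input group — including those already removed — so the
keep/remove histogram covers the whole screen.

## Quantal model suite

Eight response models (forms in `models.py`), constrained to
non-decreasing curves: background g ∈ [0, 1), slopes ≥ 0, and the gamma
shape, Weibull power and log-probit slope box-bounded to [0.2, 18] to
exclude degenerate near-step fits. The logistic and probit models carry
no explicit background term; their dose-0 value plays that role in the
extra-risk scale. Log-dose models take the value g at dose 0 by
continuity, so control rows still inform the background.

Fitting maximizes the binomial log-likelihood of the pooled counts
(binomial coefficients omitted; they are constant in the parameters, so
likelihood ratios and AIC differences are unaffected). Probabilities are
clipped to [1e-9, 1 − 1e-9], turning impossible observations into large
finite penalties; a fit whose curve touches the clip bounds at an
observed dose is flagged. The optimizer is L-BFGS-B on the bounded box
from five deterministic starts: one moment-style heuristic (background
from the control response, dose scale from the half-maximal dose) plus
four perturbations drawn from a generator seeded by the user seed and
the model's index, so identical inputs and seeds reproduce identical
fits. AIC = 2k + 2·NLL with k the number of free parameters (2 for
logistic/probit/quantal-linear, 3 otherwise).

## Selection workflow

Per group: (1) drop unconverged fits; (2) Pearson χ² goodness of fit
against the pooled counts, df = #doses − k; candidates with p < 0.1 are
removed, fits with df ≤ 0 are kept but flagged `gof_undefined`; (3) AIC
window — candidates within 2 of the smallest AIC (inclusive); (4) BMDL
for every candidate; (5) winner = smallest BMDL, ties broken by lower
AIC, then by the conventional model listing order. If every BMDL is
undefined the lowest-AIC candidate is reported flagged
`bmdl_unavailable`.

**BMD.** Extra risk is the default scale (added risk available via
`risk="added"`). Closed forms are used for quantal-linear
(−ln(1−q)/b) and Weibull ((−ln(1−q)/b)^{1/a}); other models are solved
by bracketed Brent root-finding at relative tolerance 1e-10. The two
routes agree to 1e-6 relative on parameter grids (tested). Fits with all
slope-like parameters ≤ 1e-8 are flat: no BMD exists. A finite BMD more
than 10× beyond the largest tested concentration is treated as not
attained — the benchmark response is reached only by extrapolation far
outside the data, which is the operational meaning of "the treatment
shows no concentration effect" here — and the group's status becomes
`not_fit`.

**BMDL.** Profile likelihood at the 95% one-sided level: the slope-like
parameter is re-expressed exactly in terms of a hypothesized BMD (for
each model a closed-form inversion exists), the remaining parameters are
re-optimized, and the bound is the smallest BMD whose profiled deviance
stays within χ²₁(0.90) = 2.706 of the MLE deviance. The crossing is
located by a downward geometric walk from the MLE followed by bisection
in log-dose (relative tolerance 1e-3, floor at BMD×1e-8); warm starts
chain along the walk. BMDL ≤ BMD is enforced by construction. Measured
on the standard simulated design, the bound undercovers the true BMD at
≈ 95% as intended (the acceptance script recomputes this).

## Outputs

Wilson score intervals at 95% (via statsmodels, clipped to [0, 1]) are
the binomial CIs in `dose.csv` and the plots; method and level are
arguments. The `fits.csv` grid is 100 log-spaced points from (smallest
positive dose)/10 to the largest dose, plus dose 0; plots draw dose 0 at
the grid origin on the log axis. Reports are plain markdown (or the same
text wrapped in minimal HTML) with a fixed section order — Data Input,
Pre-processing, Filtering, Model Fitting, Parameters — and are
byte-identical for identical state when `--reproducible` suppresses the
timestamp.

## Synthetic data

The generator emulates a plate-based screen: the default design is six
concentrations {0, 0.5, 1, 5, 10, 50} µM, 32 wells per concentration on
two plates, and a quantal-linear truth with 5% background and slope
0.2 µM⁻¹ — a mid-potency active chemical in a typical zebrafish assay.
The mixed study (`default_study`) adds flat (inactive) chemicals, sparse
concentration series, and plates with forced 60–75% control response, so
every filter and fit status is exercised. The LPR generator produces
low-movement light phases and a dark-phase burst that attenuates with
dose following a saturating (EC₅₀-style) curve, with Gaussian noise
clipped at zero.

What the generator does not emulate: plate effects and spatial
(edge-well) correlation, inter-fish variability beyond binomial
sampling, dose-measurement error, and the heavy endpoint correlation of
real morphology panels. Passing tests therefore demonstrate the
estimator's behavior under clean binomial sampling, not robustness to
those real-data artifacts.

## Problem sizes in the checks

The simulation-backed checks use 500 replicates for the GOF calibration,
100 replicates for BMD recovery/BMDL coverage, and 50 replicates for the
end-to-end model-recovery regression, all at the standard six-dose,
32-wells-per-dose design; these sizes put the Monte-Carlo error
comfortably inside the asserted bands while keeping the suite quick to
run.

## Known limitations

- Proportional input without counts weakens the likelihood (unit
  weights); GOF p-values are then not calibrated.
- The Pearson χ² GOF is asymptotic; with very small n per dose its
  calibration degrades (the suite verifies it at n = 32).
- Profile BMDL assumes the χ²₁ deviance calibration; for parameters on
  the boundary (g = 0) the bound is conservative.
- Model-count outcomes on large screens are sensitive to optimizer
  starts and GOF conventions; different but defensible choices shift
  which of several near-equivalent models wins a group.
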