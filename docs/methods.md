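# Methods

## Outcome statistic

Each OCT scan yields mean layer thicknesses on the ETDRS grid quadrants
(temporal/superior/nasal/inferior) of the 3 mm inner and 6 mm outer rings,
for eleven Spectralis segmentation layers. The analysis tracks the GCL of
the *most affected inner quadrant*: the quadrant with the most negative
percent change at the patient's earliest scan, held fixed over follow-up
(re-selecting per visit would bias the time series toward noise minima).
Ties break in the fixed order T < S < N < I. "Most affected" is
operationalised as largest percent loss, not largest absolute loss — a
choice, documented rather than asserted.

Percent change is `-(1 - affected/reference) x 100`, so negative values are
thinning and -100 is total loss. Thickening is retained, not clipped. The
reference is the healthy fellow eye when the patient has one, otherwise the
normative per-(quadrant, layer) mean from a reference group of non-BRAO
eyes; the two sources are never mixed within one cell and the chosen source
is flagged. Scans are never averaged within a day: each scan is one
regression observation.

## Decay model

`%change(t) = (Y0 - P) e^(-kt) + P` with Y0 = change at day 0, P = plateau,
k >= 0 per day. Fitting is ordinary nonlinear least squares
(`scipy.optimize.least_squares`, bounded k >= 0, ftol/xtol/gtol 1e-12).
Initialisation is deterministic: the model is linear in (amplitude,
plateau) for fixed k, so a profiled scan over ~60 log-spaced k candidates
(plus k = 0) solves the inner linear problem exactly and seeds the polish;
a quartile-mean heuristic start (Y0 from the earliest quartile of days, P
from the latest, k = ln 2 / median day) is run as a second start and the
better objective wins. Points are canonically sorted before fitting, making
the result exactly permutation-invariant. Seeded jittered restarts are a
rescue path only; non-convergence raises, never returns silently.

Fit statistics: residual SD `Sy.x = sqrt(SSE/(n-3))` (the sigma consumed by
the power analysis), `R^2 = 1 - SSE/SST` (undefined, reported as NaN, when
SST = 0), parameter SEs from the Jacobian at the solution, and a p-value
from the extra-sum-of-squares F test of the 3-parameter decay against the
1-parameter constant-mean model (df 2, n-3).

A brute-force grid search over (Y0, P, k) serves as an independent
least-squares oracle in the tests: it must never undercut the optimizer's
objective.

## Trial sizing

Treated mean at day t under drug efficacy e in [0, 1] is
`(1 - e) x %change(t)`: a fully effective drug abolishes all loss, an
ineffective one leaves the natural course. Cohen's d is
`e |%change(t)| / sigma`. The minimum patients per group is the smallest
integer n whose two-sided two-sample t-test at alpha = 0.05 reaches power
0.8, computed from the noncentral-t distribution (noncentrality
`d sqrt(n/2)`, df `2n - 2`), floored at 2. The power function is
implemented in-repo on `scipy.stats.nct`; `statsmodels` power solvers and a
Monte-Carlo power simulation are used as independent oracles in the tests,
never as the implementation. scipy's noncentral-t CDF is NaN for some large
noncentralities at small df; the lower-tail term is zeroed there (it is
below 1e-15 wherever the NaN occurs).

### Reconstructing the published planning table

The published table's sigma is unprinted. Back-calculating from the printed
cells shows (a) a single constant sigma close to 24% underlies the whole
grid, and (b) the grid is **only** reproducible when the intermediate
quantities are rounded at the precision planning tables print them:
predicted %change to a whole percent and Cohen's d to two decimals, before
the sample-size lookup. Without rounding, no constant sigma gets the
20%-efficacy column closer than ~7–16 patients/group (n scales as 1/d^2, so
small-d cells amplify any sigma misfit); with the rounding convention the
reconstruction matches 16/20 cells exactly and none worse than 2.

Sigma is therefore calibrated by least squares on patients-per-group over
the printed cells (leave-one-out when a cell is itself being predicted),
scanning sigma over 20–28% in steps of 0.005: with integer sample sizes the
objective is piecewise constant, so the scan is exact up to the step and
the mean of the minimising set is returned (sigma = 23.83% on all 20
cells). The rounding convention is exposed as parameters
(`change_decimals`, `d_decimals`) and applied only by the reconstruction
helpers; the generic grid builder defaults to no rounding, which is the
right choice when sigma comes from one's own fit rather than from a printed
table.

The design treats the n patients as supplying both arms (one BRAO and one
unaffected eye per patient) but the statistical unit is the unpaired
two-group t-test, matching the published design; paired or crossover
designs are out of scope.

## Synthetic cohort generator

Defaults are the study conditions: 17 patients; 1–5 scans per patient with
counts drawn from a truncated geometric (mean ≈ 2.2, matching 38 scans from
17 patients); visit days uniform on [0, 1040] (an `early_weighted` schedule
with density ∝ 1/sqrt(day) is available); decay truth Y0 = -9.5%,
P = -55.7%, k = 0.01/day; Gaussian noise SD 24% added **on the %-change
scale**, because that is the scale the regression is fit on. Raw micrometre
thickness is back-computed from the reference value, so the %-change
pipeline inverts the generator exactly — the generated noise is the fit's
residual noise, with no extra distortion from the thickness round trip
(applied change is truncated just above -100% to keep thickness positive;
at the default noise this affects <1% of scans). Between-patient
heterogeneity of k is exposed (`between_patient_sd_k`, truncated at 0) but
defaults to 0: individual patients visibly differ in decay rate, but no
published estimate of that spread exists, so none is asserted.

Each eye's reference thicknesses are drawn once from the normative profile
and held constant across visits: raw-scale measurement noise is not
modelled. Consequences: fellow-eye references are noiseless repeats, and
unaffected cells show %-change scatter only relative to the normative mean
(tested to centre on 0). The normative profile's absolute values are
documented placeholders with realistic magnitudes (GCL ≈ 50 um inner ring);
they cancel out of every %-change quantity and carry no scientific claim.

What passing tests show — and what they do not: the pipeline recovers known
decay parameters from data with the study's noise structure, and the power
arithmetic is correct; nothing here validates segmentation quality,
reperfusion dynamics, co-morbidity effects or any other feature of real
BRAO records.

## Expected fit quality by visit schedule

With noise SD 24 and n = 38, uniform visit days give a population R^2 of
about 0.13 (Var of the curve over uniform days ≈ 83 against noise variance
576), mean fitted R^2 ≈ 0.18; the early-weighted schedule concentrates
observations where the curve moves and yields mean R^2 ≈ 0.36. Aggregate
fit quality is thus as much a property of the visit schedule as of the
biology, which matters when comparing synthetic and clinical fits.

## Problem sizes

Simulation-backed tests use 200 replicates of 500-point series for
parameter recovery, 30 seeds for the R^2-regime check, and 50,000
Monte-Carlo replicates per cell for the power oracle; the acceptance script
uses 50 replicates of 500-point series. These sizes make the checks stable
at the stated tolerances while keeping the default suite fast.

## Known limitations

* The efficacy model (treated mean = (1 - e) x placebo mean) and the
  constant-sigma reading of "standard error of the regression line" are
  reconstructions consistent with the printed grid, not printed procedure.
* The published table's own calculator internals are unknowable; individual
  cells can legitimately differ by 1–2 patients from a principled
  noncentral-t answer (back-solved per-cell sigma spreads ≈ 23.7–24.8%).
* No mixed-effects modelling: pooling patients' points understates
  between-patient correlation; the aggregate fit is a population-average
  curve, as in the source design.
* Only the inner 3 mm ring drives the default analysis; outer-ring rows are
  parsed but unused unless configured.
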