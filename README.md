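# braotrial

Branch retinal artery occlusion (BRAO) infarcts a sector of the inner
retina. On OCT, the ganglion cell layer (GCL) of the affected quadrant
thins rapidly over the weeks after onset, which makes GCL thickness a
candidate structural endpoint for trials of neuroprotective drugs (e.g.
calpain inhibitors). `braotrial` implements that planning pipeline as a
tested library:

1. **Percent change** — for each patient, the most affected inner-ring
   (ETDRS 3 mm) GCL quadrant is tracked against a reference: the healthy
   fellow eye when present, otherwise a normative profile of non-BRAO eyes:
   `%change = -(1 - BRAO/non-BRAO) x 100`.
2. **Decay fit** — the pooled (day, %change) points are fit by nonlinear
   least squares to a single-phase exponential decay
   `%change(t) = (Y0 - P) e^(-kt) + P`, with Y0 the change at onset, P the
   plateau and k the decay constant per day. The published aggregate fit is
   `%change(t) = 46.2 e^(-0.01 t) - 55.7`.
3. **Trial sizing** — a drug of efficacy e is assumed to scale the natural
   loss by (1 - e). Cohen's d at trial day t is `e |%change(t)| / sigma`
   with sigma the residual SD (Sy.x) of the regression, and the minimum
   patients per group comes from exact noncentral-t power of a two-sided
   two-sample t-test (alpha 0.05, power 0.8).
4. **Synthetic cohorts** — a generator draws eye-level thickness tables
   with the study's longitudinal structure (17 patients, 1–5 scans each,
   days 0–1040, %-scale noise SD 24), so every stage is testable without
   patient data.

## Worked example

```sh
python analysis/01_simulate_cohort.py
python analysis/02_fit_decay.py
python analysis/03_plan_trial.py
```

The first script draws a synthetic cohort (17 patients, 37 affected-eye
scans over days 13–1040 with the default seed). The second pools the
%-change series and fits the decay; with 37 noisy scans the estimates are
wide, e.g.

```
fit: %change(t) = 35.6*exp(-0.0026*t) + (-59.5)
     Sy.x = 27.2%, R2 = 0.11, p(decay vs constant) = 0.13
```

— a reminder that at this noise level (%SD 24) a ~38-scan cohort constrains
the plateau far better than the rate. The third script rebuilds the
published planning table from the published curve, calibrating sigma from
the printed cells (sigma = 23.83%):

```
efficacy    0.2  0.4  0.6  0.8  1.0
trial_days
30          486  130   57   34   22
60          253   64   29   17   11
90          165   42   20   12    8
180         100   25   12    8    6
agreement with the published table: 16/20 cells exact, max deviation 2 patients/group
```

Read: a 60-day trial of a 60%-effective drug needs 29 patients per group; a
fully effective drug tested over 180 days needs only 6. The same script
then sizes the grid from the synthetic cohort's own fit.

The pieces are also exposed on a CLI:

```sh
braotrial simulate --seed 1 --out cohort/
braotrial percent-change --in cohort/thickness.csv --out series.csv
braotrial fit --in series.csv --out fit.json
braotrial plan --fit fit.json --out grid.csv
```

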