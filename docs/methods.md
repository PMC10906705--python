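# Methods

## Setting and data model

An optical particle counter (100 L/min flow, isokinetic inlet) placed
near the patient's mouth reports differential particle counts in six
diameter channels — 0.5–0.7, 0.7–1.0, 1.0–3.0, 3.0–5.0, 5.0–10.0 and
10.0–25.0 μm — averaged over 7-second intervals. Timestamps are
interval starts; every window in the package is half-open, `[t, t+7)`,
so window membership is unambiguous. Channels are summed into two size
fractions at a 5 μm cutoff: *aerosols* (≤ 5 μm) and *droplets* (> 5 μm).
Each channel must lie entirely on one side of the cutoff, making the
fractions a partition that conserves row sums. Counts are stored as
per-channel differential counts; cumulative ≥-size exports can be
differenced on read.

One *procedure* is a recording plus metadata: arm (EGD or Cytosponge),
procedure start/end, sedation, demographics, and timestamped event
annotations from a closed vocabulary (insertion, removal, intubation,
extubation, throat_spray, burp, null_reference). "Burp" deliberately
covers any involuntary audible expulsion of air — coughs and gags
included — so there is no separate cough label.

## Whole-procedure analysis

Counts are normalised for procedure length to a 20-minute equivalent,
`N₂₀ = N · 20/T` (T in minutes), so arms with different mean durations
(7.2 vs 8.1 min) are compared per unit time. A 5-minute reference
window immediately before the procedure start provides the
within-patient background level; it is flagged (and excluded from
paired comparisons) if any annotated event falls inside it, or absent
when the recording starts less than 5 minutes before the procedure.

Respiratory particle production is multiplicative across its sources,
so counts are modelled as log-normal. A between-group fold change is
the geometric-mean ratio `exp(mean log a − mean log b)`; inference is a
Welch (unequal-variance) *t*-test on the log scale with Satterthwaite
degrees of freedom — the arms have unequal n and no variance-equality
claim is warranted — and the 95% CI is the exponentiated *t* interval.
Procedure-vs-reference comparisons are paired *t*-tests on within-patient
log differences. A pseudocount of +1 is added before every log
transform, identically in all groups, so zero counts are representable;
at 20-minute-equivalent magnitudes (10³–10⁵ counts) its effect is
negligible. CIs are fixed at 95% and p-values are reported raw, without
multiple-testing correction.

The *spike* variant subtracts a running median from each fraction's
series before windowing. The kernel is 11 samples (≈ 77 s): long
relative to event transients (a few seconds, smeared over ~3 intervals
by the counter's averaging) and short relative to room-background
drift. Edge windows shrink rather than pad, so no counts outside the
recording are fabricated. The residual's positive part is the spike
series; the signed residual is retained because the event-excess
distribution needs its negative half. The filter runs on the aggregated
fractions by default (per-channel filtering before aggregation is a
config switch; the two orders differ only through the nonlinearity of
the median and are indistinguishable at these count levels).

## Event-based analysis

An event's *excess* in each fraction is the count sum over
`[t, t+21 s)` (three intervals) minus the per-interval median over the
preceding 70 s (ten intervals) times three. The median baseline is
robust to nearby transients; subtracting it makes the excess invariant
to adding any constant to the series. Excesses are signed: when the
local baseline happens to overestimate the event window the excess goes
negative, which is why the pooled excess distribution is modelled as a
mixture of a log-normal (genuine event production, support x > 0) and a
normal (subtraction noise). The mixture is fitted by EM with four
starting weights (0.05, 0.3, 0.6, 0.9) and the best log-likelihood
kept; non-positive samples have zero log-normal responsibility by
construction, component scales are floored at 1e-4 to avoid collapse,
and the log-likelihood trace is stored so monotonicity is checkable on
every fit. Fewer than 8 samples, or no positive sample, is refused.

*Null-reference* windows — moments with no annotated activity — are the
baseline for event fold excesses. Per procedure, up to 3 null windows
are sampled uniformly without replacement from interval starts that are
(i) at least 60 s from every annotation, (ii) pairwise 60 s apart,
(iii) at least one baseline window after the procedure start, so the
step in procedure-attributable production at the onset does not
contaminate the local baseline, and (iv) early enough that the event
window fits before the procedure end.

Fold excesses are ratios of group summaries. Because excesses can be
non-positive, the summary is the mean of positive parts
(`mean(max(x, 0))`, floored at 1e-9 and flagged when the floor binds)
rather than a geometric mean; median and plain-mean summaries are
available behind a config switch. Inference is a percentile bootstrap:
both event lists are resampled with replacement n_boot times (default
10,000; at least 1,000), the 95% CI is the 2.5–97.5 percentile interval
of the bootstrap ratios, and the two-sided p-value is twice the smaller
proportion of bootstrap ratios on either side of 1, with a +1/(n_boot+1)
continuity correction so p is never exactly zero. All resampling is
driven by explicit seeds recorded in the run manifest.

## Cohort comparison

Discrete demographics (smoking, sex, throat-spray use) are compared
with a two-sided Fisher exact test implemented by summing, in log
space, the hypergeometric probabilities of every table (margins fixed)
whose point probability does not exceed the observed one — the
conventional minimum-likelihood rule, with a 1e-9 relative slack
absorbing floating-point ties. Degenerate margins return p = 1.
Continuous variables (age, BMI, burp rate per 20 minutes, duration) use
Welch *t*-tests. Burp counts are standardised to events per 20 minutes
of procedure time.

## Synthetic-study generator

The generator emulates the measurement setting so that every analysis
stage can be validated against known ground truth.

**Room background.** Log intensity follows a stationary AR(1)
(coefficient 0.9, innovation SD 0.05) around a mean drifting 0.1
log-units/hour, with a mean rate of 20 counts/interval summed over
channels — "slowly varying" on the scale of a 15-minute recording while
strictly positive. The intensity is split across the six channels by a
decreasing power law (exponent 2.2; most particles are small) and
Poisson-rounded to integers. In the intensity-dominated regime the
lag-1 autocorrelation of log counts reproduces the AR coefficient;
at the default low rate Poisson noise partly masks it, as it would on a
real counter.

**Procedure-attributable source.** During the procedure window a
continuous source adds Poisson counts at 230 aerosol and 25 droplet
counts/interval (Cytosponge arm), scaled by a per-patient log-normal
production propensity (σ = 0.6) and, in the EGD arm, by the configured
arm folds (aerosol 2.16, droplet 1.0). The source dominates the
background so the configured fold is identifiable from realistic cohort
sizes; real recordings carry a proportionally larger background — which
is exactly why the spike variant exists — so recovery results on
synthetic data say nothing about signal-to-background ratios in the
clinic.

**Events.** Each procedure gets its arm's schedule: throat spray
shortly after the start (all EGD patients, 22% of Cytosponge patients,
matching observed usage), insertion/intubation ~2 minutes in (late
enough that the event's baseline window lies wholly inside the
procedure), removal/extubation 30–60 s before the end (so the event
window lies wholly inside), and Poisson-scheduled burps at 1.97 (EGD)
and 1.46 (Cytosponge) per 20 minutes. An event draws one log-normal
amplitude (σ = 0.8, shared across fractions), decays it geometrically
over 3 intervals (ratio 0.5), and splits each fraction's share across
that fraction's channels multinomially, so injected counts are integers
recorded exactly in the truth manifest.

**Amplitude calibration.** Event amplitudes are expressed through the
expected fold excess over the null-window noise scale ε (the mean
positive excess of null windows, ~12 aerosol / ~4.5 droplet counts
under the defaults, estimated by `estimate_null_excess`, which mirrors
the pipeline's null sampling exactly). The default medians follow
`median = fold × ε / exp(σ²/2)` with the fold excesses observed in the
clinical study — removal 14.6× (aerosol) and 62.6× (droplet), throat
spray 138.1× and 16.2×, burps marginal aerosol and 14.6× droplet,
insertion ~1× — plus EGD-arm scalings of 2.82× for burp aerosol and
9.8× for spray droplet. `calibrated_amplitude` applies the same rule
for any target fold.

**Reproducibility.** All randomness flows from one `SeedSequence`;
identical config and seed give byte-identical output files. The truth
manifest stores per-event injected counts per interval and channel and
a digest of the pre-injection matrix.

## Problem sizes in the validation suite

The test suite validates type-I error with 1,000 null-arm studies
(cohorts of 10+10) and 500 matched event/null comparisons, and
parameter recovery with 200 full-size studies per target (arm fold
2.16; removal excess 14.6×), using 1,000–2,000 bootstrap resamples per
test — sizes at which the binomial/Monte-Carlo error of the checked
rates is a small fraction of the tolerance bands. The bootstrap default
of 10,000 resamples remains the analysis-facing setting.

## Known limitations

- The generator's event amplitudes are transient point sources; it does
  not model continuous respiration ramps, ventilation, evaporation or
  deposition, so passing recovery tests demonstrates correctness of the
  estimators, not physical fidelity.
- Whole-procedure inference is unadjusted for covariates (age, BMI,
  smoking); the cohort table exists to check arm balance, not to adjust.
- The event fold-change summary (mean of positive parts) is one of
  several defensible statistics for signed excesses; the mixture fit
  characterises the full distribution but is not itself the headline
  estimator.
- Percentile-bootstrap CIs on heavy-tailed ratios with ~17 events per
  group are approximate; their finite-sample coverage sits near, not
  above, the nominal level.
- Counter coincidence-loss correction and conversion to mass or volume
  concentration are out of scope.
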