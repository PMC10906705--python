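# aerosolwatch

Quantify respiratory **aerosols** (particles ≤ 5 μm, which stay airborne
for hours) and **droplets** (> 5 μm, which settle onto surfaces) produced
during clinical procedures, from six-channel optical particle-counter
time series. The package was built to compare a swallowed capsule-sponge
esophageal test (Cytosponge) against standard upper-GI endoscopy (EGD),
but the machinery is generic for any two-arm procedure comparison
recorded with a counter that reports differential counts in diameter
channels (0.5–0.7, 0.7–1.0, 1.0–3.0, 3.0–5.0, 5.0–10.0, 10.0–25.0 μm) at
7-second averaging intervals.

## The analyses

**Whole-procedure.** Per-procedure counts in each size fraction are
rescaled to a 20-minute equivalent, `N₂₀ = N · 20/T`, with a 5-minute
pre-procedure reference window as the within-patient background
comparator. Particle counts are modelled as log-normal, so a fold change
between groups is the geometric-mean ratio

```
R = exp( mean(log Nₐ) − mean(log N_b) )
```

tested with a Welch *t*-test on the logs (paired *t* for
procedure-vs-reference); 95% CIs are exponentiated *t* intervals. A
second "spike" variant first subtracts a running-median background
(kernel 11 samples ≈ 77 s) from each fraction, isolating sharp transient
increases from slow room-background drift.

**Event-based.** Each annotated event (sponge insertion/removal,
endoscope intubation/extubation, anaesthetic throat spray, burps — a
label that includes coughs and gags) is scored by its *excess*: counts
in a 21-second window after the event minus the local baseline
expectation (median per-interval count of the preceding 70 s, times the
number of event intervals). Excesses can be negative, so their
distribution is modelled as a log-normal + normal mixture (fitted by
EM). Fold excesses of an event class over sampled *null-reference*
windows (moments with no annotated activity) are tested with a
percentile bootstrap on the ratio of group summaries, with a two-sided
crossing p-value.

A synthetic-study generator produces complete ground-truth studies —
drifting log-AR(1) room background, a continuous procedure-attributable
source with a configurable between-arm fold, and log-normal event
transients — so every stage of the pipeline is validated against known
truth without any data download.

## Worked example

```python
import aerosolwatch as aw

study = aw.generate_study(aw.SyntheticConfig(n_egd=8, n_cytosponge=8, seed=42),
                          out_dir="demo_study")
res = aw.run_study_frames(study.frames, study.records,
                          aw.AnalysisConfig(n_boot=2000), seed=42)

r = res.get("EGD_vs_Cytosponge", "aerosol", "raw")
print(f"aerosol raw fold change (EGD / Cytosponge): {r.ratio:.2f}x "
      f"(95% CI {r.ci_low:.2f}-{r.ci_high:.2f}), p={r.p_value:.4f}, n={r.n_a}/{r.n_b}")
e = res.get("removal_vs_null", "aerosol")
print(f"Cytosponge removal vs null reference (aerosol): {e.ratio:.1f}x "
      f"(95% CI {e.ci_low:.1f}-{e.ci_high:.1f}), p={e.p_value:.4f}, n={e.n_a}")
```

prints

```
aerosol raw fold change (EGD / Cytosponge): 2.70x (95% CI 1.58-4.62), p=0.0016, n=8/8
Cytosponge removal vs null reference (aerosol): 22.3x (95% CI 7.5-65.6), p=0.0010, n=8
```

The first line says EGD produced 2.7× more aerosol per unit time than
Cytosponge in this 16-procedure synthetic study (the generator's
configured fold is 2.16; single-study estimates scatter around it within
the CI). The second line says sponge-removal windows carried ~22× the
positive excess of activity-free windows.

The same analyses are available from the shell:

```
aerosolwatch simulate --out study_dir --seed 1
aerosolwatch run study_dir --out results_dir --seed 1
aerosolwatch whole-procedure study_dir --fraction aerosol --variant spike
aerosolwatch events study_dir --compare null --n-boot 10000
aerosolwatch cohort study_dir
```

`run` writes `results.csv` (every fold change with CI, p, group sizes),
`cohort.csv`, a human-readable `report.txt` and a `run_manifest.json`
recording every parameter and seed; re-running with the same inputs and
seed reproduces every number bit-for-bit.

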