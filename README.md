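# oxicopd

Early detection of COPD exacerbations from home telemonitoring data.

People with COPD who are treated earlier at exacerbation recover faster,
but day-to-day symptom variation makes onset hard to recognize. `oxicopd`
implements a per-patient standardization pipeline for home monitoring
series — heart rate and SpO2 from pulse oximetry (a single morning spot
reading, or overnight 4-second sampling collapsed to nightly means), plus
daily CAT symptom scores and peak expiratory flow — and asks, per patient
and per variable, *when did this signal first leave its own stable range?*

The core statistic: a 14-day stable window gives each patient/variable a
baseline mean `x̄` and sample SD `s`; each daily value `X` becomes
`Z = (X − x̄)/s`, and a day is abnormal when `|Z| ≥ 1.96` (the nominal 95%
band). A composite oximetry score `Z_HR − Z_SpO2` pools tachycardia and
desaturation into one alarm signal. Downstream the package computes
detection lead times (days of warning before treatment started), event-level
sensitivity/specificity/PPV against a second, disjoint stable fortnight,
stable/pre/post phase comparisons, and figure-style group mean-Z
trajectories. A synthetic cohort generator emulates both monitoring arms —
baselines, day-to-day variability, prodromal drift, recovery, quantization,
missingness — so the whole pipeline runs and is tested with no external
data. See `docs/methods.md` for the model and its assumptions.

Intended users: researchers in respiratory telehealth and biostatistics who
want a reproducible reference implementation of Z-score baselining and
event-level evaluation for home-monitoring time series.

## Worked example

Simulate a 20-patient cohort (both arms, default study conditions), run the
full pipeline, and inspect lead times and composite-score performance:

```python
from oxicopd import SimConfig, AnalysisConfig, run_pipeline

analysis = run_pipeline(
    SimConfig(n_patients=20, seed=7),
    AnalysisConfig(),
    "runs/demo",
    make_plots=False,
)
print(f"eligible: {len(analysis.eligible)} / {len(analysis.patients)}, "
      f"events: {len(analysis.event_patients)}")
print(analysis.lead_table().to_string(index=False))
perf = analysis.performance("composite")
print(f"composite: tp={perf.tp} fp={perf.fp} tn={perf.tn} fn={perf.fn} "
      f"sensitivity={perf.sensitivity:.3f} specificity={perf.specificity:.3f}")
```

Output:

```
eligible: 19 / 20, events: 5
       arm  variable  n_detected  n_censored  median_days  iqr_low  iqr_high
once_daily        HR           2           1          5.0      5.0       5.0
 overnight        HR           2           0          5.5      5.0       6.0
once_daily      SpO2           3           0          5.0      1.0       5.0
 overnight      SpO2           2           0          2.0      0.0       4.0
once_daily       CAT           3           0         10.0      3.0      13.0
 overnight       CAT           2           0          3.5      3.0       4.0
once_daily       PEF           3           0         10.0     10.0      14.0
 overnight       PEF           2           0         11.5      9.0      14.0
once_daily composite           3           0          3.0      3.0       5.0
 overnight composite           2           0          5.5      5.0       6.0
composite: tp=5 fp=4 tn=15 fn=0 sensitivity=1.000 specificity=0.789
```

Reading it: one patient was excluded by the QC rules (no fully observed
stable fortnight, or a ≥2-day gap just before the event). Among event
patients, `median_days` is how many days before treatment each variable
first crossed ±1.96 SD — the overnight arm's composite score gave a median
5.5 days of warning here. The 2×2 line counts event patients flagged in the
pre-event fortnight (tp/fn) and patients whose composite strayed outside
the band during a separate stable fortnight (fp/tn).

The run directory contains `zscores.csv`, `detections.csv`,
`lead_times.csv`, `performance.csv`, `trajectories.csv`, `exclusions.csv`,
a `run.log`, and the resolved `config.yaml`; every CSV starts with a
provenance comment naming the config hash, and reruns with the same seed
are byte-identical.

The same stages are available from a shell:

```bash
oxicopd simulate --config cohort.yaml --out raw/ --seed 1
oxicopd score    --in raw/ --out zscores.csv
oxicopd detect   --zscores zscores.csv --threshold 1.96 --out detections.csv
oxicopd evaluate --detections detections.csv --manifest raw/manifest.csv --out report/
oxicopd run      --config cohort.yaml --out runs/full --seed 1   # all-in-one
```

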