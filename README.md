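# diamotion

Quantification of diaphragmatic motion from dynamic (cine) sagittal
thoracic MRI.

Respiratory impairment in neuromuscular disease — most prominently
Duchenne muscular dystrophy (DMD) — is conventionally tracked with
spirometry, which is noisy and demands subject cooperation. A
single-slice sagittal cine MR acquisition during deep breathing offers
a more direct window on diaphragm mechanics. `diamotion` implements a
semi-automated pipeline for such data: given a 2-D+time series and
three user-placed landmarks (anterior chest-wall margin, carina,
posterior chest-wall margin) on one reference frame, it segments the
lung on every frame, measures on each frame

* the lung cross-sectional area **CSA** (cm²),
* the 1-D lung lengths **ANT**, **CNT**, **PST** at the three landmark
  columns (mm),
* the total distance of motion **TDM = ANT + CNT + PST** (mm),
* the diaphragm length **DIA** — the arc over the diaphragmatic dome
  plus the zones of apposition, between fixed attachment points (mm),

and derives per-series summary measures (min, max, delta = max − min,
mean, SD of each) plus ordinary least-squares regressions of every
length against CSA over the respiratory cycle (slope *S*, intercept
*C*, correlation *R*, *p*). High *R* means the regional motions
co-vary linearly with lung area (synchrony); *S* is the contribution
of that length to a unit CSA change; *C* is the extrapolated length at
CSA = 0, a size-robust cross-subject comparator.

The package ships a synthetic breathing-lung phantom with analytic
ground truth (parabolic diaphragm dome through three control points,
raised-cosine deep-breathing waveforms, optional per-region phase lags
for dyssynchrony, seeded Gaussian noise), so every pipeline stage is
testable without patient data, plus the statistics layer for
cohort-style analyses: percentage group differences,
covariate-adjusted two-group comparison, Pearson correlations with
spirometry, %CV observer-reliability analysis and an exact Wilcoxon
rank-sum test. It is aimed at imaging scientists prototyping
respiratory MRI endpoints and at anyone needing a reproducible,
scriptable reference implementation of these measures.

## Worked example

```python
import diamotion as dm

spec = dm.preset_spec("control")          # healthy-control geometry
series, truth = dm.generate_phantom(spec)  # 60 frames, 2 mm px, 0.5 s
results = dm.DiaphragmMotion(series, dm.phantom_landmarks(spec)).fit()
print(results.summary())
```

```
                       Diaphragm motion analysis
========================================================================
frames: 60 total, 60 valid   pixel spacing: 2 mm   frame interval: 0.5 s
------------------------------------------------------------------------
 measure        min        max      delta       mean         SD
 CSA cm2     191.52     272.40      80.88     231.88      28.80
  ANT mm     172.00     212.00      40.00     192.00      13.97
  CNT mm     146.00     218.00      72.00     181.40      25.54
  PST mm     182.00     258.00      76.00     220.00      26.86
  TDM mm     500.00     688.00     188.00     593.40      66.36
  DIA mm     134.51     255.48     120.97     194.26      42.72
------------------------------------------------------------------------
length vs CSA regressions (slope S mm/cm2, intercept C mm)
 measure          S          C          R            p      n
     ANT     0.4850      79.54     0.9996    1.391e-92     60
     CNT     0.8868     -24.23     0.9998   2.741e-101     60
     PST     0.9324       3.79     0.9999   1.437e-115     60
     TDM     2.3042      59.10     1.0000   1.496e-120     60
     DIA    -1.4829     538.11    -0.9998   6.574e-102     60
========================================================================
```

The phantom programs its control-point lengths from published
healthy-control group means (ANT 172.6→211.0 mm, CNT 146.2→217.3 mm,
PST 182.6→258.0 mm), and the pipeline recovers each within one pixel
(2 mm); the measured peak CSA of 272.4 cm² sits within 2% of the
analytic 267.64 cm². All length measures are almost perfectly linear
in CSA (R ≥ 0.9996) because the phantom breathes synchronously; DIA's
R is strongly *negative* — as the lung inflates the zones of
apposition shorten faster than the dome lengthens. Adding
`phase_lag=(0.63, 0, 0)` to the spec desynchronizes the anterior
diaphragm and drops R(ANT) by ≈ 0.16.

`results.save(out_dir)` writes the per-frame profile, summary and
regression CSVs, the temporal-variation plot (PNG) and a QC overlay
animation (GIF). The same pipeline runs from the shell:

```sh
diamotion phantom --preset control --seed 0 --out phantom/
diamotion analyze --series phantom/series.nii.gz \
                  --landmarks phantom/landmarks.json --out out/
diamotion stats --summaries cohort_summaries.csv \
                --clinical clinical.csv --covariate height_m --out stats/
```

Real data enter as NIfTI (2-D+time) or multi-page TIFF plus a landmark
JSON; cohort-level longitudinal/mixed-effects modelling is out of
scope by design — the `stats` layer exports tidy CSV tables for
external statistics software.

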