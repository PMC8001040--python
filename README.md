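# ptscreen

MSD model fitting and trajectory screening for multiple-particle-tracking
(PT) experiments — built for the question that drives oral-nanomedicine
design: *what fraction of a nanocarrier formulation actually diffuses
through the intestinal mucus layer?*

In PT, each particle's trajectory is summarised by its mean squared
displacement as a function of lag time and fitted to the 2-D anomalous
diffusion model

```
MSD(τ) = 4 D τ^α
```

where `D` is the diffusion coefficient (µm²/s) and `α` the anomalous
exponent (α ≈ 1 free diffusion, α → 0 trapped). The standard practice of
keeping only trajectories whose fit `R² = 1 − RSS/TSS` exceeds a threshold
has a built-in flaw: a particle stuck in the mucus mesh produces a *flat*
MSD curve, whose `R²` collapses to 0 no matter how well the model fits —
so an R²-only trim silently deletes the mucoadhesive subpopulation and
overestimates how mobile the formulation is.

`ptscreen` implements a combined decision rule: a trajectory is kept if
the fit is good (`R² ≥ r2_min`) **or** the residuals are small
(`RSS ≤ rss_max`); only trajectories failing both — genuinely erratic
tracks — are discarded. Around that rule the package provides:

- **I/O** — tidy XLSX/CSV workbooks (`data` + `metadata` sheets), results
  tables, minimum-segment filtering (`n_ij ≥ 10`);
- **MSD tools** — time-averaged MSD from raw 2-D positions, lag-time
  trimming (default 1 s), the per-video median "prototype particle";
- **Fitting** — log-log OLS and bounded nonlinear least squares of the
  power law, with R², RSS, TSS, RMSE diagnostics and the α ≥ 0 clamp;
- **Screening** — conventional, combined, and strict-AND modes, α ≤ 1.1
  validity, retention statistics, and threshold-sweep tables;
- **Metrics** — D_m/D_w reference ratios, diffusivity factor
  DF = D_long/D_short, transport classes (immobile / hindered /
  subdiffusive / diffusive), mucus-layer passage times, and mean/median
  heterogeneity summaries;
- **Synthetic data** — seeded generators for MSD curves (power law +
  noise + "stop diffusing" plateau), fractional-Brownian 2-D tracks, and
  labeled diffusive/adhesive/erratic mixtures, so the whole pipeline is
  testable without microscope data.

## Worked example

Simulate a 400-particle mixed population (40% mobile, 55% mucoadhesive,
5% erratic), screen it with the combined rule, and sweep R² thresholds:

```
$ ptscreen simulate --n-particles 400 --seed 0 --out demo.xlsx
wrote 400 simulated curves to demo.xlsx

$ ptscreen screen --input demo.xlsx --mode combined --out screened.csv
kept 380/400 (95.0%) with mode=combined

$ ptscreen sweep --input demo.xlsx --r2-grid 0,0.3,0.5,0.9 --out sweep.csv
approach    alpha  D_over_Dref   n  pct
   R2>=0 0.420432     0.097331 395 98.8
 R2>=0.3 0.649765     0.183200 201 50.2
 R2>=0.5 0.706772     0.206690 178 44.5
 R2>=0.9 0.797840     0.223290  56 14.0
  R2+RSS 0.398213     0.097507 380 95.0
```

Reading the sweep: as the R² cutoff rises, the retained fraction falls
from ~99% to 14% and the mean exponent inflates from 0.42 to 0.80 — the
flat, mucus-trapped trajectories are being discarded, so the surviving
sample looks far more mobile than the formulation is. The combined
`R2+RSS` row keeps 95% of the trajectories and reproduces the unscreened
mean α (0.40 vs 0.42) and D/D_ref almost exactly: it removed only the
erratic tracks (large residuals *and* poor fit), not the adhesive ones.

The same analysis is available as a library (`ptscreen.simulate_mixture`,
`fit_dataset`, `screen_combined`, `threshold_sweep`, …) and as a single
pipeline call driven by a JSON config (`ptscreen run --config cfg.json`),
which logs trajectory counts at every filter stage.

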