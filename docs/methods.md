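# Methods

## Model

Each trajectory j in video i yields an MSD curve over lag times
τ_k = k·Δt (segments k = 1..n_ij). The curve is fitted to the 2-D
anomalous diffusion law MSD = 4Dτ^α. Two estimators are provided:

- **Log-linear** (default): OLS of log MSD on log τ. The slope is α̂, and
  D̂ = exp(β̂₀)/4 from the intercept. Exact on noiseless power laws;
  under multiplicative noise the log transform makes the regression
  homoscedastic, which is why it is the default.
- **Nonlinear**: bounded least squares (`scipy.optimize.least_squares`)
  of Σ(msd_k − 4Dτ_k^α)² with D > 0, α ∈ [0, 3], initialised from the
  log-linear fit (else D = msd_last/(4τ_last), α = 1); cost tolerance
  1e-10, at most 200 function evaluations; non-convergence returns the
  best iterate flagged `converged=False`.

D̂ is reported as the numeric coefficient of MSD[µm²] = 4·D·τ[s]^α; its
SI unit depends on α and is not converted.

### Diagnostics

R², RSS, TSS and RMSE = √(RSS/n) are computed in the **original** MSD
space against the (back-transformed) model for both estimators, so one
set of screening thresholds — in particular RSS ≤ 5 (µm²)² — applies
uniformly. Log-space diagnostics are available via
`diagnostic_space="transformed"`.

R² is defined as max(0, 1 − RSS/TSS), with R² := 0 when TSS ≤ 1e-12
(µm²)². The floor covers two degenerate regimes with one convention: an
exactly flat curve has no variance to explain, and a model explaining
less variance than the mean is, for screening purposes, indistinguishable
from the flat-curve limit. This also matches the non-negative R² an OLS
fit reports in its own space.

### α handling

Noise on immobile particles can drive the fitted slope below zero;
α* = max(0, α̂) clamps it, and the particle is kept (immobile particles
are data). Exponents *above* 1.1 usually indicate flow artifacts
(unsealed samples), so α* > 1.1 is discarded as superdiffusive; the
boundary is inclusive-keep. Transport classes partition the valid range
lower-closed/upper-open: immobile [0, 0.2), hindered [0.2, 0.4),
subdiffusive [0.4, 0.9), diffusive [0.9, alpha_max].

Particles with fewer than 3 usable points, or with more than 20% of
points excluded as non-positive (no logarithm), are flagged `unfit`,
excluded from both screening modes and counted separately — never
silently dropped.

## Screening

- **Conventional**: keep iff R² ≥ r2_min (default 0.5).
- **Combined** (default): keep iff R² ≥ r2_min **or** RSS ≤ rss_max
  (default 5 (µm²)²). Flat adhesive curves have low R² but tiny RSS and
  are kept; erratic tracks fail both and are discarded. The disjunction
  is forced by the retention figures it must reproduce: a combined rule
  retaining ~95% of trajectories when the R²-only trim at 0.5 retains
  ~35% is impossible under a conjunction. A `strict_and` mode is
  provided for comparison.
- The residual threshold can be applied to RMSE instead of RSS
  (`rss_metric="rmse"`); RMSE weights RSS by n and shares MSD's units.

The threshold-sweep table reports, per R² cutoff plus a final combined
row, the chosen summary statistic of α* and D/D_ref, the kept count and
the retention percentage (one decimal).

## Other numerical choices

- **Time-averaged MSD** uses all overlapping pairs at each lag
  (the standard PT estimator); sampling must be uniform within 1e-6 s,
  and gap interpolation is deliberately not attempted — missing frames
  terminate a trajectory, because trajectory length is itself data.
- **Lag trimming** keeps τ ≤ 1 s + 1e-9 by default: long-lag MSD values
  average few pairs and are statistically weak.
- **Prototype particle**: per-lag median over the curves that reach that
  lag (ragged support; fewer trajectories exist at long lags);
  even-count median = mean of the central pair; particle id 0.
- **Diffusivity factor** DF = D̂(τ ≤ 1 s)/D̂(τ ≤ 0.2 s) with the
  configured fitter; DF = 1 for any exact power law, DF < 0.9 flags
  motion that slows as particles engage the mesh. Curves not reaching
  the long window return None rather than a number.
- **Passage time**: the printed form of the passage-time relation is
  dimensionally inconsistent, so the package adopts the exponential
  first-passage reading consistent with its cited usage: crossing a
  layer of thickness r with probability p by time
  t = r²·ln(1/(1−p))/(4D), natural log, with the factor 4 (2-D MSD
  scaling) exposed as `dimension_factor`. Defaults: r = 100 µm (the
  intestinal mucus blanket), p = 0.999.
- **Population summaries** compute mean or median of D, D/D_ref and α*
  over kept particles; the mean/median ratio of D is always reported as
  the heterogeneity indicator (≈1 Gaussian-like, ≫1 skewed mixture).
  D/D_ref is computed per particle and then summarised.

## Synthetic data

The MSD-space generator is the primary simulation path (the screening
method consumes MSD curves, not positions): clean value
4·D·min(τ, stop_lag)^α — a hard plateau beyond the "stop diffusing" lag —
observed under multiplicative log-normal noise exp(σZ − σ²/2) with
σ² = ln(1 + cv²), giving a unit-mean multiplier with coefficient of
variation `noise_cv`. Additive Gaussian noise is available for
sensitivity checks. Position-space tracks are fractional Brownian motion
per axis (circulant-embedding fGn, Hurst H = α/2) scaled so the ensemble
MSD is 4Dτ^α; they exist to exercise the MSD estimator end-to-end.

The default labeled mixture emulates a heterogeneous oral formulation in
intestinal mucus at 100 fps (Δt = 0.01 s, 100 lags = 1 s), with
reference D_w = 5 µm²/s (Stokes–Einstein, ~120 nm particle, 37 °C):

| component | weight | α | D (µm²/s, log-normal) | noise cv | stop lag (s) |
|---|---|---|---|---|---|
| diffusive | 0.40 | U(0.45, 1.05) | median 0.85, σ_ln 0.7 | U(0.05, 0.30) | — |
| adhesive | 0.55 | U(0.0, 0.35) | median 0.0065, σ_ln 0.7 | U(0.10, 0.45) | U(0.05, 1.0) |
| erratic | 0.05 | U(0.9, 1.1) | median 0.85, σ_ln 0.7 | U(1.20, 2.00) | — |

Parameters are drawn per particle from ranges rather than fixed because
real formulations show a *continuum* of exponents and fit qualities —
empirical retention falls smoothly, not stepwise, as the R² threshold
rises, and the mobile fraction of a partially digested formulation spans
hindered to freely diffusing motion. The mobile component's D median is
~0.17·D_w (mucodiffusive particles), the adhesive component's ~1.3×10⁻³·D_w
with MSD plateaus within the observation window. Under these defaults
~97% of diffusive-labeled trajectories have R² ≥ 0.6, ~80% of
adhesive-labeled ones have R² ≤ 0.3 and only ~7% reach R² ≥ 0.5, so the
generator reproduces the qualitative fit-quality signatures of
mucodiffusive and mucoadhesive control particles.

Component counts are deterministic (largest remainder), ordering and
parameter draws come from one seeded generator, and identical specs with
identical seeds yield bit-identical datasets.

**What the generator does not emulate:** localisation error (static and
dynamic), motion blur, track-linking errors, spatially varying mucus
viscosity, inter-particle interactions, and finite-track statistical
noise in MSD curves themselves (MSD-space curves are smooth power laws
plus observation noise, whereas MSD estimated from a finite track has
lag-correlated errors growing with lag). Passing tests therefore show
that the *analysis chain* is correct and that the screening logic behaves
as designed on populations with the stated structure — not that any
specific laboratory formulation will produce these numbers.

## Problem sizes

The simulation experiments use 1000 curves for parameter recovery, 2000
particles for the mixture/threshold-sweep experiments, 100-lag curves
throughout, and 50 random tracks for the brute-force MSD cross-checks;
at these sizes every experiment completes in seconds while the
population-level monotonicity properties are well resolved.

## Known limitations

- The log-linear fitter requires strictly positive MSD values; zeros are
  excluded rather than offset.
- The combined rule's RSS threshold is scale-dependent (units (µm²)²):
  datasets with much larger or smaller MSD magnitudes need a rescaled
  `rss_max`, which is why it is a config field rather than a constant.
- Confidence intervals for D̂ and α̂ are not computed; the screening
  pipeline does not use them.
- The XLSX round trip preserves reals to ~16 significant digits (cell
  serialisation), the CSV round trip exactly.
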