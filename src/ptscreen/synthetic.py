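"""Seeded synthetic MSD curves, 2-D tracks and labeled mixed populations.

The primary simulation path works directly in MSD space: a clean power law
``4 D tau^alpha`` with an optional hard plateau beyond a "stop diffusing"
lag, observed under multiplicative log-normal noise (MSD is positive and
its spread grows with its magnitude, so multiplicative noise is the
natural model; additive Gaussian noise is available for sensitivity
checks).  Position-space fractional-Brownian tracks are provided to
exercise the MSD estimator end-to-end.

The default mixture emulates the three subpopulations seen when tracking
nanoparticles in intestinal mucus: freely diffusing particles (alpha near
1, moderate noise), mucoadhesive particles (flat, low-MSD curves with
small residuals) and a small erratic fraction (very large noise: poor fit
AND large residuals).  Component parameters are drawn per particle from
ranges rather than fixed, because real formulations show a continuum of
exponents and fit qualities — retention falls smoothly, not stepwise, as
the R2 threshold rises.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import Metadata, MSDCurve, PositionTrack, TrackDataset

#: Reference diffusivity of ~120 nm particles in water at 37 C
#: (Stokes-Einstein), um^2/s; used as the default D_w of simulated samples.
DEFAULT_REFERENCE_D = 5.0


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one simulated MSD curve.

    noise_cv is the coefficient of variation of the multiplicative
    log-normal noise; stop_lag (s) is the lag beyond which the clean MSD
    plateaus at its stop-lag value (math.inf = never stops).
    """

    D_true: float
    alpha_true: float
    n_lags: int = 100
    dt: float = 0.01
    noise_cv: float = 0.0
    stop_lag: float = math.inf
    seed: int | None = None
    noise_model: str = "lognormal"  # or "additive"

    def __post_init__(self) -> None:
        if self.D_true <= 0:
            raise ValueError("D_true must be > 0")
        if self.alpha_true < 0:
            raise ValueError("alpha_true must be >= 0")
        if self.n_lags < 3:
            raise ValueError("n_lags must be >= 3")
        if self.dt <= 0 or self.noise_cv < 0 or self.stop_lag <= 0:
            raise ValueError("dt, stop_lag must be > 0 and noise_cv >= 0")
        if self.noise_model not in ("lognormal", "additive"):
            raise ValueError("noise_model must be 'lognormal' or 'additive'")


def clean_msd(spec: SimSpec) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free MSD values of a spec: power law with hard plateau."""
    lags = spec.dt * np.arange(1, spec.n_lags + 1)
    eff = np.minimum(lags, spec.stop_lag)
    msd = 4.0 * spec.D_true * np.power(eff, spec.alpha_true)
    return lags, msd


def simulate_msd_curve(
    spec: SimSpec,
    rng: np.random.Generator | None = None,
    video_id: int | str = 1,
    particle_id: int | str = 1,
) -> tuple[MSDCurve, dict]:
    """Simulate one MSD curve; returns the curve and its truth record.

    Log-normal noise multiplies each clean value by
    ``exp(sigma Z - sigma^2/2)`` with ``sigma^2 = ln(1 + cv^2)`` so the
    multiplier has unit mean and coefficient of variation ``noise_cv``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    lags, clean = clean_msd(spec)
    if spec.noise_cv > 0:
        z = rng.standard_normal(spec.n_lags)
        if spec.noise_model == "lognormal":
            sigma = math.sqrt(math.log(1.0 + spec.noise_cv**2))
            msd = clean * np.exp(sigma * z - 0.5 * sigma**2)
        else:
            msd = np.maximum(clean + spec.noise_cv * clean * z, 0.0)
    else:
        msd = clean.copy()
    curve = MSDCurve(
        video_id=video_id, particle_id=particle_id, lags=lags, msd=msd
    )
    truth = {
        "video_id": video_id,
        "particle_id": particle_id,
        "D_true": spec.D_true,
        "alpha_true": spec.alpha_true,
        "noise_cv": spec.noise_cv,
        "stop_lag": spec.stop_lag,
        "n_lags": spec.n_lags,
        "dt": spec.dt,
    }
    return curve, truth


# ---------------------------------------------------------------------------
# Position-space simulation: fractional Brownian tracks


def _fgn(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance fractional Gaussian noise via circulant embedding.

    Builds the circulant extension of the fGn autocovariance and colours
    complex white noise by the square root of its (non-negative) spectrum;
    exact for the fGn covariance up to floating-point roundoff.
    """
    if n == 1:
        return rng.standard_normal(1)
    k = np.arange(n, dtype=float)
    gamma = 0.5 * (
        np.abs(k + 1) ** (2 * hurst)
        - 2 * np.abs(k) ** (2 * hurst)
        + np.abs(k - 1) ** (2 * hurst)
    )
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    m = row.size
    lam = np.fft.fft(row).real
    lam = np.clip(lam, 0.0, None)  # clip tiny negative roundoff
    w = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    x = np.fft.fft(np.sqrt(lam) * w) / math.sqrt(m)
    return x.real[:n]


def simulate_track_2d(
    D_true: float,
    alpha_true: float,
    n_steps: int,
    dt: float,
    seed: int | None = None,
    video_id: int | str = 1,
    particle_id: int | str = 1,
) -> PositionTrack:
    """2-D fractional-Brownian track with ensemble MSD = 4 D tau^alpha.

    Each axis is fractional Brownian motion with Hurst exponent
    H = alpha/2, scaled so the per-axis displacement variance at lag tau
    is 2 D tau^alpha (4 D tau^alpha for both axes together).  alpha must
    lie in (0, 2).
    """
    if not 0.0 < alpha_true < 2.0:
        raise ValueError("alpha_true must lie in (0, 2) for an fBM track")
    if D_true < 0:
        raise ValueError("D_true must be non-negative")
    rng = np.random.default_rng(seed)
    hurst = alpha_true / 2.0
    sigma_step = math.sqrt(2.0 * D_true * dt**alpha_true)
    steps_x = sigma_step * _fgn(n_steps, hurst, rng)
    steps_y = sigma_step * _fgn(n_steps, hurst, rng)
    x = np.concatenate([[0.0], np.cumsum(steps_x)])
    y = np.concatenate([[0.0], np.cumsum(steps_y)])
    times = dt * np.arange(n_steps + 1)
    return PositionTrack(
        video_id=video_id, particle_id=particle_id, times=times, x=x, y=y
    )


# ---------------------------------------------------------------------------
# Labeled mixed populations


@dataclass(frozen=True)
class ComponentDistribution:
    """Per-particle parameter ranges for one mixture component.

    alpha is drawn uniformly from alpha_range, noise_cv uniformly from
    noise_cv_range, D log-normally around d_median (natural-log sigma
    d_log_sigma), and the stop lag uniformly from stop_lag_range (None =
    the component never stops diffusing).
    """

    alpha_range: tuple[float, float]
    d_median: float
    d_log_sigma: float
    noise_cv_range: tuple[float, float]
    stop_lag_range: tuple[float, float] | None = None


#: Mobile particles: a subdiffusive-to-diffusive exponent continuum (real
#: formulations span hindered to free motion, not a single exponent), D
#: around 0.17 * D_w, moderate noise.
DIFFUSIVE_COMPONENT = ComponentDistribution(
    alpha_range=(0.45, 1.05),
    d_median=0.85,
    d_log_sigma=0.7,
    noise_cv_range=(0.05, 0.30),
)

#: Mucoadhesive particles: nearly flat curves roughly three orders of
#: magnitude below the reference, most stopping within a few tenths of a
#: second — low R2 but tiny residuals.
ADHESIVE_COMPONENT = ComponentDistribution(
    alpha_range=(0.0, 0.35),
    d_median=0.0065,
    d_log_sigma=0.7,
    noise_cv_range=(0.10, 0.45),
    stop_lag_range=(0.05, 1.0),
)

#: Erratic tracks (linking/focus artifacts): diffusive-scale MSD with very
#: large noise, failing both the R2 and the RSS criterion.
ERRATIC_COMPONENT = ComponentDistribution(
    alpha_range=(0.90, 1.10),
    d_median=0.85,
    d_log_sigma=0.7,
    noise_cv_range=(1.20, 2.00),
)


@dataclass(frozen=True)
class MixtureSpec:
    """A labeled population of diffusive / adhesive / erratic particles."""

    n_particles: int = 400
    weights: dict = field(
        default_factory=lambda: {
            "diffusive": 0.40,
            "adhesive": 0.55,
            "erratic": 0.05,
        }
    )
    components: dict = field(
        default_factory=lambda: {
            "diffusive": DIFFUSIVE_COMPONENT,
            "adhesive": ADHESIVE_COMPONENT,
            "erratic": ERRATIC_COMPONENT,
        }
    )
    n_lags: int = 100
    dt: float = 0.01
    n_videos: int = 5
    reference_D: float = DEFAULT_REFERENCE_D
    sample_name: str = "synthetic mixture"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1 or self.n_videos < 1:
            raise ValueError("n_particles and n_videos must be >= 1")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {total}")
        if set(self.weights) != set(self.components):
            raise ValueError("weights and components must share keys")


def _component_counts(spec: MixtureSpec) -> dict:
    """Deterministic largest-remainder apportionment of particles."""
    names = sorted(spec.weights)
    exact = {c: spec.weights[c] * spec.n_particles for c in names}
    counts = {c: int(math.floor(exact[c])) for c in names}
    short = spec.n_particles - sum(counts.values())
    by_frac = sorted(names, key=lambda c: exact[c] - counts[c], reverse=True)
    for c in by_frac[:short]:
        counts[c] += 1
    return counts


def _draw_spec(
    comp: ComponentDistribution, spec: MixtureSpec, rng: np.random.Generator
) -> SimSpec:
    alpha = rng.uniform(*comp.alpha_range)
    d = comp.d_median * math.exp(comp.d_log_sigma * rng.standard_normal())
    cv = rng.uniform(*comp.noise_cv_range)
    stop = (
        rng.uniform(*comp.stop_lag_range)
        if comp.stop_lag_range is not None
        else math.inf
    )
    return SimSpec(
        D_true=d,
        alpha_true=alpha,
        n_lags=spec.n_lags,
        dt=spec.dt,
        noise_cv=cv,
        stop_lag=stop,
    )


def simulate_mixture(
    spec: MixtureSpec, noiseless: bool = False
) -> tuple[TrackDataset, pd.DataFrame]:
    """Simulate a labeled mixed population.

    Returns the dataset and a labels DataFrame (one row per particle with
    the component label and true parameters).  Component counts are
    deterministic (largest remainder); particle order is shuffled by the
    seeded generator and particles are dealt round-robin across videos.
    ``noiseless=True`` zeroes noise and removes plateaus (exact power
    laws), for round-trip checks.
    """
    rng = np.random.default_rng(spec.seed)
    counts = _component_counts(spec)
    labels = [c for c in sorted(counts) for _ in range(counts[c])]
    rng.shuffle(labels)

    curves: list[MSDCurve] = []
    rows: list[dict] = []
    per_video_counter = {v: 0 for v in range(1, spec.n_videos + 1)}
    for idx, label in enumerate(labels):
        video_id = (idx % spec.n_videos) + 1
        per_video_counter[video_id] += 1
        particle_id = per_video_counter[video_id]
        pspec = _draw_spec(spec.components[label], spec, rng)
        if noiseless:
            pspec = replace(pspec, noise_cv=0.0, stop_lag=math.inf)
        curve, truth = simulate_msd_curve(
            pspec, rng=rng, video_id=video_id, particle_id=particle_id
        )
        curves.append(curve)
        truth["label"] = label
        rows.append(truth)

    metadata = Metadata(
        sample_name=spec.sample_name,
        reference_D=spec.reference_D,
        frame_interval=spec.dt,
    )
    dataset = TrackDataset(metadata=metadata, curves=curves)
    return dataset, pd.DataFrame(rows)
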