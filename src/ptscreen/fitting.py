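"""Per-particle fitting of the anomalous-diffusion MSD model.

The model is the 2-D anomalous diffusion power law

    MSD(tau) = 4 D tau^alpha

fitted either by ordinary least squares on the log-log transform

    log(MSD) = log(4 D) + alpha * log(tau) + eps

(slope beta1 = alpha, intercept beta0 gives D = exp(beta0)/4), or by
bounded nonlinear least squares directly in MSD space.

Goodness-of-fit diagnostics (R2, RSS, TSS, RMSE) are by default computed in
the ORIGINAL MSD-vs-lag space against the back-transformed model for both
methods, so that a single set of screening thresholds (e.g. RSS <= 5 um^4)
applies uniformly.  Log-space diagnostics are available via
``diagnostic_space="transformed"``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import optimize, stats

from .datatypes import MSDCurve

#: TSS below this value (um^4) is treated as an exactly flat curve, for
#: which R2 is defined to be 0 (the residual-vs-total variance ratio is
#: meaningless when the data carry no variance).
TSS_FLOOR = 1e-12

#: Upper bound for alpha in the nonlinear fit; screening later discards
#: anything above ~1.1 as superdiffusive, so 3 is a safe optimisation box.
ALPHA_UPPER = 3.0

#: A particle is flagged unfit when more than this fraction of its points
#: must be excluded (non-positive MSD cannot enter the log transform).
MAX_EXCLUDED_FRACTION = 0.20


class GoodnessOfFit(NamedTuple):
    R2: float
    RSS: float
    TSS: float
    RMSE: float


@dataclass(frozen=True)
class FitResult:
    """Estimated MSD-model parameters and diagnostics for one particle.

    ``alpha_hat`` is the raw estimate; ``alpha_star = max(0, alpha_hat)``
    is the physically clamped exponent used downstream (negative exponents
    arise from noise on immobile particles and mean alpha = 0).  ``unfit``
    marks particles with too few usable points; their numeric fields are
    NaN and they are reported — never silently dropped.
    """

    method: str
    D_hat: float
    alpha_hat: float
    alpha_star: float
    R2: float
    RSS: float
    TSS: float
    RMSE: float
    n_points: int
    converged: bool
    unfit: bool = False
    beta0_hat: float | None = None
    beta1_hat: float | None = None
    video_id: int | str | None = None
    particle_id: int | str | None = None


def clamp_alpha(alpha_hat: float) -> float:
    """Clamp a fitted exponent to the physical range: max(0, alpha_hat)."""
    return max(0.0, alpha_hat)


def goodness_of_fit(
    curve: MSDCurve,
    D: float,
    alpha: float,
    tss_floor: float = TSS_FLOOR,
) -> GoodnessOfFit:
    """R2, RSS, TSS and RMSE of ``4 D tau^alpha`` against a curve.

    R2 = 1 - RSS/TSS, floored at 0: for (near-)exactly flat data
    (TSS <= tss_floor), and for models explaining less variance than the
    mean, R2 is 0 — the flat-curve limit, matching the non-negative R2 of
    an OLS fit evaluated in its own space.  Note that flat curves from
    mucus-trapped particles legitimately have R2 near 0 while their
    residuals — and hence RSS — are tiny; that asymmetry is what the
    combined screening exploits.
    """
    if curve.n_segments == 0:
        raise ValueError("cannot evaluate goodness of fit on an empty curve")
    pred = 4.0 * D * np.power(curve.lags, alpha)
    resid = curve.msd - pred
    rss = float(np.dot(resid, resid))
    centered = curve.msd - np.mean(curve.msd)
    tss = float(np.dot(centered, centered))
    r2 = max(0.0, 1.0 - rss / tss) if tss > tss_floor else 0.0
    rmse = math.sqrt(rss / curve.n_segments)
    return GoodnessOfFit(R2=r2, RSS=rss, TSS=tss, RMSE=rmse)


def _unfit(method: str, curve: MSDCurve) -> FitResult:
    nan = float("nan")
    return FitResult(
        method=method,
        D_hat=nan,
        alpha_hat=nan,
        alpha_star=nan,
        R2=nan,
        RSS=nan,
        TSS=nan,
        RMSE=nan,
        n_points=curve.n_segments,
        converged=False,
        unfit=True,
        video_id=curve.video_id,
        particle_id=curve.particle_id,
    )


def _diagnostics(
    curve: MSDCurve,
    D: float,
    alpha: float,
    diagnostic_space: str,
    log_lags: np.ndarray | None = None,
    log_msd: np.ndarray | None = None,
) -> GoodnessOfFit:
    if diagnostic_space == "original":
        return goodness_of_fit(curve, D, alpha)
    if diagnostic_space == "transformed":
        if log_lags is None or log_msd is None:
            mask = (curve.lags > 0) & (curve.msd > 0)
            log_lags = np.log(curve.lags[mask])
            log_msd = np.log(curve.msd[mask])
        pred = math.log(4.0 * D) + alpha * log_lags
        resid = log_msd - pred
        rss = float(np.dot(resid, resid))
        centered = log_msd - np.mean(log_msd)
        tss = float(np.dot(centered, centered))
        r2 = max(0.0, 1.0 - rss / tss) if tss > TSS_FLOOR else 0.0
        rmse = math.sqrt(rss / log_msd.size)
        return GoodnessOfFit(R2=r2, RSS=rss, TSS=tss, RMSE=rmse)
    raise ValueError(
        f"diagnostic_space must be 'original' or 'transformed', "
        f"got {diagnostic_space!r}"
    )


def fit_log_linear(
    curve: MSDCurve, diagnostic_space: str = "original"
) -> FitResult:
    """OLS fit of log(MSD) on log(lag).

    Points with non-positive MSD are excluded (no logarithm); if more than
    20% of points are excluded, or fewer than 3 usable points remain, the
    particle is flagged unfit.
    """
    mask = (curve.lags > 0) & (curve.msd > 0)
    n_used = int(mask.sum())
    if (
        n_used < 3
        or (curve.n_segments - n_used) > MAX_EXCLUDED_FRACTION * curve.n_segments
    ):
        return _unfit("log_linear", curve)
    log_lags = np.log(curve.lags[mask])
    log_msd = np.log(curve.msd[mask])
    if np.ptp(log_lags) == 0.0:
        return _unfit("log_linear", curve)
    res = stats.linregress(log_lags, log_msd)
    beta0, beta1 = float(res.intercept), float(res.slope)
    d_hat = math.exp(beta0) / 4.0
    gof = _diagnostics(curve, d_hat, beta1, diagnostic_space, log_lags, log_msd)
    return FitResult(
        method="log_linear",
        D_hat=d_hat,
        alpha_hat=beta1,
        alpha_star=clamp_alpha(beta1),
        R2=gof.R2,
        RSS=gof.RSS,
        TSS=gof.TSS,
        RMSE=gof.RMSE,
        n_points=n_used,
        converged=True,
        beta0_hat=beta0,
        beta1_hat=beta1,
        video_id=curve.video_id,
        particle_id=curve.particle_id,
    )


def fit_nonlinear(
    curve: MSDCurve, diagnostic_space: str = "original"
) -> FitResult:
    """Bounded nonlinear least squares of MSD = 4 D tau^alpha.

    Minimises sum (msd_k - 4 D tau_k^alpha)^2 with D > 0 and
    alpha in [0, 3], starting from the log-linear estimates when available
    (else D = msd_last / (4 lag_last), alpha = 1).  Non-convergence
    returns the best iterate with ``converged=False``.
    """
    if curve.n_segments < 3:
        return _unfit("nonlinear", curve)

    lin = fit_log_linear(curve)
    if not lin.unfit:
        d0 = max(lin.D_hat, 1e-12)
        a0 = min(max(lin.alpha_hat, 0.0), ALPHA_UPPER)
    else:
        d0 = max(curve.msd[-1] / (4.0 * curve.lags[-1]), 1e-12)
        a0 = 1.0

    lags, msd = curve.lags, curve.msd

    def residuals(theta: np.ndarray) -> np.ndarray:
        d, a = theta
        return msd - 4.0 * d * np.power(lags, a)

    sol = optimize.least_squares(
        residuals,
        x0=np.array([d0, a0]),
        bounds=([1e-300, 0.0], [np.inf, ALPHA_UPPER]),
        ftol=1e-10,
        xtol=1e-12,
        gtol=1e-10,
        max_nfev=200,
    )
    d_hat, alpha_hat = float(sol.x[0]), float(sol.x[1])
    gof = _diagnostics(curve, d_hat, alpha_hat, diagnostic_space)
    return FitResult(
        method="nonlinear",
        D_hat=d_hat,
        alpha_hat=alpha_hat,
        alpha_star=clamp_alpha(alpha_hat),
        R2=gof.R2,
        RSS=gof.RSS,
        TSS=gof.TSS,
        RMSE=gof.RMSE,
        n_points=curve.n_segments,
        converged=bool(sol.success),
        video_id=curve.video_id,
        particle_id=curve.particle_id,
    )


FITTERS = {"linear": fit_log_linear, "nonlinear": fit_nonlinear}


def get_fitter(name: str):
    """Resolve a fitter by CLI name ('linear' or 'nonlinear')."""
    try:
        return FITTERS[name]
    except KeyError:
        raise ValueError(
            f"unknown fit type {name!r}; choose from {sorted(FITTERS)}"
        ) from None
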