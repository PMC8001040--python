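"""Trajectory screening: conventional R2 trim and the combined R2+RSS rule.

The conventional approach keeps only trajectories whose fit R2 exceeds a
threshold.  Because flat MSD curves from mucus-trapped particles have
R2 -> 0 *by construction* (no variance to explain) even when they fit the
model well, an R2-only trim systematically deletes the adhesive
subpopulation and overestimates population diffusivity.

The combined rule keeps a trajectory if EITHER the fit is good (R2 >=
r2_min) OR the residuals are small (RSS <= rss_max), discarding only
trajectories that fail both — genuinely erratic tracks whose large,
unstructured excursions give both a poor fit and large residuals.  A
strict conjunction (`strict_and`) is also provided for comparison.

Independently of either rule, trajectories with a clamped exponent above
``alpha_max`` (default 1.1) are discarded as superdiffusive: exponents
above ~1.1 in mucus typically indicate flow artifacts from unsealed
samples rather than transport.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import math

import numpy as np
import pandas as pd

from .fitting import FitResult

DISCARD_REASONS = (
    "none",
    "low_r2",
    "erratic_high_rss",
    "alpha_superdiffusive",
    "unfit",
)


@dataclass(frozen=True)
class ScreeningConfig:
    """Thresholds of the screening decision tree.

    rss_metric selects whether the residual threshold applies to RSS
    (um^4, default) or to RMSE (um^2), which weights RSS by the number of
    points and shares MSD's units.
    """

    r2_min: float = 0.5
    rss_max: float = 5.0
    alpha_max: float = 1.1
    alpha_min: float = 0.0
    mode: str = "combined"
    rss_metric: str = "rss"

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2_min <= 1.0:
            raise ValueError("r2_min must lie in [0, 1]")
        if self.rss_max < 0:
            raise ValueError("rss_max must be >= 0")
        if not self.alpha_max > self.alpha_min:
            raise ValueError("alpha_max must exceed alpha_min")
        if self.mode not in ("conventional", "combined", "strict_and"):
            raise ValueError(f"unknown screening mode {self.mode!r}")
        if self.rss_metric not in ("rss", "rmse"):
            raise ValueError("rss_metric must be 'rss' or 'rmse'")


@dataclass
class ScreeningOutcome:
    """Per-particle keep/discard verdicts plus retention statistics."""

    kept: np.ndarray
    reasons: list[str]
    n_total: int
    n_kept: int
    retention_pct: float
    mode: str
    config: ScreeningConfig = field(repr=False, default=None)

    def summary(self) -> dict:
        counts: dict = {}
        for r in self.reasons:
            counts[r] = counts.get(r, 0) + 1
        return {
            "mode": self.mode,
            "n_total": self.n_total,
            "n_kept": self.n_kept,
            "retention_pct": self.retention_pct,
            "discard_counts": {
                k: v for k, v in counts.items() if k != "none"
            },
        }


def retention_percentage(n_kept: int, n_total: int) -> float:
    """Percentage of trajectories retained, to one decimal place."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_kept <= n_total:
        raise ValueError("n_kept must lie in [0, n_total]")
    return round(100.0 * n_kept / n_total, 1)


def _residual_stat(fit: FitResult, cfg: ScreeningConfig) -> float:
    return fit.RSS if cfg.rss_metric == "rss" else fit.RMSE


def _alpha_invalid(fit: FitResult, cfg: ScreeningConfig) -> bool:
    return fit.alpha_star > cfg.alpha_max or fit.alpha_star < cfg.alpha_min


def alpha_validity_filter(
    fits: Sequence[FitResult], alpha_max: float = 1.1
) -> np.ndarray:
    """True where a particle's clamped exponent is within (<=) alpha_max.

    Negative raw exponents were already clamped to 0 upstream and remain
    valid — immobile particles are data, not artifacts.  The boundary is
    inclusive: only alpha_star strictly above alpha_max is discarded.
    """
    return np.array(
        [not f.unfit and f.alpha_star <= alpha_max for f in fits], dtype=bool
    )


def _decide(fit: FitResult, cfg: ScreeningConfig, mode: str) -> str:
    """Return the discard reason for one particle ('none' = keep)."""
    if fit.unfit:
        return "unfit"
    if _alpha_invalid(fit, cfg):
        return "alpha_superdiffusive"
    passes_r2 = fit.R2 >= cfg.r2_min
    passes_rss = _residual_stat(fit, cfg) <= cfg.rss_max
    if mode == "conventional":
        return "none" if passes_r2 else "low_r2"
    if mode == "combined":
        return "none" if (passes_r2 or passes_rss) else "erratic_high_rss"
    if mode == "strict_and":
        if passes_r2 and passes_rss:
            return "none"
        return "low_r2" if not passes_r2 else "erratic_high_rss"
    raise ValueError(f"unknown screening mode {mode!r}")


def _screen(
    fits: Sequence[FitResult], cfg: ScreeningConfig, mode: str
) -> ScreeningOutcome:
    reasons = [_decide(f, cfg, mode) for f in fits]
    kept = np.array([r == "none" for r in reasons], dtype=bool)
    n_total = len(fits)
    n_kept = int(kept.sum())
    pct = retention_percentage(n_kept, n_total) if n_total else math.nan
    return ScreeningOutcome(
        kept=kept,
        reasons=reasons,
        n_total=n_total,
        n_kept=n_kept,
        retention_pct=pct,
        mode=mode,
        config=cfg,
    )


def screen_conventional(
    fits: Sequence[FitResult], cfg: ScreeningConfig | None = None
) -> ScreeningOutcome:
    """R2-only trim: keep iff R2 >= r2_min (and alpha valid, not unfit)."""
    return _screen(fits, cfg or ScreeningConfig(), "conventional")


def screen_combined(
    fits: Sequence[FitResult], cfg: ScreeningConfig | None = None
) -> ScreeningOutcome:
    """Combined rule: keep iff R2 >= r2_min OR RSS <= rss_max.

    Only particles failing both thresholds are discarded (reason
    ``erratic_high_rss``); flat low-R2 curves with small residuals — the
    mucus-retained subpopulation — are retained.
    """
    return _screen(fits, cfg or ScreeningConfig(), "combined")


def screen(
    fits: Sequence[FitResult], cfg: ScreeningConfig
) -> ScreeningOutcome:
    """Screen with the mode named in the config."""
    return _screen(fits, cfg, cfg.mode)


def threshold_sweep(
    fits: Sequence[FitResult],
    r2_grid: Sequence[float],
    cfg: ScreeningConfig | None = None,
    reference_D: float | None = None,
    statistic: str = "mean",
) -> pd.DataFrame:
    """Summary table across R2 thresholds, plus the combined-rule row.

    One row per grid value using the conventional trim and a final
    ``R2+RSS`` row using the combined rule; each row reports the chosen
    summary statistic of alpha_star and D/D_ref over kept particles, the
    kept count and the retention percentage — the shape used to compare
    screening approaches on real formulations.
    """
    cfg = cfg or ScreeningConfig()
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    agg = np.mean if statistic == "mean" else np.median

    def _row(label: str, outcome: ScreeningOutcome) -> dict:
        kept_fits = [f for f, k in zip(fits, outcome.kept) if k]
        alphas = np.array([f.alpha_star for f in kept_fits])
        ds = np.array([f.D_hat for f in kept_fits])
        row = {
            "approach": label,
            "alpha": float(agg(alphas)) if alphas.size else math.nan,
            "D_over_Dref": (
                float(agg(ds / reference_D))
                if (alphas.size and reference_D)
                else math.nan
            ),
            "n": outcome.n_kept,
            "pct": outcome.retention_pct,
        }
        return row

    rows = []
    for r2_min in r2_grid:
        c = ScreeningConfig(
            r2_min=float(r2_min),
            rss_max=cfg.rss_max,
            alpha_max=cfg.alpha_max,
            alpha_min=cfg.alpha_min,
            mode="conventional",
            rss_metric=cfg.rss_metric,
        )
        rows.append(_row(f"R2>={r2_min:g}", screen_conventional(fits, c)))
    combined_cfg = ScreeningConfig(
        r2_min=cfg.r2_min,
        rss_max=cfg.rss_max,
        alpha_max=cfg.alpha_max,
        alpha_min=cfg.alpha_min,
        mode="combined",
        rss_metric=cfg.rss_metric,
    )
    rows.append(_row("R2+RSS", screen_combined(fits, combined_cfg)))
    return pd.DataFrame(rows)
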