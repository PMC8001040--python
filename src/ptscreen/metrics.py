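"""Per-particle and population diffusion metrics.

Covers the reference ratio D_m/D_w, the diffusivity factor
DF = D_long/D_short, transport-mode classification by the anomalous
exponent, the mucus-layer passage time, and mean/median population
summaries with the heterogeneity (mean/median) ratio.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .datatypes import MSDCurve
from .fitting import FitResult, fit_log_linear
from .msd import trim_to_lag


class TransportClass(str, Enum):
    """Transport mode of a particle, by its clamped anomalous exponent.

    Boundaries are lower-closed/upper-open ([0.2, 0.4) is hindered, etc.),
    with the diffusive class closed at alpha_max; exponents above
    alpha_max indicate flow artifacts and are reported separately.
    """

    IMMOBILE = "immobile"
    HINDERED = "hindered"
    SUBDIFFUSIVE = "subdiffusive"
    DIFFUSIVE = "diffusive"
    SUPERDIFFUSIVE_DISCARDED = "superdiffusive_discarded"


def classify_transport(
    alpha_star: float, alpha_max: float = 1.1
) -> TransportClass:
    """Sort a particle into immobile / hindered / subdiffusive / diffusive.

    immobile: alpha < 0.2; hindered: 0.2 <= alpha < 0.4; subdiffusive:
    0.4 <= alpha < 0.9; diffusive: 0.9 <= alpha <= alpha_max; above
    alpha_max: superdiffusive (discarded from population summaries).
    """
    if alpha_star < 0:
        raise ValueError("alpha_star must be non-negative (clamped upstream)")
    if alpha_star > alpha_max:
        return TransportClass.SUPERDIFFUSIVE_DISCARDED
    if alpha_star < 0.2:
        return TransportClass.IMMOBILE
    if alpha_star < 0.4:
        return TransportClass.HINDERED
    if alpha_star < 0.9:
        return TransportClass.SUBDIFFUSIVE
    return TransportClass.DIFFUSIVE


def ratio_to_reference(D_hat: float, reference_D: float) -> float:
    """D_m/D_r: measured diffusivity relative to a reference medium.

    ~1 marks freely diffusing (mucodiffusive) particles, << 1 particles
    trapped by the mucus mesh.
    """
    if not reference_D > 0:
        raise ValueError("reference_D must be > 0")
    return D_hat / reference_D


def diffusivity_factor(
    curve: MSDCurve,
    long_lag: float = 1.0,
    short_lag: float = 0.2,
    fitter: Callable[[MSDCurve], FitResult] = fit_log_linear,
) -> float | None:
    """DF = D_long / D_short from two windowed fits of the same curve.

    D is fitted over the full window (lag <= long_lag) and a short window
    (lag <= short_lag).  Freely diffusing particles show the same power
    law on both windows (DF ~ 1, in practice DF >= 0.9); particles whose
    motion slows as they engage the mucus mesh show DF < 0.9.  Returns
    None when the curve does not reach long_lag or either windowed fit is
    unusable.
    """
    if not short_lag < long_lag:
        raise ValueError("short_lag must be smaller than long_lag")
    if curve.max_lag + 1e-9 < long_lag:
        return None
    fit_long = fitter(trim_to_lag(curve, long_lag))
    fit_short = fitter(trim_to_lag(curve, short_lag))
    if fit_long.unfit or fit_short.unfit or fit_short.D_hat == 0:
        return None
    return fit_long.D_hat / fit_short.D_hat


def passage_time(
    D_hat: float,
    thickness_r: float = 100.0,
    p: float = 0.999,
    dimension_factor: float = 4.0,
) -> float:
    """Time for a particle to cross a mucus layer with probability p.

    Adopts exponential crossing kinetics with rate ``dimension_factor *
    D / r^2`` (the 2-D MSD scaling MSD = 4 D t gives the default factor
    4), so the time by which a fraction p of particles has traversed a
    layer of thickness r is

        t = r^2 * ln(1 / (1 - p)) / (dimension_factor * D)

    The intestinal mucus blanket is ~100 um thick, the conventional
    crossing probability 99.9%.  D = 0 returns infinity.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly between 0 and 1")
    if thickness_r <= 0:
        raise ValueError("thickness_r must be > 0")
    if D_hat < 0:
        raise ValueError("D_hat must be non-negative")
    if D_hat == 0:
        return math.inf
    return thickness_r**2 * math.log(1.0 / (1.0 - p)) / (dimension_factor * D_hat)


@dataclass(frozen=True)
class PopulationSummary:
    """Population-level diffusion summary over kept particles.

    ``mean_median_ratio_D`` is the heterogeneity indicator: ~1 for
    Gaussian-like populations, >> 1 for skewed mixtures, where the mean is
    dragged by a fast minority and the median is the honest summary.
    """

    statistic: str
    D_summary: float
    D_over_ref_summary: float
    alpha_summary: float
    mean_median_ratio_D: float
    class_fractions: dict
    n_kept: int


def summarize_population(
    records: pd.DataFrame | Sequence[dict],
    statistic: str = "median",
    reference_D: float | None = None,
    alpha_max: float = 1.1,
) -> PopulationSummary:
    """Summarise kept per-particle metrics by mean or median.

    ``records`` needs columns ``D`` and ``alpha_star`` (and optionally
    ``D_over_ref``, else it is derived from ``reference_D``).  The
    mean/median ratio of D is always computed, whichever statistic is
    chosen, and class fractions are over the kept particles.
    """
    df = pd.DataFrame(records)
    if df.empty:
        raise ValueError("cannot summarise an empty population")
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    agg = np.mean if statistic == "mean" else np.median

    d = df["D"].to_numpy(float)
    alpha = df["alpha_star"].to_numpy(float)
    if "D_over_ref" in df.columns:
        d_ref = df["D_over_ref"].to_numpy(float)
    elif reference_D is not None:
        d_ref = d / reference_D
    else:
        d_ref = np.full_like(d, np.nan)

    med_d = float(np.median(d))
    ratio = float(np.mean(d) / med_d) if med_d != 0 else math.inf

    classes = [classify_transport(a, alpha_max).value for a in alpha]
    fractions = {c.value: 0.0 for c in TransportClass}
    for c in classes:
        fractions[c] += 1.0 / len(classes)

    return PopulationSummary(
        statistic=statistic,
        D_summary=float(agg(d)),
        D_over_ref_summary=float(agg(d_ref)),
        alpha_summary=float(agg(alpha)),
        mean_median_ratio_D=ratio,
        class_fractions=fractions,
        n_kept=len(df),
    )


def histogram_data(
    values: Sequence[float], n_bins: int = 30, log10: bool = False
) -> dict:
    """Bin edges and counts for exploratory histograms (D/D_ref, alpha,
    R2, RSS) as exported for population-heterogeneity inspection."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if log10:
        arr = np.log10(arr[arr > 0])
    counts, edges = np.histogram(arr, bins=n_bins)
    return {"edges": edges.tolist(), "counts": counts.tolist(), "log10": log10}
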