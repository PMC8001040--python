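"""Time-averaged MSD computation, lag trimming and the prototype particle."""
from __future__ import annotations

import numpy as np

from .datatypes import MSDCurve, PositionTrack

_UNIFORMITY_TOL = 1e-6  # seconds


def compute_time_averaged_msd(
    track: PositionTrack, max_lag: float
) -> MSDCurve:
    """Time-averaged MSD of a uniformly sampled 2-D track.

    For lag ``k * dt`` the MSD is the average squared displacement over all
    overlapping ordered pairs of points separated by ``k`` frames:

        msd_k = mean_t [ (x(t + k dt) - x(t))^2 + (y(t + k dt) - y(t))^2 ]

    The overlapping-window (time-averaged) estimator is the standard choice
    in particle tracking; ensemble averaging only enters at the
    prototype-particle and population-summary level.
    """
    dt_all = np.diff(track.times)
    dt = float(np.median(dt_all))
    if np.any(np.abs(dt_all - dt) > _UNIFORMITY_TOL):
        raise ValueError(
            "track is not uniformly sampled within 1e-6 s; "
            "gap-tolerant MSD is not supported"
        )
    if max_lag < dt:
        raise ValueError("max_lag must be at least the frame interval")
    n = track.n_points
    k_max = min(n - 1, int(np.floor(max_lag / dt + 1e-9)))
    lags = np.empty(k_max, dtype=float)
    msd = np.empty(k_max, dtype=float)
    x, y = track.x, track.y
    for k in range(1, k_max + 1):
        dx = x[k:] - x[:-k]
        dy = y[k:] - y[:-k]
        lags[k - 1] = k * dt
        msd[k - 1] = np.mean(dx * dx + dy * dy)
    return MSDCurve(
        video_id=track.video_id,
        particle_id=track.particle_id,
        lags=lags,
        msd=msd,
    )


def trim_to_lag(curve: MSDCurve, lag_max: float = 1.0) -> MSDCurve:
    """Keep only points with lag <= lag_max (inclusive within 1e-9 s).

    MSD estimates at long lags average few displacement pairs and are
    statistically weak, so curves are trimmed to a maximum lag (1 s by
    default for 100 fps acquisitions) before fitting.
    """
    mask = curve.lags <= lag_max + 1e-9
    return MSDCurve(
        video_id=curve.video_id,
        particle_id=curve.particle_id,
        lags=curve.lags[mask],
        msd=curve.msd[mask],
    )


def prototype_particle(curves: list[MSDCurve]) -> MSDCurve:
    """Median ("prototype") particle of a video.

    Returns a virtual particle with id 0 whose MSD at each lag is the
    median across all curves that reach that lag; curves are ragged, so a
    lag's median uses only the trajectories long enough to contribute.
    Even-count medians are the mean of the two central values.
    """
    if not curves:
        raise ValueError("prototype_particle needs at least one curve")
    all_lags = np.unique(np.concatenate([c.lags for c in curves]))
    med = np.empty(all_lags.size, dtype=float)
    for idx, lag in enumerate(all_lags):
        vals = []
        for c in curves:
            hit = np.nonzero(c.lags == lag)[0]
            if hit.size:
                vals.append(c.msd[hit[0]])
        med[idx] = np.median(vals)
    return MSDCurve(
        video_id=curves[0].video_id,
        particle_id=0,
        lags=all_lags,
        msd=med,
    )
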