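"""Core containers for particle-tracking MSD data.

Indexing follows the usual multiple-particle-tracking convention: video
``i``, trajectory ``j`` within a video, segment (lag step) ``k`` along the
trajectory.  A trajectory's MSD curve therefore has ``n_ij`` segments, and a
video holds ``m_i`` trajectories.

Internal units are fixed: lengths in micrometres, times in seconds, MSD in
um^2 and diffusion coefficients in um^2/s (for anomalous exponents != 1 the
reported D is the coefficient of ``MSD = 4 D tau^alpha`` with tau in
seconds).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DataIntegrityError(ValueError):
    """Raised when input data violates a structural invariant."""


@dataclass(frozen=True)
class Metadata:
    """Sample-level metadata accompanying an MSD dataset.

    Parameters
    ----------
    sample_name
        Free-text identifier of the formulation / sample.
    reference_D
        Diffusion coefficient of the same particles in a simple reference
        medium (water or saline), um^2/s.  Used for the D_m/D_w ratio.
    frame_interval
        Acquisition frame interval, seconds.
    control_D
        Optional diffusion coefficient of a mucodiffusive control measured
        in the same mucus sample, um^2/s.
    notes
        Optional free text.
    """

    sample_name: str
    reference_D: float
    frame_interval: float = 0.01
    control_D: float | None = None
    notes: str | None = None

    def __post_init__(self) -> None:
        if not self.reference_D > 0:
            raise ValueError(f"reference_D must be > 0, got {self.reference_D}")
        if not self.frame_interval > 0:
            raise ValueError(
                f"frame_interval must be > 0, got {self.frame_interval}"
            )
        if self.control_D is not None and not self.control_D > 0:
            raise ValueError(f"control_D must be > 0, got {self.control_D}")


@dataclass(frozen=True)
class MSDCurve:
    """One particle's MSD as a function of lag time.

    ``lags`` are strictly increasing lag times in seconds; ``msd`` the
    corresponding mean squared displacements in um^2.  A curve may be empty
    (for example after trimming); downstream minimum-segment filtering
    decides whether it is usable.
    """

    video_id: int | str
    particle_id: int | str
    lags: np.ndarray
    msd: np.ndarray

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        msd = np.asarray(self.msd, dtype=float)
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "msd", msd)
        if lags.ndim != 1 or msd.ndim != 1:
            raise ValueError("lags and msd must be one-dimensional")
        if lags.shape != msd.shape:
            raise ValueError(
                f"lags and msd lengths differ: {lags.size} vs {msd.size}"
            )
        if lags.size:
            if np.any(lags <= 0):
                raise ValueError("lag times must be positive")
            if np.any(np.diff(lags) <= 0):
                raise ValueError("lag times must be strictly increasing")
            if np.any(msd < 0):
                raise ValueError("MSD values must be non-negative")

    @property
    def n_segments(self) -> int:
        return int(self.lags.size)

    @property
    def max_lag(self) -> float:
        return float(self.lags[-1]) if self.lags.size else 0.0


@dataclass(frozen=True)
class PositionTrack:
    """Raw 2-D particle positions (t, x, y), micrometres and seconds."""

    video_id: int | str
    particle_id: int | str
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if not (times.shape == x.shape == y.shape):
            raise ValueError("times, x and y must have equal lengths")
        if times.size < 2:
            raise ValueError("a track needs at least 2 points")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_points(self) -> int:
        return int(self.times.size)


@dataclass
class TrackDataset:
    """A collection of MSD curves grouped by video, plus sample metadata.

    ``removed_per_video`` records how many curves each filtering step
    removed (populated by :func:`ptscreen.io.filter_min_segments`);
    ``n_rejected_rows`` counts non-numeric rows dropped on read.
    """

    metadata: Metadata
    curves: list[MSDCurve] = field(default_factory=list)
    removed_per_video: dict = field(default_factory=dict)
    n_rejected_rows: int = 0

    def __post_init__(self) -> None:
        keys = [(c.video_id, c.particle_id) for c in self.curves]
        if len(keys) != len(set(keys)):
            raise DataIntegrityError(
                "duplicate (video_id, particle_id) pairs in dataset"
            )

    @property
    def n_curves(self) -> int:
        return len(self.curves)

    @property
    def video_ids(self) -> list:
        seen: dict = {}
        for c in self.curves:
            seen.setdefault(c.video_id, None)
        return list(seen)

    def curves_for_video(self, video_id) -> list[MSDCurve]:
        return [c for c in self.curves if c.video_id == video_id]
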