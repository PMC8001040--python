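import numpy as np
import pytest

from ptscreen import Metadata, MSDCurve, TrackDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20210310)


def power_law_curve(D, alpha, n_lags=100, dt=0.01, video_id=1, particle_id=1):
    """Exact noiseless MSD = 4 D tau^alpha curve."""
    lags = dt * np.arange(1, n_lags + 1)
    return MSDCurve(
        video_id=video_id,
        particle_id=particle_id,
        lags=lags,
        msd=4.0 * D * lags**alpha,
    )


@pytest.fixture
def small_dataset():
    """2 videos x 3 particles x 10 lags of exact power laws."""
    curves = []
    for vid in (1, 2):
        for pid in (1, 2, 3):
            curves.append(
                power_law_curve(
                    D=0.1 * pid, alpha=0.8, n_lags=10,
                    video_id=vid, particle_id=pid,
                )
            )
    meta = Metadata(
        sample_name="fixture", reference_D=5.0, frame_interval=0.01
    )
    return TrackDataset(metadata=meta, curves=curves)
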