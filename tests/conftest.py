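import numpy as np
import pytest

import tirfgran as tg


@pytest.fixture(scope="session")
def fusion_movie30():
    """One SNR-5 movie with 30 injected fusion events (loss over 2 frames),
    shared by the simulator and detector test modules."""
    cfg = tg.SimConfig.for_snr(5, image_shape=(200, 200), n_frames=120,
                               frame_interval=1.0, seed=1003)
    movie, gt = tg.simulate_fusion_movie(cfg, n_events=30, loss_frames=2)
    return cfg, movie, gt


@pytest.fixture(scope="session")
def fusion_tracks30(fusion_movie30):
    cfg, movie, gt = fusion_movie30
    det = tg.detect_movie(movie, tg.DetectionParams(smoothing_sigma=cfg.psf_sigma))
    return tg.link_tracks(det, tg.DockingParams())


def make_track(track_id, frames, xy, intensities=None):
    """Synthetic Track at a fixed position with given intensities."""
    frames = np.asarray(frames, int)
    pos = np.tile(np.asarray(xy, float), (frames.size, 1))
    if intensities is None:
        intensities = np.full(frames.size, 100.0)
    return tg.Track(track_id, frames, pos, np.asarray(intensities, float))
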