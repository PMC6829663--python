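"""End-to-end analysis paths on simulated data.

Each function here runs one of the package's three analysis chains —
docking/density, exocytosis, enrichment — from movie generation through
measurement, against the simulator's ground truth.  They serve both as
executable documentation of how the stages compose and as
parameter-recovery benchmarks: the generator is set up with a known
docked share, event count or spot density, and the measurement should
give it back.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import fuse, spots, track
from .simulate import ResidenceModel, SimConfig, simulate_field, simulate_fusion_movie, simulate_movie
from .spots import DetectionParams
from .track import DockingParams

__all__ = [
    "DockingRun",
    "run_docking_measurement",
    "count_fusion_events",
    "field_density",
    "percent_reduction",
]


@dataclass
class DockingRun:
    n_approach: int
    n_stable: int
    stable_pct: float            # percentage of approaches stably docked
    true_docked_share: float     # generator's realized long-lived share


def run_docking_measurement(
    seed: int,
    n_approaches: int = 200,
    p_dock: float = 0.5,
    dock_residence=(45.0, 120.0),
    visitor_residence=(2.0, 20.0),
    snr: float = 10.0,
    image_shape: tuple[int, int] = (256, 256),
    n_frames: int = 400,
    frame_interval: float = 1.0,
    arrival_window: tuple[int, int] = (5, 350),
) -> DockingRun:
    """Simulate granule approaches and measure the stable-docking fraction.

    The generator injects ``n_approaches`` arrivals, each long-lived with
    probability ``p_dock`` (residence from ``dock_residence``, supporting
    the 40-s survival criterion) and otherwise a visitor.  The chain is
    detect -> link -> classify -> docking_fraction with the standard
    dwell-time thresholds (t_min 2 s, t_dock 25 s, survival 40 s).
    """
    cfg = SimConfig.for_snr(snr, image_shape=image_shape, n_frames=n_frames,
                            frame_interval=frame_interval, seed=seed)
    res = ResidenceModel(p_dock=p_dock, dock_residence=dock_residence,
                         visitor_residence=visitor_residence)
    movie, gt = simulate_movie(cfg, res, n_granules=n_approaches,
                               arrival_window=arrival_window)
    det = spots.detect_movie(movie, DetectionParams(smoothing_sigma=cfg.psf_sigma))
    params = DockingParams()
    tracks = track.link_tracks(det, params)
    events = [track.classify_docking(t, params, frame_interval) for t in tracks]
    summary = track.docking_fraction(events, tracks, params, frame_interval,
                                     n_frames=n_frames)
    share = float(np.mean([k == "docked" for k in gt.kinds()]))
    return DockingRun(summary.n_approach, summary.n_stable_at_survival,
                      100.0 * summary.fraction, share)


def count_fusion_events(
    seed: int,
    n_events: int,
    snr: float = 5.0,
    loss_frames: int = 2,
    image_shape: tuple[int, int] = (200, 200),
    n_frames: int = 120,
    frame_interval: float = 1.0,
) -> tuple[int, int]:
    """Detect abrupt-loss fusion events in a simulated movie.

    Returns (n_detected, n_injected); with good detection the two match
    exactly and there are no false positives.
    """
    cfg = SimConfig.for_snr(snr, image_shape=image_shape, n_frames=n_frames,
                            frame_interval=frame_interval, seed=seed)
    movie, gt = simulate_fusion_movie(cfg, n_events=n_events, loss_frames=loss_frames)
    det = spots.detect_movie(movie, DetectionParams(smoothing_sigma=cfg.psf_sigma))
    tracks = track.link_tracks(det, DockingParams())
    events = fuse.detect_fusion_events(tracks, frame_interval, movie=movie)
    return len(events), len(gt.fusion_events)


def field_density(
    seed: int,
    n_spots: int,
    snr: float = 10.0,
    image_shape: tuple[int, int] = (250, 250),
    min_separation: float = 6.0,
    pixel_size_nm: float = 100.0,
) -> float:
    """Granule density (per um^2) measured by the detector on one rendered field."""
    cfg = SimConfig.for_snr(snr, image_shape=image_shape, n_frames=1, seed=seed)
    frame, _ = simulate_field(cfg, n_spots, min_separation=min_separation)
    det = spots.detect_maxima(frame, DetectionParams(smoothing_sigma=cfg.psf_sigma))
    h, w = image_shape
    area = h * w * (pixel_size_nm / 1000.0) ** 2
    return spots.granule_density(det, area)


def percent_reduction(control: float, treated: float) -> float:
    """(1 - treated/control) * 100."""
    return (1.0 - treated / control) * 100.0
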