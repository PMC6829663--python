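"""Synthetic TIRF movie generation with ground truth.

Secretory granules imaged by TIRF microscopy appear as diffraction-limited
spots on a noisy background: only the ~100-200 nm of cytosol closest to the
coverslip is illuminated, so granules become visible when they approach the
plasma membrane axially and vanish when they retreat or fuse.  This module
renders movies of that process with a minimal but statistically faithful
camera model:

    expected photons = background + sum of 2-D Gaussian spots
    pixel value      = clip(Poisson(expected) + N(0, read_noise_sd), 0, 65535)

quantised to 16 bits, matching EMCCD counting statistics qualitatively.
Every injected granule, its trajectory, kind (docked / visitor / transit)
and any fusion event is recorded in a :class:`GroundTruth` object so that
detector, tracker and classifier output can be scored against an exact
oracle.  All randomness flows from a single integer seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .traces import Trace

__all__ = [
    "SimConfig",
    "ResidenceModel",
    "GroundTruth",
    "SpotRecord",
    "FusionRecord",
    "truncated_exponential",
    "simulate_movie",
    "simulate_fusion_movie",
    "simulate_crop_pair",
    "simulate_footprint_trace",
    "simulate_field",
    "place_spots",
    "render_frame",
]

MAX_DN = 65535  # 16-bit camera full well


# --------------------------------------------------------------------------- #
# configuration
# --------------------------------------------------------------------------- #

@dataclass
class SimConfig:
    """Camera / optics configuration for rendered movies.

    Parameters
    ----------
    image_shape : (H, W) in pixels.
    n_frames : number of frames.
    frame_interval : seconds between frames.
    pixel_size : nm per pixel (100 nm for the TIRF setups emulated here).
    psf_sigma : Gaussian PSF sigma in pixels.
    background_level : mean background photon count per pixel.
    read_noise_sd : additive Gaussian read noise, photons.
    spot_amplitude : peak photon count of one granule above background.
    seed : integer seed for all randomness of a simulation call.
    poisson_noise : disable to render noiseless expectation images
        (read noise is then also omitted when ``read_noise_sd == 0``).
    """

    image_shape: tuple[int, int] = (128, 128)
    n_frames: int = 100
    frame_interval: float = 1.0
    pixel_size: float = 100.0
    psf_sigma: float = 1.3
    background_level: float = 100.0
    read_noise_sd: float = 2.0
    spot_amplitude: float = 100.0
    seed: int = 0
    poisson_noise: bool = True

    def __post_init__(self) -> None:
        h, w = self.image_shape
        if h <= 0 or w <= 0 or self.n_frames <= 0:
            raise ValueError("image dimensions and n_frames must be positive")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.background_level + self.spot_amplitude > MAX_DN:
            raise ValueError("background + amplitude overflows 16-bit range")

    @property
    def noise_sd(self) -> float:
        """Per-pixel noise sd at background level (shot + read noise)."""
        return math.sqrt(self.background_level + self.read_noise_sd**2)

    @classmethod
    def for_snr(cls, snr: float, **kwargs) -> "SimConfig":
        """Config whose spot amplitude is ``snr`` times the background noise sd."""
        cfg = cls(**kwargs)
        return dataclasses.replace(cfg, spot_amplitude=snr * cfg.noise_sd)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["image_shape"] = tuple(d["image_shape"])
        return cls(**d)


DurationSpec = float | tuple[float, float] | Callable[[np.random.Generator], float]


def _sample_duration(spec: DurationSpec, rng: np.random.Generator) -> float:
    """Sample a residence time (seconds) from a duration specification.

    Accepts a constant, a ``(lo, hi)`` uniform range, or any callable
    taking a Generator and returning a positive float (scipy frozen
    distributions can be wrapped as ``lambda rng: dist.rvs(random_state=rng)``).
    """
    if callable(spec):
        val = float(spec(rng))
    elif isinstance(spec, tuple):
        val = float(rng.uniform(*spec))
    else:
        val = float(spec)
    if val <= 0:
        raise ValueError("residence durations must be positive")
    return val


def truncated_exponential(mean: float, minimum: float) -> Callable[[np.random.Generator], float]:
    """Exponential duration sampler with mean ``mean``, resampled until >= ``minimum``."""
    def sample(rng: np.random.Generator) -> float:
        while True:
            v = rng.exponential(mean)
            if v >= minimum:
                return v
    return sample


@dataclass
class ResidenceModel:
    """Arrival / residence / departure kinetics of simulated granules.

    A granule arriving in the evanescent field is long-lived ("docked")
    with probability ``p_dock``, a ballistically moving passer-by
    ("transit") with probability ``p_transit``, and otherwise a
    short-lived "visitor".  Docked and visitor granules jitter around
    their arrival point with per-frame Gaussian displacements of sd
    ``confinement_sd``; transit granules drift at ``transit_speed``.
    Appearance is rendered as a 2-frame intensity ramp (axial approach
    into the evanescent field); departure is abrupt by default.
    """

    arrival_rate: float = 0.1            # expected arrivals per frame
    p_dock: float = 0.5
    dock_residence: DurationSpec = (45.0, 120.0)   # seconds, support > 40 s
    visitor_residence: DurationSpec = (2.0, 20.0)  # seconds, support >= 2 s
    confinement_sd: float = 0.3          # px
    transit_speed: float = 2.0           # px / frame
    p_transit: float = 0.0
    appearance_ramp_frames: int = 2
    departure_ramp_frames: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_dock <= 1.0:
            raise ValueError("p_dock must lie in [0, 1]")
        if not 0.0 <= self.p_transit <= 1.0 or self.p_dock + self.p_transit > 1.0:
            raise ValueError("p_transit must lie in [0, 1 - p_dock]")


# --------------------------------------------------------------------------- #
# ground truth
# --------------------------------------------------------------------------- #

@dataclass
class SpotRecord:
    """One injected granule: frame extent, trajectory and kinetic kind."""
    id: int
    frame_start: int
    frame_end: int                 # inclusive
    trajectory: np.ndarray         # (n, 2) of (x, y), one row per live frame
    kind: str                      # docked | visitor | transit


@dataclass
class FusionRecord:
    id: int
    frame: int                     # first frame with reduced amplitude


@dataclass
class GroundTruth:
    """Simulator record of everything injected into a movie."""
    spots: list[SpotRecord] = field(default_factory=list)
    fusion_events: list[FusionRecord] = field(default_factory=list)
    structure_centers: list[tuple[float, float]] = field(default_factory=list)

    def kinds(self) -> list[str]:
        return [s.kind for s in self.spots]

    def positions_at(self, frame: int) -> np.ndarray:
        """(n, 2) array of (x, y) of granules live in ``frame``."""
        out = [s.trajectory[frame - s.frame_start]
               for s in self.spots if s.frame_start <= frame <= s.frame_end]
        return np.array(out).reshape(-1, 2)

    def to_json(self, path) -> None:
        d = {
            "spots": [
                {"id": s.id, "frame_start": s.frame_start, "frame_end": s.frame_end,
                 "kind": s.kind, "trajectory": np.asarray(s.trajectory).tolist()}
                for s in self.spots
            ],
            "fusion_events": [{"id": f.id, "frame": f.frame} for f in self.fusion_events],
            "structure_centers": [list(c) for c in self.structure_centers],
        }
        with open(path, "w") as fh:
            json.dump(d, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        gt = cls()
        gt.spots = [SpotRecord(s["id"], s["frame_start"], s["frame_end"],
                               np.asarray(s["trajectory"], float), s["kind"])
                    for s in d["spots"]]
        gt.fusion_events = [FusionRecord(f["id"], f["frame"]) for f in d["fusion_events"]]
        gt.structure_centers = [tuple(c) for c in d["structure_centers"]]
        return gt

    def spots_to_csv(self, path) -> None:
        rows = []
        for s in self.spots:
            for i, (x, y) in enumerate(np.asarray(s.trajectory)):
                rows.append((s.id, s.frame_start + i, x, y, s.kind))
        pd.DataFrame(rows, columns=["id", "frame", "x", "y", "kind"]).to_csv(path, index=False)


# --------------------------------------------------------------------------- #
# rendering primitives
# --------------------------------------------------------------------------- #

def render_frame(
    shape: tuple[int, int],
    background: float,
    positions: Sequence[tuple[float, float]],
    amplitudes: Sequence[float],
    psf_sigma: float,
) -> np.ndarray:
    """Noiseless expectation image: background plus one Gaussian per spot.

    Positions are (x, y) in pixel coordinates (x = column, y = row).
    Each spot is rendered on a local window of +-ceil(5 sigma) pixels.
    """
    h, w = shape
    img = np.full((h, w), float(background))
    r = int(math.ceil(5 * psf_sigma))
    for (x, y), amp in zip(positions, amplitudes):
        if amp == 0:
            continue
        x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
        y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        img[y0:y1, x0:x1] += amp * np.exp(
            -((xx - x) ** 2 + (yy - y) ** 2) / (2 * psf_sigma**2)
        )
    return img


def _apply_camera(expected: np.ndarray, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    out = np.asarray(expected, float)
    if cfg.poisson_noise:
        out = rng.poisson(out).astype(float)
    if cfg.read_noise_sd > 0:
        out = out + rng.normal(0.0, cfg.read_noise_sd, out.shape)
    return np.clip(np.rint(out), 0, MAX_DN).astype(np.uint16)


def place_spots(
    n: int,
    shape: tuple[int, int],
    min_separation: float,
    rng: np.random.Generator,
    margin: float = 8.0,
    max_tries: int = 20000,
) -> np.ndarray:
    """Uniform (x, y) positions with pairwise distance >= min_separation."""
    h, w = shape
    pos: list[np.ndarray] = []
    tries = 0
    while len(pos) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(f"cannot place {n} spots at separation {min_separation}")
        p = rng.uniform([margin, margin], [w - margin, h - margin])
        if all(np.hypot(*(p - q)) >= min_separation for q in pos):
            pos.append(p)
    return np.array(pos).reshape(n, 2)


def _amplitude_ramp(n_live: int, up: int, down: int) -> np.ndarray:
    """Per-frame amplitude multipliers with appearance/departure ramps
    folded inside the residence window."""
    up = min(up, n_live)
    down = min(down, max(0, n_live - up))
    m = np.ones(n_live)
    for i in range(up):
        m[i] = (i + 1) / up
    for j in range(down):
        m[n_live - down + j] = (down - j) / (down + 1)
    return m


# --------------------------------------------------------------------------- #
# movie simulators
# --------------------------------------------------------------------------- #

def simulate_movie(
    cfg: SimConfig,
    res: ResidenceModel,
    n_granules: int | None = None,
    arrival_window: tuple[int, int] | None = None,
    min_separation: float = 6.0,
    n_initial: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a docking movie and return it with its ground truth.

    Granules arrive as a Poisson process at ``res.arrival_rate`` per frame
    (or, when ``n_granules`` is given, as exactly that many arrivals at
    frames drawn uniformly from ``arrival_window``), receive a kinetic
    kind and residence time from ``res``, and are rendered with the PSF
    and camera model of ``cfg``.  ``n_initial`` docked granules can be
    present from frame 0 to emulate the standing docked pool; these are
    distinguishable from arrivals by ``frame_start == 0``.

    Returns (movie, ground_truth) with movie of shape (T, H, W), uint16.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_shape
    dt = cfg.frame_interval

    if arrival_window is None:
        arrival_window = (1, max(1, cfg.n_frames - 10))
    lo, hi = arrival_window
    no_arrivals = (n_granules == 0) or cfg.n_frames == 1
    if not no_arrivals and not (1 <= lo <= hi < cfg.n_frames):
        raise ValueError("arrival_window must lie within (0, n_frames)")

    if no_arrivals:
        arrivals = np.array([], int)
    elif n_granules is not None:
        arrivals = np.sort(rng.integers(lo, hi + 1, size=n_granules))
    else:
        counts = rng.poisson(res.arrival_rate, size=cfg.n_frames)
        counts[:lo] = 0
        arrivals = np.repeat(np.arange(cfg.n_frames), counts)

    gt = GroundTruth()
    # (frame_start, positions-by-frame, multipliers) per granule, built first
    # so concurrent-granule separation can be enforced at arrival time
    active: list[tuple[int, int]] = []  # (spot index, frame_end)

    def _start_position(frame: int) -> np.ndarray:
        live = [gt.spots[i].trajectory[frame - gt.spots[i].frame_start]
                for i, end in active if end >= frame]
        for _ in range(80):
            p = rng.uniform([8.0, 8.0], [w - 8.0, h - 8.0])
            if all(np.hypot(*(p - q)) >= min_separation for q in live):
                return p
        return p  # crowded field: accept the last draw

    def _add_granule(sid: int, frame0: int, kind: str, residence_s: float) -> None:
        n_live = max(1, int(round(residence_s / dt)))
        n_live = min(n_live, cfg.n_frames - frame0)
        p0 = _start_position(frame0)
        if kind == "transit":
            theta = rng.uniform(0, 2 * np.pi)
            v = res.transit_speed * np.array([np.cos(theta), np.sin(theta)])
            traj = p0 + np.arange(n_live)[:, None] * v
            inside = ((traj[:, 0] >= 1) & (traj[:, 0] < w - 1)
                      & (traj[:, 1] >= 1) & (traj[:, 1] < h - 1))
            n_live = max(1, int(np.argmin(inside)) if not inside.all() else n_live)
            traj = traj[:n_live]
        else:
            traj = p0 + rng.normal(0.0, res.confinement_sd, (n_live, 2))
        traj = np.clip(traj, 1.0, [w - 2.0, h - 2.0])
        rec = SpotRecord(sid, frame0, frame0 + n_live - 1, traj, kind)
        gt.spots.append(rec)
        active.append((len(gt.spots) - 1, rec.frame_end))

    sid = 0
    for _ in range(n_initial):
        resid = _sample_duration(res.dock_residence, rng)
        _add_granule(sid, 0, "docked", max(resid, cfg.n_frames * dt))
        sid += 1
    for frame0 in arrivals:
        u = rng.uniform()
        if u < res.p_transit:
            kind, spec = "transit", res.visitor_residence
        elif u < res.p_transit + res.p_dock:
            kind, spec = "docked", res.dock_residence
        else:
            kind, spec = "visitor", res.visitor_residence
        _add_granule(sid, int(frame0), kind, _sample_duration(spec, rng))
        sid += 1

    mult = {
        s.id: _amplitude_ramp(len(s.trajectory),
                              res.appearance_ramp_frames, res.departure_ramp_frames)
        for s in gt.spots
    }
    movie = np.empty((cfg.n_frames, h, w), np.uint16)
    for t in range(cfg.n_frames):
        positions, amps = [], []
        for s in gt.spots:
            if s.frame_start <= t <= s.frame_end:
                i = t - s.frame_start
                positions.append(s.trajectory[i])
                amps.append(cfg.spot_amplitude * mult[s.id][i])
        expected = render_frame((h, w), cfg.background_level, positions, amps, cfg.psf_sigma)
        movie[t] = _apply_camera(expected, cfg, rng)
    return movie, gt


def simulate_fusion_movie(
    cfg: SimConfig,
    n_events: int,
    loss_frames: int = 2,
    n_distractors: int = 10,
    min_separation: float = 10.0,
    confinement_sd: float = 0.3,
    event_window: tuple[int, int] | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Movie of docked granules of which ``n_events`` fuse.

    Fusion removes a granule's fluorescence within ``loss_frames`` frames
    (1: gone between consecutive frames; 2: one intermediate frame at half
    amplitude) with no reappearance — the abrupt-loss signature used to
    score exocytosis.  Non-fusing distractor granules persist through the
    whole movie.  Ground truth records exactly ``n_events`` fusion events,
    time-stamped at the first reduced-amplitude frame.

    The default 10-px minimum separation reflects how sparse docked,
    fusion-competent granules are at the cell footprint (of the ~10,000
    granules in a beta cell fewer than 100 are docked, several
    micrometres apart on average).
    """
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    if not 1 <= loss_frames <= 2:
        raise ValueError("loss_frames must be 1 or 2")
    if cfg.n_frames < 25:
        raise ValueError("fusion movies need at least 25 frames")
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_shape
    n_total = n_events + n_distractors
    pos0 = place_spots(n_total, (h, w), min_separation, rng)

    if event_window is None:
        event_window = (10, cfg.n_frames - 10)
    lo, hi = event_window
    if not (5 <= lo <= hi <= cfg.n_frames - 5):
        raise ValueError("event_window must leave 5 clean frames at both ends")
    event_frames = rng.integers(lo, hi + 1, size=n_events)

    gt = GroundTruth()
    for i in range(n_total):
        if i < n_events:
            e = int(event_frames[i])
            end = e if loss_frames == 2 else e - 1  # half-amplitude frame is live
            gt.fusion_events.append(FusionRecord(i, e))
        else:
            end = cfg.n_frames - 1
        n_live = end + 1
        traj = pos0[i] + rng.normal(0.0, confinement_sd, (n_live, 2))
        traj = np.clip(traj, 1.0, [w - 2.0, h - 2.0])
        gt.spots.append(SpotRecord(i, 0, end, traj, "docked"))

    fuse_frame = {f.id: f.frame for f in gt.fusion_events}
    movie = np.empty((cfg.n_frames, h, w), np.uint16)
    for t in range(cfg.n_frames):
        positions, amps = [], []
        for s in gt.spots:
            if s.frame_start <= t <= s.frame_end:
                a = cfg.spot_amplitude
                if s.id in fuse_frame and loss_frames == 2 and t == fuse_frame[s.id]:
                    a *= 0.5
                positions.append(s.trajectory[t - s.frame_start])
                amps.append(a)
        expected = render_frame((h, w), cfg.background_level, positions, amps, cfg.psf_sigma)
        movie[t] = _apply_camera(expected, cfg, rng)
    return movie, gt


def simulate_field(
    cfg: SimConfig,
    n_spots: int,
    min_separation: float = 6.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Single rendered frame with ``n_spots`` granules; returns (frame, positions).

    Convenience for density / counting experiments: one camera frame of a
    static field, positions (x, y) drawn with the given minimum separation.
    """
    rng = np.random.default_rng(cfg.seed)
    pos = place_spots(n_spots, cfg.image_shape, min_separation, rng)
    expected = render_frame(cfg.image_shape, cfg.background_level, pos,
                            [cfg.spot_amplitude] * n_spots, cfg.psf_sigma)
    return _apply_camera(expected, cfg, rng), pos


# --------------------------------------------------------------------------- #
# two-channel structure crops
# --------------------------------------------------------------------------- #

def simulate_crop_pair(
    n_structures: int,
    granule_amplitude: float,
    bound_fraction: float,
    wide_bg_sigma: float,
    seed: int,
    crop_size: int = 30,
    psf_sigma: float = 1.3,
    baseline: float = 50.0,
    probe_signal: float | None = None,
    read_noise_sd: float = 2.0,
    noise: bool = True,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Two-channel 30x30 crops centered on granule-marker structures.

    Channel 1 is the granule marker: a narrow Gaussian (sd ``psf_sigma``)
    of peak ``granule_amplitude`` at the crop center.  Channel 2 is the
    probe: a fraction ``bound_fraction`` of its above-baseline integrated
    signal sits in a narrow granule-bound component and the remainder in a
    wide component (sd ``wide_bg_sigma``), emulating a protein partly
    recruited to the granule surface and partly membrane-distributed.
    Poisson + read noise as in movie rendering when ``noise`` is True.

    Returns (crops_ch1, crops_ch2, ground_truth) with crops of shape
    (n_structures, crop_size, crop_size) in photon units (float).
    """
    if not 0.0 <= bound_fraction <= 1.0:
        raise ValueError("bound_fraction must lie in [0, 1]")
    if n_structures < 1:
        raise ValueError("need at least one structure")
    rng = np.random.default_rng(seed)
    c = (crop_size - 1) / 2.0
    yy, xx = np.mgrid[0:crop_size, 0:crop_size]
    r2 = (xx - c) ** 2 + (yy - c) ** 2
    narrow = np.exp(-r2 / (2 * psf_sigma**2))
    wide = np.exp(-r2 / (2 * wide_bg_sigma**2))
    if probe_signal is None:
        probe_signal = granule_amplitude * 2 * np.pi * psf_sigma**2
    # split integrated (not peak) signal between components
    ch2_expect = baseline + probe_signal * (
        bound_fraction * narrow / (2 * np.pi * psf_sigma**2)
        + (1.0 - bound_fraction) * wide / (2 * np.pi * wide_bg_sigma**2)
    )
    ch1_expect = baseline + granule_amplitude * narrow

    shape = (n_structures, crop_size, crop_size)
    ch1 = np.broadcast_to(ch1_expect, shape).astype(float).copy()
    ch2 = np.broadcast_to(ch2_expect, shape).astype(float).copy()
    if noise:
        ch1 = rng.poisson(ch1) + rng.normal(0.0, read_noise_sd, shape)
        ch2 = rng.poisson(ch2) + rng.normal(0.0, read_noise_sd, shape)
        ch1 = np.clip(ch1, 0, MAX_DN)
        ch2 = np.clip(ch2, 0, MAX_DN)
    gt = GroundTruth(structure_centers=[(c, c)] * n_structures)
    return ch1, ch2, gt


# --------------------------------------------------------------------------- #
# whole-footprint traces
# --------------------------------------------------------------------------- #

def simulate_footprint_trace(
    baseline: float,
    step_time: float,
    step_amplitude: float,
    plateau_time: float,
    decay_tau: float,
    noise_sd: float,
    seed: int = 0,
    dt: float = 0.5,
    rise_tau: float = 2.0,
    total_time: float | None = None,
) -> Trace:
    """Stimulus-locked whole-footprint fluorescence trace.

    Flat at ``baseline`` until ``step_time``, then rises exponentially
    (time constant ``rise_tau``) toward ``baseline + step_amplitude`` for
    ``plateau_time`` seconds of stimulation, then decays back toward
    baseline with time constant ``decay_tau`` (the reuptake phase of a
    pHluorin response).  Additive Gaussian noise of sd ``noise_sd``.
    """
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    if decay_tau <= 0 or rise_tau <= 0:
        raise ValueError("time constants must be > 0")
    if total_time is None:
        total_time = step_time + plateau_time + 5 * decay_tau
    t = np.arange(0.0, total_time + dt / 2, dt)
    t_off = step_time + plateau_time
    y = np.full_like(t, float(baseline))
    during = (t >= step_time) & (t < t_off)
    y[during] = baseline + step_amplitude * (1 - np.exp(-(t[during] - step_time) / rise_tau))
    y_off = baseline + step_amplitude * (1 - np.exp(-plateau_time / rise_tau))
    after = t >= t_off
    y[after] = baseline + (y_off - baseline) * np.exp(-(t[after] - t_off) / decay_tau)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, t.shape)
    return Trace(time=t, raw=y, background=0.0, stimulus_window=(step_time, t_off))


# --------------------------------------------------------------------------- #
# output
# --------------------------------------------------------------------------- #

def save_movie(path, movie: np.ndarray) -> None:
    """Write a (T, H, W) stack as a multi-page 16-bit TIFF."""
    tifffile.imwrite(path, np.asarray(movie, np.uint16))


def load_movie(path) -> np.ndarray:
    return tifffile.imread(path)
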