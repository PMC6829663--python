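"""Fusion (exocytosis) event detection and fusion kinetics.

A granule that fuses with the plasma membrane loses its marker
fluorescence abruptly — within one or two frames — and never reappears,
in contrast to the gradual dimming of a granule retreating axially out
of the evanescent field.  The detector automates that criterion on
linked tracks: an event is called where the background-corrected spot
intensity collapses from a stable pre-event level to below half of it
within at most ``max_drop_frames`` frames, with no recovery and no
re-detection near the site afterwards.

Also provided: cumulative exocytosis time courses and robust
single-exponential fitting, y(t) = A exp(-t/tau) + C, used for
single-granule fusion kinetics and for trace reuptake.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .track import Track

__all__ = [
    "FusionEvent",
    "ExpFit",
    "FitError",
    "detect_fusion_events",
    "cumulative_exocytosis",
    "fit_single_exponential",
    "write_fusion_csv",
]


@dataclass
class FusionEvent:
    track_id: int
    event_frame: int
    pre_mean: float       # background-corrected mean over pre-event window
    post_mean: float      # background-corrected mean over post-event window
    drop_frames: int      # frames over which the loss completed (<= 2)

    def event_time(self, frame_interval: float) -> float:
        return self.event_frame * frame_interval


class FitError(ValueError):
    """Raised when an exponential fit is unidentifiable or fails to converge."""


@dataclass
class ExpFit:
    amplitude: float
    tau: float
    offset: float
    residual_rms: float


def _track_background(tracks: list[Track], movie: np.ndarray | None) -> float:
    if movie is not None:
        return float(np.median(movie))
    return 0.0


def _movie_spot_value(movie: np.ndarray, frame: int, x: float, y: float,
                      background: float, sigma: float = 1.3) -> float:
    """Background-corrected smoothed intensity at (x, y) in one movie frame,
    on the same scale as the detector's peak intensities."""
    from scipy import ndimage as ndi

    t, h, w = movie.shape
    r, c = int(round(y)), int(round(x))
    rad = int(np.ceil(4 * sigma)) + 1
    r0, r1 = max(0, r - rad), min(h, r + rad + 1)
    c0, c1 = max(0, c - rad), min(w, c + rad + 1)
    win = ndi.gaussian_filter(movie[frame, r0:r1, c0:c1].astype(float), sigma,
                              mode="nearest")
    return float(win[r - r0, c - c0]) - background


def detect_fusion_events(
    tracks: list[Track],
    frame_interval: float,
    movie: np.ndarray | None = None,
    n_frames: int | None = None,
    background: float | None = None,
    pre_window: int = 5,
    post_window: int = 5,
    drop_fraction: float = 0.5,
    level_gate: float = 0.7,
    max_drop_frames: int = 2,
    reappear_radius: float = 2.0,
    smoothing_sigma: float = 1.3,
) -> list[FusionEvent]:
    """Detect abrupt-loss fusion events on linked tracks.

    For every track the background-corrected intensity series is scanned
    for the first point where it falls below ``drop_fraction`` times the
    mean of the preceding ``pre_window`` detections, having been at
    >= ``level_gate`` of that level no more than ``max_drop_frames``
    frames earlier — a collapse completed within one or two frames.
    Track disappearance counts as intensity zero; when ``movie`` is
    given the post-event level is instead sampled from the smoothed
    movie at the last position, on the same intensity scale as the
    detector's peak values.  The event is kept only if the mean over
    the following ``post_window`` frames stays below ``drop_fraction``
    of the pre-level, the spot does not recover, and no other track has
    a detection within ``reappear_radius`` px of the site during the
    post window.  Events within 2 frames of the movie end are discarded
    because the post window is incomplete there.

    Thresholds are configuration: the underlying scoring criterion is
    qualitative ("rapid loss within one or two frames") and these
    defaults are echoed into all outputs.
    """
    if background is None:
        background = _track_background(tracks, movie)
    if n_frames is None and movie is not None:
        n_frames = movie.shape[0]

    # all detections, for the reappearance veto
    all_det: dict[int, list[tuple[int, float, float]]] = {}
    for tr in tracks:
        for f, (x, y) in zip(tr.frames, tr.positions):
            all_det.setdefault(int(f), []).append((tr.track_id, x, y))

    def other_spot_near(track_id: int, frame: int, x: float, y: float) -> bool:
        for f in range(frame, frame + post_window + 1):
            for tid, dx, dy in all_det.get(f, []):
                if tid != track_id and np.hypot(dx - x, dy - y) <= reappear_radius:
                    return True
        return False

    events: list[FusionEvent] = []
    for tr in tracks:
        if tr.intensities.size == 0 or np.isnan(tr.intensities).all():
            raise ValueError(f"track {tr.track_id} carries no intensity data")
        c = tr.intensities - background
        n = c.size
        frames = tr.frames

        def value_at(frame: int, last_pos) -> float | None:
            """Corrected intensity at a frame: in-track sample, movie sample,
            or 0 for a frame where the spot is observably absent.  ``None``
            when the frame lies outside everything we can observe (so a
            track that merely ends with the recording is not an event)."""
            idx = np.nonzero(frames == frame)[0]
            if idx.size:
                return float(c[idx[0]])
            if movie is not None and 0 <= frame < movie.shape[0]:
                return _movie_spot_value(movie, frame, *last_pos, background,
                                         sigma=smoothing_sigma)
            if n_frames is not None and 0 <= frame < n_frames:
                return 0.0          # no detection anywhere near: spot gone
            return None

        found = None
        # scan for the last stable sample r after which the signal collapses:
        # some frame within max_drop_frames of it drops below drop_fraction
        # of the pre-level and never recovers
        for r in range(2, n):           # need >= 3 frames of stable pre-level
            pre = float(c[max(0, r - pre_window + 1): r + 1].mean())
            if pre <= 0 or c[r] < level_gate * pre:
                continue
            last_pos = tr.positions[r]
            drop_j = None
            for j in range(1, max_drop_frames + 1):
                v = value_at(int(frames[r]) + j, last_pos)
                if v is None:
                    break
                if j > 1:          # the collapse must already be under way
                    v_mid = value_at(int(frames[r]) + j - 1, last_pos)
                    if v_mid is None or v_mid >= level_gate * pre:
                        continue
                # the signal must end below half the pre-level AND have lost
                # at least half of it within j frames: a gradual dimming
                # passes the first test eventually but never the second
                if v < drop_fraction * pre and c[r] - v >= drop_fraction * pre:
                    drop_j = j
                    break
            if drop_j is None:
                continue
            event_frame = int(frames[r]) + 1
            post_vals = [value_at(f, last_pos)
                         for f in range(int(frames[r]) + drop_j,
                                        int(frames[r]) + drop_j + post_window)]
            post_vals = [v for v in post_vals if v is not None]
            if not post_vals:
                continue
            post = float(np.mean(post_vals))
            if post >= drop_fraction * pre:
                continue
            if max(post_vals) >= level_gate * pre:      # spot came back
                continue
            if other_spot_near(tr.track_id, event_frame, *last_pos):
                continue
            found = FusionEvent(tr.track_id, event_frame, pre, post, drop_j)
            break
        if found is None:
            continue
        if n_frames is not None and found.event_frame > n_frames - 3:
            continue  # post window incomplete at the movie end
        events.append(found)
    events.sort(key=lambda e: e.event_frame)
    return events


def cumulative_exocytosis(
    events: list[FusionEvent],
    t_grid: np.ndarray,
    frame_interval: float,
) -> np.ndarray:
    """Non-decreasing count of fusion events up to (and including) each time."""
    times = np.sort([e.event_time(frame_interval) for e in events])
    return np.searchsorted(times, np.asarray(t_grid, float), side="right").astype(int)


def fit_single_exponential(t: np.ndarray, y: np.ndarray) -> ExpFit:
    """Least-squares fit of y(t) = A exp(-t/tau) + C.

    Initialisation is log-linear (regressing log(y - C0) on t with C0
    slightly below the trace minimum), followed by Levenberg-Marquardt
    refinement, so no user-supplied starting values are needed.  Raises
    :class:`FitError` for constant traces (tau unidentifiable), traces
    with fewer than 5 samples, non-convergence, or a non-positive
    fitted tau.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if t.size != y.size or t.size < 5:
        raise FitError("need at least 5 samples")
    span = float(np.ptp(y))
    if span <= 1e-12 * max(1.0, abs(float(y[0]))):
        raise FitError("constant trace: tau is unidentifiable")

    c0 = float(y.min()) - 0.05 * span
    z = y - c0
    a_log, b_log = np.polyfit(t, np.log(np.maximum(z, 1e-12 * span)), 1)
    tau0 = -1.0 / a_log if a_log < 0 else float(t[-1] - t[0])
    a0 = float(np.exp(b_log))

    def model(tt, a, tau, cc):
        return a * np.exp(-tt / tau) + cc

    try:
        popt, _ = curve_fit(model, t, y, p0=(a0, tau0, c0), method="lm",
                            maxfev=20000, xtol=1e-13, ftol=1e-13, gtol=1e-13)
    except RuntimeError as exc:
        raise FitError(f"exponential fit did not converge: {exc}") from exc
    a, tau, cc = (float(v) for v in popt)
    if tau <= 0:
        raise FitError("fitted tau is non-positive; trace is not a decay")
    rms = float(np.sqrt(np.mean((model(t, a, tau, cc) - y) ** 2)))
    return ExpFit(a, tau, cc, rms)


def write_fusion_csv(events: list[FusionEvent], frame_interval: float, path) -> None:
    rows = [(e.track_id, e.event_time(frame_interval), e.pre_mean, e.post_mean,
             e.drop_frames) for e in events]
    pd.DataFrame(rows, columns=["track_id", "time_s", "pre_mean", "post_mean",
                                "drop_frames"]).to_csv(path, index=False)


def write_fit_json(fit: ExpFit, path) -> None:
    with open(path, "w") as fh:
        json.dump({"A": fit.amplitude, "tau": fit.tau, "C": fit.offset,
                   "rms": fit.residual_rms}, fh)
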