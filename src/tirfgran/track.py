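"""Track linking and dwell-time docking classification.

Per-frame detections are linked into granule tracks by greedy
nearest-neighbour assignment (closest pair first, gated at a maximum
link radius, with short detection gaps bridged).  Each track is then
classified by the dwell-time rules used for granule docking at the
plasma membrane:

* a granule that appears during the recording and stays laterally
  confined for at least ``t_min`` (2 s) counts as an *approach*;
* if its confined residence reaches ``t_dock`` (25 s) it is *docked*;
* shorter-lived confined granules are *visitors*;
* granules that fail the confinement criterion are *transit*.

Stable docking (the 0 s vs 40 s comparison) asks which approaches are
still present ``t_survival`` (40 s) after their approach frame.
Confinement is operationalized as a maximum excursion from the track's
median position of at most ``confine_radius`` pixels; the radius is not
fixed by the qualitative "laterally confined" criterion and therefore
remains explicit configuration, echoed into every report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Track",
    "DockingParams",
    "DockingEvent",
    "DockingSummary",
    "link_tracks",
    "classify_docking",
    "docking_fraction",
    "write_tracks_csv",
    "write_events_csv",
]


@dataclass
class Track:
    """One granule's linked trajectory."""

    track_id: int
    frames: np.ndarray          # int, strictly increasing, gaps <= max_gap
    positions: np.ndarray       # (n, 2) of (x, y) px
    intensities: np.ndarray     # smoothed peak intensity per detection

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, int)
        self.positions = np.asarray(self.positions, float).reshape(-1, 2)
        self.intensities = np.asarray(self.intensities, float)

    @property
    def start_frame(self) -> int:
        return int(self.frames[0])

    @property
    def end_frame(self) -> int:
        return int(self.frames[-1])

    def residence_time(self, frame_interval: float) -> float:
        return (self.end_frame - self.start_frame + 1) * frame_interval

    @property
    def max_excursion(self) -> float:
        """Maximum distance of any position from the track median position."""
        med = np.median(self.positions, axis=0)
        return float(np.hypot(*(self.positions - med).T).max())


@dataclass
class DockingParams:
    """Linking gates and dwell-time thresholds (seconds)."""

    link_radius: float = 4.0     # px
    max_gap: int = 1             # frames a detection may drop out
    confine_radius: float = 1.5  # px (150 nm at 100 nm/px)
    t_min: float = 2.0
    t_dock: float = 25.0
    t_survival: float = 40.0

    def __post_init__(self) -> None:
        if not (self.t_min < self.t_dock <= self.t_survival):
            raise ValueError("need t_min < t_dock <= t_survival")
        if self.confine_radius >= self.link_radius:
            raise ValueError("confine_radius must be smaller than link_radius")


@dataclass
class DockingEvent:
    track_id: int
    kind: str                    # docked | visitor | transit
    approach_frame: int


@dataclass
class DockingSummary:
    n_approach: int
    n_stable_at_survival: int
    fraction: float              # nan when undefined
    defined: bool
    params: DockingParams = field(repr=False, default_factory=DockingParams)


def link_tracks(spots: pd.DataFrame, params: DockingParams | None = None) -> list[Track]:
    """Link per-frame detections into tracks.

    ``spots`` needs columns ``frame``, ``x``, ``y`` and optionally
    ``intensity``.  Assignment is greedy closest-pair-first within
    ``link_radius``; a track survives up to ``max_gap`` frames without a
    detection.  Each detection joins at most one track.  Granule
    densities at the footprint are low enough that globally optimal
    assignment buys nothing over this.
    """
    params = params or DockingParams()
    if len(spots) == 0:
        return []
    if "intensity" not in spots.columns:
        spots = spots.assign(intensity=np.nan)
    spots = spots.sort_values("frame", kind="stable")

    # active track state: [frames list, positions list, intensities list]
    active: list[list] = []
    done: list[list] = []
    for frame, grp in spots.groupby("frame", sort=True):
        frame = int(frame)
        # retire tracks that exceeded the gap
        still = []
        for tr in active:
            if frame - tr[0][-1] > params.max_gap + 1:
                done.append(tr)
            else:
                still.append(tr)
        active = still

        det_xy = grp[["x", "y"]].to_numpy()
        det_int = grp["intensity"].to_numpy()
        pairs = []
        for i, tr in enumerate(active):
            last = tr[1][-1]
            d = np.hypot(det_xy[:, 0] - last[0], det_xy[:, 1] - last[1])
            for j in np.nonzero(d <= params.link_radius)[0]:
                pairs.append((d[j], i, int(j)))
        pairs.sort(key=lambda p: p[0])
        used_t: set[int] = set()
        used_d: set[int] = set()
        for d, i, j in pairs:
            if i in used_t or j in used_d:
                continue
            used_t.add(i)
            used_d.add(j)
            active[i][0].append(frame)
            active[i][1].append(det_xy[j])
            active[i][2].append(det_int[j])
        for j in range(len(det_xy)):
            if j not in used_d:
                active.append([[frame], [det_xy[j]], [det_int[j]]])
    done.extend(active)
    done.sort(key=lambda tr: (tr[0][0], tr[1][0][0], tr[1][0][1]))
    return [Track(k, f, np.array(p), np.array(v)) for k, (f, p, v) in enumerate(done)]


def classify_docking(
    track: Track,
    params: DockingParams,
    frame_interval: float,
) -> DockingEvent:
    """Classify one track as docked, visitor or transit.

    Confinement holds iff the maximum excursion from the median position
    is at most ``confine_radius``.  A confined track with residence
    >= ``t_dock`` is docked (ties at exactly t_dock dock); confined
    residence in [t_min, t_dock) is a visitor; everything else —
    unconfined tracks and confined blips shorter than t_min — is transit.
    """
    if frame_interval is None or frame_interval <= 0:
        raise ValueError("frame_interval must be a positive number of seconds")
    if track.frames.size == 0:
        raise ValueError("empty track")
    residence = track.residence_time(frame_interval)
    if track.max_excursion > params.confine_radius:
        kind = "transit"
    elif residence >= params.t_dock:
        kind = "docked"
    elif residence >= params.t_min:
        kind = "visitor"
    else:
        kind = "transit"
    return DockingEvent(track.track_id, kind, track.start_frame)


def docking_fraction(
    events: list[DockingEvent],
    tracks: list[Track],
    params: DockingParams,
    frame_interval: float,
    n_frames: int | None = None,
) -> DockingSummary:
    """Stable-docking fraction among approaching granules.

    Approaches are tracks that appear during the observation
    (start_frame > 0, so the standing pre-docked pool is excluded) and
    meet the confined >= t_min criterion, i.e. classify as docked or
    visitor.  Of those, the stable ones are still present ``t_survival``
    seconds after their approach frame.  When ``n_frames`` is given,
    approaches too close to the end of the movie for the survival window
    to be observable are excluded rather than counted as failures.
    """
    by_id = {t.track_id: t for t in tracks}
    surv_frames = int(round(params.t_survival / frame_interval))
    n_approach = 0
    n_stable = 0
    for ev in events:
        if ev.kind == "transit":
            continue
        tr = by_id[ev.track_id]
        if tr.start_frame == 0:
            continue
        if n_frames is not None and tr.start_frame + surv_frames > n_frames - 1:
            continue  # censored: survival not observable
        n_approach += 1
        if tr.end_frame >= tr.start_frame + surv_frames:
            n_stable += 1
    if n_approach == 0:
        return DockingSummary(0, 0, math.nan, False, params)
    return DockingSummary(n_approach, n_stable, n_stable / n_approach, True, params)


def write_tracks_csv(tracks: list[Track], path) -> None:
    rows = []
    for tr in tracks:
        for f, (x, y), v in zip(tr.frames, tr.positions, tr.intensities):
            rows.append((tr.track_id, int(f), x, y, v))
    pd.DataFrame(rows, columns=["track_id", "frame", "x", "y", "intensity"]).to_csv(
        path, index=False)


def write_events_csv(
    events: list[DockingEvent],
    tracks: list[Track],
    frame_interval: float,
    path,
) -> None:
    by_id = {t.track_id: t for t in tracks}
    rows = [
        (ev.track_id, ev.kind, ev.approach_frame * frame_interval,
         by_id[ev.track_id].residence_time(frame_interval))
        for ev in events
    ]
    pd.DataFrame(rows, columns=["track_id", "class", "approach_time_s",
                                "residence_s"]).to_csv(path, index=False)


def params_from_yaml(path) -> DockingParams:
    with open(path) as fh:
        return DockingParams(**yaml.safe_load(fh))
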