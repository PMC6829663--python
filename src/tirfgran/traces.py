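"""Whole-footprint fluorescence trace quantification.

Reporter traces (e.g. VAMP2-pHluorin imaged over the adherent cell
footprint) are background-corrected and expressed as F/F0, fluorescence
relative to the mean pre-stimulus level.  On the normalized trace the
module measures the maximal stimulus response and the post-stimulus
reuptake kinetics (single-exponential decay back toward baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import medfilt

__all__ = ["Trace", "normalize_trace", "max_response", "reuptake_rate", "ReuptakeResult"]


@dataclass
class Trace:
    """A fluorescence time course.

    ``background`` may be a scalar or a per-sample array; ``f_over_f0``
    is populated by :func:`normalize_trace`.  ``stimulus_window`` is the
    (t_on, t_off) interval in seconds.
    """

    time: np.ndarray
    raw: np.ndarray
    background: float | np.ndarray = 0.0
    f_over_f0: np.ndarray | None = None
    stimulus_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.raw = np.asarray(self.raw, float)
        if self.time.shape != self.raw.shape:
            raise ValueError("time and raw must have equal length")

    def corrected(self) -> np.ndarray:
        return self.raw - np.asarray(self.background, float)

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"time_s": self.time, "raw": self.raw})
        df["background"] = np.broadcast_to(np.asarray(self.background, float), self.time.shape)
        if self.f_over_f0 is not None:
            df["F_over_F0"] = self.f_over_f0
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, stimulus_window=None) -> "Trace":
        df = pd.read_csv(path)
        bg = df["background"].to_numpy() if "background" in df else 0.0
        tr = cls(df["time_s"].to_numpy(), df["raw"].to_numpy(), bg,
                 stimulus_window=stimulus_window)
        if "F_over_F0" in df:
            tr.f_over_f0 = df["F_over_F0"].to_numpy()
        return tr


def normalize_trace(trace: Trace, baseline_window: tuple[float, float] | None = None) -> Trace:
    """Background-correct and normalize to the pre-stimulus level (F/F0).

    F/F0 = (raw - background) / mean(raw - background over baseline window).
    The baseline window defaults to everything before stimulus onset and
    must precede it; the mean of F/F0 over the window is 1 by construction.
    """
    if baseline_window is None:
        if trace.stimulus_window is None:
            raise ValueError("need a baseline_window or a stimulus_window")
        baseline_window = (float(trace.time[0]), trace.stimulus_window[0])
    lo, hi = baseline_window
    if trace.stimulus_window is not None and hi > trace.stimulus_window[0]:
        raise ValueError("baseline window must precede stimulus onset")
    sel = (trace.time >= lo) & (trace.time < hi)
    if not sel.any():
        raise ValueError("baseline window contains no samples")
    corrected = trace.corrected()
    f0 = corrected[sel].mean()
    if f0 <= 0:
        raise ValueError("baseline mean is <= 0 after background subtraction")
    return replace(trace, f_over_f0=corrected / f0)


def max_response(trace: Trace) -> float:
    """Maximal F/F0 - 1 within the stimulus window after 3-point median smoothing.

    The median pre-filter keeps single-frame events (one granule fusing
    under the footprint) from dominating a whole-cell statistic.
    """
    if trace.f_over_f0 is None:
        raise ValueError("normalize the trace first")
    if trace.stimulus_window is None:
        raise ValueError("stimulus window not set")
    t_on, t_off = trace.stimulus_window
    if t_on < trace.time[0] - 1e-9 or t_on > trace.time[-1]:
        raise ValueError("stimulus window outside trace")
    smooth = medfilt(trace.f_over_f0, 3)
    sel = (trace.time >= t_on) & (trace.time <= t_off)
    return float(smooth[sel].max() - 1.0)


@dataclass
class ReuptakeResult:
    tau_s: float
    amplitude: float
    offset: float
    residual_rms: float
    fractional_recovery: float   # recovery toward baseline at the horizon
    horizon_s: float


def reuptake_rate(trace: Trace, horizon_s: float | None = None) -> ReuptakeResult:
    """Single-exponential fit of the post-stimulus decay of F/F0.

    Fits y(t) = A exp(-t/tau) + C to the segment after stimulus offset
    and reports tau plus the fractional recovery toward the F/F0 = 1
    baseline at ``horizon_s`` seconds after offset (default: end of the
    trace).  A non-decreasing post-stimulus segment is flagged as an error.
    """
    from .fuse import fit_single_exponential  # late import: fuse imports nothing back

    if trace.f_over_f0 is None:
        raise ValueError("normalize the trace first")
    if trace.stimulus_window is None:
        raise ValueError("stimulus window not set")
    t_off = trace.stimulus_window[1]
    sel = trace.time >= t_off
    t, y = trace.time[sel], trace.f_over_f0[sel]
    if t.size < 5:
        raise ValueError("post-stimulus segment needs >= 5 samples")
    n = max(1, t.size // 5)
    if y[:n].mean() <= y[-n:].mean():
        raise ValueError("post-stimulus segment is not decreasing; no reuptake to fit")
    fit = fit_single_exponential(t - t_off, y)
    if horizon_s is None:
        horizon_s = float(t[-1] - t_off)
    start = fit.amplitude + fit.offset
    at_h = fit.amplitude * np.exp(-horizon_s / fit.tau) + fit.offset
    denom = start - 1.0
    frac = float((start - at_h) / denom) if abs(denom) > 1e-12 else float("nan")
    return ReuptakeResult(fit.tau, fit.amplitude, fit.offset, fit.residual_rms,
                          frac, horizon_s)
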