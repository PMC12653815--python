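"""EWMA smoothing, adaptive thresholds, and sliding-window event detection.

The pipeline smooths the EAR, MAR, and pitch channels independently with
an exponentially weighted moving average (``out[t] = a*x[t] +
(1-a)*out[t-1]``, a = 0.2 by default), personalises the eye-closure
threshold from the first two frames, classifies per-frame eye state with
hysteresis, extracts blink / yawn / nod events as duration-filtered
threshold excursions, and summarises overlapping sliding windows
(900 frames, stride 150 at the 30 fps default) into BF / YF / NF counts
and PERCLOS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "DetectorConfig", "Event", "EventLog", "WindowSummary",
    "ewma_smooth", "init_ear_threshold", "detect_eye_state",
    "detect_events", "segment_windows", "window_summary",
    "scale_partial_window", "run_temporal_pipeline",
]

EventKind = Literal["blink", "yawn", "nod"]


@dataclass(frozen=True)
class DetectorConfig:
    """Tunable parameters of the temporal detector.

    alpha
        EWMA smoothing coefficient in (0, 1].
    ear_baseline
        Upper bound for the personalised eye-closure threshold.
    mar_threshold, hpr_threshold_deg
        Yawn (MAR) and nod (pitch deviation, degrees) thresholds.
    hysteresis_h
        Reopening margin added to the EAR threshold.
    min_blink_frames, min_yawn_frames, min_nod_frames
        Minimum run lengths for an excursion to count as an event.
    window_T, stride_S
        Sliding-window length and stride in frames.
    neutral_calib_s
        Seconds at the start of the sequence whose median smoothed
        pitch defines the neutral head pose for nod detection.
    """

    alpha: float = 0.2
    ear_baseline: float = 0.25
    mar_threshold: float = 0.75
    hpr_threshold_deg: float = 10.0
    hysteresis_h: float = 0.02
    min_blink_frames: int = 2
    min_yawn_frames: int = 50
    min_nod_frames: int = 15
    window_T: int = 900
    stride_S: int = 150
    neutral_calib_s: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        for name in ("ear_baseline", "mar_threshold", "hpr_threshold_deg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.hysteresis_h < 0:
            raise ValueError("hysteresis_h must be non-negative")
        if not 0 < self.stride_S <= self.window_T:
            raise ValueError("require 0 < stride_S <= window_T")
        for name in ("min_blink_frames", "min_yawn_frames", "min_nod_frames"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass(frozen=True)
class Event:
    kind: EventKind
    start_frame: int
    end_frame: int           # inclusive

    def __post_init__(self) -> None:
        if self.end_frame < self.start_frame:
            raise ValueError("event end before start")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass
class EventLog:
    """Detected (or scripted ground-truth) events plus per-frame eye state."""

    events: List[Event] = field(default_factory=list)
    eye_state: Optional[np.ndarray] = None   # bool, True = closed

    def of_kind(self, kind: EventKind) -> List[Event]:
        return [e for e in self.events if e.kind == kind]

    def counts(self) -> Tuple[int, int, int]:
        return (len(self.of_kind("blink")), len(self.of_kind("yawn")),
                len(self.of_kind("nod")))


@dataclass(frozen=True)
class WindowSummary:
    """Per-window behavioural counts and PERCLOS.

    ``bf/yf/nf`` count events whose start frame lies in the window;
    ``*_per_min`` convert to rates with ``count * 60 * fps / n_frames``.
    ``perclos`` is the closed-eye frame fraction in [0, 1].
    """

    window_index: int
    start_frame: int
    n_frames: int
    bf: float
    yf: float
    nf: float
    perclos: float
    fps: float
    partial: bool = False

    @property
    def bf_per_min(self) -> float:
        return self.bf * 60.0 * self.fps / self.n_frames

    @property
    def yf_per_min(self) -> float:
        return self.yf * 60.0 * self.fps / self.n_frames

    @property
    def nf_per_min(self) -> float:
        return self.nf * 60.0 * self.fps / self.n_frames


# ------------------------------------------------------------------- smoothing

def ewma_smooth(values: Sequence[float], alpha: float) -> np.ndarray:
    """Exponentially weighted moving average, seeded with the first value."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot smooth an empty series")
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    out = np.empty_like(v)
    out[0] = v[0]
    # scipy.signal.lfilter would vectorise this, but the explicit loop is
    # clear and fast enough for offline frame-rate series
    c = 1.0 - alpha
    acc = v[0]
    for t in range(1, v.size):
        acc = alpha * v[t] + c * acc
        out[t] = acc
    return out


def init_ear_threshold(ear_series: Sequence[float], baseline: float = 0.25) -> float:
    """Personalised eye-closure threshold.

    The mean EAR of the first two valid frames is compared with the
    population baseline (0.25) and the smaller value is used, so a
    narrow-eyed subject is not scored as perpetually closed.
    """
    v = np.asarray(ear_series, dtype=float)
    valid = v[np.isfinite(v)]
    if valid.size < 2:
        raise ValueError(
            "need at least two valid EAR frames to personalise the threshold; "
            "fall back to the baseline value"
        )
    return float(min(valid[:2].mean(), baseline))


# -------------------------------------------------------------------- eye state

def detect_eye_state(smoothed_ear: Sequence[float], threshold: float,
                     h: float = 0.02) -> np.ndarray:
    """Per-frame closed-eye flags with hysteresis.

    Open -> closed when the smoothed EAR drops below ``threshold``;
    closed -> open only when it rises above ``threshold + h``.  The
    initial state is open.  Returns a boolean array, True = closed.
    """
    v = np.asarray(smoothed_ear, dtype=float)
    closed = np.zeros(v.size, dtype=bool)
    state = False
    for t in range(v.size):
        if state:
            if v[t] > threshold + h:
                state = False
        else:
            if v[t] < threshold:
                state = True
        closed[t] = state
    return closed


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal True runs of a boolean array as (start, end) inclusive."""
    out: List[Tuple[int, int]] = []
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return out
    padded = np.diff(np.concatenate(([0], m.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def detect_events(
    smoothed_mar: Optional[Sequence[float]],
    eye_state: np.ndarray,
    config: DetectorConfig,
    smoothed_pitch: Optional[Sequence[float]] = None,
    fps: float = 30.0,
) -> EventLog:
    """Extract blink / yawn / nod events from thresholded smoothed series.

    * blink: maximal closed-eye run of >= ``min_blink_frames``;
    * yawn:  maximal run with smoothed MAR > ``mar_threshold`` of
      >= ``min_yawn_frames``;
    * nod:   maximal run with |smoothed pitch - neutral| >
      ``hpr_threshold_deg`` of >= ``min_nod_frames``, the neutral pitch
      being the median over the first ``neutral_calib_s`` seconds.

    Each maximal run yields exactly one event.  A missing pitch channel
    skips nod detection.
    """
    events: List[Event] = []
    for s, e in _runs(np.asarray(eye_state, dtype=bool)):
        if e - s + 1 >= config.min_blink_frames:
            events.append(Event("blink", s, e))
    if smoothed_mar is not None:
        mar = np.asarray(smoothed_mar, dtype=float)
        for s, e in _runs(mar > config.mar_threshold):
            if e - s + 1 >= config.min_yawn_frames:
                events.append(Event("yawn", s, e))
    if smoothed_pitch is not None:
        pitch = np.asarray(smoothed_pitch, dtype=float)
        n_cal = max(1, int(round(config.neutral_calib_s * fps)))
        head = pitch[:n_cal]
        head = head[np.isfinite(head)]
        neutral = float(np.median(head)) if head.size else 0.0
        dev = np.abs(pitch - neutral)
        for s, e in _runs(dev > config.hpr_threshold_deg):
            if e - s + 1 >= config.min_nod_frames:
                events.append(Event("nod", s, e))
    events.sort(key=lambda ev: (ev.start_frame, ev.kind))
    return EventLog(events=events, eye_state=np.asarray(eye_state, dtype=bool))


# --------------------------------------------------------------------- windows

def segment_windows(n_frames: int, window_T: int = 900, stride_S: int = 150
                    ) -> List[Tuple[int, int, bool]]:
    """Overlapping window layout as (start, length, partial) triples.

    Full windows start at 0, S, 2S, ... while ``start + T <= n_frames``.
    Any trailing frames beyond the last full window form one final
    partial window.  A series shorter than T is a single partial window.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if not 0 < stride_S <= window_T:
        raise ValueError("require 0 < stride_S <= window_T")
    windows: List[Tuple[int, int, bool]] = []
    start = 0
    while start + window_T <= n_frames:
        windows.append((start, window_T, False))
        start += stride_S
    covered = windows[-1][0] + window_T if windows else 0
    if covered < n_frames:
        windows.append((covered, n_frames - covered, True))
    return windows


def window_summary(
    events: EventLog,
    window: Tuple[int, int, bool],
    fps: float = 30.0,
    window_index: int = 0,
) -> WindowSummary:
    """Count events starting inside the window and compute PERCLOS."""
    start, length, partial = window
    if length < 1:
        raise ValueError("empty window")
    end = start + length
    kinds = {"blink": 0, "yawn": 0, "nod": 0}
    for ev in events.events:
        if start <= ev.start_frame < end:
            kinds[ev.kind] += 1
    if events.eye_state is not None:
        closed = np.asarray(events.eye_state, dtype=bool)[start:end]
        perclos = float(closed.sum()) / length
    else:
        perclos = 0.0
    return WindowSummary(window_index=window_index, start_frame=start,
                         n_frames=length, bf=kinds["blink"], yf=kinds["yawn"],
                         nf=kinds["nod"], perclos=perclos, fps=fps,
                         partial=partial)


def scale_partial_window(summary: WindowSummary, window_T: int,
                         mode: str = "extrapolate") -> WindowSummary:
    """Normalise a trailing partial window for comparison with full ones.

    ``extrapolate`` (default) rescales the BF/YF/NF counts by
    ``window_T / n_frames`` so a half window with 3 blinks reads as 6 on
    the full-window scale; ``rate-only`` leaves the counts untouched and
    relies on the per-minute rates (which already divide by the window
    length).  PERCLOS is a proportion and is never rescaled.
    """
    if not summary.partial:
        raise ValueError("scale_partial_window expects a partial window")
    if summary.n_frames == 0:
        raise ValueError("empty partial window")
    if summary.n_frames >= window_T:
        raise ValueError("partial window must be shorter than window_T")
    if mode == "rate-only":
        return summary
    if mode != "extrapolate":
        raise ValueError(f"unknown partial-window mode {mode!r}")
    f = window_T / summary.n_frames
    return replace(summary, bf=summary.bf * f, yf=summary.yf * f,
                   nf=summary.nf * f)


# ----------------------------------------------------------------- convenience

def run_temporal_pipeline(
    ear: Sequence[float],
    mar: Sequence[float],
    pitch: Optional[Sequence[float]],
    config: DetectorConfig = DetectorConfig(),
    fps: float = 30.0,
    partial_mode: str = "extrapolate",
) -> Tuple[EventLog, List[WindowSummary]]:
    """Full temporal stage: smooth, threshold, detect, window, summarise."""
    ear_s = ewma_smooth(ear, config.alpha)
    mar_s = ewma_smooth(mar, config.alpha)
    pitch_s = ewma_smooth(pitch, config.alpha) if pitch is not None else None
    try:
        thr = init_ear_threshold(np.asarray(ear, dtype=float), config.ear_baseline)
    except ValueError:
        thr = config.ear_baseline
    eye = detect_eye_state(ear_s, thr, config.hysteresis_h)
    log = detect_events(mar_s, eye, config, smoothed_pitch=pitch_s, fps=fps)
    summaries: List[WindowSummary] = []
    for i, win in enumerate(segment_windows(len(ear_s), config.window_T,
                                            config.stride_S)):
        s = window_summary(log, win, fps=fps, window_index=i)
        if s.partial and s.n_frames < config.window_T:
            s = scale_partial_window(s, config.window_T, mode=partial_mode)
        summaries.append(s)
    return log, summaries


def windows_to_dataframe(summaries: List[WindowSummary]):
    """Window table with the documented column order."""
    import pandas as pd

    rows = [{
        "window": s.window_index, "start": s.start_frame, "frames": s.n_frames,
        "partial": s.partial, "BF": s.bf, "YF": s.yf, "NF": s.nf,
        "BF_per_min": s.bf_per_min, "YF_per_min": s.yf_per_min,
        "NF_per_min": s.nf_per_min, "perclos": s.perclos,
    } for s in summaries]
    cols = ["window", "start", "frames", "partial", "BF", "YF", "NF",
            "BF_per_min", "YF_per_min", "NF_per_min", "perclos"]
    return pd.DataFrame(rows, columns=cols)


def events_to_dataframe(log: EventLog):
    """Event table: kind, start_frame, end_frame."""
    import pandas as pd

    rows = [{"kind": e.kind, "start_frame": e.start_frame,
             "end_frame": e.end_frame} for e in log.events]
    return pd.DataFrame(rows, columns=["kind", "start_frame", "end_frame"])
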