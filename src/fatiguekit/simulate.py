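"""Seeded simulator for fatigue-behaviour fixtures with known ground truth.

Generates per-frame EAR / MAR / pitch series (and, optionally, full
68-point landmark sequences that project those signals through a pinhole
camera) containing scripted blink, yawn and nod events.  The signal
model mirrors what an alert subject's feature traces look like at a
nominal 30 fps: EAR fluctuating in a narrow band around 0.28 with sharp
blink dips, MAR around 0.34 with long (> 50 frame) yawn plateaus, and a
stable pitch baseline punctuated by nod excursions.  Event excursions
are trapezoids — linear onset and offset around a flat core — plus
optional additive Gaussian observation noise.

All randomness flows from one ``numpy`` generator seeded per script, in
a fixed draw order (event placement first, then per-channel noise), so
a script is bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .geometry import CameraIntrinsics, load_face_template, rotation_from_euler, HeadPose
from .landmarks import LandmarkSequence, sequence_from_array
from .temporal import Event, EventLog

__all__ = [
    "EventScript", "FeatureSeries", "make_event_script",
    "simulate_feature_series", "simulate_landmark_sequence",
]

#: frames kept event-free at the start (threshold / neutral calibration)
#: and minimum spacing between any two events, so that smoothing lag
#: cannot merge neighbouring excursions.
START_GUARD = 90
EVENT_GAP = 30


@dataclass(frozen=True)
class FeatureSeries:
    """Raw per-frame feature channels produced by the simulator."""

    ear: np.ndarray
    mar: np.ndarray
    pitch: np.ndarray
    fps: float = 30.0

    def __len__(self) -> int:
        return self.ear.size


@dataclass(frozen=True)
class EventScript:
    """Fully resolved simulation script: placed events plus signal shape.

    Event intervals are the flat cores, [start, end] inclusive, and are
    non-overlapping across all kinds with an :data:`EVENT_GAP` guard.
    """

    duration_frames: int
    fps: float
    blinks: Tuple[Tuple[int, int], ...]
    yawns: Tuple[Tuple[int, int], ...]
    nods: Tuple[Tuple[int, int], ...]
    ear_baseline: float = 0.28
    mar_baseline: float = 0.34
    pitch_baseline: float = 0.0
    blink_depth: float = 0.10
    yawn_peak: float = 0.90
    nod_amplitude_deg: float = 15.0
    ramp_frames: int = 3
    sigma_ear: float = 0.0
    sigma_mar: float = 0.0
    sigma_pitch_deg: float = 0.0
    seed: int = 0

    def ground_truth(self) -> EventLog:
        events = (
            [Event("blink", s, e) for s, e in self.blinks]
            + [Event("yawn", s, e) for s, e in self.yawns]
            + [Event("nod", s, e) for s, e in self.nods]
        )
        events.sort(key=lambda ev: (ev.start_frame, ev.kind))
        return EventLog(events=events)


def make_event_script(
    duration_frames: int = 2700,
    fps: float = 30.0,
    n_blinks: int = 5,
    n_yawns: int = 2,
    n_nods: int = 3,
    blink_frames: int = 8,
    yawn_frames: int = 70,
    nod_frames: int = 30,
    seed: int = 0,
    **signal_params,
) -> EventScript:
    """Place the requested events uniformly at random without overlap.

    Events of every kind share one timeline: the admissible span
    excludes the first :data:`START_GUARD` frames (reserved for
    threshold and neutral-pose calibration), and consecutive events are
    separated by at least :data:`EVENT_GAP` frames.  Raises
    ``ValueError`` naming the limiting constraint when the requested
    events cannot pack.
    """
    rng = np.random.default_rng(seed)
    lengths = ([("blink", blink_frames)] * n_blinks
               + [("yawn", yawn_frames)] * n_yawns
               + [("nod", nod_frames)] * n_nods)
    ramp = int(signal_params.get("ramp_frames", 3))
    span = duration_frames - START_GUARD - ramp
    occupied = sum(l for _, l in lengths) + EVENT_GAP * len(lengths)
    if lengths and (span <= 0 or occupied > span):
        raise ValueError(
            f"cannot pack {len(lengths)} events ({occupied} frames incl. "
            f"{EVENT_GAP}-frame gaps) into {max(span, 0)} admissible frames; "
            f"increase duration_frames or request fewer/shorter events"
        )
    placed: List[Tuple[str, int, int]] = []
    if lengths:
        order = rng.permutation(len(lengths))
        lengths = [lengths[i] for i in order]
        # distribute the slack as random gaps before each event and after
        # the last one (uniform Dirichlet over integer slack)
        slack = span - occupied
        cuts = np.sort(rng.integers(0, slack + 1, size=len(lengths)))
        extra = np.diff(np.concatenate(([0], cuts)))
        cursor = START_GUARD
        for (kind, ln), gap in zip(lengths, extra):
            start = cursor + int(gap) + EVENT_GAP
            placed.append((kind, start, start + ln - 1))
            cursor = start + ln
    return EventScript(
        duration_frames=duration_frames, fps=fps,
        blinks=tuple((s, e) for k, s, e in placed if k == "blink"),
        yawns=tuple((s, e) for k, s, e in placed if k == "yawn"),
        nods=tuple((s, e) for k, s, e in placed if k == "nod"),
        seed=seed, **signal_params,
    )


def _trapezoid_channel(n: int, baseline: float, target: float,
                       intervals: Tuple[Tuple[int, int], ...],
                       ramp: int) -> np.ndarray:
    """Baseline series with trapezoidal excursions to ``target``.

    The flat core spans each interval; linear ramps of ``ramp`` frames
    precede and follow it.
    """
    x = np.full(n, baseline, dtype=float)
    for s, e in intervals:
        for k in range(1, ramp + 1):
            w = k / (ramp + 1)
            for idx in (s - ramp + k - 1, e + ramp - k + 1):
                if 0 <= idx < n:
                    x[idx] = baseline + (target - baseline) * w
        x[max(s, 0):min(e + 1, n)] = target
    return x


def simulate_feature_series(script: EventScript
                            ) -> Tuple[FeatureSeries, EventLog]:
    """Render a script into raw feature channels plus its ground truth.

    Draw order: placement noise is consumed by
    :func:`make_event_script`; here a fresh generator seeded with
    ``script.seed + 1`` draws EAR, MAR, then pitch noise.
    """
    n = script.duration_frames
    ear = _trapezoid_channel(n, script.ear_baseline, script.blink_depth,
                             script.blinks, script.ramp_frames)
    mar = _trapezoid_channel(n, script.mar_baseline, script.yawn_peak,
                             script.yawns, script.ramp_frames)
    pitch = _trapezoid_channel(n, script.pitch_baseline,
                               script.pitch_baseline + script.nod_amplitude_deg,
                               script.nods, script.ramp_frames)
    rng = np.random.default_rng(script.seed + 1)
    if script.sigma_ear > 0:
        ear = ear + rng.normal(0.0, script.sigma_ear, n)
    if script.sigma_mar > 0:
        mar = mar + rng.normal(0.0, script.sigma_mar, n)
    if script.sigma_pitch_deg > 0:
        pitch = pitch + rng.normal(0.0, script.sigma_pitch_deg, n)
    ear = np.clip(ear, 0.0, None)
    mar = np.clip(mar, 0.0, None)
    return FeatureSeries(ear=ear, mar=mar, pitch=pitch, fps=script.fps), \
        script.ground_truth()


# --------------------------------------------------------------- landmark mode

_RIGHT_PAIRS = ((37, 41), (38, 40))
_LEFT_PAIRS = ((43, 47), (44, 46))
_MOUTH_PAIRS = ((50, 58), (52, 56))

_FACE_DISTANCE_MM = 600.0


def _deform_template(template: np.ndarray, ear: float, mar: float) -> np.ndarray:
    """Vertical-displacement deformation hitting exact EAR / MAR values.

    Only the eyelid and inner upper/lower lip landmarks move; the aspect
    ratios depend on nothing else, so the deformation is exact under a
    frontal pose.
    """
    pts = template.copy()
    for corner_a, corner_b, pairs in (
        (36, 39, _RIGHT_PAIRS), (42, 45, _LEFT_PAIRS), (48, 54, _MOUTH_PAIRS),
    ):
        width = abs(pts[corner_b, 0] - pts[corner_a, 0])
        mid_y = 0.5 * (pts[corner_a, 1] + pts[corner_b, 1])
        target = ear if pairs is not _MOUTH_PAIRS else mar
        half = 0.5 * target * width
        for upper, lower in pairs:
            pts[upper, 1] = mid_y - half
            pts[lower, 1] = mid_y + half
    return pts


def simulate_landmark_sequence(
    script: EventScript,
    face_template: Optional[np.ndarray] = None,
    camera: Optional[CameraIntrinsics] = None,
) -> Tuple[LandmarkSequence, EventLog]:
    """Render a script into a projected 68-point landmark sequence.

    Per frame, the canonical template is deformed to the scripted
    EAR / MAR, rotated by the scripted pitch about the inter-ocular
    origin, placed 600 mm in front of the camera, and projected.
    Feeding the result through feature extraction recovers the scripted
    channels (exactly for a frontal pose; vertical foreshortening at
    nod-scale pitch keeps EAR well inside the open-eye band).
    """
    if face_template is None:
        face_template = load_face_template()
    if camera is None:
        camera = CameraIntrinsics.default()
    series, truth = simulate_feature_series(script)
    n = len(series)
    coords = np.empty((n, 68, 2))
    t = np.array([0.0, 0.0, _FACE_DISTANCE_MM])
    for i in range(n):
        pts = _deform_template(face_template, series.ear[i], series.mar[i])
        rot = rotation_from_euler(HeadPose(series.pitch[i], 0.0, 0.0))
        coords[i] = camera.project(pts @ rot.T + t)
    return sequence_from_array(coords, fps=script.fps), truth
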