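"""Data model and I/O for 68-point facial-landmark time series.

Landmarks follow the 0-based iBUG-68 convention: jaw 0-16, brows 17-26,
nose 27-35, right eye 36-41, left eye 42-47, mouth 48-67.  "Right eye"
means the subject's right eye, which appears on the image left.  This is
the 0-based scheme; Dlib documentation often numbers the same points
1-68, a common off-by-one trap.

Coordinates are image-plane pixels, x right, y down.  Frame rate is
sequence-level metadata; variable-rate video is out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple

import numpy as np

N_LANDMARKS = 68

#: iBUG-68 index groups (0-based)
RIGHT_EYE = tuple(range(36, 42))
LEFT_EYE = tuple(range(42, 48))
MOUTH = tuple(range(48, 68))


class LandmarkParseError(ValueError):
    """Raised when a landmark file violates the dialect or the invariants."""


@dataclass(frozen=True)
class LandmarkFrame:
    """One video frame's 68 landmark coordinates.

    Parameters
    ----------
    frame_index : int
        Non-negative frame number, unique within a sequence.
    points : ndarray of shape (68, 2)
        Pixel coordinates, iBUG-68 order, x right / y down.
    """

    frame_index: int
    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (N_LANDMARKS, 2):
            raise ValueError(
                f"frame {self.frame_index}: expected ({N_LANDMARKS}, 2) points, "
                f"got {pts.shape}"
            )
        object.__setattr__(self, "points", pts)

    def is_finite(self) -> bool:
        return bool(np.all(np.isfinite(self.points)))


@dataclass
class LandmarkSequence:
    """Ordered landmark frames plus the nominal frame rate.

    Invariants: strictly increasing ``frame_index``; ``fps > 0``.
    """

    frames: List[LandmarkFrame] = field(default_factory=list)
    fps: float = 30.0

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def as_array(self) -> np.ndarray:
        """Stack coordinates into an (n_frames, 68, 2) array."""
        if not self.frames:
            return np.empty((0, N_LANDMARKS, 2))
        return np.stack([f.points for f in self.frames])

    @property
    def frame_indices(self) -> np.ndarray:
        return np.array([f.frame_index for f in self.frames], dtype=int)


def validate_sequence(seq: LandmarkSequence) -> List[str]:
    """Check every sequence invariant; return human-readable violations.

    Never raises: an empty list means the sequence is valid.
    """
    violations: List[str] = []
    if not seq.fps > 0:
        violations.append(f"fps must be positive, got {seq.fps}")
    prev = -1
    for fr in seq.frames:
        if fr.frame_index < 0:
            violations.append(f"frame {fr.frame_index}: negative frame index")
        if fr.frame_index <= prev:
            violations.append(
                f"frame {fr.frame_index}: non-monotone index (previous {prev})"
            )
        prev = fr.frame_index
        if not fr.is_finite():
            violations.append(f"frame {fr.frame_index}: non-finite coordinate")
    return violations


def _require_valid(seq: LandmarkSequence, where: str) -> None:
    bad = validate_sequence(seq)
    if bad:
        raise LandmarkParseError(f"{where}: " + "; ".join(bad))


_CSV_HEADER = "frame," + ",".join(f"x{i},y{i}" for i in range(N_LANDMARKS))


def write_landmark_sequence(
    seq: LandmarkSequence, path: str | Path, dialect: str = "csv"
) -> Path:
    """Write a landmark sequence as CSV or JSON-lines.

    CSV dialect: a ``# fps=<value>`` comment line, then the header
    ``frame,x0,y0,...,x67,y67``, one row per frame.  JSONL dialect: a
    ``# header`` line carrying fps, then one JSON object per frame with
    keys ``frame`` and ``points``.  Output is deterministic (repr-based
    float formatting), so identical sequences produce identical bytes.
    """
    _require_valid(seq, "write_landmark_sequence")
    path = Path(path)
    if dialect == "csv":
        lines = [f"# fps={float(seq.fps)!r}", _CSV_HEADER]
        for fr in seq.frames:
            coords = ",".join(repr(float(v)) for v in fr.points.ravel())
            lines.append(f"{fr.frame_index},{coords}")
    elif dialect == "jsonl":
        lines = [json.dumps({"header": True, "fps": seq.fps})]
        for fr in seq.frames:
            lines.append(
                json.dumps({"frame": fr.frame_index, "points": fr.points.tolist()})
            )
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use 'csv' or 'jsonl'")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_landmark_sequence(
    path: str | Path, dialect: str = "csv", fps: float = 30.0
) -> LandmarkSequence:
    """Read a landmark sequence written by :func:`write_landmark_sequence`.

    ``fps`` is a fallback used when the file carries no rate metadata.
    Malformed rows raise :class:`LandmarkParseError` naming the line.
    """
    path = Path(path)
    text = path.read_text()
    if dialect == "csv":
        seq = _read_csv(text, fps)
    elif dialect == "jsonl":
        seq = _read_jsonl(text, fps)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use 'csv' or 'jsonl'")
    _require_valid(seq, str(path))
    return seq


def _read_csv(text: str, fps: float) -> LandmarkSequence:
    frames: List[LandmarkFrame] = []
    header_seen = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            meta = line.lstrip("#").strip()
            if meta.startswith("fps="):
                fps = float(meta[4:])
            continue
        if not header_seen:
            if line != _CSV_HEADER:
                raise LandmarkParseError(
                    f"line {lineno}: bad header; expected 'frame,x0,y0,...,x67,y67'"
                )
            header_seen = True
            continue
        fields = line.split(",")
        if len(fields) != 1 + 2 * N_LANDMARKS:
            raise LandmarkParseError(
                f"line {lineno}: expected {1 + 2 * N_LANDMARKS} fields, "
                f"got {len(fields)}"
            )
        try:
            idx = int(fields[0])
            vals = np.array([float(v) for v in fields[1:]])
        except ValueError as exc:
            raise LandmarkParseError(f"line {lineno}: {exc}") from None
        frames.append(LandmarkFrame(idx, vals.reshape(N_LANDMARKS, 2)))
    if not header_seen:
        raise LandmarkParseError("missing CSV header line")
    return LandmarkSequence(frames=frames, fps=fps)


def _read_jsonl(text: str, fps: float) -> LandmarkSequence:
    frames: List[LandmarkFrame] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise LandmarkParseError(f"line {lineno}: {exc}") from None
        if obj.get("header"):
            fps = float(obj.get("fps", fps))
            continue
        if "frame" not in obj or "points" not in obj:
            raise LandmarkParseError(f"line {lineno}: missing 'frame' or 'points'")
        pts = np.asarray(obj["points"], dtype=float)
        if pts.shape != (N_LANDMARKS, 2):
            raise LandmarkParseError(
                f"line {lineno}: expected {N_LANDMARKS} [x, y] pairs, "
                f"got shape {pts.shape}"
            )
        frames.append(LandmarkFrame(int(obj["frame"]), pts))
    return LandmarkSequence(frames=frames, fps=fps)


def sequence_from_array(
    coords: np.ndarray | Sequence, fps: float = 30.0,
    frame_indices: Iterable[int] | None = None,
) -> LandmarkSequence:
    """Build a sequence from an (n, 68, 2) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    idx = list(frame_indices) if frame_indices is not None else list(range(n))
    frames = [LandmarkFrame(i, c) for i, c in zip(idx, coords)]
    return LandmarkSequence(frames=frames, fps=fps)
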