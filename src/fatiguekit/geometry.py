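"""Per-frame geometric features: eye/mouth aspect ratios and head pose.

The eye aspect ratio (EAR) and mouth aspect ratio (MAR) are similarity
invariants of the landmark constellation::

    EAR = (|P37 - P41| + |P38 - P40|) / (2 |P36 - P39|)     (right eye)
    MAR = (|P50 - P58| + |P52 - P56|) / (2 |P54 - P48|)

with 0-based iBUG-68 indices.  Head pose is recovered by fitting a rigid
3-D face template to a landmark subset through a pinhole camera
(perspective-n-point) and reading off Euler angles from the rotation.

Angles are degrees at every API boundary.  The Euler convention is
intrinsic z-y-x (roll about the camera axis, then yaw, then pitch), i.e.
``R = Rz(roll) @ Ry(yaw) @ Rx(pitch)``, which the atan2 extraction in
:func:`euler_from_rotation` inverts exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation as _Rot

from .landmarks import LandmarkFrame, LandmarkSequence

__all__ = [
    "HeadPose", "PoseRanges", "CameraIntrinsics", "FeatureFrame",
    "DegenerateGeometryError", "PoseEstimationError",
    "eye_aspect_ratio", "mouth_aspect_ratio",
    "rotation_from_euler", "euler_from_rotation",
    "load_face_template", "estimate_head_pose", "is_abnormal_pose",
    "extract_feature_series", "RIGID_SUBSET",
]


class DegenerateGeometryError(ValueError):
    """Landmark constellation collapses a required distance to zero."""


class PoseEstimationError(RuntimeError):
    """Perspective-n-point solve failed or the configuration is degenerate."""


@dataclass(frozen=True)
class HeadPose:
    """Head orientation in degrees: pitch (x), yaw (y), roll (z).

    ``gimbal_lock`` marks poses within ~1e-6 deg of |yaw| = 90, where
    pitch and roll are no longer separable; the documented fallback sets
    roll = 0 and folds the remaining rotation into pitch.
    """

    pitch: float
    yaw: float
    roll: float
    gimbal_lock: bool = False

    def as_tuple(self) -> Tuple[float, float, float]:
        return (self.pitch, self.yaw, self.roll)


@dataclass(frozen=True)
class PoseRanges:
    """Anatomical head-motion ranges (degrees) and the abnormality rule.

    An axis is flagged abnormal when the signed angle exceeds
    ``abnormal_fraction`` of the range endpoint on its own side
    (strict inequality).
    """

    pitch_range: Tuple[float, float] = (-60.4, 69.6)
    roll_range: Tuple[float, float] = (-41.0, 36.3)
    yaw_range: Tuple[float, float] = (-75.0, 75.0)
    abnormal_fraction: float = 0.7


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole camera: focal lengths and principal point in pixels.

    The monocular default assumes focal length equal to the image width
    and the principal point at the image centre, zero distortion.
    """

    fx: float
    fy: float
    cx: float
    cy: float

    @classmethod
    def default(cls, width: int = 640, height: int = 480) -> "CameraIntrinsics":
        return cls(fx=float(width), fy=float(width),
                   cx=width / 2.0, cy=height / 2.0)

    def project(self, points_cam: np.ndarray) -> np.ndarray:
        """Project (n, 3) camera-frame points to (n, 2) pixels."""
        p = np.asarray(points_cam, dtype=float)
        z = p[:, 2]
        if np.any(z <= 0):
            raise ValueError("points behind the camera (z <= 0)")
        return np.column_stack(
            (self.fx * p[:, 0] / z + self.cx, self.fy * p[:, 1] / z + self.cy)
        )


@dataclass(frozen=True)
class FeatureFrame:
    """Per-frame features; ``pose`` is None when estimation is disabled
    or failed, ``valid`` is False when the geometry was degenerate."""

    frame_index: int
    ear_left: float
    ear_right: float
    ear_mean: float
    mar: float
    pose: Optional[HeadPose] = None
    valid: bool = True


# ---------------------------------------------------------------- aspect ratios

_RIGHT_EYE_IDX = (36, 39, 37, 41, 38, 40)   # corners then vertical pairs
_LEFT_EYE_IDX = (42, 45, 43, 47, 44, 46)


def _aspect_ratio(pts: np.ndarray, corner_a: int, corner_b: int,
                  pairs: Sequence[Tuple[int, int]], what: str) -> float:
    width = float(np.linalg.norm(pts[corner_a] - pts[corner_b]))
    if width <= 0.0:
        raise DegenerateGeometryError(
            f"{what}: zero horizontal distance between P{corner_a} and P{corner_b}"
        )
    vertical = sum(float(np.linalg.norm(pts[a] - pts[b])) for a, b in pairs)
    return vertical / (2.0 * width)


def eye_aspect_ratio(frame: LandmarkFrame, side: str) -> float:
    """EAR for one eye; ``side`` is the subject's 'left' or 'right'."""
    if side == "right":
        c0, c1, u0, l0, u1, l1 = _RIGHT_EYE_IDX
    elif side == "left":
        c0, c1, u0, l0, u1, l1 = _LEFT_EYE_IDX
    else:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    return _aspect_ratio(frame.points, c0, c1, [(u0, l0), (u1, l1)],
                         f"{side} eye")


def mouth_aspect_ratio(frame: LandmarkFrame) -> float:
    """MAR from the outer-lip landmarks."""
    return _aspect_ratio(frame.points, 54, 48, [(50, 58), (52, 56)], "mouth")


# ------------------------------------------------------------------- rotations

def rotation_from_euler(pose: HeadPose) -> np.ndarray:
    """Compose R = Rz(roll) @ Ry(yaw) @ Rx(pitch), angles in degrees."""
    px, yw, rl = np.deg2rad([pose.pitch, pose.yaw, pose.roll])
    cx, sx = np.cos(px), np.sin(px)
    cy, sy = np.cos(yw), np.sin(yw)
    cz, sz = np.cos(rl), np.sin(rl)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


_GIMBAL_TOL_DEG = 1e-6


def euler_from_rotation(r: np.ndarray) -> HeadPose:
    """Extract (pitch, yaw, roll) in degrees from a rotation matrix.

    pitch = atan2(r21, r22), yaw = atan2(-r20, hypot(r21, r22)),
    roll = atan2(r10, r00).  Near |yaw| = 90 deg the extraction is
    degenerate; the result is flagged and roll is set to 0 with
    pitch = atan2(-r01, r11).
    """
    r = np.asarray(r, dtype=float)
    if r.shape != (3, 3):
        raise ValueError("rotation matrix must be 3x3")
    if not np.allclose(r.T @ r, np.eye(3), atol=1e-6):
        raise ValueError("matrix is not orthonormal within 1e-6")
    hyp = float(np.hypot(r[2, 1], r[2, 2]))
    yaw = np.rad2deg(np.arctan2(-r[2, 0], hyp))
    if 90.0 - abs(yaw) < _GIMBAL_TOL_DEG:
        pitch = np.rad2deg(np.arctan2(-r[0, 1], r[1, 1]))
        return HeadPose(pitch=float(pitch), yaw=float(yaw), roll=0.0,
                        gimbal_lock=True)
    pitch = np.rad2deg(np.arctan2(r[2, 1], r[2, 2]))
    roll = np.rad2deg(np.arctan2(r[1, 0], r[0, 0]))
    return HeadPose(pitch=float(pitch), yaw=float(yaw), roll=float(roll))


# ------------------------------------------------------------------- head pose

#: Landmark indices treated as rigid for pose fitting: chin, nose bridge
#: and tip, nose wings, eye corners, mouth corners.  Eyelid and inner-lip
#: points deform with expressions and are excluded.
RIGID_SUBSET: Tuple[int, ...] = (8, 27, 28, 29, 30, 31, 35, 36, 39, 42, 45, 48, 54)


def load_face_template() -> np.ndarray:
    """Load the canonical 68x3 face template (millimetres, y down)."""
    text = (resources.files("fatiguekit") / "data" / "face_template_68.txt").read_text()
    rows = [ln.split() for ln in text.splitlines()
            if ln.strip() and not ln.startswith("#")]
    pts = np.array(rows, dtype=float)
    if pts.shape != (68, 3):
        raise ValueError(f"template must be 68x3, got {pts.shape}")
    return pts


def _weak_perspective_init(model: np.ndarray, image: np.ndarray,
                           cam: CameraIntrinsics) -> Tuple[np.ndarray, np.ndarray]:
    """Scaled-orthographic initial guess for (rotation vector, translation)."""
    img_n = np.column_stack(((image[:, 0] - cam.cx) / cam.fx,
                             (image[:, 1] - cam.cy) / cam.fy))
    mc = model.mean(axis=0)
    ic = img_n.mean(axis=0)
    a = model - mc
    b = img_n - ic
    # least-squares 2x3 affine map, then nearest rotation via SVD
    m, *_ = np.linalg.lstsq(a, b, rcond=None)
    m = m.T                                 # 2x3
    s = 0.5 * (np.linalg.norm(m[0]) + np.linalg.norm(m[1]))
    if s <= 0 or not np.isfinite(s):
        raise PoseEstimationError("degenerate correspondence configuration")
    r3 = np.vstack([m / s, np.cross(m[0] / s, m[1] / s)])
    u, _, vt = np.linalg.svd(r3)
    rot = u @ np.diag([1.0, 1.0, np.sign(np.linalg.det(u @ vt))]) @ vt
    tz = 1.0 / s
    t = np.array([ic[0] * tz, ic[1] * tz, tz]) - rot @ mc
    return _Rot.from_matrix(rot).as_rotvec(), t


def estimate_head_pose(
    frame: LandmarkFrame,
    camera: CameraIntrinsics,
    face_model: Optional[np.ndarray] = None,
    subset: Sequence[int] = RIGID_SUBSET,
) -> HeadPose:
    """Recover head pose by a perspective-n-point fit on rigid landmarks.

    A weak-perspective (scaled-orthographic Procrustes) solution seeds a
    Levenberg-Marquardt refinement of the reprojection error over the
    rotation vector and translation.  Raises
    :class:`PoseEstimationError` for degenerate configurations
    (e.g. collinear points) or non-convergence.
    """
    if face_model is None:
        face_model = load_face_template()
    model = np.asarray(face_model, dtype=float)[list(subset)]
    image = frame.points[list(subset)]
    if len(subset) < 6:
        raise PoseEstimationError("need at least 6 correspondences")
    if np.linalg.matrix_rank(model - model.mean(axis=0), tol=1e-9) < 2:
        raise PoseEstimationError("degenerate correspondence configuration: "
                                  "model points are collinear")
    if np.linalg.matrix_rank(image - image.mean(axis=0), tol=1e-9) < 2:
        raise PoseEstimationError("degenerate correspondence configuration: "
                                  "image points are collinear")

    rvec0, t0 = _weak_perspective_init(model, image, camera)

    def residual(params: np.ndarray) -> np.ndarray:
        rot = _Rot.from_rotvec(params[:3]).as_matrix()
        cam_pts = model @ rot.T + params[3:]
        if np.any(cam_pts[:, 2] <= 1e-9):
            return np.full(image.size, 1e6)
        proj = camera.project(cam_pts)
        return (proj - image).ravel()

    sol = least_squares(residual, np.concatenate([rvec0, t0]),
                        method="lm", xtol=1e-12, ftol=1e-12)
    if not sol.success:
        raise PoseEstimationError(f"PnP refinement failed: {sol.message}")
    return euler_from_rotation(_Rot.from_rotvec(sol.x[:3]).as_matrix())


def is_abnormal_pose(pose: HeadPose, ranges: PoseRanges = PoseRanges()
                     ) -> Tuple[bool, bool, bool]:
    """Per-axis abnormality flags (pitch, yaw, roll).

    True when the signed angle strictly exceeds ``abnormal_fraction``
    times the range endpoint on the matching side.
    """
    def flag(angle: float, rng: Tuple[float, float]) -> bool:
        lo, hi = rng
        f = ranges.abnormal_fraction
        return (angle > f * hi) or (angle < f * lo)

    return (flag(pose.pitch, ranges.pitch_range),
            flag(pose.yaw, ranges.yaw_range),
            flag(pose.roll, ranges.roll_range))


# ------------------------------------------------------------ series extraction

def extract_feature_series(
    seq: LandmarkSequence,
    estimate_pose: bool = True,
    camera: Optional[CameraIntrinsics] = None,
    face_model: Optional[np.ndarray] = None,
) -> List[FeatureFrame]:
    """Compute EAR/MAR (and optionally head pose) for every frame.

    ``ear_mean`` averages both eyes for robustness to unilateral
    occlusion.  Frames with degenerate geometry are returned with
    ``valid=False`` and NaN features rather than aborting the series;
    pose failures null only the pose.
    """
    if estimate_pose:
        if camera is None:
            camera = CameraIntrinsics.default()
        if face_model is None:
            face_model = load_face_template()
    out: List[FeatureFrame] = []
    for fr in seq.frames:
        try:
            el = eye_aspect_ratio(fr, "left")
            er = eye_aspect_ratio(fr, "right")
            mar = mouth_aspect_ratio(fr)
        except DegenerateGeometryError:
            out.append(FeatureFrame(fr.frame_index, np.nan, np.nan, np.nan,
                                    np.nan, None, valid=False))
            continue
        if not all(np.isfinite([el, er, mar])):
            out.append(FeatureFrame(fr.frame_index, np.nan, np.nan, np.nan,
                                    np.nan, None, valid=False))
            continue
        pose: Optional[HeadPose] = None
        if estimate_pose:
            try:
                pose = estimate_head_pose(fr, camera, face_model)
            except (PoseEstimationError, ValueError):
                pose = None
        out.append(FeatureFrame(fr.frame_index, el, er, (el + er) / 2.0,
                                mar, pose))
    return out


def features_to_dataframe(features: List[FeatureFrame]):
    """Tabulate features as a DataFrame with the documented column order:
    frame, ear_left, ear_right, ear_mean, mar, pitch, yaw, roll, pose_ok."""
    import pandas as pd

    rows = []
    for f in features:
        rows.append({
            "frame": f.frame_index,
            "ear_left": f.ear_left, "ear_right": f.ear_right,
            "ear_mean": f.ear_mean, "mar": f.mar,
            "pitch": f.pose.pitch if f.pose else np.nan,
            "yaw": f.pose.yaw if f.pose else np.nan,
            "roll": f.pose.roll if f.pose else np.nan,
            "pose_ok": f.pose is not None,
        })
    cols = ["frame", "ear_left", "ear_right", "ear_mean", "mar",
            "pitch", "yaw", "roll", "pose_ok"]
    return pd.DataFrame(rows, columns=cols)
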