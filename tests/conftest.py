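import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def face_template():
    from fatiguekit.geometry import load_face_template

    return load_face_template()


@pytest.fixture()
def neutral_frame(face_template):
    """A frontal, undeformed face projected through the default camera."""
    from fatiguekit.geometry import CameraIntrinsics
    from fatiguekit.landmarks import LandmarkFrame

    cam = CameraIntrinsics.default()
    pts = cam.project(face_template + np.array([0.0, 0.0, 600.0]))
    return LandmarkFrame(0, pts)


def brute_force_runs(mask):
    """Independent run-length oracle: maximal True runs as (start, end)."""
    runs, start = [], None
    for i, v in enumerate(list(mask) + [False]):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i - 1))
            start = None
    return runs
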