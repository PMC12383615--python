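import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lateralis import PoseTrack

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def rigid_track(
    heading_deg: np.ndarray,
    frame_rate: float = 30.0,
    hemisphere: str = "right",
    center: np.ndarray | None = None,
    scale: float = 1.0,
) -> PoseTrack:
    """Build a rigid four-landmark track from a per-frame heading series."""
    h = np.deg2rad(np.asarray(heading_deg, dtype=float))
    n = h.size
    u = np.stack([np.cos(h), np.sin(h)], axis=1)
    left = np.stack([-np.sin(h), np.cos(h)], axis=1)
    mid = np.zeros((n, 2)) if center is None else np.broadcast_to(center, (n, 2))
    return PoseTrack(
        time=np.arange(n) / frame_rate,
        nose=(mid + 1.5 * u) * scale,
        left_ear=(mid + 0.5 * left) * scale,
        right_ear=(mid - 0.5 * left) * scale,
        tailbase=(mid - 3.0 * u) * scale,
        frame_rate=frame_rate,
        hemisphere=hemisphere,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
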