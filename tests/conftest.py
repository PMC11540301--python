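import numpy as np
import pytest

from axonav.session import BehaviorRaw, RoiTrace, Session


@pytest.fixture
def small_session():
    """100-frame hand-built session with 2 ROIs, familiar->novel at 50."""
    rng = np.random.default_rng(42)
    n = 100
    pos = np.linspace(0, 180, n) % 200.0
    behavior = BehaviorRaw(
        position_cm=pos,
        reward_frames=np.array([40], dtype=np.int64),
        teleport_frames=np.array([50], dtype=np.int64),
        valid=np.ones(n, dtype=bool),
    )
    rois = [
        RoiTrace("axon000", "axon", 100 + rng.normal(0, 1, n)),
        RoiTrace("bleb000", "bleb", 100 + rng.normal(0, 1, n)),
    ]
    return Session(
        session_id="toy",
        source="LC",
        frame_rate_hz=30.0,
        track_length_cm=200.0,
        env_schedule=[("familiar", 0), ("novel", 50)],
        behavior=behavior,
        rois=rois,
        meta={"mouse": "m1", "custom_key": [1, 2]},
    )


def random_toy_trace(rng, n=400, fs=30.0):
    """Blocky random velocity trace for motion-onset oracle tests."""
    v = np.zeros(n)
    t = 0
    while t < n:
        dur = int(rng.integers(10, 120))
        level = rng.choice([0.0, 2.0, 8.0, 15.0])
        v[t:t + dur] = level + rng.normal(0, 0.3, size=min(dur, n - t))
        t += dur
    return v
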