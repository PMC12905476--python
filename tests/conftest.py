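import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import stemmorph as sm

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def square():
    return sm.Outline("square", [(0, 0), (1, 0), (1, 1), (0, 1)])


@pytest.fixture
def triangle():
    return sm.Outline("triangle", [(0, 0), (4, 0), (0, 3)])


def make_circle(radius=1.0, n=360, center=(0.0, 0.0), specimen_id="circle"):
    t = 2 * np.pi * np.arange(n) / n
    pts = np.column_stack([center[0] + radius * np.cos(t),
                           center[1] + radius * np.sin(t)])
    return sm.Outline(specimen_id, pts)


def make_ellipse(a=3.0, b=1.0, n=720, specimen_id="ellipse"):
    t = 2 * np.pi * np.arange(n) / n
    return sm.Outline(specimen_id, np.column_stack([a * np.cos(t), b * np.sin(t)]))


def make_blob(seed, n=720, n_modes=6, specimen_id=None):
    """Random smooth star-shaped closed outline."""
    rng = np.random.default_rng(seed)
    t = 2 * np.pi * np.arange(n) / n
    r = np.ones(n)
    for k in range(1, n_modes + 1):
        amp = rng.normal(0, 0.3 / k)
        phase = rng.uniform(0, 2 * np.pi)
        r += amp * np.cos(k * t + phase)
    r = np.clip(r, 0.2, None)
    pts = np.column_stack([r * np.cos(t), r * np.sin(t)])
    return sm.Outline(specimen_id or f"blob{seed}", pts)


@pytest.fixture
def circle():
    return make_circle()
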