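import numpy as np
import pytest

from otoshape.outline import Outline


def random_star_outline(rng: np.random.Generator, n_points: int = 256,
                        n_modes: int = 8, amp: float = 0.12) -> Outline:
    """Random smooth star-shaped outline: radius 1 plus decaying Fourier
    bumps, guaranteed simple and star-shaped about the origin."""
    th = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    r = np.ones_like(th)
    for k in range(2, n_modes + 2):
        a = rng.normal(0.0, amp / k)
        b = rng.normal(0.0, amp / k)
        r += a * np.cos(k * th) + b * np.sin(k * th)
    r = np.clip(r, 0.2, None)
    return Outline(np.column_stack([r * np.cos(th), r * np.sin(th)]))


@pytest.fixture
def rng():
    return np.random.default_rng(20210929)


@pytest.fixture
def star_outline(rng):
    return random_star_outline(rng)


def ellipse_outline(a=2.0, b=1.0, n=512, phase=0.0, center=(0.0, 0.0)):
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False) + phase
    return Outline(np.column_stack([center[0] + a * np.cos(t),
                                    center[1] + b * np.sin(t)]))
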