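import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from seedmorph import SeedContour, build_template, resample_contour

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

MORPHOTYPES = ("heben_like", "chenin_like", "sylvestris_like")


def circle_contour(r: float = 1.0, n: int = 360, center=(0.0, 0.0)) -> SeedContour:
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return SeedContour(np.column_stack([center[0] + r * np.cos(t), center[1] + r * np.sin(t)]))


def ellipse_contour(a: float = 2.0, b: float = 1.0, n: int = 720) -> SeedContour:
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return SeedContour(np.column_stack([a * np.cos(t), b * np.sin(t)]))


def square_contour(side: float = 1.0, n: int = 400) -> SeedContour:
    corners = SeedContour(side * np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float))
    return resample_contour(corners, n)


@pytest.fixture(scope="session")
def circle():
    return circle_contour()


@pytest.fixture(scope="session")
def ellipse21():
    return ellipse_contour()


@pytest.fixture(scope="session")
def unit_square():
    return square_contour()


@pytest.fixture(scope="session")
def templates():
    return {name: build_template(name) for name in MORPHOTYPES}


@pytest.fixture(scope="session")
def template_contours(templates):
    return {name: t.contour(360) for name, t in templates.items()}
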