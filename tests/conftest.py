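import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")

from vesselvpop import Centerline, default_spec, synth_population


@pytest.fixture
def straight_centerline() -> Centerline:
    """11 unit-spaced collinear points with constant radius 1.5."""
    x = np.arange(11.0)
    pts = np.column_stack([x, np.zeros(11), np.zeros(11)])
    return Centerline(points=pts, radii=np.full(11, 1.5), id="straight", label="BA")


@pytest.fixture
def semicircle_dense() -> Centerline:
    """Semicircle of radius 10 mm sampled at 1000 points."""
    theta = np.linspace(0.0, np.pi, 1000)
    pts = np.column_stack([10 * np.cos(theta), 10 * np.sin(theta), np.zeros_like(theta)])
    return Centerline(points=pts, radii=np.full(1000, 2.0), id="semi", label="ICA")


@pytest.fixture(scope="session")
def ica_pop_30():
    """Synthetic ICA-like cohort of 30 arteries (session-scoped, deterministic)."""
    return synth_population(default_spec("ICA_like", n=30, seed=7))


@pytest.fixture(scope="session")
def ba_pop_small():
    return synth_population(default_spec("BA_like", n=12, seed=3))


def random_centerline(rng: np.random.Generator, n: int = 20) -> Centerline:
    """A generic valid random centerline (monotone x keeps points distinct)."""
    x = np.cumsum(rng.uniform(0.2, 1.5, n))
    pts = np.column_stack([x, rng.normal(0, 2, n), rng.normal(0, 2, n)])
    radii = rng.uniform(0.5, 3.0, n)
    return Centerline(points=pts, radii=radii, id="rand")
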