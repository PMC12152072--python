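import numpy as np
import pytest

from emaxfit import ThreePointDesign, SampleSummary, d_optimal_x2, eta


@pytest.fixture
def paper_setting():
    """Reference setting used throughout: a=0.001, b=150, theta=(2,0.467,50)."""
    return {
        "a": 0.001,
        "b": 150.0,
        "theta0": 2.0,
        "theta1": 0.467,
        "theta2": 50.0,
        "sigma": 0.1,
        "counts": (6, 6, 6),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_summary(x, ybar, counts=(1, 1, 1), sigma=1.0):
    x = np.asarray(x, dtype=float)
    design = ThreePointDesign(float(x[0]), float(x[1]), float(x[2]))
    return SampleSummary(design, tuple(counts), tuple(float(v) for v in ybar), sigma)


def exact_summary(a, b, x2, theta, counts=(6, 6, 6), sigma=0.1):
    """Summary whose means lie exactly on the Emax curve."""
    design = ThreePointDesign(a, x2, b)
    means = eta(design.support, theta)
    return SampleSummary(design, tuple(counts), tuple(means), sigma)


def random_admissible_theta(rng, a=0.0, n=1):
    """Random increasing-concave parameters with theta2 > max(0, -a)."""
    t0 = rng.uniform(-2, 4, n)
    t1 = rng.uniform(0.1, 5, n)
    t2 = np.exp(rng.uniform(np.log(0.5), np.log(200), n))
    return np.column_stack([t0, t1, t2])
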