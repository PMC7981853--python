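import numpy as np
import pytest

from ivhr import SurvivalSample


def make_random_sample(seed: int, n: int = 120, beta: float = 0.5) -> SurvivalSample:
    """Right-censored sample with binary exposure, continuous times (no ties),
    and an instrument correlated with the exposure."""
    rng = np.random.default_rng(seed)
    w = rng.standard_normal(n)
    x = (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-1.5 * w))).astype(float)
    t = rng.exponential(np.exp(-beta * x))
    c = rng.uniform(0.0, 3.0, n)
    return SurvivalSample(
        time=np.minimum(t, c), event=(t <= c).astype(float), exposure=x, instrument=w
    )


@pytest.fixture
def random_sample() -> SurvivalSample:
    return make_random_sample(seed=7)


@pytest.fixture
def tiny_sample() -> SurvivalSample:
    # three subjects, all events, hand-checkable risk sets
    return SurvivalSample(
        time=[1.0, 2.0, 3.0], event=[1, 1, 1], exposure=[1, 0, 1], instrument=[1, 0, 0]
    )


@pytest.fixture
def csv_file(tmp_path):
    path = tmp_path / "sample.csv"
    path.write_text(
        "time,event,x,w\n"
        "1.0,1,1,0.3\n"
        "2.5,0,0,-0.1\n"
        "0.7,1,1,1.2\n"
        "3.0,0,0,0.5\n"
    )
    return path
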