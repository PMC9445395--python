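import numpy as np
import pytest

from deltalognorm import ModelParams, SeriesSettings

SEED = 20260927


@pytest.fixture(scope="session")
def settings() -> SeriesSettings:
    return SeriesSettings(epsilon=1e-10, max_terms=10_000)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(SEED)


@pytest.fixture(scope="session")
def table1_params() -> dict[float, ModelParams]:
    """The simulation-study parameter triples: mu = 1.5, sigma = 2."""
    return {p0: ModelParams.from_sigma(p0, 1.5, 2.0) for p0 in (0.1, 0.5, 0.9)}


def variance_se(x: np.ndarray) -> float:
    """Plug-in standard error of a sample variance (fourth-moment based)."""
    c = np.asarray(x, float) - np.mean(x)
    m2 = np.mean(c * c)
    m4 = np.mean(c**4)
    return float(np.sqrt(max(m4 - m2 * m2, 0.0) / c.size))
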