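import numpy as np
import pytest

from pgxtl.core import GenotypeMatrix, PGxCohort


def make_genotypes(rng: np.random.Generator, n: int, m: int) -> GenotypeMatrix:
    """Unstructured {0,1,2} genotypes with simple metadata."""
    dosages = rng.integers(0, 3, size=(n, m)).astype(float)
    return GenotypeMatrix(
        dosages,
        np.asarray([f"s{i}" for i in range(n)], dtype=object),
        np.asarray([f"v{j}" for j in range(m)], dtype=object),
        np.asarray(["A"] * m, dtype=object),
        np.asarray(["G"] * m, dtype=object),
        np.asarray(["1"] * m, dtype=object),
        np.arange(1, m + 1) * 1000,
    )


def make_cohort(rng: np.random.Generator, n: int, m: int, h2: float = 0.4) -> PGxCohort:
    """Small cohort with genuine prognostic + predictive signal."""
    g = make_genotypes(rng, n, m)
    z = (g.dosages - g.dosages.mean(0)) / np.where(g.dosages.std(0) > 0, g.dosages.std(0), 1)
    beta = rng.normal(0, 1, m) / np.sqrt(m)
    alpha = rng.normal(0, 1, m) / np.sqrt(m)
    t = (rng.random(n) < 0.5).astype(float)
    gen = z @ beta + (z * t[:, None]) @ alpha
    noise = rng.normal(0, np.sqrt(np.var(gen) * (1 - h2) / h2), n)
    y = 0.5 * t + gen + noise
    return PGxCohort(g, t, y, None)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260401)
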