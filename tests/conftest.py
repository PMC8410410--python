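import numpy as np
import pytest

from metamarker import datasets
from metamarker.diagnostic import TwoByTwo
from metamarker.meta import EffectSize


@pytest.fixture(scope="session")
def chip_records():
    return datasets.chip_summaries()


@pytest.fixture(scope="session")
def all_records():
    return datasets.all_study_records()


@pytest.fixture(scope="session")
def chip_tables(chip_records):
    return [r.counts for r in chip_records]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_effects(rng, k, tau: float = 0.4):
    """Arbitrary well-formed effect sizes for property tests."""
    g = rng.normal(-0.5, tau, size=k)
    v = rng.uniform(0.02, 0.8, size=k)
    return [EffectSize(f"S{i}", float(g[i]), float(v[i])) for i in range(k)]


def simulate_bivariate_tables(k, mu, psi, rng, n_range=(30, 120)):
    """2x2 tables drawn from the bivariate logit-normal accuracy model."""
    from scipy.special import expit

    chol = np.linalg.cholesky(psi)
    out = []
    for _ in range(k):
        eta = mu + chol @ rng.standard_normal(2)
        n1 = int(rng.integers(*n_range))
        n2 = int(rng.integers(*n_range))
        se, sp = expit(eta)
        tp = int(rng.binomial(n1, se))
        tn = int(rng.binomial(n2, sp))
        out.append(TwoByTwo(tp=tp, fp=n2 - tn, fn=n1 - tp, tn=tn))
    return out
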