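import numpy as np
import pytest

from dermaflim import synthetic as syn


@pytest.fixture(scope="session")
def tiny_cohort_config():
    """A small but structurally complete cohort: 2 AD + 2 healthy subjects,
    one 64-px stack each, depths covering every epidermal layer."""
    return syn.CohortConfig(
        seed=7,
        n_ad_subjects=2,
        n_healthy_subjects=2,
        stacks_per_subject=(1, 1),
        total_stacks=4,
        frames_per_stack=12,
        field_px=64,
        field_um=20.0,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_cohort_config):
    return syn.generate_cohort(tiny_cohort_config)


@pytest.fixture(scope="session")
def t_axis():
    """256 TCSPC bin centers over one 12.5 ns laser period."""
    nt = 256
    dt = 12.5 / nt
    return (np.arange(nt) + 0.5) * dt


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def biexp_histogram(t, a1, tau1, tau2, photons, rng=None):
    """Expected (or Poisson-sampled) biexponential decay histogram."""
    shape = a1 * np.exp(-t / tau1) + (1.0 - a1) * np.exp(-t / tau2)
    shape = shape / shape.sum() * photons
    if rng is None:
        return shape
    return rng.poisson(shape)
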