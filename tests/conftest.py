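import numpy as np
import pandas as pd
import pytest

from cropfda import (
    BasisSystem,
    VCFRMSpec,
    center,
    functionalize,
    make_synthetic_study,
)
from cropfda.experiments import pipeline_samples


@pytest.fixture(scope="session")
def small_bases():
    """Small basis pair used by most model-level tests."""
    sb = BasisSystem((0.0, 60.0), n_basis=6)
    tb = BasisSystem((0.0, 300.0), n_basis=5)
    return sb, tb


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240524)


def random_functional_samples(rng, sb, tb, n=40, J=2, noise=0.1):
    """Independent random smooth predictor curves with model-generated y."""
    from cropfda import FunctionalDatum, FunctionalSample

    t_lo, t_hi = tb.domain
    samples = []
    B_true = [rng.normal(0, 0.05, (sb.n_basis, tb.n_basis)) for _ in range(J)]
    sg = np.linspace(*sb.domain, 601)
    from cropfda import eval_basis

    Phi = eval_basis(sb, sg)
    Psi_of = lambda t: eval_basis(tb, np.array([t]))[0]
    for i in range(n):
        t_i = rng.uniform(t_lo, t_hi)
        fds, y = [], 0.0
        for j in range(J):
            c = rng.normal(0, 2.0, sb.n_basis)
            fds.append(FunctionalDatum(j, c, sb))
            x = Phi @ c
            beta = Phi @ B_true[j] @ Psi_of(t_i)
            y += np.trapezoid(x * beta, sg)
        y += rng.normal(0, noise)
        samples.append(FunctionalSample(index=i + 1, t=t_i, x=fds, y=y))
    return samples


@pytest.fixture(scope="session")
def fsamples(rng, small_bases):
    sb, tb = small_bases
    return random_functional_samples(rng, sb, tb)


@pytest.fixture(scope="session")
def tiny_study():
    """One fast synthetic study shared across pipeline-level tests."""
    return make_synthetic_study(seed=11, cadence_minutes=30, n_years=2)


@pytest.fixture(scope="session")
def tiny_samples(tiny_study):
    return pipeline_samples(tiny_study, subsample_step=3)
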