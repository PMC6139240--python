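import numpy as np
import pytest

from lrtvg import (
    Phantom,
    SolverConfig,
    assemble_spectrum,
    degrade,
    dft3,
    idft3,
    make_phantom,
    perturb_boundary,
)
from lrtvg.phantom_sim import AssembledSpectrum, observed_spectrum


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom16():
    return make_phantom((16, 16, 16), seed=1)


@pytest.fixture(scope="session")
def noisy_data32():
    """32^3 phantom observed twice (orthogonal axes) at beta=4, 1% noise."""
    p = make_phantom((32, 32, 32), seed=3)
    obs = [
        degrade(p, axis=2, beta=4, noise_pct=1.0, seed=11),
        degrade(p, axis=1, beta=4, noise_pct=1.0, seed=12),
    ]
    return p, obs, assemble_spectrum(obs, p.shape)


@pytest.fixture(scope="session")
def consistent16():
    """Consistent spectrum-truncation instance on a compact support.

    The measured coefficients are exactly those of a support-limited
    truth, so the intersection of the support and spectrum constraint
    sets contains the truth and POCS/ADMM share a common limit.
    """
    N = 16
    base = make_phantom((N, N, N), seed=1)
    sup = perturb_boundary(base.support, -2)
    truth = base.truth * sup
    p = Phantom(truth=truth, support=sup, seed=1)
    shape = (N, N, N)
    _, om1 = observed_spectrum(degrade(p, axis=2, beta=2), shape)
    _, om2 = observed_spectrum(degrade(p, axis=1, beta=2), shape)
    omega = om1 | om2
    s = dft3(truth)
    data = AssembledSpectrum(
        f0_prime=np.where(omega, s, 0.0),
        omega=omega,
        profile_spectrum=np.ones(shape),
    )
    return p, data


@pytest.fixture(scope="session")
def default48():
    """The default desk-scale experiment cell: 48^3, beta=4, 1% noise."""
    p = make_phantom((48, 48, 48), seed=0)
    obs = [
        degrade(p, axis=2, beta=4, noise_pct=1.0, seed=1),
        degrade(p, axis=1, beta=4, noise_pct=1.0, seed=2),
    ]
    return p, obs, assemble_spectrum(obs, p.shape)


@pytest.fixture
def small_state(noisy_data32):
    """A mid-flight solver state on a tiny instance for oracle checks."""
    from lrtvg.solver import solve

    shape = (8, 8, 8)
    r = np.random.default_rng(5)
    sup = np.zeros(shape, np.uint8)
    sup[2:6, 2:6, 2:6] = 1
    truth = sup * (0.5 + 0.5 * r.random(shape))
    p = Phantom(truth=truth, support=sup, seed=5)
    obs = [degrade(p, axis=2, beta=2, noise_pct=1.0, seed=7)]
    data = assemble_spectrum(obs, p.shape)
    cfg = SolverConfig(lambda_tv=0.05, lambda_lr=0.05, epsilon=0.01,
                       max_iter=5, tol=1e-12, cg_tol=1e-12, cg_max_iter=400)
    res = solve(data, p.support, cfg)
    return res.state, data, p.support, cfg
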