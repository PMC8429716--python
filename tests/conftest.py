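import numpy as np
import pytest

from sigclone import (
    ModelParams,
    SampleData,
    SignatureMatrix,
    SimulationConfig,
    random_signature_matrix,
    simulate_sample,
)


@pytest.fixture(scope="session")
def sigs5() -> SignatureMatrix:
    return random_signature_matrix(5, seed=11)


@pytest.fixture(scope="session")
def disjoint_sigs() -> SignatureMatrix:
    """Two signatures with disjoint supports (cosine distance 1)."""
    mu = np.zeros((2, 96))
    mu[0, :48] = 1.0 / 48
    mu[1, 48:] = 1.0 / 48
    return SignatureMatrix(names=("FIRST", "SECOND"), mu=mu)


@pytest.fixture(scope="session")
def two_clone_sample(disjoint_sigs):
    """Well-separated two-clone sample with clone-specific signatures."""
    cfg = SimulationConfig(
        sigs=disjoint_sigs,
        J=2,
        N=1000,
        xi=np.array([0.5, 0.5]),
        phi=np.array([1.0, 0.4]),
        pi=np.eye(2),
        rho=60.0,
        purity=0.8,
        depth=100.0,
        seed=42,
    )
    return simulate_sample(cfg)


def random_small_instance(rng: np.random.Generator):
    """Tiny random model instance for exhaustive-enumeration checks."""
    N = int(rng.integers(1, 11))
    J = int(rng.integers(1, 4))
    L = int(rng.integers(1, 6))
    mu = rng.dirichlet(np.ones(96) * 0.5, size=L)
    sigs = SignatureMatrix(names=tuple(f"S{i}" for i in range(L)), mu=mu)
    xi = rng.dirichlet(np.ones(J))
    phi = np.sort(rng.uniform(0.1, 1.0, size=J))[::-1]
    pi = rng.dirichlet(np.ones(L), size=J)
    rho = float(rng.uniform(20, 150))
    params = ModelParams(xi=xi, phi=phi, pi=pi, rho=rho)
    purity = float(rng.uniform(0.3, 0.99))
    c_major = rng.integers(1, 4, size=N)
    c_minor = np.minimum(rng.integers(0, 3, size=N), c_major)
    D = rng.integers(10, 120, size=N)
    B = rng.binomial(D, rng.uniform(0.05, 0.6, size=N))
    T = rng.integers(0, 96, size=N)
    sample = SampleData.from_arrays(
        B=B, D=D, T=T, C_major=c_major, C_minor=c_minor,
        C_normal=np.full(N, 2), purity=purity,
    )
    return sample, params, sigs
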