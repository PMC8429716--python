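"""Generative simulator for tumor samples under the clone/signature model.

Unless fixed by the user, parameters are drawn from the following priors:

* number of active signatures ~ min(Poisson(7) + 1, L), chosen uniformly
  without replacement among the L available signatures; per-clone exposures
  of the active signatures ~ Dirichlet(1, ..., 1);
* clone CCFs: the largest clone sits at CCF 1 and each subsequent CCF is
  drawn uniformly, in decreasing order, above 0.1 and at least 0.05 below
  the previous one;
* clone proportions ~ Dirichlet(1, ..., 1), redrawn until the smallest is
  above 0.05;
* overdispersion rho ~ Normal(60, sd sqrt(5)) (the "variance 5" reading;
  ``moments_as_sd=True`` switches to sd 5), floored at 1;
* purity ~ min(Normal(0.7, sd sqrt(0.1)), 0.99), redrawn while <= 0.05.

Copy number: a configurable fraction of loci is diploid (2, 1, 1); the rest
draw a total copy number either from a right-skewed discrete distribution
centered at 2 ("bell") or from a rounded log-normal(1, 0.3) ("lognormal"),
with minor = round(Beta(5, 3) * total) clipped so that minor <= major.
Reads: depth ~ Poisson(mean depth) floored at 1; variant counts follow the
model's beta-binomial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import ModelParams, SampleData, SignatureMatrix

_MAX_ATTEMPTS = 10_000

# right-skewed discrete total-copy-number law centered at 2 ("bell" mode)
_BELL_TOTALS = np.array([1, 2, 3, 4, 5, 6])
_BELL_PROBS = np.array([0.15, 0.40, 0.25, 0.12, 0.05, 0.03])


@dataclass
class SimulationConfig:
    """Settings of one simulated sample."""

    sigs: SignatureMatrix
    J: int = 2
    N: int = 1000
    xi: Optional[np.ndarray] = None
    phi: Optional[np.ndarray] = None
    pi: Optional[np.ndarray] = None
    rho: Optional[float] = None
    purity: Optional[float] = None
    diploid_fraction: float = 0.5
    depth: float = 100.0
    cn_mode: str = "bell"
    moments_as_sd: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not (0 <= self.diploid_fraction <= 1):
            raise ValueError("diploid_fraction must lie in [0, 1]")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.cn_mode not in ("bell", "lognormal"):
            raise ValueError("cn_mode must be 'bell' or 'lognormal'")
        if self.J < 1:
            raise ValueError("J must be >= 1")


@dataclass
class GroundTruth:
    """Latent record of a simulated sample, for metric computation."""

    params: ModelParams
    purity: float
    U: np.ndarray
    S: np.ndarray
    M: np.ndarray
    active_signatures: np.ndarray

    @property
    def n_clones(self) -> int:
        return self.params.n_clones

    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "xi": self.params.xi.tolist(),
            "phi": self.params.phi.tolist(),
            "pi": self.params.pi.tolist(),
            "rho": self.params.rho,
            "purity": self.purity,
            "U": self.U.tolist(),
            "S": self.S.tolist(),
            "M": self.M.tolist(),
            "active_signatures": self.active_signatures.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        params = ModelParams(
            xi=np.array(d["xi"]), phi=np.array(d["phi"]), pi=np.array(d["pi"]),
            rho=d["rho"],
        )
        return cls(
            params=params,
            purity=d["purity"],
            U=np.array(d["U"], dtype=int),
            S=np.array(d["S"], dtype=int),
            M=np.array(d["M"], dtype=int),
            active_signatures=np.array(d["active_signatures"], dtype=int),
        )

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def random_signature_matrix(
    L: int, seed: int | np.random.Generator = 0, concentration: float = 0.1
) -> SignatureMatrix:
    """Synthetic signature matrix: L sparse Dirichlet profiles over 96 types.

    A small concentration gives peaked, well-separated profiles similar in
    sparsity to catalogued signatures.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    mu = rng.dirichlet(np.full(96, concentration), size=L)
    mu = np.maximum(mu, 1e-12)
    mu /= mu.sum(axis=1, keepdims=True)
    names = tuple(f"SIG{i + 1}" for i in range(L))
    return SignatureMatrix(names=names, mu=mu)


def _draw_phi(J: int, rng: np.random.Generator) -> np.ndarray:
    # sequential uniform draws can leave no room for the next clone
    # (previous CCF within 0.15 of the floor); redraw the whole vector then
    for _ in range(_MAX_ATTEMPTS):
        phi = np.empty(J)
        phi[0] = 1.0
        ok = True
        for j in range(1, J):
            upper = phi[j - 1] - 0.05
            if upper <= 0.1:
                ok = False
                break
            phi[j] = rng.uniform(0.1, upper)
        if ok:
            return phi
    raise RuntimeError(f"cannot place {J} clone CCFs above 0.1 with 0.05 spacing")


def _draw_xi(J: int, rng: np.random.Generator) -> np.ndarray:
    if J == 1:
        return np.ones(1)
    for _ in range(_MAX_ATTEMPTS):
        xi = rng.dirichlet(np.ones(J))
        if xi.min() > 0.05:
            return xi
    raise RuntimeError("clone-proportion rejection sampling did not terminate")


def _draw_pi(
    J: int, L: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n_active = min(int(rng.poisson(7)) + 1, L)
    active = rng.choice(L, size=n_active, replace=False)
    pi = np.zeros((J, L))
    for j in range(J):
        pi[j, active] = rng.dirichlet(np.ones(n_active))
    return pi, np.sort(active)


def _draw_rho(rng: np.random.Generator, moments_as_sd: bool = False) -> float:
    sd = 5.0 if moments_as_sd else np.sqrt(5.0)
    return float(max(rng.normal(60.0, sd), 1.0))


def draw_prior_params(
    J: int, L: int, rng: np.random.Generator, moments_as_sd: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, np.ndarray]:
    """One draw of (xi, phi, pi, rho, active signatures) from the priors."""
    xi = _draw_xi(J, rng)
    phi = _draw_phi(J, rng)
    pi, active = _draw_pi(J, L, rng)
    rho = _draw_rho(rng, moments_as_sd)
    return xi, phi, pi, rho, active


def draw_parameters(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, np.ndarray]:
    """Model parameters for one sample: fixed values from the config where
    given, prior draws otherwise."""
    J, L = config.J, config.sigs.n_signatures
    xi = np.asarray(config.xi, dtype=float) if config.xi is not None else _draw_xi(J, rng)
    phi = np.asarray(config.phi, dtype=float) if config.phi is not None else _draw_phi(J, rng)
    if config.pi is not None:
        pi = np.asarray(config.pi, dtype=float)
        active = np.flatnonzero(pi.sum(axis=0) > 0)
    else:
        pi, active = _draw_pi(J, L, rng)
    rho = config.rho if config.rho is not None else _draw_rho(rng, config.moments_as_sd)
    return xi, phi, pi, float(rho), active


def draw_purity(rng: np.random.Generator, moments_as_sd: bool = False) -> float:
    """min(Normal(0.7, sd sqrt(0.1)), 0.99), redrawn while <= 0.05."""
    sd = 0.1 if moments_as_sd else np.sqrt(0.1)
    for _ in range(_MAX_ATTEMPTS):
        p = min(rng.normal(0.7, sd), 0.99)
        if p > 0.05:
            return float(p)
    raise RuntimeError("purity rejection sampling did not terminate")


def draw_copy_number(
    config: SimulationConfig, rng: np.random.Generator, N: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNV (C_normal, C_major, C_minor)."""
    c_normal = np.full(N, 2, dtype=np.int64)
    c_major = np.ones(N, dtype=np.int64)
    c_minor = np.ones(N, dtype=np.int64)
    diploid = rng.random(N) < config.diploid_fraction
    n_other = int((~diploid).sum())
    if n_other:
        if config.cn_mode == "lognormal":
            total = np.maximum(
                np.round(np.exp(rng.normal(1.0, 0.3, size=n_other))), 1
            ).astype(np.int64)
        else:
            total = rng.choice(_BELL_TOTALS, size=n_other, p=_BELL_PROBS)
        minor = np.round(rng.beta(5.0, 3.0, size=n_other) * total).astype(np.int64)
        minor = np.clip(minor, 0, total // 2)
        major = total - minor
        # construction guarantees major >= 1; guard stays for safety
        redo = major < 1
        minor[redo] = 0
        major[redo] = total[redo]
        c_major[~diploid] = major
        c_minor[~diploid] = minor
    return c_normal, c_major, c_minor


def _categorical_rows(prob_rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one category per row of a (N, K) row-stochastic matrix."""
    cum = np.cumsum(prob_rows, axis=1)
    r = rng.random(prob_rows.shape[0])
    return (r[:, None] > cum).sum(axis=1).astype(np.int64)


def simulate_sample(config: SimulationConfig) -> tuple[SampleData, GroundTruth]:
    """Draw one full sample and its latent ground truth (seed-deterministic)."""
    rng = np.random.default_rng(config.seed)
    mu = config.sigs.mu
    xi, phi, pi, rho, active = draw_parameters(config, rng)
    purity = config.purity if config.purity is not None else draw_purity(
        rng, config.moments_as_sd
    )
    N = config.N

    U = _categorical_rows(np.tile(xi, (N, 1)), rng)
    S = _categorical_rows(pi[U], rng)
    T = _categorical_rows(mu[S], rng)
    c_normal, c_major, c_minor = draw_copy_number(config, rng, N)
    M = (np.floor(rng.random(N) * c_major) + 1).astype(np.int64)
    D = np.maximum(rng.poisson(config.depth, size=N), 1)

    denom = purity * (c_major + c_minor) + (1 - purity) * c_normal
    eta = purity * M / denom
    mean = np.clip(phi[U] * eta, 1e-10, 1 - 1e-10)
    p_success = rng.beta(rho * mean, rho * (1 - mean))
    B = rng.binomial(D, p_success)

    sample = SampleData.from_arrays(
        B=B, D=D, T=T, C_major=c_major, C_minor=c_minor, C_normal=c_normal,
        purity=purity,
    )
    truth = GroundTruth(
        params=ModelParams(xi=xi, phi=phi, pi=pi, rho=rho),
        purity=purity,
        U=U,
        S=S,
        M=M,
        active_signatures=active,
    )
    return sample, truth


def _cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    return float(1.0 - a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


def clone_profile_cosine_distance(pi: np.ndarray, sigs: SignatureMatrix) -> float:
    """Cosine distance between the 96-type profiles of the first two clones."""
    profiles = pi @ sigs.mu
    return _cosine_distance(profiles[0], profiles[1])


def two_clone_grid(
    config: SimulationConfig,
    ccf_gaps: Sequence[float],
    n_pi_samples: int,
    cosine_target: str = "uniform",
    pool_size: int = 10_000,
) -> list[SimulationConfig]:
    """Configurations for the two-clone separating-power grid.

    Clones are equal-weighted (50%/50%) with the larger CCF pinned at 1 and
    the other at ``1 - gap``.  Exposure pairs are drawn by rejection sampling
    so that the cosine distance between the two clone profiles follows the
    requested target distribution ("uniform" or "beta(1.5,8)", the latter
    concentrating on small distances), using an empirical proposal density
    estimated from a reference pool of prior draws.
    """
    from scipy.stats import beta as beta_dist

    for g in ccf_gaps:
        if not (0 < g < 1):
            raise ValueError(f"ccf gap must lie in (0, 1), got {g}")
    if cosine_target not in ("uniform", "beta(1.5,8)"):
        raise ValueError("cosine_target must be 'uniform' or 'beta(1.5,8)'")

    rng = np.random.default_rng(config.seed)
    L = config.sigs.n_signatures
    pool = []
    dists = np.empty(pool_size)
    for i in range(pool_size):
        pi, _ = _draw_pi(2, L, rng)
        pool.append(pi)
        dists[i] = clone_profile_cosine_distance(pi, config.sigs)

    d_max = float(dists.max())
    n_bins = 40
    edges = np.linspace(0, d_max + 1e-12, n_bins + 1)
    hist, _ = np.histogram(dists, bins=edges, density=True)
    bin_of = np.clip(np.digitize(dists, edges) - 1, 0, n_bins - 1)
    proposal = np.maximum(hist[bin_of], 1e-12)
    if cosine_target == "uniform":
        target = np.ones_like(dists) / max(d_max, 1e-12)
    else:
        target = beta_dist.pdf(np.clip(dists / max(d_max, 1e-12), 1e-9, 1 - 1e-9), 1.5, 8)
    if n_pi_samples > pool_size:
        raise ValueError("cannot keep more exposure pairs than the pool holds")
    # importance resampling: weights target/proposal, drawn without
    # replacement, so exactly n_pi_samples pairs come out distributed (over
    # the pool's support) according to the target
    weights = target / proposal
    kept = rng.choice(
        pool_size, size=n_pi_samples, replace=False, p=weights / weights.sum()
    )

    configs = []
    for gap in ccf_gaps:
        for rank, idx in enumerate(kept):
            configs.append(
                SimulationConfig(
                    sigs=config.sigs,
                    J=2,
                    N=config.N,
                    xi=np.array([0.5, 0.5]),
                    phi=np.array([1.0, 1.0 - gap]),
                    pi=pool[idx].copy(),
                    rho=config.rho,
                    purity=config.purity,
                    diploid_fraction=config.diploid_fraction,
                    depth=config.depth,
                    cn_mode=config.cn_mode,
                    seed=int(rng.integers(2**31 - 1)),
                )
            )
    return configs
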