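"""Core probabilistic model.

Observed variables per SNV: variant read count ``B``, total depth ``D``,
mutation-type index ``T`` (one of the 96 pyrimidine-centric trinucleotide
substitution types), and the clonal allele-specific copy-number state
``(C_normal, C_major, C_minor)``.  Sample-level: tumor purity ``p``.

Latent variables per SNV: the clone ``U`` (J clones with weights xi and CCFs
phi), the signature ``S`` (L signatures with per-clone exposures pi), and the
multiplicity ``M`` (number of copies carrying the mutation, uniform on
``1..C_major``).  Read counts follow

    B | D, U, C, M ~ BetaBinomial(D, rho * phi_U * eta, rho * (1 - phi_U * eta))

with ``eta(M, C) = p*M / (p*C_tumor + (1-p)*C_normal)``, so that the mean of
``B/D`` is the expected variant allele frequency and ``rho`` controls
overdispersion.  All computation is carried out in the log domain.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, gammaln, logsumexp

logger = logging.getLogger(__name__)

# floor/ceiling applied to phi * eta before forming beta-binomial shapes
_EPS = 1e-10

_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_FLANKS = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class MutationTypeSpace:
    """The 96 trinucleotide substitution types in COSMIC SBS96 order.

    Index layout is substitution-major: ``sub_idx * 16 + five_prime_idx * 4 +
    three_prime_idx`` with flank alphabet A, C, G, T.  Labels look like
    ``"A[C>A]A"``.
    """

    def __init__(self) -> None:
        labels = []
        for sub in _SUBSTITUTIONS:
            for five in _FLANKS:
                for three in _FLANKS:
                    labels.append(f"{five}[{sub}]{three}")
        self.labels: tuple[str, ...] = tuple(labels)
        self.index_of: dict[str, int] = {lab: i for i, lab in enumerate(labels)}

    def __len__(self) -> int:
        return 96

    def index_from_context(self, ref: str, alt: str, five: str, three: str) -> int:
        """Type index for a substitution with its flanking bases.

        Purine reference bases (A/G) are reverse-complemented to the
        pyrimidine-centric convention.
        """
        ref, alt, five, three = ref.upper(), alt.upper(), five.upper(), three.upper()
        if ref in ("A", "G"):
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
            five, three = _COMPLEMENT[three], _COMPLEMENT[five]
        label = f"{five}[{ref}>{alt}]{three}"
        try:
            return self.index_of[label]
        except KeyError:
            raise ValueError(f"not a valid SNV context: {label!r}") from None


MUTATION_TYPES = MutationTypeSpace()


@dataclass(frozen=True)
class SignatureMatrix:
    """Known mutational signatures: an L x 96 row-stochastic matrix."""

    names: tuple[str, ...]
    mu: np.ndarray

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "names", tuple(self.names))
        if mu.ndim != 2 or mu.shape[1] != 96:
            raise ValueError(f"signature matrix must be L x 96, got {mu.shape}")
        if len(self.names) != mu.shape[0]:
            raise ValueError("number of names does not match number of rows")
        if mu.shape[0] < 1:
            raise ValueError("need at least one signature")
        if np.any(mu < 0):
            raise ValueError("signature probabilities must be non-negative")
        if not np.allclose(mu.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("signature rows must sum to 1")

    @property
    def n_signatures(self) -> int:
        return self.mu.shape[0]


@dataclass(frozen=True)
class SnvObservation:
    """One observed SNV: read counts, mutation type and copy-number state."""

    B: int
    D: int
    T: int
    C_major: int
    C_minor: int
    C_normal: int = 2

    def __post_init__(self) -> None:
        if not (0 <= self.B <= self.D):
            raise ValueError(f"need 0 <= B <= D, got B={self.B}, D={self.D}")
        if self.D < 1:
            raise ValueError("total depth D must be >= 1")
        if not (0 <= self.T < 96):
            raise ValueError(f"mutation-type index out of range: {self.T}")
        if self.C_major < 1:
            raise ValueError("an observed SNV cannot sit on zero copies (C_major >= 1)")
        if not (0 <= self.C_minor <= self.C_major):
            raise ValueError("need 0 <= C_minor <= C_major")
        if self.C_normal < 1:
            raise ValueError("C_normal must be >= 1")

    @property
    def C_tumor(self) -> int:
        return self.C_major + self.C_minor


class SampleData:
    """All observed SNVs of one tumor sample plus its purity.

    Stores the observations both as a list of :class:`SnvObservation` and as
    flat numpy arrays for vectorized likelihood evaluation.
    """

    def __init__(self, snvs: list[SnvObservation], purity: float):
        if len(snvs) < 1:
            raise ValueError("a sample needs at least one SNV")
        if not (0 < purity <= 1):
            raise ValueError(f"purity must be in (0, 1], got {purity}")
        self.snvs = list(snvs)
        self.purity = float(purity)
        self.B = np.array([s.B for s in snvs], dtype=np.int64)
        self.D = np.array([s.D for s in snvs], dtype=np.int64)
        self.T = np.array([s.T for s in snvs], dtype=np.int64)
        self.C_major = np.array([s.C_major for s in snvs], dtype=np.int64)
        self.C_minor = np.array([s.C_minor for s in snvs], dtype=np.int64)
        self.C_normal = np.array([s.C_normal for s in snvs], dtype=np.int64)
        self.C_tumor = self.C_major + self.C_minor

    @classmethod
    def from_arrays(
        cls,
        B,
        D,
        T,
        C_major,
        C_minor,
        C_normal,
        purity: float,
    ) -> "SampleData":
        snvs = [
            SnvObservation(B=int(b), D=int(d), T=int(t), C_major=int(cma),
                           C_minor=int(cmi), C_normal=int(cn))
            for b, d, t, cma, cmi, cn in zip(B, D, T, C_major, C_minor, C_normal)
        ]
        return cls(snvs, purity)

    def __len__(self) -> int:
        return len(self.snvs)

    @property
    def max_multiplicity(self) -> int:
        return int(self.C_major.max())


@dataclass(frozen=True)
class ModelParams:
    """Full model state theta = (xi, phi, pi, rho) for J clones.

    xi: clone weights (simplex of length J); phi: clone CCFs in (0, 1],
    pi: J x L per-clone signature exposures (rows are simplices); rho: the
    beta-binomial precision (overdispersion) parameter.
    """

    xi: np.ndarray
    phi: np.ndarray
    pi: np.ndarray
    rho: float

    def __post_init__(self) -> None:
        xi = np.asarray(self.xi, dtype=float)
        phi = np.asarray(self.phi, dtype=float)
        pi = np.asarray(self.pi, dtype=float)
        object.__setattr__(self, "xi", xi)
        object.__setattr__(self, "phi", phi)
        object.__setattr__(self, "pi", pi)
        object.__setattr__(self, "rho", float(self.rho))
        J = xi.shape[0]
        if J < 1 or phi.shape != (J,) or pi.ndim != 2 or pi.shape[0] != J:
            raise ValueError("inconsistent parameter shapes")
        if not np.isclose(xi.sum(), 1.0, atol=1e-8) or np.any(xi < 0):
            raise ValueError("xi must be a simplex")
        if not np.allclose(pi.sum(axis=1), 1.0, atol=1e-8) or np.any(pi < 0):
            raise ValueError("each row of pi must be a simplex")
        if np.any(phi <= 0) or np.any(phi > 1):
            raise ValueError("phi entries must lie in (0, 1]")
        if self.rho <= 0:
            raise ValueError("rho must be > 0")

    @property
    def n_clones(self) -> int:
        return self.xi.shape[0]

    @property
    def n_signatures(self) -> int:
        return self.pi.shape[1]


@dataclass
class Responsibilities:
    """Joint posterior over (clone, signature, multiplicity) per SNV.

    ``gamma`` has shape (N, J, L, M_max); entries for multiplicities above an
    SNV's C_major are exactly zero.  Each SNV's table sums to one.
    """

    gamma: np.ndarray

    @property
    def clone_marginal(self) -> np.ndarray:
        return self.gamma.sum(axis=(2, 3))

    @property
    def signature_marginal(self) -> np.ndarray:
        return self.gamma.sum(axis=(1, 3))

    @property
    def multiplicity_marginal(self) -> np.ndarray:
        return self.gamma.sum(axis=(1, 2))

    @property
    def clone_signature_marginal(self) -> np.ndarray:
        return self.gamma.sum(axis=3)


def eta(m: int, snv: SnvObservation, p: float) -> float:
    """Expected VAF of a fully clonal mutation present on ``m`` copies.

    ``eta = p*m / (p*C_tumor + (1-p)*C_normal)``.
    """
    if not (1 <= m <= snv.C_major):
        raise ValueError(f"multiplicity {m} outside [1, {snv.C_major}]")
    return p * m / (p * snv.C_tumor + (1 - p) * snv.C_normal)


def expected_vaf(p: float, ccf: float, m: int, snv: SnvObservation) -> float:
    """Expected fraction of variant reads: ``ccf * eta(m, snv, p)``."""
    if not (0 <= ccf <= 1):
        raise ValueError(f"ccf must lie in [0, 1], got {ccf}")
    return ccf * eta(m, snv, p)


def corrected_ccf(snv: SnvObservation, p: float, m: int, clip: bool = False) -> float:
    """CCF of an SNV obtained by inverting the expected-VAF relation.

    ``(B/D) * (p*C_tumor + (1-p)*C_normal) / (p*m)``.  May exceed 1 from
    sampling noise; set ``clip=True`` to truncate at 1 (for plotting).
    """
    if p <= 0:
        raise ValueError("purity must be positive")
    if m < 1:
        raise ValueError("multiplicity must be >= 1")
    value = (snv.B / snv.D) * (p * snv.C_tumor + (1 - p) * snv.C_normal) / (p * m)
    return min(value, 1.0) if clip else value


def betabinom_logpmf(B, D, alpha, beta):
    """Log pmf of the beta-binomial via log-gamma identities (vectorized)."""
    B = np.asarray(B, dtype=float)
    D = np.asarray(D, dtype=float)
    return (
        gammaln(D + 1)
        - gammaln(B + 1)
        - gammaln(D - B + 1)
        + betaln(B + alpha, D - B + beta)
        - betaln(alpha, beta)
    )


def _eta_table(sample: SampleData) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNV eta for every candidate multiplicity.

    Returns ``(eta, valid)`` of shape (N, M_max); ``valid[n, m-1]`` marks
    ``m <= C_major[n]``.
    """
    p = sample.purity
    m_grid = np.arange(1, sample.max_multiplicity + 1)
    denom = p * sample.C_tumor + (1 - p) * sample.C_normal
    eta_nm = p * m_grid[None, :] / denom[:, None]
    valid = m_grid[None, :] <= sample.C_major[:, None]
    return eta_nm, valid


def _clamped_mean(
    phi: np.ndarray, eta_nm: np.ndarray, valid: np.ndarray | None = None
) -> np.ndarray:
    """phi[j] * eta[n, m] clamped into (EPS, 1-EPS), shape (N, J, M_max).

    The warning counts only multiplicities within their SNV's support;
    values on the padded part of the grid are clamped silently.
    """
    mean = phi[None, :, None] * eta_nm[:, None, :]
    bad = (mean <= 0) | (mean >= 1)
    if valid is not None:
        bad = bad & valid[:, None, :]
    if np.any(bad):
        logger.warning(
            "clamping %d beta-binomial means into (%g, %g)", int(bad.sum()), _EPS, 1 - _EPS
        )
    return np.clip(mean, _EPS, 1 - _EPS)


def loglik_cube(
    sample: SampleData, params: ModelParams, sigs: SignatureMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Log joint density log P(B, T, U=j, S=l, M=m | D, C) per SNV.

    Returns ``(cube, valid)`` where ``cube`` has shape (N, J, L, M_max) with
    ``-inf`` at invalid multiplicities, and ``valid`` is the (N, M_max) mask.
    """
    if params.n_signatures != sigs.n_signatures:
        raise ValueError("pi and mu disagree on the number of signatures")
    eta_nm, valid = _eta_table(sample)
    mean = _clamped_mean(params.phi, eta_nm, valid)  # (N, J, M)
    alpha = params.rho * mean
    beta = params.rho * (1 - mean)
    logbb = betabinom_logpmf(
        sample.B[:, None, None], sample.D[:, None, None], alpha, beta
    )  # (N, J, M)
    logbb = np.where(valid[:, None, :], logbb, -np.inf)
    with np.errstate(divide="ignore"):
        log_xi = np.log(params.xi)  # (J,)
        log_pi = np.log(params.pi)  # (J, L)
        log_mu_T = np.log(sigs.mu[:, sample.T].T)  # (N, L)
        log_m_prior = -np.log(sample.C_major.astype(float))  # (N,)
    cube = (
        log_xi[None, :, None, None]
        + log_pi[None, :, :, None]
        + log_mu_T[:, None, :, None]
        + log_m_prior[:, None, None, None]
        + logbb[:, :, None, :]
    )
    return cube, valid


def snv_loglik_components(
    snv: SnvObservation, params: ModelParams, sigs: SignatureMatrix, p: float
) -> np.ndarray:
    """Table of log joint densities over (clone, signature, multiplicity).

    Shape (J, L, C_major) for a single SNV.
    """
    sample = SampleData([snv], p)
    cube, _ = loglik_cube(sample, params, sigs)
    return cube[0, :, :, : snv.C_major]


def marginal_loglik(
    sample: SampleData, params: ModelParams, sigs: SignatureMatrix
) -> float:
    """Observed-data log-likelihood: sum over SNVs of the log-sum-exp of
    the per-SNV joint table."""
    cube, _ = loglik_cube(sample, params, sigs)
    per_snv = logsumexp(cube.reshape(len(sample), -1), axis=1)
    return float(per_snv.sum())


def posterior_responsibilities(
    sample: SampleData, params: ModelParams, sigs: SignatureMatrix
) -> Responsibilities:
    """Normalized posterior P(U, S, M | data) per SNV."""
    cube, _ = loglik_cube(sample, params, sigs)
    flat = cube.reshape(len(sample), -1)
    log_norm = logsumexp(flat, axis=1)
    gamma = np.exp(cube - log_norm[:, None, None, None])
    return Responsibilities(gamma=gamma)


def map_assignments(resp: Responsibilities) -> np.ndarray:
    """Per-SNV maximum-a-posteriori (clone, signature, multiplicity).

    Ties break toward the lowest flat index, i.e. lowest clone, then
    signature, then multiplicity.  Returns an (N, 3) integer array; the
    multiplicity column is 1-based.
    """
    N, J, L, M = resp.gamma.shape
    flat_idx = resp.gamma.reshape(N, -1).argmax(axis=1)
    j, rest = np.divmod(flat_idx, L * M)
    l, m = np.divmod(rest, M)
    return np.column_stack([j, l, m + 1])


def brute_force_posterior(
    sample: SampleData, params: ModelParams, sigs: SignatureMatrix
) -> tuple[float, np.ndarray]:
    """Reference implementation by exhaustive enumeration over (U, S, M).

    Evaluates the joint probability of every latent configuration per SNV
    with scalar arithmetic and normalizes directly.  Intended for tests on
    tiny instances; quadratic-ish and unvectorized on purpose.
    """
    from scipy.stats import betabinom as sp_betabinom

    J, L = params.n_clones, params.n_signatures
    M_max = sample.max_multiplicity
    loglik = 0.0
    gamma = np.zeros((len(sample), J, L, M_max))
    for n, snv in enumerate(sample.snvs):
        probs = {}
        for j, l, m in itertools.product(range(J), range(L), range(1, snv.C_major + 1)):
            e = eta(m, snv, sample.purity)
            mean = min(max(params.phi[j] * e, _EPS), 1 - _EPS)
            pmf = sp_betabinom.pmf(
                snv.B, snv.D, params.rho * mean, params.rho * (1 - mean)
            )
            probs[(j, l, m)] = (
                params.xi[j]
                * params.pi[j, l]
                * sigs.mu[l, snv.T]
                * (1.0 / snv.C_major)
                * pmf
            )
        total = sum(probs.values())
        loglik += np.log(total)
        for (j, l, m), v in probs.items():
            gamma[n, j, l, m - 1] = v / total
    return loglik, gamma
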