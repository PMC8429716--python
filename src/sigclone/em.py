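"""Expectation-maximization fitting for a fixed number of clones.

The E-step is the exact posterior over (clone, signature, multiplicity).
The M-step uses closed-form updates for the clone weights xi and the
exposures pi, and bounded derivative-free scalar maximization for each
clone CCF phi_j and for the overdispersion rho (a generalized EM: each
coordinate update is accepted only if it does not decrease the expected
complete-data log-likelihood, so the marginal likelihood is monotone).

Fitting with more than one clone is normally warm-started by splitting the
clone with the largest contribution to the mixture entropy of the previous
fit (see :func:`split_init`); random restarts draw initial parameters from
the same priors the simulator uses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .core import (
    ModelParams,
    Responsibilities,
    SampleData,
    SignatureMatrix,
    _eta_table,
    betabinom_logpmf,
    loglik_cube,
    posterior_responsibilities,
)

_PHI_MIN = 1e-3


@dataclass
class EmConfig:
    """Knobs of the EM fit."""

    max_iter: int = 1000
    tol: float = 1e-6
    n_restarts: int = 5
    seed: int = 0
    rho_bounds: tuple[float, float] = (10.0, 500.0)

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        lo, hi = self.rho_bounds
        if not (0 < lo < hi):
            raise ValueError("rho_bounds must be strictly positive and increasing")


@dataclass
class FitResult:
    """Outcome of one EM fit at a fixed number of clones."""

    params: ModelParams
    loglik: float
    n_iter: int
    converged: bool
    trajectory: list[float] = field(default_factory=list)
    criterion: Optional[float] = None
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "n_clones": self.params.n_clones,
            "xi": self.params.xi.tolist(),
            "phi": self.params.phi.tolist(),
            "pi": self.params.pi.tolist(),
            "rho": self.params.rho,
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "trajectory": list(self.trajectory),
            "criterion": self.criterion,
            "seed": self.seed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        params = ModelParams(
            xi=np.array(d["xi"]), phi=np.array(d["phi"]), pi=np.array(d["pi"]),
            rho=d["rho"],
        )
        return cls(
            params=params,
            loglik=d["loglik"],
            n_iter=d["n_iter"],
            converged=d["converged"],
            trajectory=list(d.get("trajectory", [])),
            criterion=d.get("criterion"),
            seed=d.get("seed"),
        )

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def e_step(
    sample: SampleData, params: ModelParams, sigs: SignatureMatrix
) -> Responsibilities:
    """Posterior responsibilities over (clone, signature, multiplicity)."""
    return posterior_responsibilities(sample, params, sigs)


def _e_step_with_loglik(
    sample: SampleData, params: ModelParams, sigs: SignatureMatrix
) -> tuple[Responsibilities, float]:
    cube, _ = loglik_cube(sample, params, sigs)
    flat = cube.reshape(len(sample), -1)
    log_norm = logsumexp(flat, axis=1)
    gamma = np.exp(cube - log_norm[:, None, None, None])
    return Responsibilities(gamma=gamma), float(log_norm.sum())


def _bb_expected_loglik(
    w_jm: np.ndarray,
    phi: np.ndarray,
    rho: float,
    sample: SampleData,
    eta_nm: np.ndarray,
    valid: np.ndarray,
) -> float:
    """Expected beta-binomial term of the complete-data log-likelihood.

    ``w_jm`` are responsibilities summed over signatures, shape (N, J, M).
    """
    mean = np.clip(phi[None, :, None] * eta_nm[:, None, :], 1e-10, 1 - 1e-10)
    logbb = betabinom_logpmf(
        sample.B[:, None, None], sample.D[:, None, None], rho * mean, rho * (1 - mean)
    )
    logbb = np.where(valid[:, None, :], logbb, 0.0)
    return float((w_jm * logbb).sum())


def m_step(
    sample: SampleData,
    resp: Responsibilities,
    params_prev: ModelParams,
    sigs: SignatureMatrix,
    config: EmConfig,
    tie_pi: bool = False,
) -> ModelParams:
    """One M-step: closed-form xi and pi, scalar maximization for phi and rho.

    With ``tie_pi=True`` the exposures are shared across clones (the
    constrained model of the signature-change test).
    """
    gamma = resp.gamma
    N = gamma.shape[0]
    w_j = gamma.sum(axis=(2, 3))  # (N, J)
    w_jl = gamma.sum(axis=3)      # (N, J, L)
    w_jm = gamma.sum(axis=2)      # (N, J, M)

    xi = w_j.sum(axis=0)
    xi = xi / xi.sum()

    counts_jl = w_jl.sum(axis=0)  # (J, L)
    if tie_pi:
        shared = counts_jl.sum(axis=0)
        if shared.sum() <= 0:
            pi = params_prev.pi
        else:
            pi = np.tile(shared / shared.sum(), (params_prev.n_clones, 1))
    else:
        pi = np.empty_like(counts_jl)
        for j in range(counts_jl.shape[0]):
            tot = counts_jl[j].sum()
            pi[j] = params_prev.pi[j] if tot <= 0 else counts_jl[j] / tot

    eta_nm, _ = _eta_table(sample)
    phi = params_prev.phi.copy()
    rho = params_prev.rho
    from scipy.special import gammaln

    B = sample.B.astype(float)
    DmB = (sample.D - sample.B).astype(float)

    # Expected beta-binomial log-likelihood restricted to one clone and
    # stripped of terms constant in phi_j (binomial coefficient and
    # gammaln(D + rho)); responsibilities are zero at invalid
    # multiplicities so no masking is needed.  SNVs with negligible weight
    # for the clone are skipped.
    for j in range(phi.shape[0]):
        w_m = w_jm[:, j, :]
        idx = np.flatnonzero(w_m.sum(axis=1) > 1e-12)
        if idx.size == 0:
            continue
        w_sub = w_m[idx]
        eta_sub = eta_nm[idx]
        B_sub = B[idx, None]
        DmB_sub = DmB[idx, None]

        def neg_q_phi(value):
            mean = np.clip(value * eta_sub, 1e-10, 1 - 1e-10)
            a = rho * mean
            b = rho - a
            terms = gammaln(B_sub + a) + gammaln(DmB_sub + b) - gammaln(a) - gammaln(b)
            return -float((w_sub * terms).sum())

        current = -neg_q_phi(phi[j])
        res = minimize_scalar(
            neg_q_phi, bounds=(_PHI_MIN, 1.0), method="bounded",
            options={"xatol": 1e-5},
        )
        if np.isfinite(res.fun) and -res.fun > current:
            phi[j] = float(res.x)

    # rho update: here gammaln(rho) and gammaln(D + rho) do vary; the
    # per-SNV responsibilities sum to one, collapsing those terms to
    # N * gammaln(rho) - sum_n gammaln(D_n + rho).
    mean_all = np.clip(phi[None, :, None] * eta_nm[:, None, :], 1e-10, 1 - 1e-10)

    def neg_q_rho(value):
        a = value * mean_all
        b = value - a
        terms = (
            gammaln(B[:, None, None] + a)
            + gammaln(DmB[:, None, None] + b)
            - gammaln(a)
            - gammaln(b)
        )
        q = (w_jm[:, :, :] * terms).sum()
        q += N * gammaln(value) - gammaln(sample.D + value).sum()
        return -float(q)

    current = -neg_q_rho(rho)
    res = minimize_scalar(
        neg_q_rho, bounds=config.rho_bounds, method="bounded",
        options={"xatol": 1e-2},
    )
    if np.isfinite(res.fun) and -res.fun > current:
        rho = float(res.x)

    return ModelParams(xi=xi, phi=phi, pi=pi, rho=rho)


def _random_init(J: int, L: int, rng: np.random.Generator) -> ModelParams:
    # same priors as the simulator's parameter draws
    from .simulate import draw_prior_params

    xi, phi, pi, rho, _ = draw_prior_params(J, L, rng)
    return ModelParams(xi=xi, phi=phi, pi=pi, rho=rho)


def _run_em(
    sample: SampleData,
    sigs: SignatureMatrix,
    init: ModelParams,
    config: EmConfig,
    tie_pi: bool,
) -> FitResult:
    params = init
    trajectory: list[float] = []
    ll_prev = -np.inf
    converged = False
    n_iter = 0
    for it in range(config.max_iter):
        resp, ll = _e_step_with_loglik(sample, params, sigs)
        trajectory.append(ll)
        n_iter = it + 1
        if it > 0 and (ll - ll_prev) < config.tol * abs(ll_prev):
            converged = True
            break
        ll_prev = ll
        params = m_step(sample, resp, params, sigs, config, tie_pi=tie_pi)
    else:
        # iteration cap reached after an M-step: report likelihood at the
        # final parameters
        _, ll = _e_step_with_loglik(sample, params, sigs)
        trajectory.append(ll)
    return FitResult(
        params=params,
        loglik=trajectory[-1],
        n_iter=n_iter,
        converged=converged,
        trajectory=trajectory,
        seed=config.seed,
    )


def fit_fixed_j(
    sample: SampleData,
    sigs: SignatureMatrix,
    J: int,
    init: Optional[ModelParams] = None,
    config: Optional[EmConfig] = None,
    tie_pi: bool = False,
) -> FitResult:
    """Fit the model with exactly ``J`` clones.

    With ``init=None`` the fit is repeated from ``config.n_restarts`` random
    initializations (drawn from the simulator priors, seeded) and the best
    log-likelihood wins; otherwise a single run starts from ``init``.
    """
    if J < 1:
        raise ValueError("J must be >= 1")
    config = config or EmConfig()
    if init is not None:
        return _run_em(sample, sigs, init, config, tie_pi)
    rng = np.random.default_rng(config.seed)
    best: Optional[FitResult] = None
    for _ in range(max(1, config.n_restarts)):
        start = _random_init(J, sigs.n_signatures, rng)
        fit = _run_em(sample, sigs, start, config, tie_pi)
        if best is None or fit.loglik > best.loglik:
            best = fit
    return best


def split_init(
    params_prev: ModelParams,
    resp_prev: Optional[Responsibilities] = None,
    delta: float = 0.05,
) -> ModelParams:
    """Initialization with one extra clone by splitting the clone with the
    largest contribution ``-xi_j log xi_j`` to the mixture entropy.

    The split clone's weight is halved between the two copies, whose CCFs
    are perturbed to ``phi +- delta`` (clipped into (0, 1]); exposures are
    copied.  ``resp_prev`` is accepted for interface symmetry but unused.
    """
    xi, phi, pi = params_prev.xi, params_prev.phi, params_prev.pi
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(xi > 0, -xi * np.log(xi), 0.0)
    j = int(np.argmax(contrib))
    new_xi = np.insert(xi, j + 1, xi[j] / 2.0)
    new_xi[j] = xi[j] / 2.0
    lo = np.clip(phi[j] - delta, _PHI_MIN, 1.0)
    hi = np.clip(phi[j] + delta, _PHI_MIN, 1.0)
    new_phi = np.insert(phi, j + 1, lo)
    new_phi[j] = hi
    new_pi = np.insert(pi, j + 1, pi[j], axis=0)
    return ModelParams(xi=new_xi, phi=new_phi, pi=new_pi, rho=params_prev.rho)
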