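"""Likelihood-ratio test for signature-activity change between clones.

The full model gives every clone its own signature exposures; the
constrained (null) model ties the exposures across clones.  Twice the
log-likelihood gap is compared against a chi-square whose degrees of
freedom are *calibrated* on simulated null data, because the comparison is
nonstandard (the EM optimum is approximate and the models are far from the
asymptotic regime).  Per grid cell (J clones, L signatures) the chi-square
df is fitted by maximum likelihood to the simulated null statistics, then a
ridge regression predicts df from (J, L); coefficients are averaged over
cross-validation folds.  A point mass of exactly-zero statistics is handled
as zero inflation.

Beyond the test, :func:`quantify_changes` reports per-signature activity
differences between the clonal clone (highest CCF) and the largest subclone
(largest expected number of SNVs).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .core import ModelParams, Responsibilities, SampleData, SignatureMatrix
from .em import EmConfig, FitResult, fit_fixed_j

logger = logging.getLogger(__name__)

_ZERO_TOL = 1e-8


@dataclass
class LrtResult:
    """Outcome of the signature-change likelihood-ratio test."""

    statistic: float
    df_used: float
    p_value: float
    significant: bool


@dataclass
class DfCalibration:
    """Linear model mapping (J, L) to chi-square degrees of freedom."""

    coefficients: dict  # {"intercept": ., "j": ., "l": .}
    cv_folds: int = 10
    regularization: float = 1.0
    zero_mass: float = 0.0
    cells: list = field(default_factory=list)  # [(J, L, fitted_df, n_used), ...]

    def predict_df(self, J: int, L: int) -> float:
        c = self.coefficients
        return float(max(c["intercept"] + c["j"] * J + c["l"] * L, 1e-2))

    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "coefficients": self.coefficients,
            "cv_folds": self.cv_folds,
            "regularization": self.regularization,
            "zero_mass": self.zero_mass,
            "cells": self.cells,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "DfCalibration":
        return cls(
            coefficients=d["coefficients"],
            cv_folds=d.get("cv_folds", 10),
            regularization=d.get("regularization", 1.0),
            zero_mass=d.get("zero_mass", 0.0),
            cells=[tuple(c) for c in d.get("cells", [])],
        )

    @classmethod
    def from_json(cls, path) -> "DfCalibration":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def default_calibration() -> DfCalibration:
    """The calibration shipped with the package (regenerable via the CLI)."""
    from importlib import resources

    ref = resources.files("sigclone").joinpath("data/df_calibration.json")
    return DfCalibration.from_dict(json.loads(ref.read_text()))


@dataclass
class ChangeReport:
    """Per-signature activity change between clonal clone and largest subclone."""

    clonal_clone: int
    largest_subclone: int
    clonal_activity: np.ndarray
    subclonal_activity: np.ndarray
    abs_difference: dict  # {signature index: A_sub - A_clonal}, |diff| > 0.05 only
    log_fold_change: dict  # {signature index: log(A_sub / A_clonal)}, floored at 1e-4


def constrained_init(params: ModelParams) -> ModelParams:
    """Tie the exposures of a fitted model (clone-weighted average) as a
    warm start for the constrained fit."""
    shared = params.xi @ params.pi
    shared = shared / shared.sum()
    return ModelParams(
        xi=params.xi,
        phi=params.phi,
        pi=np.tile(shared, (params.n_clones, 1)),
        rho=params.rho,
    )


def fit_constrained(
    sample: SampleData,
    sigs: SignatureMatrix,
    J: int,
    em_config: Optional[EmConfig] = None,
    init: Optional[ModelParams] = None,
) -> FitResult:
    """EM fit with exposures shared across the J clones."""
    return fit_fixed_j(sample, sigs, J, init=init, config=em_config, tie_pi=True)


def lrt_statistic(fit_full: FitResult, fit_constrained: FitResult) -> float:
    """2 * (loglik_full - loglik_constrained), floored at 0."""
    if fit_full.params.n_clones != fit_constrained.params.n_clones:
        raise ValueError("full and constrained fits disagree on the number of clones")
    return max(2.0 * (fit_full.loglik - fit_constrained.loglik), 0.0)


def fit_chi2_df(stats: np.ndarray, bounds=(0.01, 500.0)) -> float:
    """Maximum-likelihood chi-square df for a sample of positive statistics."""
    stats = np.asarray(stats, dtype=float)
    stats = stats[stats > _ZERO_TOL]
    if stats.size == 0:
        raise ValueError("no positive statistics to fit")

    def nll(df):
        return -chi2.logpdf(stats, df).sum()

    res = minimize_scalar(nll, bounds=bounds, method="bounded")
    return float(res.x)


def _ridge_cv_coefficients(
    X: np.ndarray, y: np.ndarray, alpha: float, folds: int
) -> dict:
    """Ridge coefficients averaged over cross-validation folds."""
    from sklearn.linear_model import Ridge
    from sklearn.model_selection import KFold

    def fit(Xt, yt):
        model = Ridge(alpha=alpha).fit(Xt, yt)
        return np.concatenate([[model.intercept_], model.coef_])

    n = X.shape[0]
    folds = min(folds, n)
    if folds < 2:
        coefs = fit(X, y)
    else:
        all_coefs = []
        for train, _ in KFold(n_splits=folds).split(X):
            all_coefs.append(fit(X[train], y[train]))
        coefs = np.mean(all_coefs, axis=0)
    return {"intercept": float(coefs[0]), "j": float(coefs[1]), "l": float(coefs[2])}


def null_statistic(
    sigs: SignatureMatrix,
    J: int,
    N: int,
    seed: int,
    depth: float = 100.0,
    em_config: Optional[EmConfig] = None,
) -> float:
    """One LRT statistic on a sample simulated under the null (shared
    exposures across clones)."""
    from .simulate import SimulationConfig, simulate_sample, _draw_pi

    rng = np.random.default_rng(seed)
    shared_row, _ = _draw_pi(1, sigs.n_signatures, rng)
    cfg = SimulationConfig(
        sigs=sigs, J=J, N=N, pi=np.tile(shared_row, (J, 1)), depth=depth,
        seed=int(rng.integers(2**31 - 1)),
    )
    sample, _ = simulate_sample(cfg)
    em = em_config or EmConfig(max_iter=150, tol=1e-5, n_restarts=3)
    fit_full = fit_fixed_j(sample, sigs, J, config=em)
    fit_con = fit_constrained(
        sample, sigs, J, em_config=em, init=constrained_init(fit_full.params)
    )
    return lrt_statistic(fit_full, fit_con)


def calibrate_df(
    grid: Sequence[tuple[int, int]],
    n_null_sims: int = 100,
    seed: int = 0,
    N: int = 300,
    depth: float = 100.0,
    em_config: Optional[EmConfig] = None,
    cv_folds: int = 10,
    regularization: float = 1.0,
) -> DfCalibration:
    """Calibrate the chi-square df on simulated null data over a (J, L) grid.

    Per cell, ``n_null_sims`` null samples are simulated with a fresh random
    signature matrix each, the LRT statistic is computed, and the chi-square
    df is fitted by maximum likelihood (zeros excluded, recorded as a
    zero-inflation mass).  A ridge regression of fitted df on (J, L), with
    coefficients averaged over cross-validation folds, gives the final
    predictor.
    """
    from .simulate import random_signature_matrix

    rng = np.random.default_rng(seed)
    cells = []
    zero_fractions = []
    for J, L in grid:
        stats = []
        for _ in range(n_null_sims):
            sigs = random_signature_matrix(L, int(rng.integers(2**31 - 1)))
            stats.append(
                null_statistic(
                    sigs, J, N, int(rng.integers(2**31 - 1)), depth, em_config
                )
            )
        stats = np.asarray(stats)
        positive = stats[stats > _ZERO_TOL]
        if positive.size == 0:
            warnings.warn(f"all null statistics zero in cell (J={J}, L={L}); dropped")
            continue
        zero_fractions.append(1.0 - positive.size / stats.size)
        cells.append((J, L, fit_chi2_df(stats), int(positive.size)))
    if not cells:
        raise RuntimeError("every calibration cell was degenerate")
    X = np.array([[c[0], c[1]] for c in cells], dtype=float)
    y = np.array([c[2] for c in cells])
    coefs = _ridge_cv_coefficients(X, y, regularization, cv_folds)
    return DfCalibration(
        coefficients=coefs,
        cv_folds=cv_folds,
        regularization=regularization,
        zero_mass=float(np.mean(zero_fractions)),
        cells=cells,
    )


def p_value_from_statistic(
    stat: float, J: int, L: int, calibration: DfCalibration
) -> float:
    """Upper-tail p-value of the LRT statistic under the calibrated
    zero-inflated chi-square null."""
    if stat <= _ZERO_TOL:
        return 1.0
    df = calibration.predict_df(J, L)
    p = float((1.0 - calibration.zero_mass) * chi2.sf(stat, df))
    return min(max(p, 0.0), 1.0)


def test_change(
    sample: SampleData,
    sigs: SignatureMatrix,
    fit_full: FitResult,
    calibration: Optional[DfCalibration] = None,
    alpha: float = 0.05,
    em_config: Optional[EmConfig] = None,
) -> LrtResult:
    """Test whether signature activity differs between clones.

    Fits the constrained model at the same J (warm-started from the full
    fit with tied exposures) and compares the statistic to the calibrated
    chi-square; the zero-inflation mass scales the continuous tail.
    """
    calibration = calibration or default_calibration()
    J, L = fit_full.params.n_clones, sigs.n_signatures
    df = calibration.predict_df(J, L)
    if J == 1:
        return LrtResult(statistic=0.0, df_used=df, p_value=1.0, significant=False)
    fit_con = fit_constrained(
        sample, sigs, J, em_config=em_config, init=constrained_init(fit_full.params)
    )
    stat = lrt_statistic(fit_full, fit_con)
    p = p_value_from_statistic(stat, J, L, calibration)
    return LrtResult(statistic=stat, df_used=df, p_value=p, significant=p < alpha)


def quantify_changes(
    fit_full: FitResult,
    resp: Optional[Responsibilities] = None,
    abs_threshold: float = 0.05,
    log_floor: float = 1e-4,
) -> Optional[ChangeReport]:
    """Per-signature activity change between clonal clone and largest subclone.

    The clonal clone has the highest CCF; the largest subclone has the
    largest expected SNV count among the others (posterior counts when
    responsibilities are given, clone weights otherwise).  Absolute
    differences are reported only above ``abs_threshold``; log-fold changes
    floor activities at ``log_floor`` and drop pairs where both sides are
    below it.  Returns None for a single-clone fit.
    """
    params = fit_full.params
    J = params.n_clones
    if J < 2:
        return None
    clonal = int(np.argmax(params.phi))
    if resp is not None:
        counts = resp.clone_marginal.sum(axis=0)
    else:
        counts = params.xi
    counts = counts.copy()
    counts[clonal] = -np.inf
    sub = int(np.argmax(counts))

    a_clonal = params.pi[clonal]
    a_sub = params.pi[sub]
    abs_diff = {}
    log_fold = {}
    for l in range(params.n_signatures):
        diff = a_sub[l] - a_clonal[l]
        if abs(diff) > abs_threshold:
            abs_diff[l] = float(diff)
        if a_sub[l] < log_floor and a_clonal[l] < log_floor:
            continue
        log_fold[l] = float(
            np.log(max(a_sub[l], log_floor) / max(a_clonal[l], log_floor))
        )
    return ChangeReport(
        clonal_clone=clonal,
        largest_subclone=sub,
        clonal_activity=a_clonal.copy(),
        subclonal_activity=a_sub.copy(),
        abs_difference=abs_diff,
        log_fold_change=log_fold,
    )
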