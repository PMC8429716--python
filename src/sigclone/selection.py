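"""Choice of the number of clones.

Models with J = 1 .. j_max clones are fitted incrementally: each fit warm-
starts from the previous one by splitting the clone contributing most to
the mixture entropy.  The number of clones is chosen by a BIC-shaped
penalized-likelihood criterion

    criterion(J) = loglik - penalty_scale * k(J, L) * log(N) / 2

where k counts the free parameters ((J-1) clone weights, J CCFs, J*(L-1)
exposures, and rho).  The loop stops early once the criterion has strictly
decreased for two successive values of J.  ``penalty_scale`` can adapt to
the sample size via a calibration table fitted on simulated data (see
:func:`calibrate_penalty`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import SampleData, SignatureMatrix
from .em import EmConfig, FitResult, fit_fixed_j, split_init


@dataclass
class SelectionConfig:
    """Settings of the clone-number search."""

    j_max: int = 8
    penalty_scale: float = 1.0
    adaptive_table: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.j_max < 1:
            raise ValueError("j_max must be >= 1")
        if self.penalty_scale <= 0:
            raise ValueError("penalty_scale must be > 0")

    def effective_penalty_scale(self, N: int, L: int) -> float:
        """Penalty scale for a sample of N SNVs and L signatures.

        With an adaptive table (mapping N-bucket upper bounds to scales,
        keyed by L) the bucket covering N wins; otherwise ``penalty_scale``.
        """
        if not self.adaptive_table:
            return self.penalty_scale
        by_l = self.adaptive_table.get(str(L)) or self.adaptive_table.get("any")
        if not by_l:
            return self.penalty_scale
        bounds = sorted((int(k), v) for k, v in by_l.items())
        for upper, scale in bounds:
            if N <= upper:
                return float(scale)
        return float(bounds[-1][1])

    @classmethod
    def with_table_from_json(cls, path, **kwargs) -> "SelectionConfig":
        with open(path) as fh:
            return cls(adaptive_table=json.load(fh), **kwargs)


def default_selection_config(**kwargs) -> SelectionConfig:
    """Selection config with the adaptive penalty table shipped with the
    package (regenerable via ``sigclone calibrate --what penalty``)."""
    from importlib import resources

    ref = resources.files("sigclone").joinpath("data/penalty_table.json")
    table = json.loads(ref.read_text()) if ref.is_file() else None
    return SelectionConfig(adaptive_table=table, **kwargs)


def free_parameter_count(J: int, L: int) -> int:
    """Free parameters of a J-clone, L-signature model:
    (J-1) + J + J*(L-1) + 1."""
    if J < 1 or L < 1:
        raise ValueError("J and L must be >= 1")
    return (J - 1) + J + J * (L - 1) + 1


def selection_criterion(
    fit: FitResult, N: int, L: int, config: Optional[SelectionConfig] = None
) -> float:
    """Penalized log-likelihood; higher is better.  With penalty_scale = 1
    this equals -BIC/2."""
    config = config or SelectionConfig()
    J = fit.params.n_clones
    scale = config.effective_penalty_scale(N, L)
    return fit.loglik - scale * free_parameter_count(J, L) * np.log(N) / 2.0


def fit_model(
    sample: SampleData,
    sigs: SignatureMatrix,
    em_config: Optional[EmConfig] = None,
    sel_config: Optional[SelectionConfig] = None,
) -> FitResult:
    """Full fit: incremental EM over J = 1..j_max with the two-strikes
    stopping rule; returns the fit maximizing the selection criterion."""
    em_config = em_config or EmConfig()
    sel_config = sel_config or SelectionConfig()
    N, L = len(sample), sigs.n_signatures

    fits: list[FitResult] = []
    fit = fit_fixed_j(sample, sigs, 1, init=None, config=em_config)
    fit.criterion = selection_criterion(fit, N, L, sel_config)
    fits.append(fit)
    n_decreases = 0
    for J in range(2, sel_config.j_max + 1):
        init = split_init(fits[-1].params)
        fit = fit_fixed_j(sample, sigs, J, init=init, config=em_config)
        fit.criterion = selection_criterion(fit, N, L, sel_config)
        if fit.criterion < fits[-1].criterion:
            n_decreases += 1
        else:
            n_decreases = 0
        fits.append(fit)
        if n_decreases >= 2:
            break
    return max(fits, key=lambda f: f.criterion)


def calibrate_penalty(
    sigs: SignatureMatrix,
    n_values=(100, 300, 1000),
    j_values=(1, 2, 3),
    scales=(0.5, 1.0, 2.0, 4.0),
    n_reps: int = 5,
    seed: int = 0,
    em_config: Optional[EmConfig] = None,
    depth: float = 100.0,
) -> dict:
    """Grid-search the penalty scale on simulated samples.

    For each sample-size bucket, simulates samples across clone numbers,
    fits the full model once per candidate scale, and keeps the scale
    maximizing the mean clone-number score (score1b).  Returns an adaptive
    table ``{str(L): {str(N): scale}}`` usable by :class:`SelectionConfig`.
    """
    from .metrics import score1b
    from .simulate import SimulationConfig, simulate_sample

    rng = np.random.default_rng(seed)
    em_config = em_config or EmConfig(max_iter=200, tol=1e-5, n_restarts=3)
    L = sigs.n_signatures
    table: dict[str, dict] = {str(L): {}}
    for N in n_values:
        cases = []
        for J in j_values:
            for _ in range(n_reps):
                cfg = SimulationConfig(
                    sigs=sigs, J=J, N=N, depth=depth,
                    seed=int(rng.integers(2**31 - 1)),
                )
                sample, truth = simulate_sample(cfg)
                cases.append((sample, truth.n_clones))
        best_scale, best_score = None, -np.inf
        for scale in scales:
            sel = SelectionConfig(penalty_scale=scale)
            scores = [
                score1b(j_true, fit_model(s, sigs, em_config, sel).params.n_clones)
                for s, j_true in cases
            ]
            mean = float(np.mean(scores))
            better = mean > best_score + 1e-12
            # ties resolve toward plain BIC (scale closest to 1)
            tied = abs(mean - best_score) <= 1e-12 and abs(
                np.log(scale)
            ) < abs(np.log(best_scale))
            if better or tied:
                best_scale, best_score = scale, mean
        table[str(L)][str(N)] = best_scale
    return table
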