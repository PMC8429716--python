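# Methods

## Model

`sigclone` models the somatic SNVs of one bulk tumor sample as i.i.d. draws
from a mixture over `J` clones. For SNV `n` we observe the variant and
total read counts `(B_n, D_n)`, the trinucleotide mutation type
`T_n ∈ {1..96}` (pyrimidine-centric COSMIC SBS96 layout), and the clonal
allele-specific copy-number state `(C_normal, C_major, C_minor)`; the tumor
purity `p` is a known sample-level scalar. Latent variables are the clone
`U_n`, the signature `S_n` and the multiplicity `M_n`:

```
U ~ Cat(ξ)                      ξ ∈ Σ_J          clone weights
S | U ~ Cat(π_U)                π ∈ (Σ_L)^J      per-clone signature exposures
T | S ~ Cat(μ_S)                μ ∈ (Σ_96)^L     known signature matrix
M | C ~ Uniform{1..C_major}
B | D, U, C, M ~ BetaBinomial(D, ρ·φ_U·η, ρ·(1 − φ_U·η))
      with η(M, C) = p·M / (p·C_tumor + (1 − p)·C_normal)
```

`φ ∈ (0,1]^J` are the clone cancer-cell fractions (CCFs) and `ρ > 0` is a
precision: the beta-binomial mean equals the expected VAF `φ_U·η` and its
variance shrinks as `ρ` grows. The beta-binomial's two final arguments are
read as the shape parameters `α, β`; this is the only reading under which
the mean equals the expected VAF. `φ·η` is clamped into
`[1e-10, 1 − 1e-10]` before forming `α, β` so that fully clonal mutations
on loss-of-heterozygosity segments in a pure sample do not produce
`log 0`. All likelihood computation is carried out in the log domain with
log-sum-exp and log-gamma evaluations of the beta-binomial pmf.

Multiplicity is bounded by `C_major` (a mutation is assumed to sit on one
allele only), and loci with `C_major = 0` are rejected at validation: an
observed SNV cannot sit on zero copies.

## Fitting

Parameters `θ = (ξ, φ, π, ρ)` are estimated by maximum likelihood with EM.
The E-step is exact: the joint posterior over `(U, S, M)` per SNV is a
table of at most `J × L × C_major` entries. The M-step is a generalized
M-step:

* `ξ` and `π` have closed-form updates (responsibility sums, normalized);
* each `φ_j` is maximized by bounded derivative-free scalar search
  (Brent-style) on `(10⁻³, 1]`, holding the rest fixed, then `ρ` on
  `[10, 500]`. Each coordinate update is accepted only if the expected
  complete-data log-likelihood does not decrease, so the marginal
  log-likelihood trajectory is monotone (up to the scalar-optimizer
  tolerance, in practice < 1e-6).

Convergence is declared when the relative log-likelihood change falls
below `tol` (default 1e-6) or after `max_iter` (default 1000) iterations.
`J = 1` fits use `n_restarts` (default 5) random initializations drawn
from the same priors as the simulator; `J + 1` clones are initialized from
the `J`-clone optimum by splitting the clone with the largest contribution
`−ξ_j log ξ_j` to the mixture entropy, halving its weight and perturbing
its CCF by `±0.05` (half the simulator's minimal clone spacing — large
enough to break symmetry, small enough to stay in the parent basin).

The scalar-coordinate M-step is a design choice: it needs no analytic
gradient, guarantees monotonicity, and converged indistinguishably from a
joint `(φ, ρ)` update in exploratory runs; the exact update used by other
implementations of this model family may differ in convergence path.

## Choosing the number of clones

Models with `J = 1..j_max` (default 8) are fitted incrementally; the loop
stops early when a BIC-shaped criterion

```
criterion(J) = loglik − penalty_scale · k(J, L) · log(N) / 2,
k(J, L) = (J − 1) + J + J(L − 1) + 1
```

strictly decreases for two successive `J` (equal values do not count).
The fit with maximal criterion wins. `penalty_scale = 1` is exactly
`−BIC/2`; a calibration routine (`selection.calibrate_penalty`) grid-searches
the scale on simulated samples across sample-size buckets to maximize the
clone-number score and stores the result as a JSON table keyed by
`(L, N bucket)`; ties resolve toward plain BIC. The shipped table was
generated at sample sizes N ∈ {100, 300, 1000} with 1–3 clones over
scales {0.5, 1, 2}: it selects a softer penalty (0.5) below ~300 SNVs and
plain BIC at 1000 — echoing the observation motivating an adaptive
criterion, that a fixed penalty over-penalizes small samples. The
library default without a table is plain BIC (scale 1).

## Signature-change test

The null model ties exposures across clones (`π_{jl} = π_l`), fitted with
the same EM machinery (shared-`π` update, warm-started from the full fit
with its clone-weighted average exposures). The statistic is
`Λ = 2(loglik_full − loglik_constrained)`, floored at 0. Because the
models are estimated approximately and the asymptotic regime is out of
reach at realistic `N`, the chi-square degrees of freedom are calibrated
on simulated null data: per `(J, L)` grid cell the df is fitted by maximum
likelihood to the simulated statistics (exactly-zero statistics excluded
and recorded as a zero-inflation mass), and a ridge regression predicts df
from `(J, L)`, coefficients averaged over cross-validation folds. The
p-value is `(1 − zero_mass) · χ²_df.sf(Λ)`, and 1 when `Λ = 0`. The
signature-matrix covariate is the signature count `L`; the numerical rank
of `μ` can be substituted by the caller for near-collinear catalogues.
The shipped calibration used 100 null simulations per cell on the grid
`J ∈ {2,3,4} × L ∈ {5,10}` at `N = 300`, depth 100, ridge strength 1.0,
10 folds. No multiple-testing correction is applied inside the package.

Per-signature changes are quantified between the *clonal clone* (highest
CCF) and the *largest subclone* (largest expected SNV count among the
rest): absolute differences `A_sub − A_clonal` are reported only above
0.05 to avoid noisy reports, and log-fold changes floor both activities at
1e-4, dropping pairs where both sides are below the floor.

## Simulator

`simulate_sample` draws from the generative model above. Priors, used both
for simulation and for EM random restarts:

* active signatures: `min(Poisson(7) + 1, L)` chosen uniformly without
  replacement; per-clone exposures Dirichlet(1) over the active set;
* CCFs: largest clone at 1; each next drawn uniformly above 0.1 and at
  least 0.05 below the previous (whole vector redrawn if a draw leaves no
  room);
* clone proportions Dirichlet(1), redrawn until the minimum exceeds 0.05;
* `ρ ~ Normal(60, sd √5)`, floored at 1; purity
  `min(Normal(0.7, sd √0.1), 0.99)`, redrawn while ≤ 0.05. The "variance"
  figures for these two are read literally as variances (sd = √variance);
  `moments_as_sd=True` switches to using them as standard deviations.

Copy number: a configurable fraction of loci (default 0.5) is diploid
(2, 1, 1). The rest draw a total copy number either from a right-skewed
discrete law centered at 2 — P(1..6) = 0.15, 0.40, 0.25, 0.12, 0.05, 0.03,
an explicit stand-in for a distribution only described verbally — or from
`round(lognormal(1, 0.3))` floored at 1; the minor allele is
`round(Beta(5,3) · total)` clipped so minor ≤ major. Depth is
`Poisson(mean depth)` floored at 1 (the minimal standard choice; the depth
law is configurable). Defaults: depth 100 (typical exome coverage),
diploid fraction 0.5 (mid-range of commonly simulated genome states).

`two_clone_grid` produces equal-weight two-clone configurations with the
CCF gap pinned and exposure pairs selected by importance resampling from a
pool of 10,000 prior draws so that the cosine distance between the two
clone profiles follows a uniform target (separating-power grids) or a
Beta(1.5, 8) target concentrating on small distances (sensitivity grids).

What the simulator does **not** emulate: subclonal copy-number events,
sequencing error beyond the beta-binomial, mapping artefacts, variant-caller
false positives and germline leakage, and regional context composition
(mutation types are drawn from the signature mixture alone). Tests passing
on simulated data therefore demonstrate correctness of the inference under
the model's own assumptions, not robustness to real-data violations of
them.

## Evaluation metrics

* `score1b = (J_true + 1 − min(J_true + 1, |J_pred − J_true|)) / (J_true + 1)`.
* `score1c = 1 − W₁` between the clone-weighted CCF point-mass
  distributions (scipy's `wasserstein_distance`).
* `score2a`: mean of Pearson correlation between vectorized binary
  co-clustering matrices, Matthews correlation, and V-measure; each
  rescaled by `s ↦ max(0, (s − s_bad)/(1 − s_bad))` where `s_bad` is the
  better of the two degenerate baselines (everything in one cluster; all
  singletons). This affine map is the only one anchoring the baselines at
  0 and perfection at 1; negatives are clipped to 0. A constant
  co-clustering vector has undefined Pearson correlation, anchored at 0.
  The `N × N` matrices bound applicability at 20,000 SNVs.
* `score2c`: accuracy/AUC/sensitivity/specificity of clonal-vs-subclonal
  classification, "clonal" meaning membership in the maximal-CCF clone on
  each side; AUC uses the posterior clonal-membership probability when
  available.
* `score_sig_1a/1b`: Euclidean distances between 96-type profiles
  (empirical-vs-estimated and true-vs-estimated); sample-level activity is
  the clone-weight average `ξᵀπ`.
* `score_sig_1c`: presence AUC; a signature is called present when it is
  needed to reach cumulative activity 0.95 in decreasing order.
* `score_sig_1d`: fraction of SNVs whose MAP signature matches the truth.
* `score_sig_1e`: summary (median, min, max, sd, fractions below
  0.05/0.1) of per-SNV cosine distances between true and reconstructed
  clone profiles. Cosine distance is `1 − cosine similarity` throughout.

## Numerical choices and degenerate inputs

* MAP assignment ties break to the lowest flat `(clone, signature,
  multiplicity)` index, for determinism.
* Empty clones in the M-step keep their previous exposure row; a clone
  weight of exactly zero contributes `−inf` log-weight and drops out of
  the log-sum-exp harmlessly.
* Samples of identical SNVs converge without error (the extra clones
  collapse onto one CCF).
* All randomness flows through `numpy.random.default_rng` seeds; identical
  inputs and seeds give bitwise-identical fits.

## Problem sizes used in the test suite

The statistical tests use 50 fits for monotonicity and recovery
(N = 1000, depth 100), 200 null and 100 alternative simulations for the
test calibration (N = 300 and 1000), 100 random instances for the
enumeration oracle, and 10,000 draws for the prior-constraint battery —
sizes at which the checked quantities are stable while the whole suite
stays interactive.

## Known limitations

* Only clonal copy number; subclonal CNA segments must be collapsed
  (largest-CCF event) before input.
* The selection criterion's adaptivity is calibrated on this package's own
  simulator; heavily non-model data may warrant re-calibration
  (`sigclone calibrate`).
* The change test is calibrated over `J ∈ [2, 4]`, `L ∈ [5, 10]`; the
  linear df model extrapolates outside that grid.
* Signature activities are estimated conditional on a user-supplied
  catalogue; near-collinear catalogues make per-signature activities (not
  the reconstructed profiles) unstable.
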