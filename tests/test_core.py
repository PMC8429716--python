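"""Core model: eta/VAF algebra, likelihood oracle equivalence, posteriors."""

import numpy as np
import pytest
from scipy.special import gammaln

from sigclone import (
    ModelParams,
    MutationTypeSpace,
    SampleData,
    SignatureMatrix,
    SnvObservation,
    corrected_ccf,
    eta,
    expected_vaf,
    map_assignments,
    marginal_loglik,
    posterior_responsibilities,
    snv_loglik_components,
)
from sigclone.core import Responsibilities, brute_force_posterior

from conftest import random_small_instance

DIPLOID = dict(C_major=1, C_minor=1, C_normal=2)


class TestMutationTypeSpace:
    def test_96_distinct_labels_in_cosmic_order(self):
        space = MutationTypeSpace()
        assert len(space.labels) == 96
        assert len(set(space.labels)) == 96
        assert space.labels[0] == "A[C>A]A"
        assert space.index_of["A[C>A]C"] == 1
        assert space.index_of["C[C>A]A"] == 4
        assert space.index_of["A[C>G]A"] == 16
        assert space.index_of["T[T>G]T"] == 95

    def test_purine_context_reverse_complemented(self):
        space = MutationTypeSpace()
        # G>T on the minus strand reads C>A with swapped, complemented flanks
        assert space.index_from_context("G", "T", "T", "T") == space.index_of["A[C>A]A"]
        assert space.index_from_context("C", "A", "A", "A") == space.index_of["A[C>A]A"]


class TestEtaAndVaf:
    @pytest.mark.parametrize(
        "m, kwargs, p, expected",
        [
            (1, DIPLOID, 1.0, 0.5),
            (1, DIPLOID, 0.5, 0.25),
            (2, dict(C_major=2, C_minor=1, C_normal=2), 0.6, 1.2 / 2.6),
        ],
    )
    def test_eta_formula(self, m, kwargs, p, expected):
        snv = SnvObservation(B=5, D=10, T=0, **kwargs)
        assert eta(m, snv, p) == pytest.approx(expected)

    def test_eta_rejects_out_of_range_multiplicity(self):
        snv = SnvObservation(B=5, D=10, T=0, **DIPLOID)
        with pytest.raises(ValueError):
            eta(2, snv, 0.9)
        with pytest.raises(ValueError):
            eta(0, snv, 0.9)

    @pytest.mark.parametrize(
        "p, ccf, expected",
        [(1.0, 1.0, 0.5), (0.7, 0.5, 0.175), (0.9, 0.0, 0.0)],
    )
    def test_expected_vaf_diploid(self, p, ccf, expected):
        snv = SnvObservation(B=5, D=10, T=0, **DIPLOID)
        assert expected_vaf(p, ccf, 1, snv) == pytest.approx(expected)

    def test_corrected_ccf_inverts_expected_vaf(self):
        snv = SnvObservation(B=35, D=100, T=0, **DIPLOID)
        assert corrected_ccf(snv, p=0.7, m=1) == pytest.approx(1.0)
        assert corrected_ccf(SnvObservation(B=0, D=50, T=0, **DIPLOID), 0.7, 1) == 0.0
        snv2 = SnvObservation(B=30, D=100, T=0, **DIPLOID)
        assert corrected_ccf(snv2, p=1.0, m=1) == pytest.approx(2 * 0.3)
        # noisy observations may exceed 1 unless clipped
        snv3 = SnvObservation(B=60, D=100, T=0, **DIPLOID)
        assert corrected_ccf(snv3, p=1.0, m=1) == pytest.approx(1.2)
        assert corrected_ccf(snv3, p=1.0, m=1, clip=True) == 1.0


class TestLoglikComponents:
    def test_single_component_reduces_to_betabinomial(self):
        # one clone, one signature, mu peaked at the observed type, C_major=1:
        # the only entry is the beta-binomial log pmf itself
        mu = np.full((1, 96), 1e-12)
        mu[0, 7] = 1.0
        mu /= mu.sum(axis=1, keepdims=True)
        sigs = SignatureMatrix(names=("S",), mu=mu)
        params = ModelParams(xi=[1.0], phi=[1.0], pi=[[1.0]], rho=100.0)
        snv = SnvObservation(B=5, D=10, T=7, **DIPLOID)
        table = snv_loglik_components(snv, params, sigs, p=1.0)
        assert table.shape == (1, 1, 1)
        # independent evaluation through log-gamma identities:
        # BetaBinomial(5; 10, 50, 50)
        a, b = 50.0, 50.0
        expected = (
            gammaln(11) - gammaln(6) - gammaln(6)
            + gammaln(5 + a) + gammaln(5 + b) - gammaln(10 + a + b)
            - gammaln(a) - gammaln(b) + gammaln(a + b)
        )
        # frozen from an independent evaluation (scipy.stats.betabinom
        # agrees to 1e-13)
        assert expected == pytest.approx(-1.4499250703574, abs=1e-9)
        assert table[0, 0, 0] == pytest.approx(expected + np.log(mu[0, 7]), abs=1e-9)

    def test_identical_clones_differ_only_by_log_weight(self):
        rng = np.random.default_rng(0)
        mu = rng.dirichlet(np.ones(96), size=3)
        sigs = SignatureMatrix(names=("a", "b", "c"), mu=mu)
        pi = rng.dirichlet(np.ones(3), size=1)
        params = ModelParams(
            xi=[0.7, 0.3], phi=[0.6, 0.6], pi=np.vstack([pi, pi]), rho=80.0
        )
        snv = SnvObservation(B=12, D=40, T=30, C_major=2, C_minor=1)
        table = snv_loglik_components(snv, params, sigs, p=0.8)
        np.testing.assert_allclose(
            table[0] - table[1], np.log(0.7) - np.log(0.3), atol=1e-10
        )


class TestMarginalLoglik:
    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(123)
        for _ in range(10):
            sample, params, sigs = random_small_instance(rng)
            ll = marginal_loglik(sample, params, sigs)
            ll_brute, _ = brute_force_posterior(sample, params, sigs)
            assert ll == pytest.approx(ll_brute, abs=1e-9)

    def test_duplicating_snvs_doubles_loglik(self):
        rng = np.random.default_rng(5)
        sample, params, sigs = random_small_instance(rng)
        doubled = SampleData(sample.snvs + sample.snvs, sample.purity)
        assert marginal_loglik(doubled, params, sigs) == pytest.approx(
            2 * marginal_loglik(sample, params, sigs), rel=1e-12
        )

    def test_invariant_under_clone_permutation(self):
        rng = np.random.default_rng(6)
        sample, params, sigs = random_small_instance(rng)
        if params.n_clones == 1:
            sample, params, sigs = random_small_instance(np.random.default_rng(8))
        perm = np.random.default_rng(1).permutation(params.n_clones)
        permuted = ModelParams(
            xi=params.xi[perm], phi=params.phi[perm], pi=params.pi[perm],
            rho=params.rho,
        )
        assert marginal_loglik(sample, permuted, sigs) == pytest.approx(
            marginal_loglik(sample, params, sigs), rel=1e-12
        )

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            SampleData([], purity=0.8)


class TestPosteriors:
    def test_rows_normalize_and_match_brute_force(self):
        rng = np.random.default_rng(77)
        sample, params, sigs = random_small_instance(rng)
        resp = posterior_responsibilities(sample, params, sigs)
        sums = resp.gamma.reshape(len(sample), -1).sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-8)
        _, gamma_brute = brute_force_posterior(sample, params, sigs)
        np.testing.assert_allclose(resp.gamma, gamma_brute, atol=1e-9)

    def test_symmetric_clones_split_posterior_equally(self):
        mu = np.random.default_rng(3).dirichlet(np.ones(96), size=2)
        sigs = SignatureMatrix(names=("a", "b"), mu=mu)
        pi = np.array([[0.5, 0.5], [0.5, 0.5]])
        params = ModelParams(xi=[0.5, 0.5], phi=[0.7, 0.7], pi=pi, rho=60.0)
        sample = SampleData(
            [SnvObservation(B=10, D=30, T=4, **DIPLOID) for _ in range(5)], 0.9
        )
        resp = posterior_responsibilities(sample, params, sigs)
        np.testing.assert_allclose(resp.clone_marginal, 0.5, atol=1e-10)

    def test_single_copy_forces_multiplicity_one(self):
        mu = np.random.default_rng(4).dirichlet(np.ones(96), size=2)
        sigs = SignatureMatrix(names=("a", "b"), mu=mu)
        params = ModelParams(
            xi=[0.4, 0.6], phi=[1.0, 0.5], pi=np.full((2, 2), 0.5), rho=60.0
        )
        sample = SampleData([SnvObservation(B=10, D=30, T=4, **DIPLOID)], 0.9)
        resp = posterior_responsibilities(sample, params, sigs)
        np.testing.assert_allclose(resp.multiplicity_marginal[:, 0], 1.0, atol=1e-12)


class TestMapAssignments:
    def test_point_mass_recovered(self):
        gamma = np.zeros((1, 2, 3, 2))
        gamma[0, 1, 2, 1] = 1.0
        assert map_assignments(Responsibilities(gamma))[0].tolist() == [1, 2, 2]

    def test_ties_break_to_lowest_index(self):
        gamma = np.full((1, 2, 2, 1), 0.25)
        assert map_assignments(Responsibilities(gamma))[0].tolist() == [0, 0, 1]

    def test_agrees_with_exhaustive_argmax(self):
        rng = np.random.default_rng(9)
        g = rng.random((20, 3, 4, 2))
        g /= g.reshape(20, -1).sum(axis=1)[:, None, None, None]
        result = map_assignments(Responsibilities(g))
        for n in range(20):
            best, best_val = None, -1
            for j in range(3):
                for l in range(4):
                    for m in range(2):
                        if g[n, j, l, m] > best_val:
                            best, best_val = (j, l, m + 1), g[n, j, l, m]
            assert tuple(result[n]) == best


def test_simulated_vaf_mean_matches_expectation():
    """Mean of simulated B/D at fixed (phi, m, C, p) approaches expected VAF."""
    rng = np.random.default_rng(11)
    phi_val, rho, p, depth = 0.6, 60.0, 0.8, 100
    snv = SnvObservation(B=0, D=depth, T=0, **DIPLOID)
    mean_vaf = expected_vaf(p, phi_val, 1, snv)
    n = 20_000
    D = np.full(n, depth)
    theta = rng.beta(rho * mean_vaf, rho * (1 - mean_vaf), size=n)
    B = rng.binomial(D, theta)
    vaf = B / D
    se = vaf.std() / np.sqrt(n)
    assert abs(vaf.mean() - mean_vaf) < 3 * se
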