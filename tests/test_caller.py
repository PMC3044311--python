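import itertools

import numpy as np
import pytest

import ldcall as lc
from conftest import random_models
from ldcall.caller import (
    apply_no_call_threshold,
    backward_pass,
    brute_force_marginals,
    forward_backward,
    forward_pass,
    genotype_marginals,
    loglik_backward,
    model_genotype_prior,
    posterior_decode,
    site_emission,
)
from ldcall.evidence import NO_CALL, GenotypeLikelihoods, single_snp_call
from ldcall.training import _init_model


def _uniform_L(n):
    return GenotypeLikelihoods(np.ones((n, 3)))


class TestSiteEmission:
    def test_no_reads_gives_unit_table(self):
        models = random_models(np.random.default_rng(0), 4, 3, 2)
        phi, split = site_emission(models, 2, [1.0, 1.0, 1.0])
        np.testing.assert_allclose(phi, 1.0)
        np.testing.assert_allclose(split.sum(axis=2), 1.0)

    def test_k1_hand_product(self):
        p, q = 0.3, 0.8
        def one_state(pr):
            return lc.HaplotypeHMM(
                initial=[1.0],
                transitions=np.empty((0, 1, 1)),
                emissions=np.array([[[1 - pr, pr]]]),
            )
        models = lc.ParentalModels(one_state(p), one_state(q))
        phi, _ = site_emission(models, 0, [1.0, 0.0, 0.0])
        assert phi[0, 0] == pytest.approx((1 - p) * (1 - q))

    def test_symmetric_models_symmetric_table(self):
        rng = np.random.default_rng(1)
        hmm = _init_model(3, 3, rng)
        models = lc.ParentalModels.from_single(hmm)
        phi, _ = site_emission(models, 1, rng.random(3))
        np.testing.assert_allclose(phi, phi.T)


class TestForwardBackward:
    def test_single_locus_base_case(self):
        rng = np.random.default_rng(2)
        models = random_models(rng, 1, 3, 2)
        L = GenotypeLikelihoods(rng.random((1, 3)))
        alpha, pre, scale, ll = forward_pass(models, L)
        phi, _ = site_emission(models, 0, L.values[0])
        expected = np.outer(
            models.maternal.initial, models.paternal.initial
        ) * phi
        np.testing.assert_allclose(alpha[0] * scale[0], expected, rtol=1e-12)
        beta = backward_pass(models, L, scale)
        np.testing.assert_allclose(beta[0], 1.0)

    def test_total_likelihood_matches_enumeration(self):
        """exp(total loglik) equals the sum over all 4^n haplotype pairs."""
        rng = np.random.default_rng(7)
        models = random_models(rng, 5, 3, 3)
        L = GenotypeLikelihoods(rng.random((5, 3)))
        _, _, _, ll = forward_pass(models, L)

        haps = list(itertools.product((0, 1), repeat=5))
        def hap_prob(hmm, h):
            a = hmm.initial * hmm.emissions[0][:, h[0]]
            for i in range(1, 5):
                a = (a @ hmm.transitions[i - 1]) * hmm.emissions[i][:, h[i]]
            return a.sum()
        total = sum(
            hap_prob(models.maternal, h)
            * hap_prob(models.paternal, hp)
            * np.prod([L.values[i, h[i] + hp[i]] for i in range(5)])
            for h in haps
            for hp in haps
        )
        assert np.exp(ll) == pytest.approx(total, rel=1e-10)

    def test_optimised_matches_naive_recurrence(self):
        rng = np.random.default_rng(20)
        models = random_models(rng, 20, 5, 5)
        L = GenotypeLikelihoods(rng.random((20, 3)))
        a_f, p_f, s_f, ll_f = forward_pass(models, L, naive=False)
        a_n, p_n, s_n, ll_n = forward_pass(models, L, naive=True)
        np.testing.assert_allclose(a_f, a_n, rtol=1e-12)
        np.testing.assert_allclose(s_f, s_n, rtol=1e-12)
        b_f = backward_pass(models, L, s_f, naive=False)
        b_n = backward_pass(models, L, s_f, naive=True)
        np.testing.assert_allclose(b_f, b_n, rtol=1e-12)

    def test_alpha_beta_product_locus_independent(self):
        rng = np.random.default_rng(3)
        models = random_models(rng, 12, 4, 3)
        L = GenotypeLikelihoods(rng.random((12, 3)))
        t = forward_backward(models, L)
        prods = (t.alpha * t.beta).sum(axis=(1, 2))
        np.testing.assert_allclose(prods, 1.0, atol=1e-9)

    def test_loglik_same_from_either_direction(self):
        rng = np.random.default_rng(4)
        models = random_models(rng, 15, 3, 2)
        L = GenotypeLikelihoods(rng.random((15, 3)))
        _, _, _, ll_f = forward_pass(models, L)
        assert loglik_backward(models, L) == pytest.approx(ll_f, abs=1e-9)

    def test_impossible_reads_raise(self):
        hmm = lc.HaplotypeHMM(
            initial=[1.0],
            transitions=np.empty((0, 1, 1)),
            emissions=np.array([[[1.0, 0.0]]]),  # only allele 0 possible
        )
        models = lc.ParentalModels.from_single(hmm)
        L = GenotypeLikelihoods(np.array([[0.0, 0.0, 1.0]]))  # demands g=2
        with pytest.raises(ValueError, match="pseudocount"):
            forward_pass(models, L)


class TestGenotypeMarginals:
    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(25):
            n = int(rng.integers(1, 7))
            models = random_models(
                rng, n, int(rng.integers(1, 4)), int(rng.integers(1, 4))
            )
            L = GenotypeLikelihoods(rng.random((n, 3)))
            fast = genotype_marginals(models, L)
            slow = brute_force_marginals(models, L)
            worst = max(worst, float(np.abs(fast - slow).max()))
        assert worst < 1e-9

    def test_no_reads_posterior_equals_model_prior(self):
        rng = np.random.default_rng(5)
        models = random_models(rng, 10, 3, 2)
        post = genotype_marginals(models, _uniform_L(10))
        np.testing.assert_allclose(post, model_genotype_prior(models), atol=1e-12)

    def test_rows_normalise(self):
        rng = np.random.default_rng(6)
        models = random_models(rng, 8, 3, 3)
        post = genotype_marginals(models, GenotypeLikelihoods(rng.random((8, 3))))
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_deep_coverage_forces_homozygote(self):
        """50 clean allele-1 reads at one locus drive P(g=2) above 0.999."""
        rng = np.random.default_rng(8)
        models = random_models(rng, 4, 2, 2)
        L = np.ones((4, 3))
        eps = 0.01
        c = 50
        L[2] = [eps**c, 0.5**c, (1 - eps) ** c]
        post = genotype_marginals(models, GenotypeLikelihoods(L))
        assert post[2, 2] > 0.999
        slow = brute_force_marginals(models, GenotypeLikelihoods(L))
        np.testing.assert_allclose(post, slow, atol=1e-9)

    def test_single_locus_reduces_to_bayes_rule(self):
        rng = np.random.default_rng(9)
        models = random_models(rng, 1, 3, 2)
        L = GenotypeLikelihoods(rng.random((1, 3)))
        post = brute_force_marginals(models, L)
        prior = model_genotype_prior(models)[0]
        expected = L.values[0] * prior
        expected /= expected.sum()
        np.testing.assert_allclose(post[0], expected, atol=1e-12)

    def test_brute_force_rejects_large_n(self):
        models = random_models(np.random.default_rng(0), 9, 2, 2)
        with pytest.raises(ValueError, match="n <= 8"):
            brute_force_marginals(models, _uniform_L(9))


class TestK1Factorisation:
    def test_k1_caller_equals_single_snp_caller(self):
        """With one founder per chain the factorial HMM has no LD left and
        posterior decoding reduces to independent Bayes calls under the
        model-implied genotype prior."""
        rng = np.random.default_rng(10)
        for _ in range(10):
            n = int(rng.integers(2, 9))
            models = random_models(rng, n, 1, 1)
            L = GenotypeLikelihoods(rng.random((n, 3)))
            post = genotype_marginals(models, L)
            prior = model_genotype_prior(models)
            for i in range(n):
                call = single_snp_call(L.values[i], prior[i], i)
                np.testing.assert_allclose(post[i], call.posterior, atol=1e-12)


class TestDecodeAndThreshold:
    def test_argmax_rows(self):
        post = np.array([[0.7, 0.2, 0.1], [0.1, 0.8, 0.1], [0.2, 0.2, 0.6]])
        np.testing.assert_array_equal(posterior_decode(post), [0, 1, 2])

    def test_tie_breaks_toward_zero_without_models(self):
        post = np.array([[0.4, 0.4, 0.2]])
        assert posterior_decode(post)[0] == 0

    def test_tie_breaks_toward_larger_model_prior(self):
        hmm = lc.HaplotypeHMM(
            initial=[1.0],
            transitions=np.empty((0, 1, 1)),
            emissions=np.array([[[0.2, 0.8]]]),  # prior favours allele 1
        )
        models = lc.ParentalModels.from_single(hmm)
        post = np.array([[0.3, 0.3, 0.4]])
        assert posterior_decode(post, models)[0] == 2
        tie12 = np.array([[0.2, 0.4, 0.4]])
        # prior: (0.04, 0.32, 0.64) -> genotype 2 wins the tie
        assert posterior_decode(tie12, models)[0] == 2

    def test_threshold_zero_calls_everything(self):
        post = np.array([[0.34, 0.33, 0.33], [0.5, 0.3, 0.2]])
        g = posterior_decode(post)
        np.testing.assert_array_equal(
            apply_no_call_threshold(g, post, 0.0), g
        )

    def test_extreme_threshold_keeps_only_near_certain(self):
        post = np.array([[1.0, 0.0, 0.0], [0.6, 0.4, 0.0]])
        g = apply_no_call_threshold(posterior_decode(post), post, 1 - 1e-12)
        np.testing.assert_array_equal(g, [0, NO_CALL])

    def test_call_rate_non_increasing_in_threshold(self):
        rng = np.random.default_rng(11)
        models = random_models(rng, 30, 3, 3)
        L = GenotypeLikelihoods(rng.random((30, 3)))
        post = genotype_marginals(models, L)
        g = posterior_decode(post, models)
        rates = [
            (apply_no_call_threshold(g, post, t) != NO_CALL).mean()
            for t in np.linspace(0, 0.99, 12)
        ]
        assert all(a >= b for a, b in zip(rates, rates[1:]))


class TestModelResultsSurface:
    def test_fit_bundles_everything(self, tiny_panel):
        res = lc.FounderHMM(tiny_panel, K=2).fit(max_iter=20, seed=0)
        cfg = lc.SimConfig(n_snps=tiny_panel.n, mean_coverage=4.0, seed=3)
        h, hp, g = lc.simulate_individual(tiny_panel, seed=3)
        reads = lc.simulate_reads(g, cfg, seed=4)
        out = lc.LDGenotypeModel(res.hmm, reads).fit(threshold=0.0)
        assert out.n == tiny_panel.n
        assert out.call_rate == 1.0
        assert np.isfinite(out.total_loglik)
        assert set(np.unique(out.genotypes)) <= {0, 1, 2}
        frame = out.to_frame()
        assert list(frame.columns[:2]) == ["locus", "call"]
        rethresh = out.recall(0.999)
        assert rethresh.call_rate <= out.call_rate
        assert "call rate" in out.summary()

    def test_locus_count_mismatch_rejected(self, tiny_panel):
        res = lc.FounderHMM(tiny_panel, K=2).fit(max_iter=5, seed=0)
        with pytest.raises(ValueError, match="loci"):
            lc.LDGenotypeModel(res.hmm, _uniform_L(tiny_panel.n + 1))
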