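"""Oracle, exact-Bayes HMM classifier and top-N_b sparsification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_loglik
from fluorem import (
    ConfigurationError,
    ErrorModel,
    FluorescenceString,
    LabelScheme,
    PosteriorBatch,
    ProteinRecord,
    Read,
    build_model,
    exact_posterior,
    exact_posterior_batch,
    hmm_loglikelihood,
    oracle_posterior,
    sparsify,
)


class TestOracle:
    def test_zero_error_is_one_hot(self):
        post = oracle_posterior(3, 0.0, 6)
        expected = np.zeros(6)
        expected[3] = 1.0
        np.testing.assert_array_equal(post, expected)

    def test_full_error_is_uniform(self):
        np.testing.assert_allclose(oracle_posterior(0, 1.0, 8), 1 / 8)

    def test_direct_evaluation(self):
        post = oracle_posterior(2, 0.1, 5)
        np.testing.assert_allclose(
            post, [0.02, 0.02, 0.92, 0.02, 0.02], atol=1e-15
        )

    def test_sampled_call_hit_rate(self):
        # drawing the call from the posterior hits the truth with
        # probability (1-e) + e/|D_F|
        e, n, reads = 0.3, 12, 20_000
        rng = np.random.default_rng(5)
        truth = rng.integers(0, n, size=reads)
        hits = 0
        for t in truth:
            call = rng.choice(n, p=oracle_posterior(int(t), e, n))
            hits += call == t
        expect = (1 - e) + e / n
        se = np.sqrt(expect * (1 - expect) / reads)
        assert abs(hits / reads - expect) < 3 * se

    def test_invalid_error_rate(self):
        with pytest.raises(ConfigurationError):
            oracle_posterior(0, 1.5, 4)


class TestHMMLoglikelihood:
    @pytest.mark.parametrize(
        "labels", [(0,), (-1, 0), (0, 1), (1, -1, 0)]
    )
    @pytest.mark.parametrize("n_cycles", [1, 2])
    def test_matches_brute_force_standard_params(self, labels, n_cycles):
        em = ErrorModel(n_cycles=n_cycles)
        f = FluorescenceString(labels)
        n_ch = max(c for c in labels if c >= 0) + 1
        rng = np.random.default_rng(hash((labels, n_cycles)) % 2**31)
        x = rng.normal(0.6 * em.mu, 0.6 * em.mu, (n_ch, em.n_timepoints))
        assert hmm_loglikelihood(Read(x), f, em) == pytest.approx(
            brute_force_loglik(x, f, em), abs=1e-8
        )

    def test_noise_free_generating_string_dominates(self):
        # a failure-free read of f must out-score every other string
        scheme = LabelScheme(channels=(frozenset("C"),))
        model = build_model(
            [ProteinRecord("p", "CKCCKCACK")], scheme, m=0.07
        )  # strings [0], [0,0], [0,.,0]: three distinct patterns
        em = ErrorModel(
            n_cycles=4, p_edman_fail=0.01, p_detach=0.01, p_bleach=0.01,
            p_dud=0.01, sigma=10.0, sigma_bg=5.0,
        )
        for s in range(1, model.n_strings):
            f = model.strings[s]
            # ideal staircase read for f
            x = np.zeros((1, em.n_timepoints))
            alive = set(f.dye_positions)
            x[0, 0] = len(alive) * em.mu
            for t in range(1, em.n_timepoints):
                alive.discard(t - 1)
                x[0, t] = len(alive) * em.mu
            lls = [
                hmm_loglikelihood(Read(x), model.strings[g], em)
                for g in range(1, model.n_strings)
            ]
            assert int(np.argmax(lls)) + 1 == s

    def test_detached_reads_carry_only_initial_information(self):
        # same initial dye counts, different positions: indistinguishable
        # once every molecule detaches after the first image
        em = ErrorModel(n_cycles=2, p_detach=0.999_999)
        fa = FluorescenceString((0, -1, 1))
        fb = FluorescenceString((1, 0))
        rng = np.random.default_rng(2)
        x = rng.normal(em.mu, em.sigma, (2, 3))
        # subtract the (negligible) non-detach branch by comparing at a
        # detach probability so close to 1 the likelihoods must agree
        assert hmm_loglikelihood(Read(x), fa, em) == pytest.approx(
            hmm_loglikelihood(Read(x), fb, em), rel=1e-4
        )


class TestExactPosterior:
    def test_single_string_universe(self):
        scheme = LabelScheme(channels=(frozenset("C"),))
        model = build_model([ProteinRecord("p", "CK")], scheme, m=0.07)
        em = ErrorModel(n_cycles=2)
        x = np.array([[em.mu, 0.0, 0.0]])
        post = exact_posterior(Read(x), model, em)
        np.testing.assert_allclose(post, [0.0, 1.0], atol=1e-15)

    def test_symmetric_channels_symmetric_posterior(self):
        # strings [ch0] and [ch1]; a read equal in both channels cannot
        # prefer either
        scheme = LabelScheme(channels=(frozenset("C"), frozenset("Y")))
        model = build_model(
            [ProteinRecord("p", "CKYK")], scheme, m=0.07
        )
        em = ErrorModel(n_cycles=2)
        x = np.full((2, 3), 0.5 * em.mu)
        post = exact_posterior(Read(x), model, em)
        assert post[0] == 0.0
        np.testing.assert_allclose(post[1], post[2], atol=1e-12)

    def test_permutation_equivariance(self, five_protein_model):
        import copy

        model = five_protein_model
        em = ErrorModel()
        rng = np.random.default_rng(3)
        x = rng.normal(em.mu, em.sigma, (3, em.n_timepoints))
        post = exact_posterior(Read(x), model, em)
        # swap two non-null strings in the model's indexing
        perm = np.arange(model.n_strings)
        perm[1], perm[2] = 2, 1
        permuted = copy.copy(model)
        permuted.strings = [model.strings[i] for i in perm]
        permuted.cond_FI = model.cond_FI[:, perm]
        post_p = exact_posterior(Read(x), permuted, em)
        np.testing.assert_allclose(post_p, post[perm], rtol=1e-10)

    def test_consistency_against_oracle_bound(self, five_protein_model):
        """On simulated reads the Bayes classifier cannot be less accurate
        than an oracle whose error rate matches its own empirical error."""
        from fluorem import generate_dataset, sample_abundances, top1_accuracy

        model = five_protein_model
        em = ErrorModel()
        p = sample_abundances(model.n_proteins, 21)
        ds = generate_dataset(model, p, 1_000, em, seed=22)
        reads = np.stack([r.intensities for r in ds.reads])
        post = exact_posterior_batch(reads, model, em)
        acc = top1_accuracy(post, ds.true_strings)
        e_emp = 1.0 - acc
        oracle_acc = (1 - e_emp) + e_emp / model.n_strings
        assert oracle_acc >= acc


class TestSparsify:
    def test_full_support_is_dense(self):
        post = np.array([0.5, 0.3, 0.2])
        sp = sparsify(post, 3)
        assert sp.residual == 0.0
        np.testing.assert_allclose(sp.dense(), post)

    def test_residual_direct_evaluation(self):
        sp = sparsify(np.array([0.7, 0.2, 0.1]), 1)
        np.testing.assert_array_equal(sp.top_indices, [0])
        np.testing.assert_allclose(sp.top_probs, [0.7])
        assert sp.residual == pytest.approx(0.1)  # (1 - 0.7) / 3

    def test_ties_break_to_lower_index(self):
        sp = sparsify(np.array([0.25, 0.25, 0.25, 0.25]), 2)
        np.testing.assert_array_equal(sp.top_indices, [0, 1])

    def test_idempotent(self):
        sp1 = sparsify(np.array([0.4, 0.3, 0.2, 0.1]), 2)
        sp2 = sparsify(sp1, 2)
        np.testing.assert_array_equal(sp1.top_indices, sp2.top_indices)
        np.testing.assert_array_equal(sp1.top_probs, sp2.top_probs)
        assert sp1.residual == sp2.residual

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6), st.integers(1, 12))
    def test_mass_preservation(self, seed, n_b):
        rng = np.random.default_rng(seed)
        draws = rng.exponential(size=10)
        sp = sparsify(draws / draws.sum(), n_b)
        total = sp.top_probs.sum() + sp.n_strings * sp.residual
        assert total == pytest.approx(1.0, abs=1e-9)
        assert sp.dense().sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(sp.top_probs) <= 0)

    def test_batch_matches_per_read(self):
        rng = np.random.default_rng(0)
        dense = rng.dirichlet(np.ones(8), size=5)
        batch = PosteriorBatch.from_dense(dense, 3)
        for k in range(5):
            sp = sparsify(dense[k], 3, read_id=k)
            np.testing.assert_array_equal(batch.indices[k], sp.top_indices)
            np.testing.assert_allclose(batch.probs[k], sp.top_probs)
            assert batch.residuals[k] == pytest.approx(sp.residual)

    def test_oracle_batch_matches_dense_oracle(self):
        truth = np.array([2, 0, 4])
        batch = PosteriorBatch.from_oracle(truth, 0.2, 5, n_b=5)
        for k, t in enumerate(truth):
            np.testing.assert_allclose(
                batch.to_sparse_list()[k].dense(),
                oracle_posterior(int(t), 0.2, 5),
                atol=1e-12,
            )
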