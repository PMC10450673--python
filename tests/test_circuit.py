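"""Neuron-astrocyte circuit: plasticity closed forms, oracle identity, traces."""

import math

import numpy as np
import pytest

from astroformer import (
    CircuitState,
    DegenerateNormalizationError,
    NotWrittenError,
    ProjectionWeights,
    TokenSequence,
    apply,
    feature_matrix,
    linear_attention,
    make_tokens,
    make_weights,
    project,
    read_token,
    run_block,
    sample_feature_map,
    softmax_self_attention,
    write_sequence,
)


def identity_instance():
    tokens = TokenSequence(np.array([[1.0, 0.0], [0.0, 1.0]]))
    weights = ProjectionWeights(np.eye(2), np.eye(2), np.eye(2), tied=True)
    return tokens, weights


class TestWritingPhase:
    def test_single_token_closed_form(self):
        # One token: H = (1/m) x phi(k)^T and g = phi(k).
        tokens = TokenSequence(np.array([[1.0], [0.0]]))
        weights = ProjectionWeights(np.eye(2), np.eye(2), np.eye(2), tied=True)
        fm = sample_feature_map("positive_exp", m=8, D=2, seed=0)
        state = write_sequence(tokens, weights, fm)
        phi = apply(fm, np.array([1.0, 0.0]))
        np.testing.assert_allclose(state.H_total, np.outer([1.0, 0.0], phi) / 8, rtol=1e-15)
        np.testing.assert_allclose(state.g_total, phi, rtol=1e-15)

    def test_writing_order_invariance_bit_exact(self):
        tokens = make_tokens(4, 8, seed=21)
        weights = make_weights(4, 5, seed=22)
        fm = sample_feature_map("cosine_rbf", m=64, D=5, seed=23)
        perm = np.random.default_rng(3).permutation(8)
        a = write_sequence(tokens, weights, fm)
        b = write_sequence(TokenSequence(tokens.X[:, perm]), weights, fm)
        assert np.array_equal(a.H_total, b.H_total)
        assert np.array_equal(a.g_total, b.g_total)

    def test_streaming_matches_batch_closed_form(self):
        # H accumulated token-by-token equals the one-shot (1/m) V phi(K)^T.
        tokens = make_tokens(2, 3, seed=31)
        weights = make_weights(2, 2, seed=32)
        fm = sample_feature_map("positive_exp", m=8, D=2, seed=33)
        state = write_sequence(tokens, weights, fm)
        P = project(tokens, weights)
        Phi = feature_matrix(fm, P.K)
        np.testing.assert_allclose(state.H_total, P.V @ Phi.T / 8, rtol=1e-12)
        np.testing.assert_allclose(state.g_total, Phi.sum(axis=1), rtol=1e-12)

    def test_fresh_state_is_zero(self):
        state = CircuitState.zeros(3, 16)
        assert not state.H_total.any() and not state.g_total.any()
        assert state.eta_H == 1.0 / 16


class TestReadingPhase:
    def test_reading_before_writing_raises(self):
        weights = make_weights(2, 2, seed=0)
        fm = sample_feature_map("positive_exp", m=4, D=2, seed=0)
        state = CircuitState.zeros(2, 4)
        with pytest.raises(NotWrittenError):
            read_token(np.ones(2), weights, fm, state)

    @pytest.mark.parametrize("kind", ["cosine_rbf", "positive_exp", "exact_kernel_oracle"])
    def test_single_written_token_ratio_collapses(self, kind):
        tokens = make_tokens(3, 1, seed=1)
        weights = make_weights(3, 4, seed=2)
        fm = sample_feature_map(kind, m=16, D=4, seed=3)
        state = write_sequence(tokens, weights, fm)
        out = read_token(tokens.column(0), weights, fm, state)
        v = weights.W_V @ tokens.column(0)
        np.testing.assert_allclose(out.ell, v + tokens.column(0), rtol=1e-10)

    def test_exact_oracle_reading_equals_softmax_column(self):
        tokens = make_tokens(3, 5, seed=4)
        weights = make_weights(3, 4, seed=5)
        fm = sample_feature_map("exact_kernel_oracle", m=7, D=4, seed=0)
        state = write_sequence(tokens, weights, fm)
        ref = softmax_self_attention(project(tokens, weights))
        for t in range(5):
            out = read_token(tokens.column(t), weights, fm, state)
            np.testing.assert_allclose(out.ell, ref.L[:, t], rtol=1e-10)

    def test_worked_example_converges_in_median_with_m(self):
        # Token 1 of the 2-token identity instance targets
        # [1 + e/(1+e), 1/(1+e)]; the median circuit output approaches it.
        tokens, weights = identity_instance()
        e = math.e
        target = np.array([1 + e / (1 + e), 1 / (1 + e)])
        med_err = []
        for m in (100, 100_000):
            cols = []
            for seed in range(20):
                fm = sample_feature_map("positive_exp", m=m, D=2, seed=seed)
                cols.append(run_block(tokens, weights, fm).L[:, 0])
            med = np.median(np.array(cols), axis=0)
            med_err.append(np.abs(med - target).max())
        assert med_err[1] < med_err[0]
        # 5% per coordinate against an absolute floor of 0.1
        med_large = np.median(
            np.array([
                run_block(tokens, weights,
                          sample_feature_map("positive_exp", m=100_000, D=2, seed=s)
                          ).L[:, 0]
                for s in range(20)
            ]), axis=0)
        assert np.all(np.abs(med_large - target) <= np.maximum(0.05 * np.abs(target), 0.1))

    def test_astrocyte_positive_with_positive_features(self):
        tokens = make_tokens(3, 4, seed=6)
        weights = make_weights(3, 4, seed=7)
        fm = sample_feature_map("positive_exp", m=32, D=4, seed=8)
        out = run_block(tokens, weights, fm)
        assert np.all(out.trace > 0.0)

    def test_degenerate_normalizer_raises(self):
        tokens = make_tokens(2, 1, seed=9)
        weights = make_weights(2, 2, seed=10)
        fm = sample_feature_map("cosine_rbf", m=4, D=2, seed=11)
        state = write_sequence(tokens, weights, fm)
        with pytest.raises(DegenerateNormalizationError):
            read_token(tokens.column(0), weights, fm, state, epsilon=1e12)


class TestRunBlock:
    def test_identical_tokens_collapse(self):
        x = np.array([0.5, -0.2, 0.8])
        tokens = TokenSequence(np.tile(x[:, None], (1, 4)))
        weights = make_weights(3, 3, seed=12)
        fm = sample_feature_map("cosine_rbf", m=16, D=3, seed=13)
        out = run_block(tokens, weights, fm)
        expected = weights.W_V @ x + x
        for t in range(4):
            np.testing.assert_allclose(out.L[:, t], expected, rtol=1e-10)

    def test_matches_linear_attention_oracle(self, small_instances):
        for inst in small_instances:
            ref = linear_attention(project(inst["tokens"], inst["weights"]), inst["fm"])
            out = run_block(inst["tokens"], inst["weights"], inst["fm"])
            np.testing.assert_allclose(out.L, ref.L, rtol=1e-10, atol=1e-10)

    def test_exact_oracle_matches_softmax(self):
        tokens = make_tokens(4, 6, seed=14)
        weights = make_weights(4, 5, seed=15)
        fm = sample_feature_map("exact_kernel_oracle", m=3, D=5, seed=0)
        ref = softmax_self_attention(project(tokens, weights))
        out = run_block(tokens, weights, fm)
        np.testing.assert_allclose(out.L, ref.L, rtol=1e-10)

    def test_tied_fastpath_bit_identical_to_general_path(self):
        tokens = make_tokens(3, 5, seed=16)
        weights = make_weights(3, 4, tied=True, seed=17)
        fm = sample_feature_map("positive_exp", m=32, D=4, seed=18)
        tied = run_block(tokens, weights, fm, mode="tied")
        general = run_block(tokens, weights, fm, mode="general")
        assert np.array_equal(tied.L, general.L)
        assert np.array_equal(tied.trace, general.trace)

    def test_prefactor_cancellation(self):
        tokens = make_tokens(3, 4, seed=19)
        weights = make_weights(3, 4, seed=20)
        fm = sample_feature_map("cosine_rbf", m=32, D=4, seed=21)
        out = run_block(tokens, weights, fm)
        out_scaled = run_block(tokens, weights, fm.scaled(17.5))
        np.testing.assert_allclose(out_scaled.L, out.L, rtol=1e-12)

    def test_permutation_equivariance(self):
        tokens = make_tokens(3, 6, seed=22)
        weights = make_weights(3, 4, seed=23)
        fm = sample_feature_map("positive_exp", m=64, D=4, seed=24)
        perm = np.random.default_rng(5).permutation(6)
        out = run_block(tokens, weights, fm)
        out_p = run_block(TokenSequence(tokens.X[:, perm]), weights, fm)
        np.testing.assert_allclose(out_p.L, out.L[:, perm], rtol=1e-10)


class TestStateSerialization:
    def test_round_trip_preserves_read_output(self, tmp_path):
        tokens = make_tokens(3, 4, seed=25)
        weights = make_weights(3, 4, seed=26)
        fm = sample_feature_map("positive_exp", m=16, D=4, seed=27)
        state = write_sequence(tokens, weights, fm)
        state.save(tmp_path / "state")
        back = CircuitState.load(tmp_path / "state")
        probe = make_tokens(3, 1, seed=28).column(0)
        a = read_token(probe, weights, fm, state)
        b = read_token(probe, weights, fm, back)
        np.testing.assert_allclose(b.ell, a.ell, rtol=1e-14)
        assert b.p == pytest.approx(a.p, rel=1e-14)

    def test_oracle_state_round_trip(self, tmp_path):
        tokens = make_tokens(2, 3, seed=29)
        weights = make_weights(2, 3, seed=30)
        fm = sample_feature_map("exact_kernel_oracle", m=5, D=3, seed=0)
        state = write_sequence(tokens, weights, fm)
        state.save(tmp_path / "oracle_state")
        back = CircuitState.load(tmp_path / "oracle_state")
        probe = tokens.column(1)
        np.testing.assert_allclose(
            read_token(probe, weights, fm, back).ell,
            read_token(probe, weights, fm, state).ell,
            rtol=1e-14,
        )
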