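"""Core network mechanics: activation, threshold, learning, normalisation."""

import numpy as np
import pytest

from cortexnet import NetworkParams, SynapticState
from cortexnet import network as net
from cortexnet.model import CorticalModule, split_seed


def small_params(**kw):
    defaults = dict(n_neurons=5, n_syn=4, sparseness=0.2)
    defaults.update(kw)
    return NetworkParams(**defaults)


def random_state(params, seed=0):
    return net.init_weights(params, seed)


class TestParams:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(sparseness=0.0),
            dict(sparseness=1.5),
            dict(g_rec=-0.1),
            dict(alpha_comp=-1),
            dict(n_neurons=0),
            dict(epochs=-1),
            dict(settle_iters=0),
            dict(normalize_every="never"),
            dict(n_neurons=10, sparseness=0.01),  # rounds to zero winners
        ],
    )
    def test_rejects_invalid(self, kw):
        with pytest.raises(ValueError):
            NetworkParams(**kw)

    def test_default_single_winner(self):
        assert NetworkParams().n_winners == 1


class TestInitWeights:
    def test_unit_row_norms_and_nonnegative(self):
        params = NetworkParams()
        syn = net.init_weights(params, 42)
        assert np.allclose(syn.row_norms(), 1.0, atol=1e-10)
        assert (syn.w_comp >= 0).all() and (syn.w_rec >= 0).all() and (syn.w_bp >= 0).all()

    def test_reproducible(self):
        a = net.init_weights(NetworkParams(), 7)
        b = net.init_weights(NetworkParams(), 7)
        assert np.array_equal(a.w_comp, b.w_comp)
        assert np.array_equal(a.w_rec, b.w_rec)
        assert np.array_equal(a.w_bp, b.w_bp)

    def test_normalisation_of_constant_row(self):
        # a row of equal weights w becomes 1/sqrt(3*n_syn) after scaling
        params = small_params()
        syn = SynapticState(
            w_comp=np.full((5, 4), 0.5),
            w_rec=np.full((5, 5), 0.5),
            w_bp=np.full((5, 4), 0.5),
        )
        syn.normalize_rows()
        assert np.allclose(syn.w_comp, 1 / np.sqrt(13))


class TestActivation:
    def test_zero_inputs_give_zero(self):
        params = small_params()
        syn = random_state(params)
        h = net.compute_activation(syn, params, np.zeros(4), np.zeros(5), np.zeros(4))
        assert np.allclose(h, 0.0)

    def test_block_gains_combine_linearly(self):
        params = small_params(g_comp=1.0, g_rec=0.1, g_bp=0.1)
        syn = SynapticState(
            w_comp=np.full((5, 4), 0.125),  # sum over 4 inputs = 0.5
            w_rec=np.full((5, 5), 0.06),  # sum over 5 inputs = 0.3
            w_bp=np.full((5, 4), 0.05),  # sum over 4 inputs = 0.2
        )
        h = net.compute_activation(syn, params, np.ones(4), np.ones(5), np.ones(4))
        assert np.allclose(h, 1.0 * 0.5 + 0.1 * 0.3 + 0.1 * 0.2)

    def test_one_hot_input_reads_single_weight(self):
        params = small_params()
        syn = random_state(params)
        x = np.zeros(4)
        x[2] = 1.0
        h = net.compute_activation(syn, params, x, np.zeros(5), np.zeros(4))
        assert np.allclose(h, params.g_comp * syn.w_comp[:, 2])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        params = NetworkParams(
            n_neurons=6,
            n_syn=7,
            sparseness=0.5,
            g_comp=rng.uniform(0.5, 2),
            g_rec=rng.uniform(0, 0.5),
            g_bp=rng.uniform(0, 0.5),
        )
        syn = net.init_weights(params, seed)
        xc, xr, xb = rng.random(7), rng.random(6), rng.random(7)
        h = net.compute_activation(syn, params, xc, xr, xb)
        for i in range(6):
            want = 0.0
            for k in range(7):
                want += params.g_comp * xc[k] * syn.w_comp[i, k]
            for l in range(6):
                want += params.g_rec * xr[l] * syn.w_rec[i, l]
            for m in range(7):
                want += params.g_bp * xb[m] * syn.w_bp[i, m]
            assert h[i] == pytest.approx(want, abs=1e-12)

    def test_dimension_mismatch(self):
        params = small_params()
        syn = random_state(params)
        with pytest.raises(ValueError):
            net.compute_activation(syn, params, np.zeros(3), np.zeros(5), np.zeros(4))


class TestSparsenessThreshold:
    def test_top_m_win(self):
        params = NetworkParams(n_neurons=3, n_syn=3, sparseness=1 / 3)
        assert np.array_equal(
            net.apply_sparseness(np.array([0.5, 0.9, 0.1]), params), [0, 1, 0]
        )

    def test_tie_break_lowest_index(self):
        params = NetworkParams(n_neurons=4, n_syn=4, sparseness=0.25)
        assert np.array_equal(
            net.apply_sparseness(np.array([0.7, 0.7, 0.7, 0.7]), params), [1, 0, 0, 0]
        )

    def test_all_nonpositive_silences_population(self):
        params = NetworkParams(n_neurons=4, n_syn=4, sparseness=0.25)
        assert net.apply_sparseness(np.zeros(4), params).sum() == 0
        assert net.apply_sparseness(-np.ones(4), params).sum() == 0

    def test_exact_winner_count(self):
        params = NetworkParams(n_neurons=10, n_syn=10, sparseness=0.3)
        h = np.random.default_rng(0).random(10)
        assert net.apply_sparseness(h, params).sum() == 3


class TestSettle:
    def test_single_pass_has_no_recurrent_contribution(self):
        params = small_params(settle_iters=1)
        syn = random_state(params)
        x = np.array([1, 0, 1, 0], dtype=float)
        out_a = net.settle(syn, params, x, np.zeros(4)).rates
        out_b = net.settle(syn, params.replace(g_rec=5.0), x, np.zeros(4)).rates
        assert np.array_equal(out_a, out_b)

    def test_zero_recurrent_gain_makes_iterations_irrelevant(self):
        params = small_params(g_rec=0.0)
        syn = random_state(params)
        x = np.array([1, 1, 0, 0], dtype=float)
        one = net.settle(syn, params.replace(settle_iters=1), x, np.zeros(4)).rates
        many = net.settle(syn, params.replace(settle_iters=5), x, np.zeros(4)).rates
        assert np.array_equal(one, many)

    def test_fixed_point_is_idempotent(self):
        params = small_params(settle_iters=3)
        syn = random_state(params)
        x = np.array([1, 0, 0, 1], dtype=float)
        s3 = net.settle(syn, params, x, np.zeros(4)).rates
        s6 = net.settle(syn, params.replace(settle_iters=6), x, np.zeros(4)).rates
        # once the rates stop changing between passes, further passes are inert
        if np.array_equal(s3, net.settle(syn, params.replace(settle_iters=4), x, np.zeros(4)).rates):
            assert np.array_equal(s3, s6)


class TestHebbianUpdate:
    def test_silent_neurons_untouched(self):
        params = small_params()
        syn = random_state(params)
        before = syn.copy()
        y = np.zeros(5)
        net.hebbian_update(syn, params, np.ones(4), np.ones(5), np.ones(4), y)
        assert np.array_equal(syn.w_comp, before.w_comp)
        assert np.array_equal(syn.w_rec, before.w_rec)
        assert np.array_equal(syn.w_bp, before.w_bp)

    def test_update_matches_manual_computation(self):
        params = small_params(alpha_comp=0.1, alpha_rec=0.03, alpha_bp=0.1)
        syn = random_state(params, seed=5)
        xc = np.array([1, 0, 1, 0], dtype=float)
        xr = np.array([0, 1, 0, 0, 1], dtype=float)
        xb = np.array([0, 0, 1, 1], dtype=float)
        y = np.array([1, 0, 0, 1, 0], dtype=float)
        expected = {
            "comp": syn.w_comp.copy(),
            "rec": syn.w_rec.copy(),
            "bp": syn.w_bp.copy(),
        }
        for i in (0, 3):
            expected["comp"][i] += 0.1 * xc
            expected["rec"][i] += 0.03 * xr
            expected["bp"][i] += 0.1 * xb
            norm = np.sqrt(
                (expected["comp"][i] ** 2).sum()
                + (expected["rec"][i] ** 2).sum()
                + (expected["bp"][i] ** 2).sum()
            )
            for blk in expected.values():
                blk[i] /= norm
        net.hebbian_update(syn, params, xc, xr, xb, y)
        assert np.allclose(syn.w_comp, expected["comp"], atol=1e-12)
        assert np.allclose(syn.w_rec, expected["rec"], atol=1e-12)
        assert np.allclose(syn.w_bp, expected["bp"], atol=1e-12)

    def test_norms_restored_after_update(self):
        params = small_params()
        syn = random_state(params)
        y = np.array([1, 1, 0, 0, 1], dtype=float)
        net.hebbian_update(syn, params, np.ones(4), np.ones(5), np.ones(4), y)
        assert np.allclose(syn.row_norms(), 1.0, atol=1e-10)
        assert (syn.w_comp >= 0).all()


class TestTraining:
    def test_zero_epochs_leaves_weights_at_initialisation(
        self, forward_set, backproj_set
    ):
        params = NetworkParams(epochs=0)
        syn0 = net.init_weights(params, 0)
        syn = net.train(syn0, params, forward_set, backproj_set, 0)
        assert np.array_equal(syn.w_comp, syn0.w_comp)

    def test_training_is_deterministic_given_seed(self, forward_set, backproj_set):
        params = NetworkParams(epochs=2)
        runs = []
        for _ in range(2):
            w_rng, p_rng = split_seed(99)
            syn = net.train(
                net.init_weights(params, w_rng), params, forward_set, backproj_set, p_rng
            )
            runs.append(syn)
        assert np.array_equal(runs[0].w_comp, runs[1].w_comp)
        assert np.array_equal(runs[0].w_rec, runs[1].w_rec)
        assert np.array_equal(runs[0].w_bp, runs[1].w_bp)

    def test_norm_and_nonnegativity_maintained_through_training(
        self, forward_set, backproj_set
    ):
        params = NetworkParams(epochs=3)
        syn = net.train(
            net.init_weights(params, 1), params, forward_set, backproj_set, 1
        )
        assert np.allclose(syn.row_norms(), 1.0, atol=1e-10)
        assert (syn.w_comp >= 0).all() and (syn.w_rec >= 0).all() and (syn.w_bp >= 0).all()

    def test_some_neurons_learn_cluster_aligned_forward_weights(self, fitted):
        # trained winners carry concentrated forward weights over their
        # category's active lines, well above the random baseline
        labels = fitted.category_labels
        fwd = fitted.model.forward.values
        for c in range(fitted.n_categories):
            winner = int(np.argmax(fitted.category_outputs[c]))
            members = fwd[labels == c]
            on_mask = members.any(axis=0).astype(bool)
            w = fitted.synapses.w_comp[winner]
            assert w[on_mask].mean() > 2 * max(w[~on_mask].mean(), 1e-6)

    def test_mismatched_pattern_sets_rejected(self, forward_set):
        from cortexnet.patterns import make_orthogonal_patterns

        params = NetworkParams()
        syn = net.init_weights(params, 0)
        with pytest.raises(ValueError):
            net.train(syn, params, forward_set, make_orthogonal_patterns(27, 100, 3), 0)


class TestTestingModes:
    def test_forward_output_sparseness_and_repeatability(self, fitted):
        params = fitted.params
        for f in fitted.model.forward.values[:5]:
            out1 = net.test_forward(fitted.synapses, params, f)
            out2 = net.test_forward(fitted.synapses, params, f)
            assert out1.sum() == params.n_winners
            assert np.array_equal(out1, out2)

    def test_attractor_from_zero_state_stays_silent(self, fitted):
        traj = net.run_attractor(fitted.synapses, fitted.params, np.zeros(100), 5)
        assert all(t.sum() == 0 for t in traj)

    def test_attractor_trajectory_keeps_exact_sparseness(self):
        params = NetworkParams(epochs=0)
        syn = net.init_weights(params, 3)  # untrained random weights
        y0 = np.zeros(100)
        y0[17] = 1
        for step in net.run_attractor(syn, params, y0, 10):
            assert step.sum() == params.n_winners

    def test_recall_of_zero_cue_is_silent(self, fitted):
        out = net.recall(fitted.synapses, fitted.params, np.zeros(100))
        assert out.sum() == 0

    def test_attention_gain_reductions(self, fitted):
        f = fitted.model.forward[3]
        b = fitted.model.backproj[3]
        full_fwd = net.attention_bias(fitted.synapses, fitted.params, f, b, 1.0, 0.0)
        assert np.array_equal(full_fwd, net.test_forward(fitted.synapses, fitted.params, f))
        full_bp = net.attention_bias(fitted.synapses, fitted.params, f, b, 0.0, 1.0)
        assert np.array_equal(full_bp, net.recall(fitted.synapses, fitted.params, b))

    def test_gain_bounds_enforced(self, fitted):
        f = fitted.model.forward[0]
        with pytest.raises(ValueError):
            net.attention_bias(fitted.synapses, fitted.params, f, f, 1.5, 0.0)


def test_full_pipeline_bit_reproducible(forward_set, backproj_set):
    a = CorticalModule(forward_set, backproj_set).fit(seed=11)
    b = CorticalModule(forward_set, backproj_set).fit(seed=11)
    assert np.array_equal(a.synapses.w_comp, b.synapses.w_comp)
    assert np.array_equal(a.forward_outputs, b.forward_outputs)
    assert np.array_equal(a.recall_outputs, b.recall_outputs)
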