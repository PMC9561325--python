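import numpy as np
import pytest

import deepmpm as dm
from deepmpm.model import (AttentionParams, HeadParams, forward,
                           loss_and_grads, _prefix_r)
from oracles import combine_weights_oracle, pool_oracle


def _attn(p=4, q=3, d=5, seed=0, scale=0.5):
    return AttentionParams.init(d, p, q, rng=np.random.default_rng(seed),
                                scale=scale)


class TestVisitAttention:
    def test_singleton_gets_full_weight(self):
        a = dm.visit_attention(np.random.default_rng(0).normal(size=(1, 4)),
                               _attn())
        np.testing.assert_allclose(a, [1.0])

    def test_identical_states_give_uniform_weights(self):
        G = np.tile(np.array([0.3, -1.0, 2.0, 0.1]), (4, 1))
        np.testing.assert_allclose(dm.visit_attention(G, _attn()),
                                   [0.25] * 4, atol=1e-12)

    def test_normalized_and_nonnegative(self):
        G = np.random.default_rng(1).normal(size=(7, 4))
        a = dm.visit_attention(G, _attn())
        assert a.sum() == pytest.approx(1.0)
        assert (a >= 0).all()

    def test_masked_positions_zeroed(self):
        G = np.random.default_rng(2).normal(size=(5, 4))
        mask = np.array([True, False, True, True, False])
        a = dm.visit_attention(G, _attn(), mask=mask)
        assert a[~mask].tolist() == [0.0, 0.0]
        assert a.sum() == pytest.approx(1.0)

    def test_all_masked_rejected(self):
        with pytest.raises(ValueError, match="masked"):
            dm.visit_attention(np.zeros((3, 4)), _attn(),
                               mask=np.zeros(3, bool))


class TestVariableAttention:
    def test_zero_params_give_zero(self):
        attn = _attn()
        attn.W_beta[...] = 0.0
        np.testing.assert_array_equal(
            dm.variable_attention(np.ones(3), attn), np.zeros(5))

    def test_bounded_in_minus_one_one(self):
        rng = np.random.default_rng(3)
        attn = _attn(scale=3.0, seed=3)
        for _ in range(20):
            b = dm.variable_attention(rng.normal(size=3), attn)
            assert (np.abs(b) <= 1.0).all()

    def test_saturates_towards_one(self):
        attn = _attn()
        attn.W_beta[...] = 0.0
        attn.b_beta[...] = 50.0
        np.testing.assert_allclose(
            dm.variable_attention(np.zeros(3), attn), np.ones(5))


class TestHarmonicWeight:
    @pytest.mark.parametrize("m,delta,expected", [
        (1.0, 0.0, 1.0),
        (1.0, np.e - 1.0, 0.5),
        (2.0, 0.0, 0.5),
    ])
    def test_closed_forms(self, m, delta, expected):
        assert dm.harmonic_weight(m, delta) == pytest.approx(expected)

    def test_in_unit_interval(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            r = dm.harmonic_weight(float(rng.choice([1.0, 2.0])),
                                   float(rng.uniform(0, 5000)))
            assert 0.0 < r <= 1.0

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            dm.harmonic_weight(1.0, -3.0)


class TestCombineAndPool:
    def test_beta_zero_gives_half_alpha(self):
        alpha = np.array([0.3, 0.7])
        w = dm.combine_weights(alpha, np.zeros((2, 4)), np.ones(2))
        np.testing.assert_allclose(w, alpha[:, None] / 2 * np.ones((2, 4)))

    def test_unit_case(self):
        w = dm.combine_weights(np.array([1.0]), np.ones((1, 3)),
                               np.array([1.0]))
        np.testing.assert_allclose(w, np.ones((1, 3)))

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(5)
        alpha = rng.dirichlet(np.ones(4))
        beta = rng.uniform(-1, 1, size=(4, 6))
        r = rng.uniform(0.1, 1.0, size=4)
        np.testing.assert_allclose(dm.combine_weights(alpha, beta, r),
                                   combine_weights_oracle(alpha, beta, r),
                                   atol=1e-14)

    def test_single_visit_pool_recovers_embedding(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(1, 5))
        w = rng.uniform(0.2, 1.0, size=(1, 5))
        np.testing.assert_allclose(dm.pool_health_status(w, X), X[0],
                                   atol=1e-12)

    def test_equal_weights_give_mean(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(3, 5))
        w = np.full((3, 5), 0.4)
        np.testing.assert_allclose(dm.pool_health_status(w, X), X.mean(0),
                                   atol=1e-12)

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(4, 6))
        w = rng.normal(size=(4, 6))
        np.testing.assert_allclose(dm.pool_health_status(w, X),
                                   pool_oracle(w, X), atol=1e-10, rtol=0)


class TestRiskHead:
    def test_zero_head_is_uniform(self):
        head = HeadParams(np.zeros((2, 5)), np.zeros(2))
        np.testing.assert_allclose(dm.predict_risk(np.ones(5), head),
                                   [0.5, 0.5])

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(9)
        head = HeadParams.init(5, rng=rng, scale=1.0)
        pr = dm.predict_risk(rng.normal(size=5), head)
        assert pr.sum() == pytest.approx(1.0)
        assert ((pr > 0) & (pr < 1)).all()

    def test_death_logit_monotonicity(self):
        head = HeadParams(np.zeros((2, 5)), np.zeros(2))
        h = np.ones(5)
        last = 0.0
        for b in (0.0, 0.5, 1.0, 2.0):
            head.fcn_bias[1] = b
            risk = dm.predict_risk(h, head)[1]
            assert risk > last or b == 0.0
            last = risk

    def test_non_finite_input_rejected(self):
        head = HeadParams.init(5)
        with pytest.raises(ValueError):
            dm.predict_risk(np.array([1.0, np.nan, 0, 0, 0]), head)


class TestForward:
    def test_output_contracts(self, toy_batch, toy_params):
        out = forward(toy_batch[0], toy_params)
        assert out.alpha.sum() == pytest.approx(1.0)
        assert (out.alpha >= 0).all()
        assert (np.abs(out.beta) <= 1.0).all()
        assert ((out.r > 0) & (out.r <= 1.0)).all()
        assert ((out.risk > 0) & (out.risk < 1)).all()

    def test_prefix_predictions_ignore_future_visits(self, toy_batch,
                                                     toy_params):
        seq = toy_batch[0]
        full = forward(seq, toy_params)
        from copy import deepcopy
        truncated = deepcopy(seq)
        for arr in ("x", "p", "m", "delta_prev", "delta_to_last", "y",
                    "mask", "admit_day", "discharge_day"):
            setattr(truncated, arr, getattr(seq, arr)[:2])
        part = forward(truncated, toy_params)
        np.testing.assert_allclose(part.risk, full.risk[:2], atol=1e-12)

    def test_ablation_is_special_case_of_combination(self, toy_batch,
                                                     toy_params):
        """Forcing beta to alpha (broadcast) makes (alpha+beta)/2 = alpha,
        so the ablated weights r*alpha coincide."""
        seq = toy_batch[0]
        out = forward(seq, toy_params, ablate_beta=True)
        alpha_vec = np.repeat(out.alpha[:, None], toy_params.d, axis=1)
        w_expected = dm.combine_weights(out.alpha, alpha_vec, out.r)
        np.testing.assert_allclose(out.w, w_expected, atol=1e-12)

    def test_single_visit_patient_composition(self, toy_params):
        rng = np.random.default_rng(11)
        from conftest import make_toy_sequence
        seq = make_toy_sequence("S", rng, T=1)
        out = forward(seq, toy_params)
        np.testing.assert_allclose(out.alpha, [1.0])
        X1 = np.maximum(toy_params.emb.W_xemb @ seq.x[0]
                        + toy_params.emb.b_x, 0.0)
        np.testing.assert_allclose(out.h_bar[0], X1, atol=1e-12)
        np.testing.assert_allclose(
            out.risk[0], dm.predict_risk(X1, toy_params.head)[1])

    def test_prefix_harmonic_weights_use_prefix_discharge(self, toy_batch):
        seq = toy_batch[0]
        r2 = _prefix_r(seq, 2)
        expected0 = 1.0 / (seq.m[0]
                           + np.log1p(seq.discharge_day[1]
                                      - seq.admit_day[0]))
        assert r2[0] == pytest.approx(expected0)
        assert r2[1] == pytest.approx(
            1.0 / (seq.m[1] + np.log1p(seq.discharge_day[1]
                                       - seq.admit_day[1])))


class TestGradients:
    def test_every_parameter_group_matches_finite_differences(
            self, toy_batch, toy_params):
        """Central finite differences of the full training loss (including
        L1+L2 penalties) agree with the analytic gradients at 1e-4 relative
        tolerance, for every entry of every parameter tensor."""
        l1 = l2 = 1e-4
        loss, grads = loss_and_grads(toy_batch, toy_params, l1=l1, l2=l2)
        assert np.isfinite(loss)
        h = 1e-6
        for name, arr in toy_params.arrays().items():
            flat = arr.reshape(-1)
            g = grads[name].reshape(-1)
            for ix in range(flat.size):
                old = flat[ix]
                flat[ix] = old + h
                lp, _ = loss_and_grads(toy_batch, toy_params, l1=l1, l2=l2,
                                       compute_grads=False)
                flat[ix] = old - h
                lm, _ = loss_and_grads(toy_batch, toy_params, l1=l1, l2=l2,
                                       compute_grads=False)
                flat[ix] = old
                fd = (lp - lm) / (2 * h)
                assert g[ix] == pytest.approx(fd, rel=1e-4, abs=1e-7), \
                    f"{name}[{ix}]"

    def test_ablated_gradient_matches_finite_differences(self, toy_batch,
                                                         toy_params):
        loss, grads = loss_and_grads(toy_batch, toy_params, ablate_beta=True)
        h = 1e-6
        rng = np.random.default_rng(0)
        for name, arr in toy_params.arrays().items():
            if name.startswith(("lstm_beta.", "attn.W_beta", "attn.b_beta")):
                assert np.all(grads[name] == 0.0)
                continue
            flat = arr.reshape(-1)
            for ix in rng.choice(flat.size, size=min(3, flat.size),
                                 replace=False):
                old = flat[ix]
                flat[ix] = old + h
                lp, _ = loss_and_grads(toy_batch, toy_params,
                                       ablate_beta=True,
                                       compute_grads=False)
                flat[ix] = old - h
                lm, _ = loss_and_grads(toy_batch, toy_params,
                                       ablate_beta=True,
                                       compute_grads=False)
                flat[ix] = old
                fd = (lp - lm) / (2 * h)
                assert grads[name].reshape(-1)[ix] == pytest.approx(
                    fd, rel=1e-4, abs=1e-7), f"{name}[{ix}]"
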