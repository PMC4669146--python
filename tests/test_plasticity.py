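import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mstdpnet as m

spike_train = st.lists(
    st.floats(0.0, 30.0), min_size=0, max_size=8
).map(lambda v: np.sort(np.array(v)))


class TestStdpPairSum:
    def test_single_causal_pair(self, plast_params):
        # pre at 0, post at 10, tau+ = 20: +e^{-0.5}
        out = m.stdp_pair_sum(np.array([0.0]), np.array([10.0]), plast_params)
        assert out == pytest.approx(np.exp(-0.5))

    def test_simultaneous_spikes_depress(self, plast_params):
        out = m.stdp_pair_sum(np.array([10.0]), np.array([10.0]), plast_params)
        assert out == pytest.approx(-1.0)

    def test_two_pre_one_post(self, plast_params):
        out = m.stdp_pair_sum(np.array([0.0, 5.0]), np.array([10.0]), plast_params)
        assert out == pytest.approx(np.exp(-0.5) + np.exp(-0.25))

    def test_empty_train_gives_zero(self, plast_params):
        assert m.stdp_pair_sum(np.empty(0), np.array([1.0]), plast_params) == 0.0

    @given(pre=spike_train, post=spike_train)
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force(self, pre, post, brute_stdp):
        params = m.PlasticityParams(tau_plus=20.0, tau_minus=17.0)
        expected = brute_stdp(pre, post, params.tau_plus, params.tau_minus)
        assert m.stdp_pair_sum(pre, post, params) == pytest.approx(expected, abs=1e-12)


class TestAstdpPairSum:
    def test_causal_pair_depresses(self, plast_params):
        out = m.astdp_pair_sum(np.array([0.0]), np.array([10.0]), plast_params)
        assert out == pytest.approx(-np.exp(-0.5))

    def test_reversed_order_potentiates(self, plast_params):
        out = m.astdp_pair_sum(np.array([10.0]), np.array([0.0]), plast_params)
        assert out == pytest.approx(np.exp(-0.5))

    def test_simultaneous_spikes_potentiate(self, plast_params):
        out = m.astdp_pair_sum(np.array([5.0]), np.array([5.0]), plast_params)
        assert out == pytest.approx(1.0)

    @given(pre=spike_train, post=spike_train)
    @settings(max_examples=40, deadline=None)
    def test_is_time_reversed_stdp(self, pre, post):
        # reversing time maps aSTDP onto STDP (ties break the exact
        # equality, so restrict to tie-free pairs)
        params = m.PlasticityParams(tau_plus=20.0, tau_minus=20.0)
        if pre.size and post.size and np.intersect1d(pre, post).size:
            return
        fwd = m.astdp_pair_sum(pre, post, params)
        rev = m.stdp_pair_sum(-pre[::-1], -post[::-1], params)
        assert fwd == pytest.approx(rev, abs=1e-12)


class TestMirroredUpdate:
    def test_exact_mirror_symmetry(self, frozen_records, plast_params):
        w = m.WeightState(np.zeros((10, 5)), np.zeros((5, 10)))
        for rec in frozen_records[:10]:
            dW, dQ = m.mstdp_trial_update(rec, w, plast_params)
            assert np.max(np.abs(dW / plast_params.eta - dQ.T / plast_params.zeta)) == 0.0

    def test_no_hidden_spikes_gives_zero_update(self, plast_params):
        rec = m.SpikeRecord(
            visible=[np.array([1.0, 2.0])] * 3, hidden=[np.empty(0)] * 2
        )
        w = m.WeightState(np.zeros((3, 2)), np.zeros((2, 3)))
        dW, dQ = m.mstdp_trial_update(rec, w, plast_params)
        assert not dW.any() and not dQ.any()

    def test_shape_mismatch_raises(self, plast_params):
        rec = m.SpikeRecord(visible=[np.empty(0)] * 2, hidden=[np.empty(0)])
        w = m.WeightState(np.zeros((3, 2)), np.zeros((2, 3)))
        with pytest.raises(ValueError):
            m.mstdp_trial_update(rec, w, plast_params)

    def test_matches_entrywise_stdp_of_spike_sets(self, frozen_records, plast_params):
        # K[i, j] must equal the plain STDP pair sum of (S_i, S_j)
        rec = frozen_records[0]
        K = m.mstdp_kernel(rec.visible, rec.hidden, plast_params)
        for i in (0, 4, 9):
            for j in (0, 2, 4):
                expected = m.stdp_pair_sum(rec.visible[i], rec.hidden[j], plast_params)
                assert K[i, j] == pytest.approx(expected, abs=1e-12)

    def test_hebbian_feedback_would_be_antisymmetric(self, plast_params):
        # replacing aSTDP by STDP on the feedback direction flips the
        # sign for every isolated spike pair: the wrong symmetry
        for tv, th in [(0.0, 7.0), (7.0, 0.0), (2.0, 12.0), (12.0, 2.0)]:
            ff = m.stdp_pair_sum(np.array([tv]), np.array([th]), plast_params)
            fb_hebbian = m.stdp_pair_sum(np.array([th]), np.array([tv]), plast_params)
            assert fb_hebbian == pytest.approx(-ff, abs=1e-12)
            fb_astdp = m.astdp_pair_sum(np.array([th]), np.array([tv]), plast_params)
            assert fb_astdp == pytest.approx(ff, abs=1e-12)

    def test_symmetry_preserved_over_updates_without_clipping(self, frozen_records):
        params = m.PlasticityParams(eta=1e-3, zeta=5e-4, w_max=1e9)
        rng = np.random.default_rng(0)
        W = rng.uniform(0, 0.1, size=(10, 5))
        w = m.WeightState(W, (params.zeta / params.eta) * W.T, "nonneg")
        for rec in frozen_records:
            dW, dQ = m.mstdp_trial_update(rec, w, params)
            w.W += dW
            w.Q += dQ
        np.testing.assert_allclose(
            w.Q, (params.zeta / params.eta) * w.W.T, rtol=0, atol=1e-12
        )


class TestClipping:
    def test_nonneg_mode_clips_to_zero_floor(self):
        params = m.PlasticityParams(w_max=0.5)
        w = m.WeightState(np.full((1, 1), 0.1), np.full((1, 1), 0.1), "nonneg")
        m.apply_trial_update(w, np.array([[-1.0]]), np.array([[2.0]]), params)
        assert w.W[0, 0] == 0.0 and w.Q[0, 0] == 0.5

    def test_signed_mode_clips_symmetrically(self):
        params = m.PlasticityParams(w_max=0.5)
        w = m.WeightState(np.zeros((1, 1)), np.zeros((1, 1)), "signed")
        m.apply_trial_update(w, np.array([[-1.0]]), np.array([[1.0]]), params)
        assert w.W[0, 0] == -0.5 and w.Q[0, 0] == 0.5


def _delta_bout_record(x, y, xhat, dt1, dt2, jitter=0.0, rng=None):
    """Spike record with all spikes at three instants (optionally jittered)."""
    t0, t1, t2 = 0.0, dt1, dt1 + dt2

    def times(n, t):
        base = np.full(n, t)
        if jitter > 0:
            base = base + rng.normal(0, jitter, size=n)
        return np.sort(base)

    visible = [np.concatenate([times(xi, t0), times(xh, t2)]) for xi, xh in zip(x, xhat)]
    hidden = [times(yj, t1) for yj in y]
    return m.SpikeRecord(visible=visible, hidden=hidden)


class TestEffectiveRule:
    def test_closed_form_example(self):
        params = m.PlasticityParams(eta=1.0, zeta=1.0, tau_plus=20.0, tau_minus=20.0)
        counts = m.TrialCounts(
            x=np.array([2]), y=np.array([3]), xhat=np.array([1]), dt1=10.0, dt2=15.0
        )
        out = m.effective_rule_prediction(counts, params)
        expected = np.exp(-0.5) * 6 - np.exp(-0.75) * 3
        assert out[0, 0] == pytest.approx(expected)
        assert expected == pytest.approx(2.2221, abs=1e-4)

    def test_no_late_bout_gives_pure_potentiation(self, plast_params):
        counts = m.TrialCounts(
            x=np.array([3]), y=np.array([2]), xhat=np.array([0]), dt1=8.0, dt2=float("nan")
        )
        out = m.effective_rule_prediction(counts, plast_params)
        beta = np.exp(-8.0 / plast_params.tau_plus)
        assert out[0, 0] == pytest.approx(plast_params.eta * beta * 6)

    def test_undefined_dt_with_pairs_raises(self, plast_params):
        counts = m.TrialCounts(
            x=np.array([3]), y=np.array([2]), xhat=np.array([0]), dt1=float("nan"), dt2=float("nan")
        )
        with pytest.raises(ValueError):
            m.effective_rule_prediction(counts, plast_params)

    def test_delta_bout_identity(self, plast_params):
        # spikes exactly at the three bout instants: the spiking update
        # equals the rate-rule prediction to machine precision
        rng = np.random.default_rng(21)
        for _ in range(5):
            x = rng.integers(0, 4, size=6)
            y = rng.integers(0, 3, size=4)
            xhat = rng.integers(0, 3, size=6)
            rec = _delta_bout_record(x, y, xhat, dt1=9.0, dt2=12.0)
            w = m.WeightState(np.zeros((6, 4)), np.zeros((4, 6)))
            dW, _ = m.mstdp_trial_update(rec, w, plast_params)
            counts = m.TrialCounts(x=x, y=y, xhat=xhat, dt1=9.0, dt2=12.0)
            predicted = m.effective_rule_prediction(counts, plast_params)
            np.testing.assert_allclose(dW, predicted, rtol=0, atol=1e-14)

    def test_jitter_convergence(self, plast_params):
        # relative error of the bout approximation shrinks as bout
        # jitter sigma -> 0
        rng = np.random.default_rng(3)
        x = np.array([4, 2, 3])
        y = np.array([2, 3])
        xhat = np.array([1, 1, 2])
        counts = m.TrialCounts(x=x, y=y, xhat=xhat, dt1=10.0, dt2=12.0)
        predicted = m.effective_rule_prediction(counts, plast_params)
        errs = []
        for sigma in (2.0, 1.0, 0.5, 0.1):
            rels = []
            for _ in range(30):
                rec = _delta_bout_record(x, y, xhat, 10.0, 12.0, jitter=sigma, rng=rng)
                w = m.WeightState(np.zeros((3, 2)), np.zeros((2, 3)))
                dW, _ = m.mstdp_trial_update(rec, w, plast_params)
                rels.append(
                    np.linalg.norm(dW - predicted) / np.linalg.norm(predicted)
                )
            errs.append(np.mean(rels))
        assert errs[0] > errs[1] > errs[2] > errs[3]


class TestScaledAutoencoderRule:
    def test_perfect_scaled_reconstruction_is_fixed_point(self):
        x = np.array([2.0, 5.0, 0.0])
        y = np.array([1.0, 2.0])
        out = m.scaled_autoencoder_rule(x, y, 0.5 * x, alpha=0.5)
        assert not out.any()

    def test_scalar_example(self):
        out = m.scaled_autoencoder_rule(np.array([2.0]), np.array([1.0]), np.array([1.0]), 0.5)
        assert out[0, 0] == 0.0

    def test_zero_hidden_activity_gives_zero(self):
        out = m.scaled_autoencoder_rule(np.ones(3), np.zeros(2), np.ones(3), 0.3)
        assert not out.any()

    def test_invalid_alpha_raises(self):
        with pytest.raises(ValueError):
            m.scaled_autoencoder_rule(np.ones(2), np.ones(2), np.ones(2), 0.0)

    def test_proportional_to_effective_rule_when_ratio_matches(self):
        # gamma/beta = 1/alpha makes the bout rule proportional to the
        # scaled autoencoder rule
        x = np.array([3.0, 1.0])
        y = np.array([2.0])
        xhat = np.array([1.0, 1.0])
        for alpha in (0.3, 0.5, 0.8):
            for dt1 in (5.0, 10.0):
                tau = 20.0
                beta = np.exp(-dt1 / tau)
                gamma = beta / alpha
                dt2 = -tau * np.log(gamma)
                params = m.PlasticityParams(eta=1.0, zeta=1.0, tau_plus=tau, tau_minus=tau)
                counts = m.TrialCounts(x=x, y=y, xhat=xhat, dt1=dt1, dt2=dt2)
                pred = m.effective_rule_prediction(counts, params)
                target = m.scaled_autoencoder_rule(x, y, xhat, alpha)
                np.testing.assert_allclose(pred, beta * target, atol=1e-12)
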