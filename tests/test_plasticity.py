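"""STDP rule: soft bounds, exponential windows, nearest-neighbour pairing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fearsim import NO_SPIKE, STDPParams, SpikePairing
from fearsim.errors import ConfigError
from fearsim.plasticity import clip_weights, stdp_delta, update_projection

P = STDPParams()


def stdp_delta_oracle(w, dt, p):
    """Direct evaluation of the pairing rule, kept independent of the
    implementation: potentiation toward w_max for pre-before-post
    (dt <= 0), depression toward w_min otherwise, both with exponential
    decay in |dt| and one Euler step of rate 1/tau_w."""
    if dt <= 0:
        return (p.w_max - w) * p.a_plus * np.exp(-abs(dt) / p.tau_plus) / p.tau_w
    return (p.w_min - w) * abs(p.a_minus) * np.exp(-dt / p.tau_minus) / p.tau_w


class TestDelta:
    def test_soft_bound_at_w_max_gives_zero_potentiation(self):
        assert stdp_delta(P.w_max, SpikePairing(-3.0), P) == 0.0

    def test_soft_bound_at_w_min_gives_zero_depression(self):
        assert stdp_delta(P.w_min, SpikePairing(5.0), P) == 0.0

    @pytest.mark.parametrize("w", [0.0, 1.3, 4.2, 6.0])
    @pytest.mark.parametrize("dt", [-25, -10, -3, 0, 1, 4, 12, 40])
    def test_matches_direct_formula_evaluation(self, w, dt):
        assert stdp_delta(w, SpikePairing(float(dt)), P) == pytest.approx(
            stdp_delta_oracle(w, dt, P), abs=1e-15
        )

    def test_potentiation_decays_with_pairing_separation(self):
        incs = [stdp_delta(1.0, SpikePairing(float(-d)), P) for d in range(0, 40, 3)]
        assert all(a > b > 0 for a, b in zip(incs, incs[1:]))

    def test_depression_magnitude_decays_with_pairing_separation(self):
        incs = [stdp_delta(1.0, SpikePairing(float(d)), P) for d in range(1, 40, 3)]
        assert all(a < b < 0 for a, b in zip(incs, incs[1:]))

    def test_default_amplitude_ratio_is_three(self):
        assert abs(P.a_plus) == pytest.approx(3 * abs(P.a_minus))

    def test_zero_depression_window_is_rejected(self):
        with pytest.raises(ConfigError):
            STDPParams(tau_minus=0.0)


def replay_oracle(n_pre, n_post, pre_raster, post_raster, w0, p):
    """Event-by-event brute-force replay of nearest-neighbour STDP."""
    w = w0.copy().astype(float)
    last_pre = np.full(n_pre, None)
    last_post = np.full(n_post, None)
    n_steps = pre_raster.shape[1]
    for t in range(n_steps):
        for i in range(n_pre):
            if pre_raster[i, t]:
                last_pre[i] = t
        for j in range(n_post):
            if post_raster[j, t]:
                last_post[j] = t
        dw = np.zeros_like(w)
        for j in range(n_post):
            if post_raster[j, t]:
                for i in range(n_pre):
                    if last_pre[i] is not None:
                        dw[j, i] += stdp_delta_oracle(w[j, i], last_pre[i] - t, p)
        for i in range(n_pre):
            if pre_raster[i, t]:
                for j in range(n_post):
                    if not post_raster[j, t] and last_post[j] is not None:
                        dw[j, i] += stdp_delta_oracle(w[j, i], t - last_post[j], p)
        w = np.clip(w + dw, p.w_min, p.w_max)
    return w


def run_update_projection(n_pre, n_post, pre_raster, post_raster, w0, p):
    w = w0.copy().astype(float)
    last_pre = np.full(n_pre, NO_SPIKE, dtype=np.int64)
    last_post = np.full(n_post, NO_SPIKE, dtype=np.int64)
    for t in range(pre_raster.shape[1]):
        sp = pre_raster[:, t]
        so = post_raster[:, t]
        last_pre[sp] = t
        last_post[so] = t
        w = update_projection(w, last_pre, last_post, sp, so, p)
    return w


class TestProjectionUpdate:
    def test_no_spikes_leaves_weights_unchanged(self):
        w = np.full((3, 2), 2.0)
        out = update_projection(
            w,
            np.full(2, NO_SPIKE, np.int64),
            np.full(3, NO_SPIKE, np.int64),
            np.zeros(2, bool),
            np.zeros(3, bool),
            P,
        )
        assert np.array_equal(out, w)

    def test_single_pre_then_post_pair_potentiates_one_entry(self):
        """Pre spike at step 10, post spike at step 12: exactly the
        (post 0, pre 0) entry is potentiated with dt = -2."""
        pre = np.zeros((1, 13), bool)
        post = np.zeros((1, 13), bool)
        pre[0, 10] = True
        post[0, 12] = True
        w0 = np.full((1, 1), 2.0)
        out = run_update_projection(1, 1, pre, post, w0, P)
        expected = 2.0 + stdp_delta_oracle(2.0, -2, P)
        assert out[0, 0] == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_random_rasters_match_brute_force_replay(self, seed):
        rng = np.random.default_rng(seed)
        n_pre = int(rng.integers(1, 8))
        n_post = int(rng.integers(1, 8))
        n_steps = int(rng.integers(5, 50))
        pre = rng.random((n_pre, n_steps)) < 0.2
        post = rng.random((n_post, n_steps)) < 0.2
        w0 = rng.uniform(P.w_min, P.w_max, size=(n_post, n_pre))
        got = run_update_projection(n_pre, n_post, pre, post, w0, P)
        want = replay_oracle(n_pre, n_post, pre, post, w0, P)
        assert np.allclose(got, want, atol=1e-12)
        assert np.all((got >= P.w_min) & (got <= P.w_max))

    def test_zero_amplitudes_freeze_weights(self):
        frozen = STDPParams(a_plus=0.0, a_minus=0.0)
        rng = np.random.default_rng(7)
        pre = rng.random((4, 30)) < 0.3
        post = rng.random((3, 30)) < 0.3
        w0 = rng.uniform(0, 6, size=(3, 4))
        out = run_update_projection(4, 3, pre, post, w0, frozen)
        assert np.allclose(out, w0)


class TestClip:
    def test_inside_bounds_is_identity(self):
        w = np.array([[0.5, 3.0], [5.9, 0.0]])
        assert np.array_equal(clip_weights(w, P), w)

    def test_mixed_matrix_matches_elementwise_oracle(self):
        w = np.array([[-1.0, 3.0, 99.0]])
        out = clip_weights(w, P)
        assert np.array_equal(out, np.minimum(np.maximum(w, P.w_min), P.w_max))
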