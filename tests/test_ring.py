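import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ringsim.core import kappa
from ringsim.plasticity import STDPParams
from ringsim.ring import (PrecedenceSpec, make_ring, present_pair, ring_learn,
                          ring_step, settle)

LAM, L = 0.8, 0.1


def probe_succession(state, i=0, j=1):
    """Drive neuron i one step with learning frozen; return r_j at the
    next step."""
    drive = np.zeros(state.K)
    drive[i] = 1.0
    state = ring_step(state, drive, L)
    state = ring_step(state, np.zeros(state.K), L)
    return state.r_now[j]


class TestRingStep:
    def test_hand_computed_propagation(self):
        state = make_ring(2, LAM)
        state.S[1, 0] = 1.0
        state.r_now = np.array([1.0, 0.0])
        state = ring_step(state, np.zeros(2), L)
        np.testing.assert_allclose(state.r_now, [LAM, 1.0])

    def test_decay_law_then_silence(self):
        # isolated neuron: activity lam**tau until it falls below l, then 0
        state = make_ring(1, LAM)
        state.r_now = np.array([1.0])
        expected = 1.0
        for _ in range(30):
            state = ring_step(state, np.zeros(1), L)
            expected *= LAM
            target = expected if expected >= L else 0.0
            assert state.r_now[0] == pytest.approx(target)
            if target == 0.0:
                break

    def test_quiescence_is_absorbing(self):
        state = make_ring(3, LAM)
        state = ring_step(state, np.zeros(3), L)
        assert not state.r_now.any()

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            ring_step(make_ring(2), np.zeros(3), L)

    def test_dynamics_see_only_clipped_weights(self):
        state = make_ring(2, LAM)
        state.S[1, 0] = 7.0  # raw weight far above the clip
        state.r_now = np.array([1.0, 0.0])
        state = ring_step(state, np.zeros(2), L)
        assert state.r_now[1] == 1.0  # kappa(7) = 1
        assert np.all(kappa(state.S) <= 1.0)


class TestRingLearn:
    def test_hand_computed_ltp(self):
        state = make_ring(2, LAM)
        state.r_prev = np.array([1.0, 0.0])
        state.r_now = np.array([LAM, 1.0])
        state = ring_learn(state, STDPParams(h=(1, 0)), 1.0)
        assert state.S[1, 0] == pytest.approx(1.0)  # r_j(t) * r_i(t-1)

    def test_silence_changes_nothing(self):
        state = make_ring(3, LAM)
        S0 = state.S.copy()
        state = ring_learn(state, STDPParams(h=(1, -1)), 1.0)
        np.testing.assert_array_equal(state.S, S0)

    @settings(derandomize=True, max_examples=25)
    @given(st.lists(st.floats(0, 1), min_size=4, max_size=4),
           st.lists(st.floats(0, 1), min_size=4, max_size=4))
    def test_diagonal_never_learned(self, r_now, r_prev):
        state = make_ring(4, LAM)
        state.r_now = np.asarray(r_now)
        state.r_prev = np.asarray(r_prev)
        state = ring_learn(state, STDPParams(h=(1, -1)), 1.0)
        np.testing.assert_array_equal(np.diag(state.S), [LAM] * 4)


class TestSuccessionLearning:
    SPEC = PrecedenceSpec(i=0, j=1, T1=2, T2=2)

    def test_per_presentation_increment_meets_bound(self):
        # each paired presentation adds at least (dt/tau_w) * lam**T2
        state = make_ring(2, LAM)
        p = STDPParams(h=(1, 0))
        bound = LAM ** self.SPEC.T2
        prev = 0.0
        for _ in range(5):
            state = present_pair(state, self.SPEC, p, L)
            assert state.S[1, 0] - prev >= bound - 1e-12
            prev = state.S[1, 0]

    def test_convergence_within_predicted_presentations(self):
        state = make_ring(2, LAM)
        p = STDPParams(h=(1, 0))
        predicted = int(np.ceil(1.0 / LAM ** self.SPEC.T2))
        n_obs = None
        for n in range(1, predicted + 1):
            state = present_pair(state, self.SPEC, p, L)
            if probe_succession(settle(state, L)) == 1.0:
                n_obs = n
                break
        assert n_obs is not None and n_obs <= predicted

    def test_no_presentations_no_inference(self):
        state = make_ring(2, LAM)
        assert state.S[1, 0] == 0.0
        assert probe_succession(state) == 0.0

    def test_exclusive_ordering_with_ltd_converges(self):
        state = make_ring(2, LAM)
        p = STDPParams(h=(1, -1))
        for _ in range(10):
            state = present_pair(state, self.SPEC, p, L)
        assert probe_succession(settle(state, L)) == 1.0

    def test_balanced_forward_reverse_stays_unconverged(self):
        # equal-frequency reversed pairings cancel LTP with LTD
        state = make_ring(2, LAM)
        p = STDPParams(h=(1, -1))
        reverse = PrecedenceSpec(i=1, j=0, T1=2, T2=2)
        for _ in range(50):
            state = present_pair(state, self.SPEC, p, L)
            state = present_pair(state, reverse, p, L)
        assert state.S[1, 0] < 1.0
        assert probe_succession(settle(state, L)) < 1.0

    def test_random_delay_draw_is_seeded(self):
        spec = PrecedenceSpec(i=0, j=1, T1=1, T2=3)
        p = STDPParams(h=(1, 0))
        out = []
        for _ in range(2):
            rng = np.random.default_rng(11)
            state = make_ring(2, LAM)
            for _ in range(4):
                state = present_pair(state, spec, p, L, rng=rng)
            out.append(state.S.copy())
        np.testing.assert_array_equal(out[0], out[1])
        with pytest.raises(ValueError):
            present_pair(make_ring(2, LAM), spec, p, L)  # rng required


def test_precedence_spec_validation():
    with pytest.raises(ValueError):
        PrecedenceSpec(i=0, j=1, T1=0, T2=2)
    with pytest.raises(ValueError):
        PrecedenceSpec(i=0, j=0, T1=1, T2=1)
    with pytest.raises(ValueError):
        make_ring(2, 1.0)
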