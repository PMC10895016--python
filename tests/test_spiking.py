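import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import small_network
from cosim.errors import ContractError, ParameterError, SequencingError
from cosim.spiking import (
    AdExParams,
    SpikeBlock,
    SynapseParams,
    apportion_slots,
    poisson_counts,
)


class TestSlotApportionment:
    def test_proportional_split(self):
        np.testing.assert_array_equal(
            apportion_slots(np.array([0.2, 0.8]), 10), [2, 8]
        )

    def test_zero_weights_give_zero_slots(self):
        np.testing.assert_array_equal(apportion_slots(np.zeros(3), 10), [0, 0, 0])

    @settings(derandomize=True, deadline=None, max_examples=40)
    @given(st.integers(0, 2**31 - 1), st.integers(0, 500), st.integers(1, 12))
    def test_sum_is_exact(self, seed, n_slots, n_sources):
        w = np.random.default_rng(seed).uniform(0, 1, n_sources)
        slots = apportion_slots(w, n_slots)
        assert slots.sum() == (n_slots if w.sum() > 0 else 0)
        assert np.all(slots >= 0)


class TestBuild:
    def test_synapse_count_binomial(self):
        net = small_network(syn=SynapseParams(p_conn=0.05))
        n_pairs = 100 * 99
        mean, sd = 0.05 * n_pairs, np.sqrt(n_pairs * 0.05 * 0.95)
        assert abs(net.n_synapses - mean) < 4 * sd

    def test_no_autapses(self):
        net = small_network()
        ptr, ind = net._adj_ptr, net._adj_indices
        for j in range(net.n):
            assert j not in ind[ptr[j]:ptr[j + 1]]

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            AdExParams(V_reset=10.0, V_peak=0.0)
        with pytest.raises(ParameterError):
            SynapseParams(p_conn=0.0)
        with pytest.raises(ParameterError):
            small_network(dt=0.0)


class TestAdExStep:
    def test_rest_is_a_fixed_point_without_exponential_term(self):
        # with Delta_T = 0 (sharp threshold) the rest state is exactly fixed
        net = small_network(
            adex_ex=AdExParams(Delta_T=0.0), adex_in=AdExParams(Delta_T=0.0),
            background_rate_hz=0.0,
        )
        V0, w0 = net.V.copy(), net.w.copy()
        for _ in range(100):
            net.step()
        np.testing.assert_array_equal(net.V, V0)
        np.testing.assert_array_equal(net.w, w0)

    def test_subthreshold_matches_lif_closed_form(self):
        # Delta_T -> 0, a = 0, no spikes: V(t) = E_L + (I/g_L)(1 - e^{-t g_L / C})
        p = AdExParams(Delta_T=0.0, a=0.0, b=0.0, C=200.0, g_L=10.0, V_T=1e6 - 1,
                       V_peak=1e6, E_L=-65.0)
        net = small_network(adex_ex=p, adex_in=p, dt=0.01, background_rate_hz=0.0)
        I = 100.0  # pA
        tau = p.C / p.g_L  # 20 ms
        n_steps = int(round(tau / 0.01))
        for _ in range(n_steps):
            net.step(I_ext=np.full(net.n, I))
        expected = p.E_L + (I / p.g_L) * (1 - np.exp(-1.0))
        assert net.V[0] == pytest.approx(expected, rel=0.01)

    def test_reset_rule(self):
        net = small_network(background_rate_hz=0.0,
                            adex_ex=AdExParams(tau_w=1e9, a=0.0, b=60.0))
        w_before = net.w[0]
        net.V[0] = net.params_ex.V_peak + 1.0
        net.step()
        assert net.V[0] == net.params_ex.V_reset  # refractory clamp holds V
        assert net.w[0] - w_before == pytest.approx(60.0, rel=1e-6)

    def test_exponential_term_is_overflow_safe(self):
        net = small_network(background_rate_hz=0.0)
        net.V[:] = net.params_ex.V_peak - 1e-9  # just below detection
        net.step()  # must not overflow or produce non-finite values
        assert np.all(np.isfinite(net.V))


class TestExternalInput:
    def test_empty_trains_change_nothing(self):
        net = small_network(background_rate_hz=0.0)
        net.inject_external_spike_trains([np.empty(0)] * net.n, (0.0, 10.0))
        net.run_chunk(0.0, 10.0)
        assert np.all(net.g_ex == 0)

    def test_single_spike_increments_conductance_after_d_min(self):
        net = small_network(background_rate_hz=0.0)
        trains = [np.empty(0)] * net.n
        trains[0] = np.array([1.0])
        net.inject_external_spike_trains(trains, (0.0, 10.0))
        # spike at 1.0 ms + d_min (0.1) arrives in the step starting at 1.1 ms
        net.run_chunk(0.0, 1.1)
        assert net.g_ex[0] == 0.0
        net.step()
        g_post = net.g_ex[0]
        Q, tau, dt = net.syn.Q_ex, net.syn.tau_ex, net.dt
        assert g_post == pytest.approx(Q * (1 - dt / tau))
        net.step()
        assert net.g_ex[0] == pytest.approx(Q * (1 - dt / tau) ** 2)

    def test_train_count_must_match_neurons(self):
        net = small_network()
        with pytest.raises(ContractError):
            net.inject_external_spike_trains([np.empty(0)] * 3, (0.0, 1.0))

    def test_counts_and_trains_injection_agree(self):
        rng = np.random.default_rng(5)
        times = np.sort(rng.uniform(0, 10.0 - 1e-6, 60))
        ids = rng.integers(0, 100, 60)
        net_a = small_network(background_rate_hz=0.0)
        net_b = small_network(background_rate_hz=0.0)
        trains = [times[ids == i] for i in range(net_a.n)]
        net_a.inject_external_spike_trains(trains, (0.0, 10.0))
        counts = np.zeros((100, net_b.n), dtype=int)
        bins = np.floor(times / 0.1 + 1e-9).astype(int)
        np.add.at(counts, (bins, ids), 1)
        net_b.inject_external_counts(counts, 0.0)
        ba, _ = net_a.run_chunk(0.0, 10.0)
        bb, _ = net_b.run_chunk(0.0, 10.0)
        np.testing.assert_array_equal(net_a.g_ex, net_b.g_ex)
        np.testing.assert_array_equal(ba.times, bb.times)

    def test_steady_state_conductance_matches_shot_noise_mean(self):
        # mean g in steady state = Q * tau * rate (shot-noise formula)
        rate = 500.0
        net = small_network(n_ex=800, n_in=200, background_rate_hz=rate,
                            adex_ex=AdExParams(V_T=1e6 - 1, V_peak=1e6, Delta_T=0.0),
                            adex_in=AdExParams(V_T=1e6 - 1, V_peak=1e6, Delta_T=0.0))
        net.run_chunk(0.0, 200.0)  # ~40 synaptic time constants
        samples = []
        for _ in range(300):
            net.step()
            samples.append(net.g_ex.mean())
        expect = net.syn.Q_ex * net.syn.tau_ex * rate * 1e-3
        assert np.mean(samples) == pytest.approx(expect, rel=0.05)


class TestPoissonBackground:
    def test_zero_rate_zero_events(self, rng):
        assert poisson_counts(0.0, 10, 100, 0.1, rng).sum() == 0

    def test_event_count_within_4_sigma(self, rng):
        counts = poisson_counts(100.0, 1, 100_000, 0.1, rng)  # 10 s at 100 Hz
        assert abs(counts.sum() - 1000) < 4 * np.sqrt(1000)

    def test_fano_factor_near_one(self, rng):
        # counts in 1000 disjoint 100 ms bins
        counts = poisson_counts(100.0, 1, 1_000_000, 0.1, rng).ravel()
        binned = counts.reshape(1000, 1000).sum(axis=1)
        fano = binned.var() / binned.mean()
        assert 0.8 < fano < 1.2


class TestRunChunk:
    def test_quiescent_network_returns_empty_block(self):
        net = small_network(background_rate_hz=0.0)
        block, _ = net.run_chunk(0.0, 10.0)
        assert block.n_events == 0

    def test_chunking_invariance(self):
        def make():
            return small_network(background_rate_hz=800.0, seed=13)

        whole = make()
        b_whole, _ = whole.run_chunk(0.0, 200.0)
        split = make()
        blocks = [split.run_chunk(t, t + 10.0)[0] for t in np.arange(0.0, 200.0, 10.0)]
        times = np.concatenate([b.times for b in blocks])
        ids = np.concatenate([b.ids for b in blocks])
        np.testing.assert_array_equal(b_whole.times, times)
        np.testing.assert_array_equal(b_whole.ids, ids)
        np.testing.assert_array_equal(whole.V, split.V)
        np.testing.assert_array_equal(whole.w, split.w)

    def test_spike_times_inside_window(self):
        net = small_network(background_rate_hz=2000.0)
        block, _ = net.run_chunk(0.0, 50.0)
        assert block.n_events > 0
        assert np.all((block.times >= 0.0) & (block.times < 50.0))

    def test_non_contiguous_chunk_rejected(self):
        net = small_network()
        net.run_chunk(0.0, 10.0)
        with pytest.raises(SequencingError):
            net.run_chunk(20.0, 30.0)

    def test_spike_conservation(self):
        net = small_network(background_rate_hz=2000.0)
        blocks = [net.run_chunk(t, t + 25.0)[0] for t in np.arange(0.0, 100.0, 25.0)]
        recorded = sum(b.n_events for b in blocks)
        assert recorded == net.n_resets

    def test_refractory_no_double_spikes(self):
        net = small_network(background_rate_hz=0.0, I_ext_pA=600.0)
        block, _ = net.run_chunk(0.0, 500.0)
        assert block.n_events > 0
        for nid in np.unique(block.ids):
            isi = np.diff(block.times[block.ids == nid])
            assert np.all(isi >= net.params_ex.t_ref - 1e-9)

    def test_recordings_shape_and_cadence(self):
        net = small_network(n_record=5)
        _, rec = net.run_chunk(0.0, 10.0)
        assert rec["V"].shape == (10, 10)  # 1 ms cadence, 5 exc + 5 inh neurons
        np.testing.assert_allclose(np.diff(rec["time"]), 1.0)
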