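"""Structural and dynamical tests of the slow-wave network simulator."""

import numpy as np
import pytest

from infomaxstdp.network import (
    NetworkConfig,
    SlowWaveNetwork,
    build_network,
    run_network_stdp,
    simulate,
)
from infomaxstdp.params import AdaptationParams, PlasticityParams
from infomaxstdp.states import classify_global_local, classify_updown


class TestBuildNetwork:
    def test_structure_invariants(self, small_net_config, rng):
        mask = build_network(small_net_config, rng)
        W = mask.weights
        cfg = small_net_config
        assert np.all(np.diag(W) == 0)  # no self-coupling
        # no I->I anywhere; no long-range I projections
        for a in range(cfg.n_local):
            for b in range(cfg.n_local):
                i_a, i_b = cfg.i_indices(a), cfg.i_indices(b)
                assert np.all(W[np.ix_(i_a, i_b)] == 0)
                if a != b:
                    e_a = cfg.e_indices(a)
                    assert np.all(W[np.ix_(e_a, i_b)] == 0)
        # dense within-network blocks at the printed weights
        e0, i0 = cfg.e_indices(0), cfg.i_indices(0)
        block = W[np.ix_(e0, e0)]
        off_diag = block[~np.eye(len(e0), dtype=bool)]
        assert np.all(off_diag == cfg.w_EE)
        assert np.all(W[np.ix_(e0, i0)] == cfg.w_EI)
        assert np.all(W[np.ix_(i0, e0)] == cfg.w_IE)

    def test_degenerate_probabilities(self, rng):
        cfg0 = NetworkConfig(n_E=80, n_I=20, p_EE_long=0.0, p_IE_long=0.0)
        mask = build_network(cfg0, rng)
        assert mask.long_range_density("EE") == 0.0
        cfg1 = NetworkConfig(n_E=80, n_I=20, p_EE_long=1.0, p_IE_long=1.0)
        mask = build_network(cfg1, rng)
        assert mask.long_range_density("EE") == 1.0

    def test_realized_density_matches_probability(self, net_config, rng):
        mask = build_network(net_config, rng)
        p = net_config.p_EE_long
        n_pairs = 800 * 600  # each E neuron to the 600 E cells elsewhere
        se = np.sqrt(p * (1 - p) / n_pairs)
        assert abs(mask.long_range_density("EE") - p) < 3 * se
        p_ie = net_config.p_IE_long
        n_pairs_ie = 200 * 600
        se_ie = np.sqrt(p_ie * (1 - p_ie) / n_pairs_ie)
        assert abs(mask.long_range_density("IE") - p_ie) < 3 * se_ie

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(p_EE_long=1.5)

    def test_deterministic_given_seed(self, small_net_config):
        a = build_network(small_net_config, np.random.default_rng(5)).weights
        b = build_network(small_net_config, np.random.default_rng(5)).weights
        assert np.array_equal(a, b)


class TestSimulate:
    def test_reproducible_given_seed(self, net_config):
        r1 = simulate(net_config, 2_000, np.random.default_rng(8), burn_in=500)
        r2 = simulate(net_config, 2_000, np.random.default_rng(8), burn_in=500)
        assert np.array_equal(r1.mean_u_E, r2.mean_u_E)
        assert np.array_equal(r1.e_counts, r2.e_counts)

    def test_quiescent_network_rests_near_u_r(self):
        """With recurrent weights zero, no input and no adaptation, the
        membrane sits at rest and fires near g(u_r) * <R>."""
        cfg = NetworkConfig(n_E=80, n_I=20, w_EE=0.0, w_EI=0.0, w_IE=0.0,
                            adaptation=AdaptationParams(beta=0.0))
        res = simulate(cfg, 20_000, np.random.default_rng(1), burn_in=1_000)
        assert np.allclose(res.mean_u_E, cfg.kernel.u_r, atol=1e-9)
        from infomaxstdp.dynamics import activation_intensity
        g_rest = activation_intensity(cfg.kernel.u_r, cfg.act_E)  # ~0.4 Hz
        rate = res.e_counts.sum() / (cfg.n_E * 20.0)  # Hz over 20 s
        se = np.sqrt(res.e_counts.sum()) / (cfg.n_E * 20.0)
        # refractory effects negligible at g*tau_R << 1
        assert abs(rate - g_rest) < 3 * se + 0.02

    def test_no_adaptation_keeps_up_state(self, net_config):
        """Removing the slow adaptation variable ungates the bistability:
        once up, a network stays up for the whole run."""
        cfg = NetworkConfig(adaptation=AdaptationParams(beta=0.0))
        res = simulate(cfg, 60_000, np.random.default_rng(2), burn_in=5_000)
        up = classify_updown(res.mean_u_E[:, 0])
        first_up = np.argmax(up)
        assert up[first_up:].all()

    def test_long_range_coupling_synchronizes_transitions(self):
        """Without between-network connections the four networks transit
        independently (label correlations at chance level for the ~45
        up/down cycles sampled); the sparse long-range connections raise
        the synchrony well above that."""
        def label_corr(cfg, seed):
            res = simulate(cfg, 60_000, np.random.default_rng(seed),
                           burn_in=10_000)
            up = np.column_stack([classify_updown(res.mean_u_E[:, k])
                                  for k in range(4)])
            assert 10 < np.abs(np.diff(up[:, 0].astype(int))).sum()
            corr = np.corrcoef(up.T.astype(float))
            return corr[~np.eye(4, dtype=bool)]

        uncoupled = label_corr(NetworkConfig(p_EE_long=0.0, p_IE_long=0.0), 3)
        coupled = label_corr(NetworkConfig(), 3)
        assert np.all(np.abs(uncoupled) < 0.4)  # ~3 sigma at n_eff ~ 45
        assert coupled.mean() > uncoupled.mean() + 0.15

    def test_forced_spike_updates_last_spike_and_adaptation(self, small_net_config):
        net = SlowWaveNetwork(small_net_config, np.random.default_rng(0))
        forced = np.zeros(small_net_config.n_total, dtype=bool)
        forced[0] = True
        net.step(forced=forced)
        assert net.t_hat[0] == 0.0
        assert net.I_a[0] == pytest.approx(small_net_config.adaptation.beta)


class TestNetworkStdp:
    def test_rejects_bad_condition(self, net_config, plasticity, rng):
        with pytest.raises(ValueError):
            run_network_stdp(net_config, "XX", [None], plasticity, rng)

    def test_reports_states_with_counts(self, net_config, plasticity):
        """Even sparsely visited states are reported with their n."""
        res = run_network_stdp(net_config, "SF", [None], plasticity,
                               np.random.default_rng(4), n_trials=20,
                               burn_in=2_000)
        assert set(s for s, _ in res.results) == {
            "global-down", "local-down", "global-up", "local-up"}
        assert sum(r["n"] for r in res.results.values()) == 20
        for r in res.results.values():
            if r["n"] == 0:
                assert np.isnan(r["mean"])
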