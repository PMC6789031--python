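import numpy as np
import pytest

from soctouch import microcircuit as mc
from soctouch.microcircuit.config import N_FULL, NetworkConfig, synapse_count
from soctouch.microcircuit.simulate import _run_phase


class TestSynapseCount:
    def test_zero_probability(self):
        assert synapse_count(0.0, 100, 100) == 0.0

    def test_unit_probability_diverges(self):
        with pytest.raises(ValueError):
            synapse_count(1.0, 10, 10)

    def test_thalamic_l4e_magnitude(self):
        k = synapse_count(0.0983, 902, 21915)
        assert k == pytest.approx(2.05e6, rel=0.01)

    def test_matches_montecarlo_pair_sampling(self):
        """K solves: probability a given pair is hit at least once by K
        uniform draws with replacement equals p_conn."""
        rng = np.random.default_rng(0)
        n_pre, n_post, p = 40, 50, 0.15
        k = int(round(synapse_count(p, n_pre, n_post)))
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            pre = rng.integers(0, n_pre, k)
            post = rng.integers(0, n_post, k)
            hits += np.any((pre == 0) & (post == 0))
        assert hits / n_rep == pytest.approx(p, abs=0.05)

    def test_consistency_with_poisson_limit(self):
        """-ln(1-p) * N_pre * N_post / K -> 1 across the printed table."""
        cfg = NetworkConfig()
        for tgt in mc.POPULATIONS:
            for src in mc.POPULATIONS + ("Thal",):
                p = cfg.conn_prob(tgt, src)
                if p == 0:
                    continue
                k = cfg.synapse_count_full(tgt, src)
                n_pre = mc.N_THAL_FULL if src == "Thal" else N_FULL[src]
                ratio = -np.log1p(-p) * n_pre * N_FULL[tgt] / k
                assert ratio == pytest.approx(1.0, rel=1e-4)

    def test_full_scale_totals(self):
        cfg = NetworkConfig()
        assert cfg.n_cortical == 77_169
        assert cfg.total_synapses_full() == pytest.approx(0.3e9, rel=0.05)


class TestBuild:
    @pytest.fixture(scope="class")
    def tiny_net(self):
        return mc.build_network(NetworkConfig(scale=0.01), seed=0)

    def test_population_sizes_scale(self, tiny_net):
        cfg = tiny_net.config
        for p in mc.POPULATIONS:
            a, b = tiny_net.pop_slice[p]
            assert b - a == max(1, round(N_FULL[p] * 0.01))

    def test_weight_statistics(self, tiny_net):
        w = tiny_net.syn_weight
        exc = w[w > 0]
        # exclude the doubled L4e->L23e weights from the plain-mean check
        plain = exc[exc < 140.0]
        assert plain.mean() == pytest.approx(87.8, rel=0.02)
        assert plain.std() == pytest.approx(8.8, rel=0.1)
        inh = w[w < 0]
        assert (-inh).mean() == pytest.approx(4 * 87.8, rel=0.02)

    def test_delays_at_least_one_step(self, tiny_net):
        assert tiny_net.syn_delay.min() >= 1

    def test_realized_synapse_counts(self, tiny_net):
        cfg = tiny_net.config
        total_expected = sum(
            cfg.synapse_count_scaled(t, s)
            for t in mc.POPULATIONS for s in mc.POPULATIONS + ("Thal",)
        )
        assert tiny_net.syn_post.size == total_expected


class TestIntegrator:
    def test_matches_analytic_single_neuron(self):
        """Subthreshold response to a constant current matches the closed
        form V(t) = Vr + I R (1 - exp(-t/tau)) to 1e-9 relative."""
        cfg = NetworkConfig()
        tau, cm, vr = cfg.tau_m, cfg.c_m, cfg.v_reset
        i_ext = 300.0  # pA -> steady state -65 + 12 mV, subthreshold
        dt = cfg.dt
        n_steps = 2000  # 200 ms
        V = np.array([vr])
        Isyn = np.zeros(1)
        ref = np.zeros(1, dtype=np.int64)
        ring = np.zeros((2, 1))
        eV = np.array([np.exp(-dt / tau)])
        c_ext = np.array([i_ext * tau / cm * (1 - eV[0])])
        c_syn = np.array([0.0])
        counts = np.zeros(1, dtype=np.int64)
        _run_phase(
            n_steps, V, Isyn, ref, ring, 0,
            np.zeros(2, np.int64), np.zeros(0, np.int32),
            np.zeros(0, np.float64), np.zeros(0, np.int64),
            eV, c_ext, c_syn, np.exp(-dt / cfg.tau_syn),
            cfg.v_th, np.array([vr]), 20,
            0.0, 1, 0, counts, False, 10**9, 1,
        )
        t = n_steps * dt
        analytic = vr + i_ext * tau / cm * (1 - np.exp(-t / tau))
        assert V[0] == pytest.approx(analytic, rel=1e-9)

    def test_spike_and_refractory(self):
        cfg = NetworkConfig()
        dt = cfg.dt
        tau, cm, vr = cfg.tau_m, cfg.c_m, cfg.v_reset
        i_ext = 600.0  # suprathreshold: steady state -65 + 24 = -41 mV
        V = np.array([vr])
        Isyn = np.zeros(1)
        ref = np.zeros(1, dtype=np.int64)
        ring = np.zeros((2, 1))
        eV = np.array([np.exp(-dt / tau)])
        c_ext = np.array([i_ext * tau / cm * (1 - eV[0])])
        c_syn = np.array([0.0])
        counts = np.zeros(1, dtype=np.int64)
        _run_phase(
            10000, V, Isyn, ref, ring, 0,
            np.zeros(2, np.int64), np.zeros(0, np.int32),
            np.zeros(0, np.float64), np.zeros(0, np.int64),
            eV, c_ext, c_syn, np.exp(-dt / cfg.tau_syn),
            cfg.v_th, np.array([vr]), int(cfg.tau_ref / dt),
            0.0, 1, 0, counts, True, 10**9, 1,
        )
        # analytic ISI: tau ln(IR / (IR - (Vth - Vr))) + refractory
        ir = i_ext * tau / cm
        isi = tau * np.log(ir / (ir - (cfg.v_th - vr))) + cfg.tau_ref
        expected = 10000 * dt / isi
        assert counts[0] == pytest.approx(expected, rel=0.05)


class TestDynamics:
    @pytest.fixture(scope="class")
    def small_net(self):
        return mc.build_network(NetworkConfig(scale=0.02), seed=3)

    def test_silent_without_drive(self, small_net):
        import dataclasses
        cfg = dataclasses.replace(
            small_net.config,
            background_b={p: 0.0 for p in mc.POPULATIONS},
            v_init_mean=-65.0, v_init_sd=0.0,
        )
        net = mc.build_network(cfg, seed=3)
        exp = mc.ModulationExperiment(
            n_trials_per_condition=1, baseline_ms=200.0, touch_ms=50.0,
            post_ms=0.0, thal_rate_touch=0.0, count_window_ms=200.0,
        )
        pre, post = mc.simulate_trial(net, exp, modulated=False, seed=0)
        assert pre.sum() == 0 and post.sum() == 0

    def test_touch_drives_l4e_above_baseline(self, small_net):
        exp = mc.ModulationExperiment(n_trials_per_condition=1,
                                      baseline_ms=700.0, post_ms=0.0)
        pre = np.zeros(small_net.n_cortical)
        post = np.zeros(small_net.n_cortical)
        for s in range(3):
            a, b = mc.simulate_trial(small_net, exp, modulated=False,
                                     seed=50 + s)
            pre += a
            post += b
        a4, b4 = small_net.pop_slice["L4e"]
        assert post[a4:b4].mean() > pre[a4:b4].mean()

    def test_null_modulation_exchangeable(self, small_net):
        """With the null modulation, modulated and non-modulated trial
        labels are exchangeable (trial-permutation test; neurons sharing
        trials are correlated, so per-neuron paired tests do not apply)."""
        from soctouch.microcircuit.simulate import exchangeability_test
        exp = mc.ModulationExperiment(
            dvr_inh=0.0, rm_factor=1.0, n_trials_per_condition=4,
            baseline_ms=700.0, post_ms=0.0, n_sample=800,
        )
        res = mc.simulate_experiment(small_net, exp, seed=7)
        assert exchangeability_test(res, n_perm=300, seed=1) > 0.05


class TestResponseSelection:
    def test_potentiation_structure_selected(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.5, 0.6, 400)
        y = 0.6 * x + rng.normal(0, 0.05, 400)
        fit = mc.response_model_selection(x, y)
        assert fit.selected == "potentiation"
        assert fit.coefficients["potentiation"]["slope"] == pytest.approx(
            0.6, abs=0.05
        )

    def test_bias_structure_selected(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.5, 0.6, 400)
        y = x + 0.4 + rng.normal(0, 0.05, 400)
        fit = mc.response_model_selection(x, y)
        assert fit.selected == "bias"
        assert fit.coefficients["bias"]["intercept"] == pytest.approx(
            0.4, abs=0.05
        )

    def test_too_few_neurons_rejected(self):
        with pytest.raises(ValueError):
            mc.response_model_selection(np.ones(5), np.ones(5))

    def test_bic_formula(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        y = x + rng.normal(0, 0.1, 50)
        fit = mc.response_model_selection(x, y)
        n = 50
        assert fit.bic["full"] == pytest.approx(
            n * np.log(fit.rss["full"] / n) + 2 * np.log(n), rel=1e-12
        )

    def test_ei_partition(self):
        rng = np.random.default_rng(4)

        class FakeResult:
            included = np.ones(100, dtype=bool)
            is_inhibitory = rng.uniform(size=100) < 0.2
            beta = {"nonmodulated": rng.normal(size=100),
                    "modulated": rng.normal(size=100)}

        df = mc.ei_response_comparison(FakeResult())
        for cond in ("nonmodulated", "modulated"):
            sub = df[df.condition == cond]
            assert sub["n"].sum() == 100
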