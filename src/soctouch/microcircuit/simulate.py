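"""Exact-integration simulation of the LIF microcircuit with touch trials.

The membrane/synapse system is linear between spikes, so each 0.1-ms step
applies the analytic propagator of

    dV/dt     = -(V - V_r)/tau_m + (I_ext + I_syn)/C_m
    dI_syn/dt = -I_syn/tau_syn

with spike arrivals (delayed per synapse) added to ``I_syn`` at step
boundaries.  Threshold crossing at -50 mV emits a spike; the neuron is
clamped at the reset potential for 2 ms.  Thalamic units fire Poisson at
0 Hz during baseline and 30 Hz during the 700-ms touch window.

A touch trial is 1000 ms baseline, 700 ms touch, 300 ms post.  In modulated
trials (interleaved with non-modulated ones) the neuromodulation is active
during the touch window only: the reset/rest potential of inhibitory
populations is depolarized by ``dvr_inh`` and the membrane time constant of
excitatory populations is multiplied by ``rm_factor`` (an input-resistance
increase, since tau_m = R_m C_m).  Per-neuron rates are estimated from
spike counts in the 700 ms before and after touch onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .network import Network

__all__ = ["ModulationExperiment", "TrialResult", "simulate_trial",
           "simulate_experiment", "exchangeability_test",
           "RunawayActivityError"]


class RunawayActivityError(RuntimeError):
    """Population activity exceeded the configured ceiling."""


@njit(cache=False)
def _run_phase(  # pragma: no cover - numba
    n_steps, V, Isyn, ref, ring, ring_pos0,
    indptr, syn_post, syn_w, syn_delay,
    eV, c_ext, c_syn, eS, v_th, v_reset, ref_steps,
    thal_p, n_cortical, n_thal,
    counts, do_count, spike_ceiling, seed,
):
    np.random.seed(seed)
    D = ring.shape[0]
    n_spikes_total = 0
    pos = ring_pos0
    spiking = np.empty(n_cortical + n_thal, dtype=np.int64)
    for step in range(n_steps):
        n_spk = 0
        # deliver arrivals scheduled for this step, then integrate
        for i in range(n_cortical):
            Isyn[i] = Isyn[i] * eS + ring[pos, i]
            ring[pos, i] = 0.0
            if ref[i] > 0:
                ref[i] -= 1
                V[i] = v_reset[i]
            else:
                V[i] = (v_reset[i] + (V[i] - v_reset[i]) * eV[i]
                        + c_ext[i] + Isyn[i] * c_syn[i])
                if V[i] >= v_th:
                    V[i] = v_reset[i]
                    ref[i] = ref_steps
                    spiking[n_spk] = i
                    n_spk += 1
                    if do_count:
                        counts[i] += 1
        if thal_p > 0.0:
            for k in range(n_thal):
                if np.random.random() < thal_p:
                    spiking[n_spk] = n_cortical + k
                    n_spk += 1
        n_spikes_total += n_spk
        if n_spk > spike_ceiling:
            return -1, pos
        for s in range(n_spk):
            j = spiking[s]
            for q in range(indptr[j], indptr[j + 1]):
                slot = (pos + syn_delay[q]) % D
                ring[slot, syn_post[q]] += syn_w[q]
        pos = (pos + 1) % D
    return n_spikes_total, pos


@dataclass
class ModulationExperiment:
    """One cell of the neuromodulation grid.

    ``dvr_inh`` (mV) depolarizes the inhibitory reset/rest potential and
    ``rm_factor`` scales the excitatory membrane time constant, both only
    during the touch window of modulated trials.
    """

    dvr_inh: float = 0.0          # mV in {0, 0.5, 1.0}
    rm_factor: float = 1.0        # in {1.0, 1.1, 1.2}
    n_trials_per_condition: int = 20
    baseline_ms: float = 1000.0
    touch_ms: float = 700.0
    post_ms: float = 300.0
    thal_rate_touch: float = 30.0  # Hz
    thal_rate_base: float = 0.0
    n_sample: int = 2000
    count_window_ms: float = 700.0
    spike_ceiling_fraction: float = 0.5  # per-step fraction of neurons


@dataclass
class TrialResult:
    """Aggregated spike counts and per-neuron touch responses."""

    counts_pre: dict              # condition -> per-neuron counts (summed)
    counts_post: dict
    n_trials: dict
    window_s: float               # counting window length per trial, s
    sample_idx: np.ndarray
    is_inhibitory: np.ndarray     # per sampled neuron
    population: np.ndarray        # per sampled neuron
    beta: dict = field(default_factory=dict)   # condition -> per-sample beta
    included: np.ndarray = None   # sampled neurons passing exclusions
    trial_counts_pre: np.ndarray = None    # (n_all_trials, n_neurons)
    trial_counts_post: np.ndarray = None
    trial_modulated: np.ndarray = None     # bool per trial

    def rates(self, condition, window):
        c = self.counts_pre if window == "pre" else self.counts_post
        return c[condition] / (self.n_trials[condition] * self.window_s)


def _phase_coefs(net: Network, tau_m, v_rest):
    cfg = net.config
    dt = cfg.dt
    eV = np.exp(-dt / tau_m)
    eS = float(np.exp(-dt / cfg.tau_syn))
    c_ext = net.i_ext * (tau_m / cfg.c_m) * (1.0 - eV)
    c_syn = (tau_m * cfg.tau_syn / (cfg.c_m * (cfg.tau_syn - tau_m))) * (eS - eV)
    return eV, c_ext, c_syn, eS


def simulate_trial(net: Network, exp: ModulationExperiment, modulated: bool,
                   seed=0, count_all=None):
    """Run one touch trial; returns per-neuron counts in the 700-ms windows
    before and after touch onset."""
    cfg = net.config
    dt = cfg.dt
    rng = np.random.default_rng(seed)
    n = net.n_cortical

    V = rng.normal(cfg.v_init_mean, cfg.v_init_sd, n)
    Isyn = np.zeros(n)
    ref = np.zeros(n, dtype=np.int64)
    D = int(net.syn_delay.max()) + 1
    ring = np.zeros((D, n), dtype=np.float64)
    pos = 0
    ref_steps = int(round(cfg.tau_ref / dt))
    ceiling = max(10, int(exp.spike_ceiling_fraction * n))

    tau_base = np.full(n, cfg.tau_m)
    vr_base = np.full(n, cfg.v_reset)
    tau_touch = tau_base.copy()
    vr_touch = vr_base.copy()
    if modulated:
        if exp.rm_factor != 1.0:
            tau_touch[~net.is_inhibitory] *= exp.rm_factor
        if exp.dvr_inh != 0.0:
            vr_touch[net.is_inhibitory] += exp.dvr_inh

    counts_pre = np.zeros(n, dtype=np.int64)
    counts_post = np.zeros(n, dtype=np.int64)
    win_steps = int(round(exp.count_window_ms / dt))
    base_steps = int(round(exp.baseline_ms / dt))
    touch_steps = int(round(exp.touch_ms / dt))
    post_steps = int(round(exp.post_ms / dt))
    thal_p_touch = exp.thal_rate_touch * dt * 1e-3
    thal_p_base = exp.thal_rate_base * dt * 1e-3

    phases = [
        # (steps, tau, vr, thal_p, counts or None)
        (base_steps - win_steps, tau_base, vr_base, thal_p_base, None),
        (win_steps, tau_base, vr_base, thal_p_base, counts_pre),
        (touch_steps, tau_touch, vr_touch, thal_p_touch, counts_post),
        (post_steps, tau_base, vr_base, thal_p_base, None),
    ]
    dummy = np.zeros(1, dtype=np.int64)
    for steps, tau, vr, thal_p, counts in phases:
        if steps <= 0:
            continue
        eV, c_ext, c_syn, eS = _phase_coefs(net, tau, vr)
        phase_seed = int(rng.integers(0, 2**31 - 1))
        total, pos = _run_phase(
            steps, V, Isyn, ref, ring, pos,
            net.indptr, net.syn_post, net.syn_weight, net.syn_delay,
            eV, c_ext, c_syn, eS, cfg.v_th, vr, ref_steps,
            thal_p, n, net.n_thal,
            counts if counts is not None else dummy,
            counts is not None, ceiling, phase_seed,
        )
        if total < 0:
            raise RunawayActivityError(
                f"population spike count exceeded {ceiling} in one step"
            )
    return counts_pre, counts_post


def simulate_experiment(net: Network, exp: ModulationExperiment, seed=0
                        ) -> TrialResult:
    """Run the interleaved modulated / non-modulated trial schedule.

    Per-neuron rates are pooled over the trials of each condition;
    ``beta = ln(r_touch / r_base)`` is computed for a random sample of
    ``n_sample`` neurons after removing neurons with fewer than three
    spikes across trials or with a zero count in either window (undefined
    log ratio).
    """
    ss = np.random.SeedSequence(seed)
    s_sample, s_trials = ss.spawn(2)
    n = net.n_cortical
    counts = {
        "nonmodulated": [np.zeros(n, np.int64), np.zeros(n, np.int64)],
        "modulated": [np.zeros(n, np.int64), np.zeros(n, np.int64)],
    }
    n_trials = {"nonmodulated": 0, "modulated": 0}
    n_all = 2 * exp.n_trials_per_condition
    trial_seeds = s_trials.generate_state(2 * n_all)
    tc_pre = np.zeros((n_all, n), dtype=np.int32)
    tc_post = np.zeros((n_all, n), dtype=np.int32)
    t_mod = np.zeros(n_all, dtype=bool)
    for i in range(n_all):
        modulated = i % 2 == 1
        cond = "modulated" if modulated else "nonmodulated"
        pre, post = simulate_trial(
            net, exp, modulated, seed=int(trial_seeds[i] % (2**31))
        )
        counts[cond][0] += pre
        counts[cond][1] += post
        tc_pre[i] = pre
        tc_post[i] = post
        t_mod[i] = modulated
        n_trials[cond] += 1

    rng = np.random.default_rng(s_sample)
    n_sample = min(exp.n_sample, n)
    sample_idx = rng.choice(n, size=n_sample, replace=False)
    pops = net.population_of()

    window_s = exp.count_window_ms * 1e-3
    result = TrialResult(
        counts_pre={c: counts[c][0] for c in counts},
        counts_post={c: counts[c][1] for c in counts},
        n_trials=n_trials,
        window_s=window_s,
        sample_idx=sample_idx,
        is_inhibitory=net.is_inhibitory[sample_idx],
        population=pops[sample_idx],
        trial_counts_pre=tc_pre[:, sample_idx],
        trial_counts_post=tc_post[:, sample_idx],
        trial_modulated=t_mod,
    )

    total_spikes = sum(
        counts[c][0][sample_idx] + counts[c][1][sample_idx] for c in counts
    )
    ok = total_spikes >= 3
    for c in counts:
        pre = counts[c][0][sample_idx]
        post = counts[c][1][sample_idx]
        ok &= (pre > 0) & (post > 0)
    result.included = ok
    for c in counts:
        pre = counts[c][0][sample_idx].astype(float)
        post = counts[c][1][sample_idx].astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = np.log(post / pre)
        result.beta[c] = beta[ok]
    return result


def _pooled_beta_diff(tc_pre, tc_post, mod_mask):
    """Population-mean difference of pooled per-neuron touch responses
    between the two trial groups (neurons with a zero window dropped)."""
    pre_m = tc_pre[mod_mask].sum(axis=0).astype(float)
    post_m = tc_post[mod_mask].sum(axis=0).astype(float)
    pre_n = tc_pre[~mod_mask].sum(axis=0).astype(float)
    post_n = tc_post[~mod_mask].sum(axis=0).astype(float)
    ok = (pre_m > 0) & (post_m > 0) & (pre_n > 0) & (post_n > 0)
    d = np.log(post_m[ok] / pre_m[ok]) - np.log(post_n[ok] / pre_n[ok])
    return float(d.mean())


def exchangeability_test(result: TrialResult, n_perm=500, seed=0) -> float:
    """Permutation test that modulated and non-modulated trials are
    exchangeable.

    Neurons sharing trials are strongly correlated, so per-neuron paired
    tests are invalid; instead the modulated/non-modulated trial labels are
    permuted and the population-mean response difference is recomputed per
    permutation.  Returns the two-sided plus-one permutation p value.
    """
    rng = np.random.default_rng(seed)
    tc_pre = result.trial_counts_pre
    tc_post = result.trial_counts_post
    mod = result.trial_modulated
    obs = _pooled_beta_diff(tc_pre, tc_post, mod)
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = _pooled_beta_diff(tc_pre, tc_post, rng.permutation(mod))
    p = (1 + int((np.abs(null) >= abs(obs)).sum())) / (n_perm + 1)
    return p
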