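"""Random instantiation of the microcircuit connectivity."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import INHIBITORY, POPULATIONS, NetworkConfig

__all__ = ["Network", "build_network"]

_SOURCES = POPULATIONS + ("Thal",)


@dataclass
class Network:
    """Instantiated network: neurons, background drive and synapse lists.

    Synapses are stored in CSR layout keyed by presynaptic neuron
    (cortical neurons first, thalamic neurons appended after them), so a
    spike of neuron ``j`` delivers to ``post[indptr[j]:indptr[j+1]]`` with
    per-synapse weights (pA) and delays (integration steps).
    """

    config: NetworkConfig
    pop_slice: dict            # population -> (start, stop) neuron indices
    n_cortical: int
    n_thal: int
    is_inhibitory: np.ndarray  # per cortical neuron
    i_ext: np.ndarray          # pA per cortical neuron
    indptr: np.ndarray
    syn_post: np.ndarray
    syn_weight: np.ndarray     # pA (float64)
    syn_delay: np.ndarray      # steps (int64, >= 1)

    @property
    def n_total(self) -> int:
        return self.n_cortical + self.n_thal

    def population_of(self) -> np.ndarray:
        pop = np.empty(self.n_cortical, dtype=object)
        for p, (a, b) in self.pop_slice.items():
            if p != "Thal":
                pop[a:b] = p
        return pop


def _truncated_normal(rng, mean, sd, n, low, max_redraw=100):
    x = rng.normal(mean, sd, n)
    for _ in range(max_redraw):
        bad = x <= low
        if not bad.any():
            break
        x[bad] = rng.normal(mean, sd, int(bad.sum()))
    return np.maximum(x, low + 1e-12)


def build_network(config: NetworkConfig, seed=0) -> Network:
    """Draw the full random connectivity.

    For each population pair, K synapses (in-degree-preserving at reduced
    scale) are assigned to uniformly drawn pre/post pairs with replacement
    (multapses and autapses permitted).  Excitatory weights are
    Normal(87.8, 8.8) pA truncated at zero by redraw; inhibitory synapses
    carry -4x the sampled excitatory weight; L4e->L2/3e weights are doubled;
    thalamic synapses use the excitatory weight and delay laws.  Delays are
    truncated below at one integration step.
    """
    rng = np.random.default_rng(seed)
    pop_slice = {}
    start = 0
    for p in POPULATIONS:
        n = config.n_neurons(p)
        pop_slice[p] = (start, start + n)
        start += n
    n_cortical = start
    n_thal = config.n_neurons("Thal")
    pop_slice["Thal"] = (n_cortical, n_cortical + n_thal)

    is_inh = np.zeros(n_cortical, dtype=bool)
    i_ext = np.empty(n_cortical)
    for p in POPULATIONS:
        a, b = pop_slice[p]
        is_inh[a:b] = p in INHIBITORY
        i_ext[a:b] = config.background_b[p] * config.i_unit

    pre_all, post_all, w_all, d_all = [], [], [], []
    for tgt in POPULATIONS:
        ta, tb = pop_slice[tgt]
        n_tgt = tb - ta
        for src in _SOURCES:
            k = config.synapse_count_scaled(tgt, src)
            if k == 0:
                continue
            sa, sb = pop_slice[src]
            pre = rng.integers(sa, sb, k)
            post = rng.integers(ta, tb, k)
            w = _truncated_normal(rng, config.w_exc_mean, config.w_exc_sd,
                                  k, 0.0)
            if src == "L4e" and tgt == "L23e":
                w = w * config.l4e_l23e_factor
            if src in INHIBITORY:
                w = -config.g_inh * w
                dmean, dsd = config.delay_inh
            else:
                dmean, dsd = config.delay_exc
            d = _truncated_normal(rng, dmean, dsd, k, 0.0)
            d_steps = np.maximum(np.round(d / config.dt), 1).astype(np.int64)
            pre_all.append(pre.astype(np.int64))
            post_all.append(post.astype(np.int32))
            w_all.append(w.astype(np.float64))
            d_all.append(d_steps)

    pre = np.concatenate(pre_all)
    post = np.concatenate(post_all)
    w = np.concatenate(w_all)
    d = np.concatenate(d_all)
    del pre_all, post_all, w_all, d_all

    order = np.argsort(pre, kind="stable")
    pre = pre[order]
    post = post[order]
    w = w[order]
    d = d[order]
    counts = np.bincount(pre, minlength=n_cortical + n_thal)
    indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)

    return Network(
        config=config, pop_slice=pop_slice, n_cortical=n_cortical,
        n_thal=n_thal, is_inhibitory=is_inh, i_ext=i_ext,
        indptr=indptr, syn_post=post, syn_weight=w, syn_delay=d,
    )
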