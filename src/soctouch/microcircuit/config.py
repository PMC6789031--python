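"""Configuration of the layered LIF cortical microcircuit.

The network covers ~1 mm^2 of sensory cortex as eight cortical populations
(excitatory and inhibitory neurons of layers 2/3, 4, 5 and 6; 77,169 LIF
neurons at full scale) plus a thalamic population of 902 Poisson units that
provides "touch" input.  Connectivity is pairwise random with replacement:
for each (source, target) population pair the total synapse number is

    K = log(1 - p_conn) / log(1 - 1 / (N_pre * N_post))

Reduced-scale networks preserve the per-target in-degree (K scales linearly
with the scaled target population) so single-neuron input statistics are
approximately invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "POPULATIONS",
    "N_FULL",
    "N_THAL_FULL",
    "CONN_PROB",
    "BACKGROUND_B",
    "synapse_count",
    "NetworkConfig",
]

POPULATIONS = ("L23e", "L23i", "L4e", "L4i", "L5e", "L5i", "L6e", "L6i")
INHIBITORY = ("L23i", "L4i", "L5i", "L6i")

N_FULL = {
    "L23e": 20683, "L23i": 5834, "L4e": 21915, "L4i": 5479,
    "L5e": 4850, "L5i": 1065, "L6e": 14395, "L6i": 2948,
}
N_THAL_FULL = 902

# connection probabilities: CONN_PROB[target][source]; source order is
# POPULATIONS + ("Thal",).  The L5e->L23i entry prints as 0.3075 in the
# source table; the value consistent with the upstream microcircuit model
# is 0.0755 and is used by default (configurable below).
_SOURCES = POPULATIONS + ("Thal",)
_P = {
    "L23e": (0.101, 0.169, 0.044, 0.082, 0.032, 0.0, 0.008, 0.0, 0.0),
    "L23i": (0.135, 0.137, 0.032, 0.052, 0.0755, 0.0, 0.004, 0.0, 0.0),
    "L4e": (0.008, 0.006, 0.05, 0.135, 0.007, 0.0003, 0.045, 0.0, 0.0983),
    "L4i": (0.069, 0.003, 0.079, 0.160, 0.003, 0.0, 0.106, 0.0, 0.0619),
    "L5e": (0.100, 0.062, 0.051, 0.006, 0.083, 0.373, 0.020, 0.0, 0.0),
    "L5i": (0.055, 0.027, 0.026, 0.002, 0.060, 0.316, 0.009, 0.0, 0.0),
    "L6e": (0.016, 0.007, 0.021, 0.017, 0.057, 0.020, 0.040, 0.225, 0.0512),
    "L6i": (0.036, 0.001, 0.003, 0.001, 0.028, 0.008, 0.066, 0.144, 0.0196),
}
CONN_PROB = {t: dict(zip(_SOURCES, row)) for t, row in _P.items()}
PRINTED_L5E_TO_L23I = 0.3075

BACKGROUND_B = {
    "L23e": 1600, "L23i": 1500, "L4e": 2100, "L4i": 1900,
    "L5e": 2000, "L5i": 1900, "L6e": 2900, "L6i": 2100,
}


def synapse_count(p_conn, n_pre, n_post) -> float:
    """Total synapse number for one population pair (real-valued; rounded to
    the nearest integer when the network is instantiated)."""
    if not 0 <= p_conn < 1:
        raise ValueError("p_conn must lie in [0, 1); the formula diverges at 1")
    if n_pre * n_post < 1:
        raise ValueError("populations must be non-empty")
    if p_conn == 0:
        return 0.0
    return float(np.log1p(-p_conn) / np.log1p(-1.0 / (n_pre * n_post)))


@dataclass
class NetworkConfig:
    """Neuron, synapse and input constants plus the network scale factor."""

    scale: float = 1.0
    use_printed_l5e_l23i: bool = False

    # LIF neuron constants
    tau_m: float = 10.0          # ms
    c_m: float = 250.0           # pF
    v_reset: float = -65.0       # mV (also the leak reversal)
    v_th: float = -50.0          # mV
    tau_ref: float = 2.0         # ms
    tau_syn: float = 0.5         # ms
    v_init_mean: float = -58.0   # mV
    v_init_sd: float = 10.0      # mV

    # synapses
    w_exc_mean: float = 87.8     # pA
    w_exc_sd: float = 8.8        # pA
    g_inh: float = 4.0           # w_i = -g * w_e
    l4e_l23e_factor: float = 2.0
    delay_exc: tuple = (1.5, 0.75)   # ms (mean, sd)
    delay_inh: tuple = (0.8, 0.4)

    # background drive: I_ext = b * 0.3512 pA, b per population
    i_unit: float = 0.3512       # pA
    background_b: dict = field(default_factory=lambda: dict(BACKGROUND_B))

    dt: float = 0.1              # ms integration step

    def __post_init__(self):
        if not 0 < self.scale <= 1:
            raise ValueError("scale must lie in (0, 1]")

    def conn_prob(self, target, source) -> float:
        p = CONN_PROB[target][source]
        if (self.use_printed_l5e_l23i and target == "L23i"
                and source == "L5e"):
            p = PRINTED_L5E_TO_L23I
        return p

    def n_neurons(self, pop) -> int:
        n_full = N_THAL_FULL if pop == "Thal" else N_FULL[pop]
        return max(1, int(round(n_full * self.scale)))

    @property
    def n_cortical(self) -> int:
        return sum(self.n_neurons(p) for p in POPULATIONS)

    def synapse_count_full(self, target, source) -> float:
        n_pre = N_THAL_FULL if source == "Thal" else N_FULL[source]
        return synapse_count(self.conn_prob(target, source), n_pre,
                             N_FULL[target])

    def synapse_count_scaled(self, target, source) -> int:
        """In-degree-preserving downscaling: K scales with the realized
        target population only."""
        k_full = self.synapse_count_full(target, source)
        return int(round(k_full * self.n_neurons(target) / N_FULL[target]))

    def total_synapses_full(self) -> float:
        return sum(
            self.synapse_count_full(t, s)
            for t in POPULATIONS for s in _SOURCES
        )
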