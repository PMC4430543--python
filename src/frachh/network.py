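"""Randomly connected network of fractional-order Hodgkin-Huxley neurons.

Each of N neurons follows the fHH patch equation plus a synaptic current
split into excitatory and inhibitory parts,

    I_syn,i = g_syn (sum_{j in S_ex} s(v_j)) (v_i - E_syn,ex)
            + g_syn (sum_{j in S_in} s(v_j)) (v_i - E_syn,in),

with an instantaneous sigmoidal gate s(v) = 1/(1+exp(-(v-V_syn)/k_syn)).
The in-degree of each neuron is Gaussian (mu = 25, sigma = 2.5 by
default), presynaptic partners are uniform over the population, and each
synapse is excitatory with probability 0.1.  Activity is evoked by a
40 uA/cm^2, 50-ms current in 13 randomly selected neurons.

Synaptic constants are stand-ins: g_syn is calibrated so that
integer-order (alpha = 1) networks sustain recurrent activity for the
whole simulation across architecture seeds — the defining baseline
behavior — while a handful of coincident excitatory inputs suffices to
fire a resting neuron.  Network-level conclusions are therefore trends
across seeded architectures, not absolute values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np

from .engine import integrate_hh
from .glcore import SolverConfig
from .metrics import detect_spikes
from .patch import PatchParams, Stimulus, steady_gates

__all__ = [
    "NetworkSpec",
    "SynapseParams",
    "NetworkSummary",
    "generate_network",
    "synaptic_gate",
    "simulate_network",
    "firing_rate",
    "synaptic_charge",
]


@dataclass
class NetworkSpec:
    """Random architecture: flat presynaptic index lists per neuron."""

    N: int
    pre_lists: List[np.ndarray]   # presynaptic indices per postsynaptic neuron
    exc_lists: List[np.ndarray]   # matching excitatory flags (bool)
    seed: int

    @property
    def indegrees(self) -> np.ndarray:
        return np.array([len(p) for p in self.pre_lists])

    def flat(self) -> dict:
        pre = np.concatenate(self.pre_lists).astype(np.int64)
        exc = np.concatenate(self.exc_lists).astype(np.int64)
        offsets = np.zeros(self.N + 1, dtype=np.int64)
        offsets[1:] = np.cumsum(self.indegrees)
        return {"pre_idx": pre, "pre_exc": exc, "offsets": offsets}


@dataclass
class SynapseParams:
    """Instantaneous sigmoidal synapse constants (mV, mS/cm^2)."""

    g_syn: float = 0.2  # calibrated so alpha=1 networks sustain activity
    E_syn_ex: float = 70.0
    E_syn_in: float = -12.0
    V_syn: float = 20.0
    k_syn: float = 2.0

    def __post_init__(self) -> None:
        if self.k_syn <= 0:
            raise ValueError("k_syn must be positive")
        if not (self.E_syn_in < self.V_syn < self.E_syn_ex):
            raise ValueError("require E_syn_in < V_syn < E_syn_ex")


@dataclass
class NetworkSummary:
    """Raster plus aggregate activity metrics of one network run."""

    spike_times: List[np.ndarray]       # per neuron, ms
    times: np.ndarray
    pEEG: np.ndarray                    # network-mean potential (mV)
    isyn_e: np.ndarray                  # network-mean excitatory current
    isyn_i: np.ndarray
    firing_rate_t: np.ndarray
    firing_rate: np.ndarray             # spikes/neuron per window
    activity_duration: float            # ms, last spike time (0 if silent)
    sustained: bool
    Q_synE: float                       # uA*ms/cm^2, magnitude
    Q_synI: float
    isi: np.ndarray = field(default_factory=lambda: np.empty(0))

    def isi_histogram(self, bin_width: float = 5.0, t_max: float = 100.0):
        """Binned interspike-interval counts: (bin edges ms, counts)."""
        edges = np.arange(0.0, t_max + bin_width, bin_width)
        counts, _ = np.histogram(self.isi, bins=edges)
        return edges, counts


def generate_network(
    N: int = 50,
    indegree_mean: float = 25.0,
    indegree_sd: float = 2.5,
    p_excitatory: float = 0.1,
    seed: int = 0,
) -> NetworkSpec:
    """Draw a random architecture, fully reproducible from the seed.

    In-degrees are rounded Gaussian draws clipped to [0, N]; presynaptic
    indices are uniform over the population (self-connections and
    duplicates are permitted, as in plain uniform sampling).
    """
    if indegree_mean > N:
        raise ValueError("mean in-degree cannot exceed the population size")
    rng = np.random.default_rng(seed)
    pre_lists, exc_lists = [], []
    for _ in range(N):
        k = int(np.clip(round(rng.normal(indegree_mean, indegree_sd)), 0, N))
        pre_lists.append(rng.integers(0, N, size=k))
        exc_lists.append(rng.random(k) < p_excitatory)
    return NetworkSpec(N=N, pre_lists=pre_lists, exc_lists=exc_lists, seed=seed)


def synaptic_gate(v_pre, sp: SynapseParams):
    """Instantaneous postsynaptic gate, logistic in the presynaptic potential."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(v_pre, dtype=float) - sp.V_syn) / sp.k_syn))


def firing_rate(
    spike_times: List[np.ndarray],
    t_end: float,
    window: float = 50.0,
    step: float = 10.0,
) -> tuple:
    """Population rate: spikes per neuron in sliding windows.

    Returns (window centers, rate); windows are clipped to [0, t_end].
    """
    n = len(spike_times)
    all_spikes = (
        np.concatenate(spike_times) if n and any(len(s) for s in spike_times)
        else np.empty(0)
    )
    starts = np.arange(0.0, max(t_end - window, 0.0) + step / 2, step)
    rate = np.empty(len(starts))
    for i, s in enumerate(starts):
        rate[i] = np.sum((all_spikes >= s) & (all_spikes < s + window)) / n
    return starts + window / 2.0, rate


def synaptic_charge(
    isyn_e: np.ndarray,
    isyn_i: np.ndarray,
    times: np.ndarray,
    t_on: float = 0.0,
    t_off: float = 50.0,
) -> tuple:
    """|time integral| of the mean synaptic currents over the stimulus window.

    Trapezoidal quadrature; returns (Q_synE, Q_synI) as magnitudes in
    uA*ms/cm^2.
    """
    sel = (times >= t_on) & (times <= t_off)
    qe = np.trapezoid(isyn_e[sel], times[sel])
    qi = np.trapezoid(isyn_i[sel], times[sel])
    return abs(float(qe)), abs(float(qi))


def simulate_network(
    net: NetworkSpec,
    sp: SynapseParams,
    p: PatchParams,
    cfg: SolverConfig,
    stim_amplitude: float = 40.0,
    stim_duration: float = 50.0,
    n_stimulated: int = 13,
    stim_seed: int = 1,
) -> NetworkSummary:
    """Simulate the network from rest under the standard evoking protocol.

    ``n_stimulated`` neurons, drawn with ``stim_seed``, receive a constant
    ``stim_amplitude`` current for the first ``stim_duration`` ms.  The
    fractional order applies to every membrane potential; gates and the
    (instantaneous) synapses are memoryless.

    Activity duration is the last spike time in the raster; the network
    counts as "sustained" when any spike falls in the final 50 ms.
    """
    rng = np.random.default_rng(stim_seed)
    chosen = rng.choice(net.N, size=n_stimulated, replace=False)
    mask = np.zeros(net.N)
    mask[chosen] = 1.0
    stim = Stimulus(kind="pulse", amplitude=stim_amplitude, onset=0.0,
                    duration=stim_duration)
    flat = net.flat()
    res = integrate_hh(
        alpha=p.alpha,
        cfg=cfg,
        gna=np.full(net.N, p.g_Na * p.conductance_scale[0]),
        gk=np.full(net.N, p.g_K * p.conductance_scale[1]),
        gl=np.full(net.N, p.g_L * p.conductance_scale[2]),
        ena=p.E_Na, ek=p.E_K, el=p.E_L,
        stim_t=stim.time_array(cfg.n_steps, cfg.dt),
        stim_mask=mask,
        gates0=np.tile(steady_gates(), (net.N, 1)),
        network={
            **flat,
            "gsyn": sp.g_syn, "esyn_ex": sp.E_syn_ex, "esyn_in": sp.E_syn_in,
            "vsyn": sp.V_syn, "ksyn": sp.k_syn,
        },
    )
    times = res["times"]
    v = res["v"]
    spike_times = [
        detect_spikes(v[i], times).peak_times for i in range(net.N)
    ]
    all_sp = np.concatenate([s for s in spike_times if len(s)]) if any(
        len(s) for s in spike_times
    ) else np.empty(0)
    t_end = times[-1]
    duration = float(all_sp.max()) if len(all_sp) else 0.0
    sustained = bool(len(all_sp) and (all_sp.max() >= t_end - 50.0))
    qe, qi = synaptic_charge(res["isyn_e"], res["isyn_i"], times,
                             0.0, stim_duration)
    fr_t, fr = firing_rate(spike_times, t_end)
    isi = np.concatenate([np.diff(s) for s in spike_times if len(s) > 1]) if any(
        len(s) > 1 for s in spike_times
    ) else np.empty(0)
    stride = cfg.record_stride
    return NetworkSummary(
        spike_times=spike_times,
        times=times[::stride].copy(),
        pEEG=v.mean(axis=0)[::stride].copy(),
        isyn_e=res["isyn_e"][::stride].copy(),
        isyn_i=res["isyn_i"][::stride].copy(),
        firing_rate_t=fr_t,
        firing_rate=fr,
        activity_duration=duration,
        sustained=sustained,
        Q_synE=qe,
        Q_synI=qi,
        isi=isi,
    )
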