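"""Compartmental central auditory neuron.

A soma electrically coupled to 10 uniform passive dendritic subunits.
Dendrites receive AMPA (and optionally NMDA) synapses from the encoder
channels; the soma carries spike-triggered adaptation and an
Ornstein-Uhlenbeck (coloured) noise current.  All state variables are
integrated with forward Euler at dt = 0.1 ms.

Unit system: mV, ms, nS, pA, pF (so g[nS] * V[mV] = I[pA] and
C[pF] * dV/dt[mV/ms] = I[pA]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .encoder import SpikeRaster


@dataclass(frozen=True)
class CompartmentGeometry:
    """Cylinder geometry and passive membrane constants of one compartment.

    Membrane area is the cylinder's lateral area times the two area
    factors; dendrites use spine_area_factor * area_scale_factor to account
    for spines and unmodelled membrane, the soma is left unscaled.
    """

    length_um: float
    diameter_um: float
    c_m_uf_cm2: float = 0.5  # specific capacitance
    r_m_kohm_cm2: float = 20.0  # specific membrane resistivity
    area_scale_factor: float = 1.0
    spine_area_factor: float = 1.0

    @property
    def area_cm2(self) -> float:
        lateral_um2 = np.pi * self.diameter_um * self.length_um
        return (lateral_um2 * self.area_scale_factor *
                self.spine_area_factor) * 1e-8

    @property
    def capacitance_pf(self) -> float:
        # uF/cm2 * cm2 = uF -> pF
        return self.c_m_uf_cm2 * self.area_cm2 * 1e6

    @property
    def leak_ns(self) -> float:
        # cm2 / (kOhm cm2) = mS -> nS
        return self.area_cm2 / self.r_m_kohm_cm2 * 1e6

    @property
    def tau_m_ms(self) -> float:
        return self.capacitance_pf / self.leak_ns


SOMA_GEOMETRY = CompartmentGeometry(length_um=25.0, diameter_um=25.0)
DENDRITE_GEOMETRY = CompartmentGeometry(
    length_um=100.0, diameter_um=1.0,
    area_scale_factor=3.0, spine_area_factor=1.5)


@dataclass(frozen=True)
class SomaParams:
    """Somatic spiking, adaptation and coloured-noise parameters."""

    e_l: float = -60.0  # mV
    v_th: float = -50.0  # mV
    v_spike: float = 0.0  # mV, value the potential is stepped to on a spike
    v_reset: float = -58.0  # mV, reset after the 0.2-ms spike hold
    spike_hold_ms: float = 0.2
    b: float = 200.0  # pA, adaptation increment per spike
    a: float = 0.8  # nS, adaptation coupling to membrane potential
    tau_w: float = 100.0  # ms
    tau_noise: float = 20.0  # ms
    sigma_noise: float = 35.0  # pA


@dataclass(frozen=True)
class SynapseParams:
    """Double-exponential AMPA/NMDA conductances and the Mg block."""

    g_ampa: float = 0.8  # nS
    g_nmda: float = 0.8  # nS
    e_syn: float = 0.0  # mV (AMPA and NMDA reversal)
    tau_rise_ampa: float = 0.2  # ms
    tau_decay_ampa: float = 3.0  # ms
    tau_rise_nmda: float = 2.0  # ms
    tau_decay_nmda: float = 60.0  # ms
    w_ampa: float = 0.5
    w_nmda: float = 0.05
    mg_mm: float = 1.0  # extracellular [Mg2+], mM
    mg_beta: float = 3.57  # mM
    mg_alpha: float = 0.062  # 1/mV
    mg_gamma: float = 0.0  # mV


def mg_block(v_mv: np.ndarray | float,
             params: SynapseParams = SynapseParams()) -> np.ndarray | float:
    """Voltage-dependent magnesium block factor of the NMDA receptor.

    1 / (1 + ([Mg]/beta) * exp(-alpha * (V - gamma))); strictly increasing
    in V, equal to 1 for [Mg] = 0.
    """
    v = np.asarray(v_mv, dtype=float)
    out = 1.0 / (1.0 + (params.mg_mm / params.mg_beta)
                 * np.exp(-params.mg_alpha * (v - params.mg_gamma)))
    return out if out.ndim else float(out)


@dataclass
class ConnectivityMap:
    """Assignment of encoder channels to dendrites.

    ``assignment[i]`` is the dendrite index of channel ``i``.  Structured
    maps assign contiguous CF blocks of equal size, so each dendrite is
    tuned to one frequency band.
    """

    assignment: np.ndarray
    n_dendrites: int = 10
    mode: str = "structured"

    @property
    def n_channels(self) -> int:
        return self.assignment.size

    def fan_in(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.n_dendrites)


def structured_connectivity(n_channels: int = 3000,
                            n_dendrites: int = 10) -> ConnectivityMap:
    """Tonotopic map: dendrite k receives the k-th contiguous channel block."""
    if n_channels % n_dendrites:
        raise ValueError("n_channels must be a multiple of n_dendrites")
    block = n_channels // n_dendrites
    return ConnectivityMap(
        assignment=np.repeat(np.arange(n_dendrites), block),
        n_dendrites=n_dendrites, mode="structured")


def randomized_connectivity(base: ConnectivityMap, mix_fraction: float,
                            seed: int) -> ConnectivityMap:
    """Mix a fraction of each dendrite's afferents across branches.

    A fraction ``mix_fraction`` of channels per dendrite is selected and
    their dendrite labels are randomly permuted among the selected set,
    which preserves every dendrite's total fan-in.  0 is the identity,
    1 a full shuffle (a channel then keeps its structured dendrite with
    probability ~1/n_dendrites).
    """
    if not 0.0 <= mix_fraction <= 1.0:
        raise ValueError("mix_fraction must lie in [0, 1]")
    if mix_fraction == 0.0:
        return ConnectivityMap(base.assignment.copy(), base.n_dendrites,
                               mode=base.mode)
    rng = np.random.default_rng(seed)
    assignment = base.assignment.copy()
    selected = []
    for d in range(base.n_dendrites):
        members = np.flatnonzero(assignment == d)
        k = int(round(mix_fraction * members.size))
        selected.append(rng.choice(members, size=k, replace=False))
    selected = np.concatenate(selected)
    labels = assignment[selected]
    assignment[selected] = rng.permutation(labels)
    return ConnectivityMap(assignment, base.n_dendrites,
                           mode=f"mixed({mix_fraction:g})")


@dataclass
class DendriticNeuron:
    """A simulatable soma + n-dendrite model (see :func:`build_neuron`)."""

    connectivity: ConnectivityMap
    soma: SomaParams = SomaParams()
    synapse: SynapseParams = SynapseParams()
    soma_geometry: CompartmentGeometry = SOMA_GEOMETRY
    dendrite_geometry: CompartmentGeometry = DENDRITE_GEOMETRY
    g_c: float = 0.8  # nS, axial coupling conductance
    nmda_on: bool = False
    weight_scale: float = 1.0

    @property
    def n_dendrites(self) -> int:
        return self.connectivity.n_dendrites


def build_neuron(connectivity: ConnectivityMap,
                 soma: SomaParams = SomaParams(),
                 synapse: SynapseParams = SynapseParams(),
                 g_c: float = 0.8,
                 nmda_on: bool = False,
                 weight_scale: float | None = None,
                 reference_fan_in: int = 300) -> DendriticNeuron:
    """Assemble the 11-compartment model.

    ``weight_scale`` multiplies both synaptic weights; by default it is
    ``reference_fan_in / actual_fan_in`` so that reduced encoder
    populations deliver the same total synaptic drive per dendrite as the
    full-scale model (300 afferents per dendrite).
    """
    fan = connectivity.fan_in()
    if np.any(fan == 0):
        raise ValueError("every dendrite must receive at least one channel")
    if weight_scale is None:
        weight_scale = reference_fan_in / float(fan.max())
    return DendriticNeuron(connectivity=connectivity, soma=soma,
                           synapse=synapse, g_c=g_c, nmda_on=nmda_on,
                           weight_scale=weight_scale)


@dataclass
class SimResult:
    """Traces and events from one simulation run.

    ``v_m`` has one column per compartment: column 0 is the soma, columns
    1..n are the dendrites.  ``s_ampa``/``s_nmda`` are the summed synaptic
    gating variables per dendrite.
    """

    t_ms: np.ndarray
    v_m: np.ndarray  # (n_steps, 1 + n_dendrites)
    spike_times_ms: np.ndarray
    s_ampa: np.ndarray  # (n_steps, n_dendrites)
    s_nmda: np.ndarray
    w: np.ndarray
    dt_ms: float
    seed: int

    @property
    def n_dendrites(self) -> int:
        return self.v_m.shape[1] - 1


@njit(cache=True)
def _neuron_kernel(spike_counts, dt, n_steps, n_d,
                   c_s, g_l_s, c_d, g_l_d, e_l, g_c,
                   v_th, v_spike, v_reset, hold_steps, b, a, tau_w,
                   tau_noise, sigma_noise,
                   g_ampa, g_nmda, e_syn, tau_r_a, tau_d_a, tau_r_n, tau_d_n,
                   w_ampa, w_nmda, nmda_on, mg_over_beta, alpha, gamma,
                   i_ext, seed):
    np.random.seed(seed)
    v_s = e_l
    v_d = np.full(n_d, e_l)
    w = 0.0
    i_noise = 0.0
    s_a = np.zeros(n_d)
    x_a = np.zeros(n_d)
    s_n = np.zeros(n_d)
    x_n = np.zeros(n_d)
    v_out = np.empty((n_steps, n_d + 1))
    s_a_out = np.empty((n_steps, n_d))
    s_n_out = np.empty((n_steps, n_d))
    w_out = np.empty(n_steps)
    spike_times = np.full(n_steps, -1.0)
    n_spk = 0
    hold = 0
    noise_step = sigma_noise * np.sqrt(2.0 / tau_noise) * np.sqrt(dt)
    for t in range(n_steps):
        # synaptic kinetics (per dendrite): rise variable jumps by the
        # weight for each presynaptic spike in this step
        for d in range(n_d):
            x_a[d] += w_ampa * spike_counts[t, d]
            s_a[d] += dt * (-s_a[d] / tau_d_a + x_a[d])
            x_a[d] += dt * (-x_a[d] / tau_r_a)
            if nmda_on:
                x_n[d] += w_nmda * spike_counts[t, d]
                s_n[d] += dt * (-s_n[d] / tau_d_n + x_n[d])
                x_n[d] += dt * (-x_n[d] / tau_r_n)
        # coloured somatic noise (OU)
        if sigma_noise > 0:
            i_noise += (-dt / tau_noise * i_noise
                        + noise_step * np.random.normal())
        # dendritic compartments
        i_axial_sum = 0.0
        new_v_d = np.empty(n_d)
        for d in range(n_d):
            i_syn = g_ampa * s_a[d] * (e_syn - v_d[d])
            if nmda_on:
                block = 1.0 / (1.0 + mg_over_beta
                               * np.exp(-alpha * (v_d[d] - gamma)))
                i_syn += g_nmda * s_n[d] * (e_syn - v_d[d]) * block
            i_ax = g_c * (v_s - v_d[d])
            i_axial_sum += g_c * (v_d[d] - v_s)
            new_v_d[d] = v_d[d] + dt / c_d * (
                -g_l_d * (v_d[d] - e_l) + i_ax + i_syn)
        # soma
        dw = dt / tau_w * (a * (v_s - e_l) - w)
        if hold > 0:
            hold -= 1
            if hold == 0:
                v_s = v_reset
        else:
            v_s = v_s + dt / c_s * (
                -g_l_s * (v_s - e_l) + i_axial_sum + i_noise - w
                + i_ext[t])
            if v_s > v_th:
                spike_times[n_spk] = t * dt
                n_spk += 1
                v_s = v_spike
                w += b
                hold = hold_steps
        w += dw
        v_d = new_v_d
        v_out[t, 0] = v_s
        for d in range(n_d):
            v_out[t, d + 1] = v_d[d]
            s_a_out[t, d] = s_a[d]
            s_n_out[t, d] = s_n[d]
        w_out[t] = w
    return v_out, s_a_out, s_n_out, w_out, spike_times[:n_spk]


def simulate(model: DendriticNeuron, raster: SpikeRaster | None,
             duration_ms: float | None = None, dt_ms: float = 0.1,
             seed: int = 0, i_ext_soma: float | np.ndarray = 0.0,
             noise_on: bool = True) -> SimResult:
    """Integrate the compartmental model driven by an encoder raster.

    ``i_ext_soma`` optionally injects an extra somatic current (pA),
    constant or per-step, used mainly for characterization.  ``noise_on``
    switches the somatic coloured noise.  Reproducible given ``seed``.
    """
    if raster is not None and raster.n_channels != model.connectivity.n_channels:
        raise ValueError(
            f"raster has {raster.n_channels} channels but connectivity "
            f"expects {model.connectivity.n_channels}")
    if duration_ms is None:
        if raster is None:
            raise ValueError("duration_ms required when no raster is given")
        duration_ms = raster.duration_ms
    n_steps = int(np.ceil(duration_ms / dt_ms))
    n_d = model.n_dendrites

    counts = np.zeros((n_steps, n_d))
    if raster is not None and raster.total_spikes():
        sizes = [t.size for t in raster.spikes]
        all_t = np.concatenate(raster.spikes)
        all_d = np.repeat(model.connectivity.assignment, sizes)
        idx = np.minimum((all_t / dt_ms).astype(np.int64), n_steps - 1)
        np.add.at(counts.ravel(), idx * n_d + all_d, 1.0)

    i_ext = np.broadcast_to(np.asarray(i_ext_soma, dtype=float),
                            (n_steps,)).copy()
    syn = model.synapse
    soma = model.soma
    sg, dg = model.soma_geometry, model.dendrite_geometry
    v, s_a, s_n, w, spikes = _neuron_kernel(
        counts, dt_ms, n_steps, n_d,
        sg.capacitance_pf, sg.leak_ns, dg.capacitance_pf, dg.leak_ns,
        soma.e_l, model.g_c,
        soma.v_th, soma.v_spike, soma.v_reset,
        max(1, int(round(soma.spike_hold_ms / dt_ms))),
        soma.b, soma.a, soma.tau_w,
        soma.tau_noise, soma.sigma_noise if noise_on else 0.0,
        syn.g_ampa, syn.g_nmda, syn.e_syn,
        syn.tau_rise_ampa, syn.tau_decay_ampa,
        syn.tau_rise_nmda, syn.tau_decay_nmda,
        syn.w_ampa * model.weight_scale, syn.w_nmda * model.weight_scale,
        model.nmda_on, syn.mg_mm / syn.mg_beta, syn.mg_alpha, syn.mg_gamma,
        i_ext, int(seed) % (2**31))
    if not np.all(np.isfinite(v)):
        bad_t, bad_c = np.argwhere(~np.isfinite(v))[0]
        raise FloatingPointError(
            f"non-finite membrane potential in compartment {bad_c} "
            f"at t = {bad_t * dt_ms:.2f} ms")
    return SimResult(t_ms=np.arange(n_steps) * dt_ms, v_m=v,
                     spike_times_ms=spikes, s_ampa=s_a, s_nmda=s_n, w=w,
                     dt_ms=dt_ms, seed=seed)


def count_spikes(result: SimResult, window_ms: tuple[float, float]) -> float:
    """Firing rate (Hz) of the somatic spike train inside ``window_ms``."""
    t0, t1 = window_ms
    if t1 <= t0:
        raise ValueError("window end must exceed its start")
    n = np.count_nonzero((result.spike_times_ms >= t0)
                         & (result.spike_times_ms < t1))
    return 1000.0 * n / (t1 - t0)
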