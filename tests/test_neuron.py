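from dataclasses import replace

import numpy as np
import pytest

from usvdend import neuron as nr
from tests.conftest import single_spike_raster


class TestMgBlock:
    def test_value_at_zero_mv(self):
        assert nr.mg_block(0.0) == pytest.approx(1 / (1 + 1 / 3.57),
                                                 rel=1e-9)

    def test_no_magnesium_means_no_block(self):
        p = replace(nr.SynapseParams(), mg_mm=0.0)
        v = np.linspace(-90, 40, 50)
        assert np.allclose(nr.mg_block(v, p), 1.0)

    def test_strictly_increasing_in_voltage(self):
        v = np.linspace(-90, 40, 200)
        out = nr.mg_block(v)
        assert np.all(np.diff(out) > 0)
        assert np.all((out > 0) & (out <= 1))


class TestGeometry:
    def test_capacitance_and_leak_from_area(self):
        g = nr.DENDRITE_GEOMETRY
        area = np.pi * 1.0 * 100.0 * 3.0 * 1.5 * 1e-8  # cm^2
        assert g.area_cm2 == pytest.approx(area)
        assert g.capacitance_pf == pytest.approx(0.5 * area * 1e6)
        assert g.leak_ns == pytest.approx(area / 20.0 * 1e6)
        # membrane time constant r_m * c_m = 10 ms for every compartment
        assert g.tau_m_ms == pytest.approx(10.0)
        assert nr.SOMA_GEOMETRY.tau_m_ms == pytest.approx(10.0)


class TestConnectivity:
    def test_structured_blocks(self):
        conn = nr.structured_connectivity(3000, 10)
        for k in range(10):
            assert np.all(conn.assignment[300 * k:300 * (k + 1)] == k)

    def test_randomize_zero_fraction_is_identity(self):
        base = nr.structured_connectivity(100, 10)
        out = nr.randomized_connectivity(base, 0.0, seed=1)
        assert np.array_equal(out.assignment, base.assignment)

    def test_fan_in_preserved_for_any_fraction(self):
        base = nr.structured_connectivity(200, 10)
        for frac in (0.2, 0.5, 1.0):
            out = nr.randomized_connectivity(base, frac, seed=2)
            assert np.array_equal(out.fan_in(), base.fan_in())

    def test_full_shuffle_retention_near_one_tenth(self):
        base = nr.structured_connectivity(300, 10)
        kept = [np.mean(nr.randomized_connectivity(base, 1.0, s).assignment
                        == base.assignment) for s in range(30)]
        assert np.mean(kept) == pytest.approx(0.1, abs=0.03)


class TestBuildNeuron:
    def test_nmda_off_means_zero_nmda_conductance(self, micro_model):
        raster = single_spike_raster(20, active=[0, 1])
        sim = nr.simulate(micro_model, raster, seed=0, noise_on=False)
        assert np.max(sim.s_nmda) == 0

    def test_weight_scale_conserves_drive(self):
        conn = nr.structured_connectivity(30, 10)
        model = nr.build_neuron(conn)
        assert model.weight_scale == pytest.approx(300 / 3)

    def test_axial_current_antisymmetry(self, micro_model):
        raster = single_spike_raster(20, active=[0])
        sim = nr.simulate(micro_model, raster, seed=0, noise_on=False)
        g_c = micro_model.g_c
        v_s = sim.v_m[:, 0]
        for d in range(10):
            v_d = sim.v_m[:, d + 1]
            soma_to_d = g_c * (v_s - v_d)
            d_to_soma = g_c * (v_d - v_s)
            assert np.allclose(soma_to_d, -d_to_soma)

    def test_channel_mismatch_rejected(self, micro_model):
        raster = single_spike_raster(15, active=[0])
        with pytest.raises(ValueError, match="channels"):
            nr.simulate(micro_model, raster, seed=0)


def somatic_peak(model, raster):
    sim = nr.simulate(model, raster, seed=0, noise_on=False)
    return np.max(sim.v_m[:, 0]) - model.soma.e_l


class TestSimulate:
    def test_rest_convergence_without_input(self, micro_model):
        sim = nr.simulate(micro_model, None, duration_ms=60, seed=0,
                          noise_on=False)
        # within 5 membrane time constants (r_m c_m = 10 ms) of silence
        assert np.allclose(sim.v_m[-1], micro_model.soma.e_l, atol=1e-3)
        assert sim.spike_times_ms.size == 0

    def test_dendritic_epsp_exceeds_somatic_epsp(self, micro_model):
        raster = single_spike_raster(20, active=[0])
        sim = nr.simulate(micro_model, raster, seed=0, noise_on=False)
        e_l = micro_model.soma.e_l
        peak_dend = np.max(sim.v_m[:, 1]) - e_l
        peak_soma = np.max(sim.v_m[:, 0]) - e_l
        assert peak_dend > peak_soma > 0
        # both return toward rest by the end of the window
        assert abs(sim.v_m[-1, 1] - e_l) < 0.2 * peak_dend

    def test_same_branch_integration_is_sublinear(self, micro_model):
        p0 = somatic_peak(micro_model, single_spike_raster(20, [0]))
        p1 = somatic_peak(micro_model, single_spike_raster(20, [1]))
        p_same = somatic_peak(micro_model, single_spike_raster(20, [0, 1]))
        assert p_same < p0 + p1

    def test_cross_branch_integration_closer_to_linear(self, micro_model):
        p0 = somatic_peak(micro_model, single_spike_raster(20, [0]))
        p1 = somatic_peak(micro_model, single_spike_raster(20, [1]))
        p2 = somatic_peak(micro_model, single_spike_raster(20, [2]))
        same = somatic_peak(micro_model, single_spike_raster(20, [0, 1]))
        diff = somatic_peak(micro_model, single_spike_raster(20, [0, 2]))
        ratio_same = same / (p0 + p1)
        ratio_diff = diff / (p0 + p2)
        assert abs(1 - ratio_diff) < abs(1 - ratio_same)

    def test_nmda_adds_inward_current(self, micro_model):
        raster = single_spike_raster(20, active=[0, 1])
        passive = somatic_peak(micro_model, raster)
        active = somatic_peak(replace(micro_model, nmda_on=True), raster)
        assert active >= passive

    def test_adaptation_lengthens_interspike_intervals(self, micro_model):
        sim = nr.simulate(micro_model, None, duration_ms=500, seed=0,
                          i_ext_soma=150.0, noise_on=False)
        assert sim.spike_times_ms.size >= 5
        isis = np.diff(sim.spike_times_ms[:6])
        assert np.all(np.diff(isis) >= 0)

    def test_zero_coupling_matches_single_compartment_oracle(self):
        conn = nr.structured_connectivity(20, 10)
        model = nr.build_neuron(conn, g_c=0.0)
        i_ext = 80.0
        sim = nr.simulate(model, None, duration_ms=200, seed=0,
                          i_ext_soma=i_ext, noise_on=False)
        # independent forward-Euler oracle of the adaptive soma alone
        soma, g = model.soma, model.soma_geometry
        dt = sim.dt_ms
        c_s, g_l = g.capacitance_pf, g.leak_ns
        v, w, hold = soma.e_l, 0.0, 0
        v_trace = np.empty(sim.t_ms.size)
        for t in range(sim.t_ms.size):
            dw = dt / soma.tau_w * (soma.a * (v - soma.e_l) - w)
            if hold > 0:
                hold -= 1
                if hold == 0:
                    v = soma.v_reset
            else:
                v += dt / c_s * (-g_l * (v - soma.e_l) + i_ext - w)
                if v > soma.v_th:
                    v = soma.v_spike
                    w += soma.b
                    hold = 2
            w += dw
            v_trace[t] = v
        assert np.allclose(sim.v_m[:, 0], v_trace, atol=1e-9)

    def test_determinism_and_seed_sensitivity(self, micro_model):
        raster = single_spike_raster(20, active=[0])
        a = nr.simulate(micro_model, raster, seed=5)
        b = nr.simulate(micro_model, raster, seed=5)
        c = nr.simulate(micro_model, raster, seed=6)
        assert np.array_equal(a.v_m, b.v_m)
        assert not np.array_equal(a.v_m, c.v_m)


class TestCountSpikes:
    def test_rate_arithmetic(self, micro_model):
        res = nr.SimResult(t_ms=np.arange(0, 100, 0.1),
                           v_m=np.zeros((1000, 11)),
                           spike_times_ms=np.array([10.0, 20.0, 30.0]),
                           s_ampa=np.zeros((1000, 10)),
                           s_nmda=np.zeros((1000, 10)),
                           w=np.zeros(1000), dt_ms=0.1, seed=0)
        assert nr.count_spikes(res, (0, 100)) == pytest.approx(30.0)
        # additivity over a partition
        parts = (nr.count_spikes(res, (0, 50)) * 50
                 + nr.count_spikes(res, (50, 100)) * 50)
        assert parts == pytest.approx(nr.count_spikes(res, (0, 100)) * 100)
        assert nr.count_spikes(res, (60, 100)) == 0

    def test_bad_window_rejected(self):
        res = nr.SimResult(t_ms=np.zeros(1), v_m=np.zeros((1, 2)),
                           spike_times_ms=np.array([]),
                           s_ampa=np.zeros((1, 1)), s_nmda=np.zeros((1, 1)),
                           w=np.zeros(1), dt_ms=0.1, seed=0)
        with pytest.raises(ValueError):
            nr.count_spikes(res, (10, 10))
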