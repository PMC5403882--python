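"""Engine tests: closed forms, determinism, linearity, refractoriness."""

import numpy as np
import pytest

from v1micro import lif as L
from v1micro import protocols as pr
from v1micro.network import CHANNEL_TAUS

from conftest import chain_graph


@pytest.fixture(scope="module")
def lif_params():
    return L.LIFParams()


class TestFICurve:
    def test_zero_below_rheobase(self, lif_params):
        # rheobase = (V_th - V_rest) / R = 15 mV / 0.04 GOhm
        assert L.lif_fi_rate(lif_params, 374.9) == 0.0
        assert L.lif_fi_rate(lif_params, 0.0) == 0.0

    def test_refractory_ceiling(self, lif_params):
        assert L.lif_fi_rate(lif_params, 1e9) <= 1000.0 / lif_params.tau_ref
        assert L.lif_fi_rate(lif_params, 1e6) == pytest.approx(
            1000.0 / lif_params.tau_ref, rel=0.01)

    @pytest.mark.parametrize("current", [380.0, 420.0, 500.0])
    def test_simulation_matches_closed_form(self, current, lif_params,
                                            single_neuron_graph):
        rec = L.simulate(single_neuron_graph,
                         L.Drives(const_current=current), 10000.0, dt=0.1,
                         seed=0)
        sim_rate = len(rec) / 10.0
        assert sim_rate == pytest.approx(L.lif_fi_rate(lif_params, current),
                                         rel=0.01)


class TestPoissonSource:
    def test_zero_rate_empty(self):
        assert len(L.poisson_spike_source(0.0, 1000.0, 0)) == 0

    def test_deterministic(self):
        t1 = L.poisson_spike_source(500.0, 1000.0, 7)
        t2 = L.poisson_spike_source(500.0, 1000.0, 7)
        assert np.array_equal(t1, t2)

    def test_count_statistics(self):
        counts = [len(L.poisson_spike_source(1000.0, 1000.0, s))
                  for s in range(100)]
        mean = np.mean(counts)
        # mean of 100 trials of Poisson(1000): SE = sqrt(1000/100)
        assert abs(mean - 1000.0) < 4.0 * np.sqrt(1000.0 / 100)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            L.poisson_spike_source(-1.0, 10.0)


class TestSingleSynapse:
    def test_psc_voltage_matches_closed_form(self):
        # neuron 0 spikes under constant drive; neuron 1 receives one
        # excitatory synapse (w=175.6 pA, tau=0.5 ms) and stays
        # subthreshold: its deflection is a sum of double exponentials
        w, tau_s, delay = 175.6, 0.5, 1.5
        g = chain_graph([w], [tau_s], [delay])
        dt = 0.1
        drive = np.array([500.0, 0.0])
        rec = L.simulate(g, L.Drives(const_current=drive), 200.0, dt=dt,
                         seed=0, record_v=[1])
        spikes = rec.times[rec.neurons == 0]
        assert len(spikes) > 2
        p = L.LIFParams()
        t_axis = np.arange(len(rec.v_trace)) * dt
        expected = np.full_like(t_axis, p.v_rest)
        for ts in spikes:
            t0 = ts + delay
            m = t_axis >= t0 + dt / 2  # arrival affects the next interval
            te = t_axis[m] - t0
            # V response to I(t) = w exp(-t/tau_s):
            # R w tau_s/(tau_s - tau_m) (exp(-t/tau_s) - exp(-t/tau_m))
            amp = p.R * w * tau_s / (tau_s - p.tau_m)
            expected[m] += amp * (np.exp(-te / tau_s)
                                  - np.exp(-te / p.tau_m))
        peak = np.max(np.abs(expected - p.v_rest))
        err = np.max(np.abs(rec.v_trace[:, 0] - expected))
        assert err < 1e-3 * peak

    def test_current_jump_equals_weight(self):
        # the PSC peak equals w at arrival: measured via the voltage slope
        # right after delivery of a very slow synapse
        w, tau_s = 100.0, 10.4
        g = chain_graph([w], [tau_s], [1.0])
        drive = np.array([500.0, 0.0])
        rec = L.simulate(g, L.Drives(const_current=drive), 50.0, dt=0.01,
                         seed=0, record_v=[1])
        p = L.LIFParams()
        v = rec.v_trace[:, 0]
        dv = np.diff(v) / 0.01
        # max dV/dt ~ R*w/tau_m (current jump w through R over tau_m)
        assert dv.max() == pytest.approx(p.R * w / p.tau_m, rel=0.05)


class TestLinearity:
    def test_superposition_of_synaptic_streams(self):
        # subthreshold dynamics are linear: a neuron receiving an
        # excitatory and an inhibitory synapse from the same driver
        # responds with exactly the sum of the single-synapse responses
        w = 30.0
        g = chain_graph([w, -w * 0.5, w, -w * 0.5],
                        [0.5, 6.0, 0.5, 6.0], [1.0, 2.0, 1.0, 2.0])
        # neuron 1 gets both synapses; neurons 2 and 3 one each
        g.post = np.array([1, 1, 2, 3], dtype=np.int32)
        d = np.zeros(5)
        d[0] = 450.0  # only the driver spikes; targets stay subthreshold
        rec = L.simulate(g, L.Drives(const_current=d), 300.0, dt=0.1,
                         seed=0, record_v=[1, 2, 3])
        v = rec.v_trace
        v_rest = L.LIFParams().v_rest
        lhs = v[:, 0] - v_rest
        rhs = (v[:, 1] - v_rest) + (v[:, 2] - v_rest)
        assert np.max(np.abs(lhs - rhs)) < 1e-9

    def test_nan_abort(self, single_neuron_graph):
        with pytest.raises(FloatingPointError):
            L.simulate(single_neuron_graph,
                       L.Drives(const_current=np.inf), 10.0, seed=0)


class TestNetworkRun:
    @pytest.fixture(scope="class")
    def spont(self, small_column):
        bg = pr.background_rate_array(small_column)
        return L.simulate(small_column, L.Drives(bg_rate=bg), 500.0,
                          seed=4)

    def test_no_isi_below_refractory(self, spont):
        p = L.LIFParams()
        order = np.lexsort((spont.times, spont.neurons))
        n, t = spont.neurons[order], spont.times[order]
        same = n[1:] == n[:-1]
        isi = np.diff(t)[same]
        assert len(isi) > 100
        assert isi.min() >= p.tau_ref

    def test_seed_reproducibility(self, small_column, spont):
        bg = pr.background_rate_array(small_column)
        rec2 = L.simulate(small_column, L.Drives(bg_rate=bg), 500.0,
                          seed=4)
        assert np.array_equal(spont.neurons, rec2.neurons)
        assert np.array_equal(spont.times, rec2.times)

    def test_no_drive_no_spikes(self, small_column):
        rec = L.simulate(small_column, L.Drives(), 100.0, seed=0)
        assert len(rec) == 0

    def test_dt_convergence(self, small_column):
        # halving dt changes the column-mean rate by < 2%
        bg = pr.background_rate_array(small_column)
        rates = []
        for dt in (0.1, 0.05):
            rec = L.simulate(small_column, L.Drives(bg_rate=bg), 1000.0,
                             dt=dt, seed=9)
            rates.append(np.sum(rec.times > 200.0)
                         / (small_column.n_neurons * 0.8))
        assert abs(rates[1] - rates[0]) / rates[0] < 0.02

    def test_delay_below_dt_rejected(self):
        g = chain_graph([10.0], [0.5], [0.05])
        with pytest.raises(ValueError, match="delays"):
            L.simulate(g, L.Drives(const_current=0.0), 10.0, dt=0.1)


class TestChannels:
    def test_channel_table_covers_model_taus(self):
        assert set(CHANNEL_TAUS) == {0.5, 2.0, 3.4, 4.3, 6.0, 6.2, 7.5,
                                     10.4}
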