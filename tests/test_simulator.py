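import math

import numpy as np
import pytest

from striatnet.morphology import BranchOrder, Compartment, MorphologyScaffold
from striatnet.netbuild import PlacementParams, build_network
from striatnet.simulator import (
    CellDynamics,
    SimConfig,
    StimSet,
    SynapseParams,
    default_synapses,
    paired_ipsp_run,
    run_network,
    step_cell,
    synapse_conductance,
    synapse_peak_time,
)


class TestSynapseConductance:
    P = SynapseParams("GABA_A", 1.0, -60.0, 0.5, 7.5)

    def test_zero_at_onset(self):
        assert synapse_conductance(0.0, self.P) == pytest.approx(0.0)

    def test_peak_at_closed_form_time_with_value_gmax(self):
        tp = synapse_peak_time(0.5, 7.5)
        expected = math.log(7.5 / 0.5) * 0.5 * 7.5 / (7.5 - 0.5)
        assert tp == pytest.approx(expected)
        assert synapse_conductance(tp, self.P) == pytest.approx(1.0)
        # strictly smaller slightly off-peak
        assert synapse_conductance(tp * 0.8, self.P) < 1.0
        assert synapse_conductance(tp * 1.2, self.P) < 1.0

    def test_null_synapse(self):
        p = SynapseParams("AMPA", 0.0, 0.0, 0.5, 2.5)
        t = np.linspace(0, 20, 50)
        assert np.all(synapse_conductance(t, p) == 0.0)

    def test_invalid_time_constants(self):
        with pytest.raises(ValueError):
            SynapseParams("AMPA", 1.0, 0.0, 3.0, 2.0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            synapse_conductance(-1.0, self.P)


def _single_compartment(C=100.0, gL=5.0, e_leak=-70.0):
    sc = MorphologyScaffold(
        "MSN", (Compartment(0, BranchOrder.SOMA, None, 16.0, 16.0),)
    )
    return CellDynamics(
        scaffold=sc, parent=np.array([-1]), C=np.array([C]), gL=np.array([gL]),
        g_ax=np.array([0.0]), e_leak=e_leak, v_thresh=1e9, v_reset=e_leak, t_ref=1.0,
    )


class TestStepCell:
    def test_rest_is_fixed_point(self):
        dyn = _single_compartment()
        V = np.array([-70.0])
        for _ in range(100):
            V, spiked = step_cell(dyn, V, 0.1)
        assert V[0] == pytest.approx(-70.0)
        assert not spiked

    def test_current_step_matches_rc_closed_form(self):
        # V(t) = EL + I*R*(1 - exp(-t/tau)) for a single RC compartment
        C, gL, I = 100.0, 5.0, 50.0
        dyn = _single_compartment(C=C, gL=gL)
        tau, R = C / gL, 1.0 / gL
        dt = 0.01
        V = np.array([-70.0])
        ts, vs = [], []
        for i in range(4000):
            V, _ = step_cell(dyn, V, dt, bias_pA=I)
            ts.append((i + 1) * dt)
            vs.append(V[0])
        expected = -70.0 + I * R * (1 - np.exp(-np.array(ts) / tau))
        assert np.max(np.abs(np.array(vs) - expected)) < 0.02  # mV

    def test_conductance_step_relaxes_to_weighted_mean(self):
        # steady state of leak + constant synaptic conductance
        C, gL, g, E = 100.0, 5.0, 10.0, 0.0
        dyn = _single_compartment(C=C, gL=gL)
        V = np.array([-70.0])
        for _ in range(20000):
            V, _ = step_cell(dyn, V, 0.05, g_syn=np.array([g]), e_syn=E)
        assert V[0] == pytest.approx((gL * -70.0 + g * E) / (gL + g), abs=1e-6)

    def test_nonfinite_state_aborts(self):
        dyn = _single_compartment()
        with pytest.raises(FloatingPointError):
            step_cell(dyn, np.array([np.nan]), 0.1)


@pytest.fixture(scope="module")
def iso_network():
    """Two isolated MSNs (no wiring) for single-cell network studies."""
    return build_network(
        PlacementParams(n_per_side=2, spacing=500.0, seed=0), seed=0,
        lateral=False, feedforward=False,
    )


def _gaba_deflection(iso_network, comp, g=0.5, hold_pA=150.0, dt=0.05):
    stim = StimSet()
    stim.add_bias("msn", 0, hold_pA)
    stim.add_train("msn", 0, comp, "GABA_A", np.array([150.0]), g)
    res = run_network(
        iso_network, stim,
        SimConfig(duration=260.0, dt=dt, lateral_on=False, feedforward_on=False,
                  record_msn=[0]),
    )
    tr = res.traces.trace("msn", 0)
    ref = StimSet()
    ref.add_bias("msn", 0, hold_pA)
    res0 = run_network(
        iso_network, ref,
        SimConfig(duration=260.0, dt=dt, lateral_on=False, feedforward_on=False,
                  record_msn=[0]),
    )
    diff = tr - res0.traces.trace("msn", 0)
    return diff


class TestCableResponse:
    def test_distal_event_attenuates_at_soma(self, iso_network):
        at_soma = np.abs(_gaba_deflection(iso_network, comp=0)).max()
        at_tip = np.abs(_gaba_deflection(iso_network, comp=13)).max()
        assert at_tip < at_soma

    def test_amplitude_monotone_in_gmax(self, iso_network):
        amps = [np.abs(_gaba_deflection(iso_network, 5, g=g)).max()
                for g in (0.2, 0.4, 0.8)]
        assert amps[0] < amps[1] < amps[2]

    def test_amplitude_monotone_in_contact_count(self, iso_network):
        def amp(n_contacts):
            stim = StimSet()
            stim.add_bias("msn", 0, 150.0)
            for _ in range(n_contacts):
                stim.add_train("msn", 0, 5, "GABA_A", np.array([150.0]), 0.4)
            res = run_network(iso_network, stim, SimConfig(
                duration=260.0, dt=0.05, lateral_on=False, feedforward_on=False,
                record_msn=[0]))
            return res.traces.trace("msn", 0)

        base = amp(0)
        one = np.abs(amp(1) - base).max()
        two = np.abs(amp(2) - base).max()
        assert one < two

    def test_subthreshold_linearity(self, iso_network):
        # tiny conductances: response to two events ~ sum of single responses
        d_a = _gaba_deflection(iso_network, 3, g=0.01)
        d_b = _gaba_deflection(iso_network, 13, g=0.01)
        stim = StimSet()
        stim.add_bias("msn", 0, 150.0)
        stim.add_train("msn", 0, 3, "GABA_A", np.array([150.0]), 0.01)
        stim.add_train("msn", 0, 13, "GABA_A", np.array([150.0]), 0.01)
        res = run_network(iso_network, stim, SimConfig(
            duration=260.0, dt=0.05, lateral_on=False, feedforward_on=False,
            record_msn=[0]))
        ref = StimSet()
        ref.add_bias("msn", 0, 150.0)
        res0 = run_network(iso_network, ref, SimConfig(
            duration=260.0, dt=0.05, lateral_on=False, feedforward_on=False,
            record_msn=[0]))
        d_ab = res.traces.trace("msn", 0) - res0.traces.trace("msn", 0)
        err = np.abs(d_ab - (d_a + d_b)).max()
        assert err < 0.02 * np.abs(d_ab).max() + 1e-9

    def test_self_convergence_under_dt_refinement(self, iso_network):
        coarse = _gaba_deflection(iso_network, 5, dt=0.1)
        fine = _gaba_deflection(iso_network, 5, dt=0.05)
        # compare on the shared grid
        err = np.abs(coarse - fine[::2]).max()
        assert err < 0.05 * np.abs(fine).max() + 1e-4


@pytest.fixture(scope="module")
def driven_network():
    net = build_network(PlacementParams(n_per_side=3, seed=21), seed=21,
                        lateral=True, feedforward=True, cortical=False)
    stim = StimSet()
    rng = np.random.default_rng(0)
    # strong noisy soma drive so MSNs and FSIs spike
    for c in range(net.n_msn):
        stim.add_bias("msn", c, float(rng.uniform(220.0, 260.0)))
    for c in range(net.n_fsi):
        stim.add_bias("fsi", c, float(rng.uniform(50.0, 70.0)))
    return net, stim


class TestNetworkRun:
    def test_no_input_no_spikes(self):
        net = build_network(PlacementParams(n_per_side=2, seed=0), seed=0)
        res = run_network(net, StimSet(), SimConfig(duration=50.0, dt=0.1))
        assert res.raster.total("msn") == 0
        assert res.raster.total("fsi") == 0

    def test_same_config_bit_identical(self, driven_network):
        net, stim = driven_network
        cfg = SimConfig(duration=300.0, dt=0.1)
        a = run_network(net, stim, cfg)
        b = run_network(net, stim, cfg)
        assert np.array_equal(a.raster.cells_times("msn")[1],
                              b.raster.cells_times("msn")[1])
        assert np.array_equal(a.raster.cells_times("msn")[0],
                              b.raster.cells_times("msn")[0])

    def test_lateral_toggle_only_silences_msn_sourced_events(self, driven_network):
        net, stim = driven_network
        on = run_network(net, stim, SimConfig(
            duration=300.0, dt=0.1, lateral_on=True, feedforward_on=True,
            record_events=True))
        off = run_network(net, stim, SimConfig(
            duration=300.0, dt=0.1, lateral_on=False, feedforward_on=True,
            record_events=True))
        on_fsi = [e for e in on.event_log if e[1] == "fsi"]
        off_fsi = [e for e in off.event_log if e[1] == "fsi"]
        assert off_fsi == on_fsi  # feedforward deliveries unchanged
        assert all(e[1] == "fsi" for e in off.event_log)  # no msn-sourced events
        assert any(e[1] == "msn" for e in on.event_log)

    def test_mismatched_stim_raises(self, driven_network):
        net, _ = driven_network
        stim = StimSet()
        stim.add_train("msn", net.n_msn + 5, 0, "AMPA", np.array([10.0]), 1.0)
        with pytest.raises(ValueError, match="out of range"):
            run_network(net, stim, SimConfig(duration=10.0, dt=0.1))

    def test_raster_times_within_duration(self, driven_network):
        net, stim = driven_network
        res = run_network(net, stim, SimConfig(duration=200.0, dt=0.1))
        _, times = res.raster.cells_times("msn")
        assert len(times) > 0
        assert times.min() >= 0.0 and times.max() <= 200.0


class TestPairedIpspRun:
    def test_silent_presyn_raises(self):
        net = build_network(PlacementParams(n_per_side=2, seed=1), seed=1)
        with pytest.raises(RuntimeError, match="did not spike"):
            paired_ipsp_run(net, StimSet(),
                            SimConfig(duration=50.0, dt=0.1, record_msn="all"),
                            "msn", 0)

    def test_difference_zero_before_first_spike_plus_delay(self):
        net = build_network(PlacementParams(n_per_side=3, seed=2), seed=2)
        stim = StimSet()
        stim.add_bias("msn", 0, 260.0)  # presyn above threshold
        for c in range(1, net.n_msn):
            stim.add_bias("msn", c, 100.0)
        paired = paired_ipsp_run(
            net, stim, SimConfig(duration=120.0, dt=0.05, record_msn="all",
                                 lateral_on=False, feedforward_on=False),
            "msn", 0)
        dt = paired.dt
        cut = int((paired.t_first_spike + net.topology.delay) / dt)
        for cell in range(1, net.n_msn):
            d = (paired.result_on.traces.trace("msn", cell)
                 - paired.result_off.traces.trace("msn", cell))
            assert np.all(d[:cut] == 0.0)

    def test_invalid_presyn_pop(self):
        net = build_network(PlacementParams(n_per_side=2, seed=1), seed=1)
        with pytest.raises(ValueError):
            paired_ipsp_run(net, StimSet(), SimConfig(duration=10.0, dt=0.1),
                            "cortex", 0)
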