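"""0-D network: element values, periodic solver, Windkessel, PD statistic."""

import numpy as np
import pytest

from conftest import make_mirror_network
from lumenpd.geometry import PlaneSet, place_planes
from lumenpd.hemodynamics import (
    BloodProperties,
    FlowWaveform,
    NetworkElement,
    NetworkError,
    NetworkModel,
    NetworkNode,
    SolverError,
    WindkesselOutlet,
    build_network,
    calibrate_windkessel,
    pd_statistic,
    plane_pressures,
    simulate,
    volume_balance,
)
from lumenpd.synthetic import nominal_dissection_model


MMHG_PER_PA = 1.0 / 133.322


def clinical_resistance_oracle(mu_pa_s, length_m, radius_m) -> float:
    """Independent unit conversion: Poiseuille in SI, then Pa.s/m^3 ->
    mmHg.s/mL via (Pa -> mmHg) and (m^3 -> 1e6 mL)."""
    r_si = 8.0 * mu_pa_s * length_m / (np.pi * radius_m**4)
    return r_si * MMHG_PER_PA / 1e6


class TestFlowWaveform:
    def test_default_aortic_mean_matches_cardiac_output(self):
        wave = FlowWaveform.default_aortic(cardiac_output_l_min=5.0)
        assert wave.mean_flow == pytest.approx(5000.0 / 60.0, rel=1e-3)
        assert wave.samples.min() < 0  # valve-closure reverse lobe

    def test_periodicity_enforced(self):
        with pytest.raises(ValueError, match="periodic"):
            FlowWaveform(period=1.0, samples=np.array([0.0, 1.0, 2.0]))

    def test_mean_flow_must_be_forward(self):
        with pytest.raises(ValueError, match="mean flow"):
            FlowWaveform(period=1.0, samples=np.array([-1.0, -1.0, -1.0]))


class TestBuildNetwork:
    def test_segment_resistance_matches_unit_conversion_oracle(self, single_outlet):
        from lumenpd.geometry import Centerline, DissectionModel, Station, Tear

        area = np.pi * 10.0**2  # r_eq = 10 mm
        pts = np.array([[0, 0, 0], [0, 0, -120.0]])
        cl = Centerline(points=pts, landmark_arc=0.0)
        model = DissectionModel(
            centerline=cl,
            stations=[Station(0.0, area, area), Station(100.0, area, area)],
            tears=[Tear(0.0, 70.0, is_primary=True)],
            inlet_arc=0.0,
        )
        net = build_network(model, outlets=[(100.0, single_outlet)])
        tl_seg = [
            e
            for e in net.elements
            if e.kind == "segment" and net.nodes[e.node_a].lumen == "TL"
        ][0]
        expected = clinical_resistance_oracle(0.004, 0.1, 0.01)
        assert tl_seg.resistance == pytest.approx(expected, rel=1e-12)
        # inertance: rho * L / A in SI, same conversion factor
        li = 1060.0 * 0.1 / (area * 1e-6) * MMHG_PER_PA / 1e6
        assert tl_seg.inertance == pytest.approx(li, rel=1e-12)

    def test_symmetric_lumens_give_pairwise_equal_elements(self, single_outlet):
        from lumenpd.geometry import Centerline, DissectionModel, Station, Tear

        area = 300.0
        pts = np.array([[0, 0, 0], [0, 0, -320.0]])
        cl = Centerline(points=pts, landmark_arc=0.0)
        stations = [Station(s, area, area) for s in np.linspace(0, 300, 11)]
        model = DissectionModel(
            centerline=cl,
            stations=stations,
            tears=[Tear(0.0, 80.0, is_primary=True), Tear(300.0, 80.0)],
            inlet_arc=0.0,
        )
        net = build_network(model, outlets=[(300.0, single_outlet)])
        tl = sorted(
            (e.resistance, e.inertance)
            for e in net.elements
            if e.kind == "segment" and net.nodes[e.node_a].lumen == "TL"
        )
        fl = sorted(
            (e.resistance, e.inertance)
            for e in net.elements
            if e.kind == "segment" and net.nodes[e.node_a].lumen == "FL"
        )
        assert tl == pytest.approx(fl)

    def test_thrombosed_stations_have_no_fl_nodes(self, single_outlet):
        model = nominal_dissection_model(thrombosis_extent=(150.0, 260.0))
        net = build_network(model, outlets=[(model.stations[-1].arc_mm, single_outlet)])
        fl_arcs = [n.arc_mm for n in net.nodes if n.lumen == "FL"]
        assert not any(150.0 <= a <= 260.0 for a in fl_arcs)

    def test_fully_thrombosed_fl_is_rejected(self, single_outlet):
        model = nominal_dissection_model(thrombosis_extent=(0.0, 1000.0))
        with pytest.raises(NetworkError, match="thrombosed"):
            build_network(model, outlets=[(400.0, single_outlet)])

    def test_tears_sealed_by_thrombus_leave_fl_unfed(self, single_outlet):
        # thrombus covers the only tear position -> no patent communication
        model = nominal_dissection_model(
            reentry_tears=(),
            thrombosis_extent=(0.0, 80.0),
        )
        with pytest.raises(NetworkError, match="patent tear"):
            build_network(model, outlets=[(400.0, single_outlet)])

    def test_missing_outlets_rejected(self, nominal_model):
        with pytest.raises(NetworkError, match="outlet"):
            build_network(nominal_model)


class TestSimulate:
    def test_steady_windkessel_reaches_closed_form_pressure(self):
        wk = WindkesselOutlet(0.0521, 0.93 - 0.0521, 0.8, 0.0)
        net = NetworkModel(
            nodes=[NetworkNode("TL", 0.0)], elements=[], inlet=0, outlets=[(0, wk)]
        )
        res = simulate(
            net, FlowWaveform.steady(100.0), max_cycles=60, tol=1e-3
        )
        assert res.node_pressures[0, -1] == pytest.approx(93.0, abs=0.1)

    def test_steady_chain_matches_linear_circuit_oracle(self):
        # five series resistances into one Windkessel, constant inflow:
        # P_k = P_out + Q * sum(R downstream of node k)
        rs = [4e-4, 6e-4, 3e-4, 8e-4, 5e-4]
        nodes = [NetworkNode("TL", 30.0 * i) for i in range(6)]
        elements = [
            NetworkElement(i, i + 1, rs[i], inertance=1e-3) for i in range(5)
        ]
        wk = WindkesselOutlet(0.05, 1.0, 1.0, 0.0)
        net = NetworkModel(nodes=nodes, elements=elements, inlet=0, outlets=[(5, wk)])
        q = 90.0
        res = simulate(net, FlowWaveform.steady(q), max_cycles=80, tol=1e-5)
        p_out = q * (wk.r_proximal + wk.r_distal)
        expected = [p_out + q * sum(rs[i:]) for i in range(6)]
        np.testing.assert_allclose(
            res.node_pressures[:, -1], expected, rtol=1e-8
        )

    def test_linear_limit_matches_direct_circuit_solve(
        self, nominal_model, calibrated_outlets
    ):
        # quadratic tear terms zeroed + steady inflow: the periodic state
        # is the solution of the pure resistance network (conductance
        # Laplacian with Windkessel total resistances to the reference)
        distal = nominal_model.stations[-1].arc_mm
        net = build_network(
            nominal_model,
            outlets=[
                (distal, calibrated_outlets[0], "TL"),
                (distal, calibrated_outlets[1], "FL"),
            ],
        )
        for e in net.elements:
            e.quad_coeff = 0.0
        q_in = 85.0
        res = simulate(
            net, FlowWaveform.steady(q_in), max_cycles=200, tol=1e-7
        )
        n = len(net.nodes)
        g = np.zeros((n, n))
        b = np.zeros(n)
        for e in net.elements:
            c = 1.0 / e.resistance
            g[e.node_a, e.node_a] += c
            g[e.node_b, e.node_b] += c
            g[e.node_a, e.node_b] -= c
            g[e.node_b, e.node_a] -= c
        for node, wk in net.outlets:
            c = 1.0 / wk.total_resistance
            g[node, node] += c
            b[node] += c * wk.p_distal
        b[net.inlet] += q_in
        expected = np.linalg.solve(g, b)
        np.testing.assert_allclose(
            res.node_pressures[:, -1], expected, rtol=1e-8
        )

    def test_flow_conservation_on_nominal_network(
        self, nominal_model, calibrated_outlets, inlet_waveform
    ):
        distal = nominal_model.stations[-1].arc_mm
        net = build_network(
            nominal_model,
            outlets=[
                (distal, calibrated_outlets[0], "TL"),
                (distal, calibrated_outlets[1], "FL"),
            ],
        )
        res = simulate(net, inlet_waveform, max_cycles=30, tol=0.01)
        v_in, v_out, err = volume_balance(res)
        assert err < 1e-3
        assert v_in == pytest.approx(
            inlet_waveform.mean_flow * inlet_waveform.period, rel=1e-6
        )

    def test_mirror_symmetric_network_has_null_pd(self, single_outlet, inlet_waveform):
        net, planes = make_mirror_network(single_outlet)
        res = simulate(net, inlet_waveform, max_cycles=30, tol=0.01)
        waves = plane_pressures(res, planes)
        for pid in planes.ids:
            _, peak = pd_statistic(waves[pid]["tl"], waves[pid]["fl"])
            assert abs(peak) < 1e-6

    def test_max_pd_converged_in_time_step(
        self, nominal_model, calibrated_outlets, inlet_waveform
    ):
        # halving dt moves the per-plane max PD by < 0.5%
        distal = nominal_model.stations[-1].arc_mm
        net = build_network(
            nominal_model,
            outlets=[
                (distal, calibrated_outlets[0], "TL"),
                (distal, calibrated_outlets[1], "FL"),
            ],
        )
        planes = place_planes(nominal_model.centerline, 12)

        def max_pd(dt_steps):
            res = simulate(
                net,
                inlet_waveform,
                max_cycles=30,
                dt=inlet_waveform.period / dt_steps,
                tol=0.01,
            )
            waves = plane_pressures(res, planes)
            return np.array(
                [pd_statistic(waves[p]["tl"], waves[p]["fl"])[1] for p in planes.ids]
            )

        coarse, fine = max_pd(1000), max_pd(2000)
        assert np.all(np.abs(fine - coarse) / np.abs(fine) < 0.005)

    def test_dt_must_resolve_the_cycle(self, single_outlet):
        net = NetworkModel(
            nodes=[NetworkNode("TL", 0.0)],
            elements=[],
            inlet=0,
            outlets=[(0, single_outlet)],
        )
        with pytest.raises(ValueError, match="period/200"):
            simulate(net, FlowWaveform.steady(80.0), dt=0.1)

    def test_nonconvergence_raises_with_history(self):
        # huge RC time constant and a single allowed cycle
        wk = WindkesselOutlet(0.05, 1.0, 500.0, 0.0)
        net = NetworkModel(
            nodes=[NetworkNode("TL", 0.0)], elements=[], inlet=0, outlets=[(0, wk)]
        )
        with pytest.raises(SolverError, match="periodic") as exc:
            simulate(net, FlowWaveform.default_aortic(), max_cycles=2, tol=1e-6)
        assert isinstance(exc.value.history, list)


class TestCalibration:
    def test_pressure_targets_reached(self, single_outlet, inlet_waveform):
        net = NetworkModel(
            nodes=[NetworkNode("TL", 0.0)],
            elements=[],
            inlet=0,
            outlets=[(0, single_outlet)],
        )
        res = simulate(net, inlet_waveform, max_cycles=40, tol=0.01)
        p = res.node_pressures[0]
        assert p.max() == pytest.approx(120.0, abs=2.0)
        assert p.min() == pytest.approx(80.0, abs=2.0)

    def test_halving_compliance_raises_pulse_pressure(
        self, single_outlet, inlet_waveform
    ):
        def pp(c):
            wk = WindkesselOutlet(
                single_outlet.r_proximal, single_outlet.r_distal, c
            )
            net = NetworkModel(
                nodes=[NetworkNode("TL", 0.0)],
                elements=[],
                inlet=0,
                outlets=[(0, wk)],
            )
            res = simulate(net, inlet_waveform, max_cycles=40, tol=0.01)
            p = res.node_pressures[0]
            return p.max() - p.min()

        c0 = single_outlet.compliance
        assert pp(c0 / 2) > pp(c0) > pp(2 * c0)

    def test_unphysiologic_targets_rejected(self, inlet_waveform):
        with pytest.raises(ValueError, match="systolic"):
            calibrate_windkessel(80.0, 120.0, inlet_waveform)

    def test_splits_must_sum_to_one(self, inlet_waveform):
        with pytest.raises(ValueError, match="sum to 1"):
            calibrate_windkessel(120.0, 80.0, inlet_waveform, splits=(0.5, 0.4))


@pytest.fixture(scope="module")
def steady_chain_result():
    rs = [5e-4] * 4
    nodes = [NetworkNode("TL", 100.0 * i) for i in range(5)]
    elements = [NetworkElement(i, i + 1, rs[i]) for i in range(4)]
    wk = WindkesselOutlet(0.05, 1.0, 1.0, 0.0)
    net = NetworkModel(nodes=nodes, elements=elements, inlet=0, outlets=[(4, wk)])
    return simulate(net, FlowWaveform.steady(100.0), max_cycles=80, tol=1e-5)


class TestPlanePressures:
    def test_plane_at_node_returns_node_waveform(self, steady_chain_result):
        planes = PlaneSet(
            ids=["Pa"], arc_positions=np.array([200.0]), normals=np.eye(3)[:1]
        )
        waves = plane_pressures(steady_chain_result, planes)
        np.testing.assert_allclose(
            waves["Pa"]["tl"], steady_chain_result.node_pressures[2], rtol=1e-12
        )
        assert waves["Pa"]["fl"] is None  # no FL in this network

    def test_midway_plane_interpolates_linearly(self, steady_chain_result):
        planes = PlaneSet(
            ids=["Pm"], arc_positions=np.array([150.0]), normals=np.eye(3)[:1]
        )
        waves = plane_pressures(steady_chain_result, planes)
        mid = 0.5 * (
            steady_chain_result.node_pressures[1]
            + steady_chain_result.node_pressures[2]
        )
        np.testing.assert_allclose(waves["Pm"]["tl"], mid, rtol=1e-12)

    def test_plane_outside_extent_flagged_missing(self, steady_chain_result):
        planes = PlaneSet(
            ids=["Px"], arc_positions=np.array([900.0]), normals=np.eye(3)[:1]
        )
        waves = plane_pressures(steady_chain_result, planes)
        assert waves["Px"]["tl"] is None

    def test_thrombosed_gap_marks_fl_missing(
        self, single_outlet, calibrated_outlets, inlet_waveform
    ):
        model = nominal_dissection_model(thrombosis_extent=(150.0, 260.0))
        distal = model.stations[-1].arc_mm
        net = build_network(
            model,
            outlets=[
                (distal, calibrated_outlets[0], "TL"),
                (distal, calibrated_outlets[1], "FL"),
            ],
        )
        res = simulate(net, inlet_waveform, max_cycles=30, tol=0.01)
        planes = place_planes(model.centerline, 12)
        waves = plane_pressures(res, planes)
        in_gap = [
            pid
            for pid, pos, _ in planes
            if 160.0 <= pos <= 250.0
        ]
        assert in_gap, "expected measurement planes inside the thrombosed gap"
        for pid in planes.ids:
            pos = planes.arc_positions[planes.ids.index(pid)]
            if pid in in_gap:
                assert waves[pid]["fl"] is None
            elif pos < 140.0 or pos > 270.0:
                assert waves[pid]["fl"] is not None


class TestPdStatistic:
    def test_identical_waveforms_are_null(self):
        w = np.linspace(80, 120, 50)
        pd_wave, peak = pd_statistic(w, w)
        assert np.all(pd_wave == 0) and peak == 0.0

    def test_sinusoidal_closed_form(self):
        t = np.linspace(0, 2 * np.pi, 2001)
        tl = 100 + 20 * np.sin(t)
        fl = 100 + 10 * np.sin(t)
        _, peak = pd_statistic(tl, fl)
        assert peak == pytest.approx(10.0, abs=1e-6)

    def test_signed_versus_absolute_maximum(self):
        t = np.linspace(0, 2 * np.pi, 2001)
        tl = 100 - 15 * np.sin(t)
        fl = 100.0 + np.zeros_like(t)
        _, signed = pd_statistic(tl, fl)
        _, absolute = pd_statistic(tl, fl, signed=False)
        assert signed == pytest.approx(15.0, abs=1e-4)
        assert absolute == pytest.approx(15.0, abs=1e-4)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="grids"):
            pd_statistic(np.zeros(10), np.zeros(11))
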