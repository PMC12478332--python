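import numpy as np
import pytest

from infusekit.manifold import PortMap, SegmentSpec, build_manifold
from infusekit.transport import DrugSpec, GridSpec, TransportSimulator, inlet_mixing, simulate


def tube(length=100.0, radius=0.5, port_x=0.0):
    return build_manifold([SegmentSpec(length, radius, "tube")], PortMap({1: port_x}))


def test_inlet_mixing_dilution_ratio():
    drugs = {1: DrugSpec("a", syringe_conc=1.0)}
    c = inlet_mixing(10.0, {1: 1.0}, drugs, port=1)
    assert c["a"] == pytest.approx(1.0 / 11.0)


def test_inlet_mixing_no_inflow_stays_zero():
    drugs = {1: DrugSpec("a")}
    assert inlet_mixing(10.0, {1: 0.0}, drugs, port=1)["a"] == 0.0


def test_inlet_mixing_two_junction_flux_weighted():
    # drug a enters at port 2 (upstream), drug b at port 1; concentrations at
    # port 1's junction follow a hand mass balance on the two-junction chain
    drugs = {2: DrugSpec("a"), 1: DrugSpec("b")}
    rates = {2: 1.0, 1: 2.0}
    up = inlet_mixing(10.0, rates, drugs, port=2)
    assert up["a"] == pytest.approx(1.0 / 11.0)
    down = inlet_mixing(10.0, rates, drugs, port=1, upstream_conc=up)
    # a: 11 * (1/11) / 13 ; b: 2 * 1 / 13
    assert down["a"] == pytest.approx(1.0 / 13.0)
    assert down["b"] == pytest.approx(2.0 / 13.0)


def test_inlet_mixing_zero_flow_at_active_port_raises():
    drugs = {1: DrugSpec("a")}
    with pytest.raises(ZeroDivisionError):
        inlet_mixing(0.0, {1: 0.0}, drugs, port=1)


def test_zero_state_zero_inflow_stays_zero():
    sim = TransportSimulator(tube(), {1: DrugSpec("a")}, GridSpec(dx_mm=1.0), (5.0, {1: 0.0}))
    sim.advance(60.0)
    assert np.all(sim.state.conc == 0.0)


def test_uniform_steady_state_unchanged():
    """A primed steady profile under steady flows stays put."""
    sim = TransportSimulator(tube(), {1: DrugSpec("a")}, GridSpec(dx_mm=1.0), (10.0, {1: 1.0}))
    sim.prime_to_steady_state()
    before = sim.state.conc.copy()
    sim.advance(120.0)
    assert np.max(np.abs(sim.state.conc - before)) < 1e-10


def test_steady_tip_concentration_is_flux_weighted_mix_any_grid():
    for dx in (2.0, 0.5):
        sim = TransportSimulator(
            tube(length=60.0), {1: DrugSpec("a")}, GridSpec(dx_mm=dx, dt_s=2.0), (10.0, {1: 1.0})
        )
        sim.advance(6000.0)  # far past breakthrough at ~0.9 mm/s... long enough
        assert sim.tip_concentration(0) == pytest.approx(1.0 / 11.0, rel=1e-6)


def test_mass_conservation_per_step():
    man, drugs, rates = _adult()
    sim = TransportSimulator(man, drugs, GridSpec(dx_mm=0.5, dt_s=0.5), rates)
    for _ in range(30):
        m0 = sim.mass_in_domain().copy()
        in0, out0 = sim.mass_in.copy(), sim.mass_out.copy()
        sim.advance(10.0)
        lhs = sim.mass_in_domain() - m0
        rhs = (sim.mass_in - in0) - (sim.mass_out - out0)
        scale = max(sim.mass_in.max(), 1e-12)
        assert np.all(np.abs(lhs - rhs) <= 1e-8 * scale)


def _adult():
    from infusekit.fixtures import adult_single_drug

    man, drugs, rates = adult_single_drug()
    return man, drugs, rates


def test_breakthrough_time_matches_plug_flow_transit():
    """High-Pe step injection: 50% arrival within 10% of Vdead/Qtot."""
    from infusekit.fixtures import adult_single_drug
    from infusekit.manifold import dead_volume

    man, drugs, (qc, qd) = adult_single_drug()
    sim = TransportSimulator(man, drugs, GridSpec(dx_mm=0.5, dt_s=0.5), (qc, qd))
    tau_p = dead_volume(man, 4) / (qc + qd[4]) * 3600.0
    t50 = None
    while sim.state.clock_s < 3 * tau_p:
        sim.advance(10.0)
        if sim.chat(0) >= 0.5:
            t50 = sim.state.clock_s
            break
    assert t50 == pytest.approx(tau_p, rel=0.10)


def test_doubling_flows_halves_breakthrough_at_high_pe():
    from infusekit.fixtures import adult_single_drug

    def t50(scale):
        man, drugs, (qc, qd) = adult_single_drug()
        sim = TransportSimulator(
            man, drugs, GridSpec(dx_mm=0.5, dt_s=0.5),
            (scale * qc, {p: scale * q for p, q in qd.items()}),
        )
        while True:
            sim.advance(5.0)
            if sim.chat(0) >= 0.5:
                return sim.state.clock_s

    assert t50(1.0) / t50(2.0) == pytest.approx(2.0, rel=0.05)


def test_crank_nicolson_temporal_order_on_gaussian_pulse():
    """Observed temporal order of convergence >= 1.8 under dt halving."""

    def run(dt):
        man = tube(length=100.0, radius=0.5)
        grid = GridSpec(dx_mm=0.25, dt_s=dt, courant_max=1e9,
                        backward_euler_first_step=False)
        sim = TransportSimulator(man, {1: DrugSpec("a")}, grid, (10.0, {1: 0.0}))
        x = sim.x_center
        sim.state.conc[0] = np.exp(-0.5 * ((x - 30.0) / 5.0) ** 2)
        sim.advance(20.0)
        return sim.state.conc[0]

    ref = run(0.125)
    errs = [np.linalg.norm(run(dt) - ref) for dt in (4.0, 2.0, 1.0)]
    orders = [np.log2(errs[i] / errs[i + 1]) for i in range(2)]
    assert min(orders) >= 1.8


def test_front_position_monotone_under_step_infusion():
    man, drugs, rates = _adult()
    sim = TransportSimulator(man, drugs, GridSpec(dx_mm=0.5, dt_s=0.5), rates)
    xs = []
    for _ in range(40):
        sim.advance(15.0)
        xs.append(sim.front_position(0))
    assert all(b >= a - 1e-12 for a, b in zip(xs, xs[1:]))
    assert xs[0] >= 0.0 and xs[-1] <= 1.0
    assert xs[-1] > 0.5  # the front actually advanced


def test_front_position_absent_drug_is_zero():
    sim = TransportSimulator(tube(), {1: DrugSpec("a")}, GridSpec(dx_mm=1.0), (10.0, {1: 1.0}))
    assert sim.front_position(0) == 0.0


def test_tip_delivery_rate_steady_state_mass_balance():
    sim = TransportSimulator(tube(length=60.0), {1: DrugSpec("a", syringe_conc=2.0)},
                             GridSpec(dx_mm=0.5, dt_s=1.0), (10.0, {1: 1.0}))
    sim.prime_to_steady_state()
    assert sim.tip_delivery_rate(0) == pytest.approx(1.0 * 2.0)  # Qd * Cs
    assert sim.chat(0) == pytest.approx(1.0)


def test_simulate_empty_schedule_all_zero():
    man, drugs, _ = _adult()
    df = simulate(man, drugs, [], GridSpec(dx_mm=1.0, dt_s=1.0), horizon_s=60.0)
    assert np.all(df["delivery_propofol"] == 0.0)
    assert np.all(df["total_flow_mlh"] == 0.0)


def test_simulate_rejects_bad_inputs():
    man, drugs, (qc, qd) = _adult()
    with pytest.raises(ValueError):
        simulate(man, drugs, [(0.0, qc, qd)], GridSpec(), horizon_s=0.0)
    with pytest.raises(ValueError):
        simulate(man, drugs, [(10.0, qc, qd), (0.0, qc, qd)], GridSpec(), horizon_s=10.0)


def test_negative_concentration_clipped_and_counted():
    man, drugs, rates = _adult()
    sim = TransportSimulator(man, drugs, GridSpec(dx_mm=0.5, dt_s=0.5), rates)
    sim.advance(300.0)
    assert np.min(sim.state.conc) >= 0.0
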