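import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from infusekit.policy import (
    ControlParams,
    PumpAction,
    brute_force_policy,
    feasible,
    from_nondim,
    guardrail,
    reward_det,
    run_controlled,
    solve_policy,
    to_nondim,
)


def params_1drug(ratio=5.0, wt=1.0, **kw):
    return ControlParams(qc_set=10.0, qd_set={4: 1.0}, qc_max=ratio * 10.0,
                         qd_max={4: ratio * 1.0}, wt=wt, **kw)


# ------------------------------------------------------------------ nondim
def test_nondim_breakpoints():
    p = params_1drug()
    assert to_nondim(PumpAction(10.0, {4: 1.0}), p) == pytest.approx([0.0, 0.0])
    assert to_nondim(PumpAction(50.0, {4: 5.0}), p) == pytest.approx([1.0, 1.0])
    assert to_nondim(PumpAction(0.0, {4: 0.0}), p) == pytest.approx([-1.0, -1.0])
    # midway between set and max
    assert to_nondim(PumpAction(30.0, {4: 3.0}), p) == pytest.approx([0.5, 0.5])


@settings(deadline=None, derandomize=True, max_examples=60)
@given(qc_hat=st.floats(-1.0, 1.0), qd_hat=st.floats(-1.0, 1.0))
def test_nondim_round_trip(qc_hat, qd_hat):
    p = params_1drug()
    act = from_nondim(np.array([qc_hat, qd_hat]), p)
    back = to_nondim(act, p)
    assert back == pytest.approx([qc_hat, qd_hat], abs=1e-12)


def test_out_of_range_rejected():
    p = params_1drug()
    with pytest.raises(ValueError):
        to_nondim(PumpAction(60.0, {4: 1.0}), p)


# ------------------------------------------------------------------ reward
def test_reward_maximum_at_set_rates_when_on_target():
    p = params_1drug()
    r_set = reward_det(1.0, PumpAction(10.0, {4: 1.0}), p)
    rng = np.random.default_rng(0)
    for _ in range(200):
        qc = rng.uniform(0, 50)
        qd = rng.uniform(0, 5)
        assert reward_det(1.0, PumpAction(qc, {4: qd}), p) <= r_set + 1e-12


def test_reward_independent_of_qcmax_when_wt_zero():
    a = ControlParams(qc_set=10.0, qd_set={4: 1.0}, qc_max=50.0, qd_max={4: 5.0}, wt=0.0)
    b = ControlParams(qc_set=10.0, qd_set={4: 1.0}, qc_max=80.0, qd_max={4: 5.0}, wt=0.0)
    act = PumpAction(10.0, {4: 1.0})
    for ch in (0.0, 0.5, 1.0):
        assert reward_det(ch, act, a) == pytest.approx(reward_det(ch, act, b))


def test_reward_ranking_matches_dense_grid_oracle():
    """Pairwise ranking of candidate actions at Chat=0.5 agrees with a
    dense grid evaluation of the same objective."""
    p = params_1drug()
    qcs = np.linspace(0, 50, 26)
    qds = np.linspace(0, 5, 26)
    vals = {}
    for qc in qcs:
        for qd in qds:
            vals[(qc, qd)] = reward_det(0.5, PumpAction(qc, {4: qd}), p)
    keys = list(vals)
    rng = np.random.default_rng(1)
    for _ in range(100):
        i, j = rng.integers(0, len(keys), 2)
        a, b = keys[i], keys[j]
        ra = reward_det(0.5, PumpAction(a[0], {4: a[1]}), p)
        rb = reward_det(0.5, PumpAction(b[0], {4: b[1]}), p)
        assert (ra > rb) == (vals[a] > vals[b]) or ra == pytest.approx(rb)


# ---------------------------------------------------------------- feasible
def test_set_rates_feasible_on_target():
    p = params_1drug()
    ok, bad = feasible(PumpAction(10.0, {4: 1.0}), 1.0, p)
    assert ok and not bad


def test_exceeding_drug_bound_reported():
    p = params_1drug()
    ok, bad = feasible(PumpAction(10.0, {4: 10.0}), 0.0, p)
    assert not ok and any("drug_bounds" in b for b in bad)


def test_kappa_zero_pins_exact_inlet_fraction():
    p = params_1drug(kappa=0.0)
    ok, _ = feasible(PumpAction(20.0, {4: 2.0}), 0.0, p)  # same fraction as set
    assert ok
    ok, bad = feasible(PumpAction(20.0, {4: 3.0}), 0.0, p)
    assert not ok and any("inlet_fraction" in b for b in bad)


def test_overshoot_constraint_flagged():
    p = params_1drug()
    ok, bad = feasible(PumpAction(50.0, {4: 5.0}), 1.0, p)  # 55 * 1 > 1.1 * 11
    assert not ok and any("overshoot" in b for b in bad)


# ------------------------------------------------------------------- solve
def test_on_target_returns_set_rates():
    p = params_1drug()
    act = solve_policy(1.0, p)
    assert act.qc == pytest.approx(10.0, abs=1e-6)
    assert act.qd[4] == pytest.approx(1.0, abs=1e-6)


def test_empty_state_drives_carrier_to_max():
    p = params_1drug()
    act = solve_policy(0.0, p)
    assert act.qc == pytest.approx(50.0, rel=1e-6)
    ok, _ = feasible(act, 0.0, p)
    assert ok


def test_sqp_matches_grid_oracle_reward():
    p = params_1drug()
    rng = np.random.default_rng(42)
    for ch in rng.uniform(0.0, 1.1, size=8):
        a_sqp = solve_policy(float(ch), p)
        a_grid = brute_force_policy(float(ch), p, grid_n=120)
        r_sqp = reward_det(float(ch), a_sqp, p)
        r_grid = reward_det(float(ch), a_grid, p)
        assert r_sqp >= r_grid - 1e-3 * abs(r_grid)


def test_policy_drug_rate_nonincreasing_near_target():
    """Commanded drug rate throttles back as the tip approaches target,
    returning exactly to the set rate once on target."""
    p = params_1drug()
    qd = [solve_policy(ch, p).qd[4] for ch in (0.5, 0.7, 0.9, 0.95)]
    assert all(b <= a + 1e-9 for a, b in zip(qd, qd[1:]))
    assert solve_policy(1.0, p).qd[4] == pytest.approx(1.0, abs=1e-6)


def test_emitted_actions_always_feasible():
    p = params_1drug()
    for ch in np.linspace(0, 1.2, 13):
        act = solve_policy(float(ch), p)
        ok, bad = feasible(act, float(ch), p)
        assert ok, bad


def test_brute_force_requires_minimum_grid():
    with pytest.raises(ValueError):
        brute_force_policy(0.5, params_1drug(), grid_n=10)


# --------------------------------------------------------------- guardrail
def test_guardrail_leaves_feasible_actions_unchanged():
    p = params_1drug()
    act = PumpAction(10.0, {4: 1.0})
    out = guardrail(act, 1.0, p)
    assert out.qc == act.qc and out.qd == act.qd


def test_guardrail_clips_drug_bound():
    p = params_1drug()
    out = guardrail(PumpAction(10.0, {4: 12.0}), 0.0, p)
    assert out.qd[4] <= 5.0 + 1e-9
    assert feasible(out, 0.0, p)[0]


def test_guardrail_scales_down_overshoot():
    p = params_1drug()
    out = guardrail(PumpAction(50.0, {4: 5.0}), 1.0, p)
    assert out.total * 1.0 <= p.beta * p.set_total + 1e-6
    assert feasible(out, 1.0, p)[0]


def test_guardrail_idempotent():
    p = params_1drug()
    rng = np.random.default_rng(3)
    for _ in range(50):
        raw = PumpAction(float(rng.uniform(0, 80)), {4: float(rng.uniform(0, 10))})
        ch = float(rng.uniform(0, 1.5))
        once = guardrail(raw, ch, p)
        twice = guardrail(once, ch, p)
        assert twice.qc == pytest.approx(once.qc, abs=1e-9)
        assert twice.qd[4] == pytest.approx(once.qd[4], abs=1e-9)


# -------------------------------------------------------------- closed loop
def test_wt_zero_equals_uncontrolled_baseline(adult_setup, coarse_grid):
    from infusekit.transport import simulate

    man, drugs, (qc, qd) = adult_setup
    p = ControlParams(qc_set=qc, qd_set=qd, qc_max=5 * qc, qd_max={4: 5 * qd[4]}, wt=0.0)
    ctl = run_controlled(man, drugs, p, coarse_grid, horizon_s=300.0)
    base = simulate(man, drugs, [(0.0, qc, qd)], coarse_grid, horizon_s=300.0, record_dt_s=5.0)
    assert np.allclose(ctl["delivery_propofol"].values, base["delivery_propofol"].values,
                       rtol=1e-9, atol=1e-12)
    # excess fluid is identically zero without control authority
    assert np.allclose(ctl["total_flow_mlh"].values, qc + qd[4])


def test_t90_improvement_monotone_in_wt(adult_setup, coarse_grid):
    from infusekit.scenarios import metrics

    man, drugs, (qc, qd) = adult_setup
    t90s = []
    for wt in (0.0, 0.5, 1.0):
        p = ControlParams(qc_set=qc, qd_set=qd, qc_max=3 * qc, qd_max={4: 3 * qd[4]}, wt=wt)
        df = run_controlled(man, drugs, p, coarse_grid, horizon_s=900.0)
        m = metrics(df["time_s"].values, df["delivery_propofol"].values, qd[4])
        t90s.append(m.t90_min)
    assert t90s[0] >= t90s[1] >= t90s[2]
    assert t90s[0] > 2 * t90s[2]  # real improvement at full authority
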