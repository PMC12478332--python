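import numpy as np
import pytest

from infusekit.policy import ControlParams
from infusekit.scenarios import (
    PKParams,
    ScenarioSpec,
    cessation_with_flush,
    manual_adhoc,
    manual_bolus_step,
    metrics,
    pk_response,
    syringe_change,
)
from infusekit.transport import DrugSpec, GridSpec


# ------------------------------------------------------------------ metrics
def test_ideal_step_metrics():
    t = np.arange(0, 601, 5.0)
    y = np.where(t >= 300.0, 1.0, 0.0)
    m = metrics(t, y, set_rate=1.0)
    assert m.t90_min == pytest.approx(5.0, abs=0.1)
    assert m.overshoot == pytest.approx(0.0)


def test_linear_ramp_t90():
    t = np.arange(0, 1201, 1.0)
    y = np.clip(t / 600.0, 0, 1)  # reaches set rate at 10 min
    m = metrics(t, y, set_rate=1.0)
    assert m.t90_min == pytest.approx(9.0, rel=1e-6)
    assert m.t50_min == pytest.approx(5.0, rel=1e-6)
    assert m.t10_min == pytest.approx(1.0, rel=1e-6)


def test_never_deviating_schedule_zero_excess():
    t = np.arange(0, 301, 5.0)
    y = np.ones_like(t)
    m = metrics(t, y, 1.0, total_flow_mlh=np.full_like(t, 11.0), set_total_mlh=11.0)
    assert m.excess_ml == 0.0


def test_unreached_crossing_reported_as_none():
    t = np.arange(0, 301, 5.0)
    m = metrics(t, np.full_like(t, 0.3), 1.0)
    assert m.t90_min is None and m.t50_min is None
    assert m.horizon_min == pytest.approx(5.0)


def test_sustained_crossing_variant():
    t = np.arange(0, 101, 1.0)
    y = np.where((t > 10) & (t < 20), 1.0, np.where(t >= 50, 1.0, 0.0))
    first = metrics(t, y, 1.0).t90_min
    sustained = metrics(t, y, 1.0, sustained=True).t90_min
    assert first < sustained


# ---------------------------------------------------------------------- PK
def test_pk_constant_input_matches_closed_form():
    pk = PKParams(volume_l=35.0, ke_per_s=np.log(2) / 300.0)
    t = np.arange(0, 3601, 5.0)
    rate = 36.0  # mass/h
    cp = pk_response(t, np.full_like(t, rate), pk)
    expected = rate / 3600.0 / (pk.volume_l * pk.ke_per_s) * (1 - np.exp(-pk.ke_per_s * t))
    assert np.max(np.abs(cp - expected)) < 1e-10


def test_pk_washout_decay():
    pk = PKParams()
    t = np.arange(0, 1801, 5.0)
    u = np.where(t < 600, 36.0, 0.0)
    cp = pk_response(t, u, pk)
    i0 = np.argmin(np.abs(t - 600))
    decay = cp[i0:] / cp[i0]
    expected = np.exp(-pk.ke_per_s * (t[i0:] - 600))
    # one-sample input lag from the piecewise-constant integrator
    assert np.allclose(decay[2:], expected[2:], rtol=1e-2)


def test_pk_ordering_mirrors_delivery_ordering():
    """Faster delivery onset reaches 90% of the PK plateau sooner."""
    pk = PKParams()
    t = np.arange(0, 7200.0, 5.0)
    fast = np.clip(t / 60.0, 0, 1.0)
    slow = np.clip(t / 1200.0, 0, 1.0)
    cp_f = pk_response(t, fast, pk)
    cp_s = pk_response(t, slow, pk)
    plateau = 1.0 / 3600.0 / (pk.volume_l * pk.ke_per_s)
    t90f = t[np.argmax(cp_f >= 0.9 * plateau)]
    t90s = t[np.argmax(cp_s >= 0.9 * plateau)]
    assert t90f < t90s


def test_pk_invalid():
    with pytest.raises(ValueError):
        PKParams(volume_l=0.0)
    with pytest.raises(ValueError):
        pk_response(np.arange(3.0), np.array([1.0, np.inf, 1.0]), PKParams())


# --------------------------------------------------------------- baselines
def test_bolus_factor_one_is_uncontrolled_baseline(adult_setup, coarse_grid):
    from infusekit.transport import simulate

    man, drugs, (qc, qd) = adult_setup
    bol = manual_bolus_step(man, drugs, (qc, qd), coarse_grid, 300.0,
                            bolus_factor=1.0, bolus_duration_s=120.0)
    base = simulate(man, drugs, [(0.0, qc, qd)], coarse_grid, 300.0, record_dt_s=5.0)
    assert np.allclose(bol["delivery_propofol"].values, base["delivery_propofol"].values,
                       rtol=1e-9)


def test_long_high_bolus_overshoots(adult_setup, coarse_grid):
    man, drugs, (qc, qd) = adult_setup
    df = manual_bolus_step(man, drugs, (qc, qd), coarse_grid, 1800.0,
                           bolus_factor=3.0, bolus_duration_s=900.0)
    m = metrics(df["time_s"].values, df["delivery_propofol"].values, qd[4])
    assert m.overshoot > 0.5  # manual bolus badly overshoots the set rate


def test_manual_adhoc_converges_toward_target(adult_setup, coarse_grid):
    man, drugs, (qc, qd) = adult_setup
    df = manual_adhoc(man, drugs, (qc, qd), coarse_grid, 2400.0)
    final = df["delivery_propofol"].values[-10:].mean()
    assert final == pytest.approx(qd[4], rel=0.35)


# ----------------------------------------------------------- syringe change
def test_zero_duration_swap_identical(two_drug_setup, coarse_grid):
    man, drugs, rates = two_drug_setup
    a = syringe_change(man, drugs, rates, coarse_grid, 4, 300.0, 0.0, 900.0, compensate=False)
    b = syringe_change(man, drugs, rates, coarse_grid, 4, 300.0, 0.0, 900.0, compensate=True)
    assert np.allclose(a["delivery_norepinephrine"], b["delivery_norepinephrine"], rtol=1e-12)


def test_compensation_keeps_other_drug_steady(two_drug_setup, coarse_grid):
    man, drugs, rates = two_drug_setup
    qc, qd = rates
    kw = dict(swap_port=4, swap_start_s=300.0, swap_duration_s=600.0, horizon_s=3600.0)
    raw = syringe_change(man, drugs, rates, coarse_grid, compensate=False, **kw)
    comp = syringe_change(man, drugs, rates, coarse_grid, compensate=True, **kw)
    sd = qd[3] * drugs[3].syringe_conc
    dev_raw = np.max(np.abs(raw["delivery_norepinephrine"].values / sd - 1.0))
    dev_comp = np.max(np.abs(comp["delivery_norepinephrine"].values / sd - 1.0))
    assert dev_comp < dev_raw
    assert dev_comp < 0.02  # total-flow preservation keeps delivery flat


def test_single_drug_swap_keeps_total_flow_constant(adult_setup, coarse_grid):
    man, drugs, rates = adult_setup
    df = syringe_change(man, drugs, rates, coarse_grid, 4, 60.0, 120.0, 300.0, compensate=True)
    assert np.allclose(df["total_flow_mlh"].values, 11.0, rtol=1e-12)


# ---------------------------------------------------------------- cessation
@pytest.fixture(scope="module")
def cessation_runs(two_drug_setup, coarse_grid):
    man, drugs, rates = two_drug_setup
    qc, qd = rates
    params = ControlParams(qc_set=qc, qd_set=dict(qd), qc_max=5 * qc,
                           qd_max={p: 5 * q for p, q in qd.items()})
    out = {}
    for flush in (False, True):
        out[flush] = cessation_with_flush(man, drugs, rates, coarse_grid, cease_port=4,
                                          params=params, horizon_s=3600.0, flush=flush)
    return rates, out


def test_flush_accelerates_cessation(cessation_runs):
    (qc, qd), runs = cessation_runs
    prior = qd[4]
    t10 = {}
    for flush, df in runs.items():
        m = metrics(df["time_s"].values, df["delivery_phenylephrine"].values, prior,
                    direction="falling")
        t10[flush] = m.t10_min
    assert t10[True] < t10[False]


def test_flush_keeps_remaining_drug_concentration_in_band(cessation_runs):
    (qc, qd), runs = cessation_runs
    plateau = qd[3] / (qc + sum(qd.values()))
    conc = runs[True]["c_tip_norepinephrine"].values
    assert np.max(np.abs(conc / plateau - 1.0)) < 0.15


def test_ceasing_inactive_drug_rejected(two_drug_setup, coarse_grid):
    man, drugs, rates = two_drug_setup
    with pytest.raises(ValueError):
        cessation_with_flush(man, drugs, rates, coarse_grid, cease_port=2)


# ---------------------------------------------------------------- scenarios
def test_scenario_yaml_round_trip(tmp_path):
    from infusekit.workbench import load_scenario, save_scenario

    spec = ScenarioSpec(
        name="t", fixture="adult", carrier_mlh=10.0,
        drugs={4: (DrugSpec("propofol"), 1.0)}, mode="det", wt=0.5,
    )
    save_scenario(spec, tmp_path / "s.yaml")
    back = load_scenario(tmp_path / "s.yaml")
    assert back == spec


def test_scenario_validation():
    with pytest.raises(ValueError):
        ScenarioSpec(name="x", fixture="adult", carrier_mlh=10.0,
                     drugs={4: (DrugSpec("a"), 1.0)}, mode="warp")
    with pytest.raises(ValueError):
        ScenarioSpec(name="x", fixture="adult", carrier_mlh=10.0,
                     drugs={4: (DrugSpec("a"), 1.0)},
                     events=({"time_s": 10.0}, {"time_s": 5.0}))


def test_all_modes_share_transport_core(adult_setup, coarse_grid):
    """Scenario operations run the same physics: identical uncontrolled
    segments produce identical trajectories across operation entry points."""
    from infusekit.transport import simulate

    man, drugs, (qc, qd) = adult_setup
    a = simulate(man, drugs, [(0.0, qc, qd)], coarse_grid, 200.0, record_dt_s=5.0)
    b = manual_bolus_step(man, drugs, (qc, qd), coarse_grid, 200.0, 1.0, 50.0)
    c = syringe_change(man, drugs, (qc, qd), coarse_grid, 4, 1e9, 0.0, 200.0)
    assert np.allclose(a["c_tip_propofol"], b["c_tip_propofol"], rtol=1e-12)
    # c starts primed; fingerprint via steady tip concentration instead
    assert c["c_tip_propofol"].iloc[0] == pytest.approx(1.0 / 11.0, rel=1e-9)


def test_explicit_manifold_geometry_in_scenario():
    """A scenario can carry its own segment/port geometry instead of a
    named fixture; the loader validates and round-trips it."""
    import yaml

    d = {
        "name": "custom", "carrier_mlh": 5.0,
        "manifold": {"segments": [{"length_mm": 100.0, "radius_mm": 0.5}],
                     "ports": {1: 0.0}},
        "drugs": [{"name": "dye", "port": 1, "rate_mlh": 0.5}],
        "horizon_min": 1.0, "grid": {"dx_mm": 1.0, "dt_s": 1.0},
    }
    spec = ScenarioSpec.from_dict(d)
    man, *_ = spec.build()
    assert man.total_length_mm == 100.0 and man.ports == {1: 0.0}
    back = ScenarioSpec.from_dict(yaml.safe_load(yaml.safe_dump(spec.to_dict())))
    man2, *_ = back.build()
    assert man2 == man
    bad = {**d, "manifold": {"segments": [{"length_mm": 10.0, "radius_mm": 0.5}],
                             "ports": {1: 50.0}}}
    with pytest.raises(ValueError):
        ScenarioSpec.from_dict(bad).build()
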