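"""Clinical scenario operations and delivery-kinetics metrics.

All operations drive the same transport core
(:class:`infusekit.transport.TransportSimulator`); there is no
scenario-specific physics.  Trajectories share the time-series schema of
:func:`infusekit.transport.simulate`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .policy import ControlParams
from .transport import DrugSpec, GridSpec, TransportSimulator

__all__ = [
    "ScenarioSpec",
    "DeliveryMetrics",
    "PKParams",
    "metrics",
    "manual_adhoc",
    "manual_bolus_step",
    "syringe_change",
    "cessation_with_flush",
    "pk_response",
]


@dataclass(frozen=True)
class DeliveryMetrics:
    """Onset/cessation kinetics of one drug's tip delivery-rate series.

    ``t10/t50/t90`` are first crossings of 10/50/90% of the set (or, for
    a falling series, the prior) delivery rate, in minutes; ``None``
    when the crossing is not reached within the horizon.  ``overshoot``
    is ``max(rate)/set - 1``; ``excess_ml`` integrates the positive part
    of (total flow − set total flow) from start to t90.
    """

    t10_min: float | None
    t50_min: float | None
    t90_min: float | None
    overshoot: float
    excess_ml: float
    horizon_min: float
    direction: str = "rising"

    def __post_init__(self) -> None:
        ts = [t for t in (self.t10_min, self.t50_min, self.t90_min) if t is not None]
        if self.direction == "falling":
            ts = ts[::-1]
        if ts != sorted(ts):
            raise ValueError("crossing times must be ordered t10 <= t50 <= t90")


def _first_crossing(
    t: np.ndarray, y: np.ndarray, level: float, direction: str, sustained: bool
) -> float | None:
    hit = y >= level if direction == "rising" else y <= level
    if sustained:
        # require the crossing to hold until the end of the record
        ok = np.flip(np.logical_and.accumulate(np.flip(hit)))
        hit = ok
    idx = np.nonzero(hit)[0]
    if len(idx) == 0:
        return None
    i = idx[0]
    if i == 0:
        return float(t[0])
    # linear interpolation between samples for cadence-independent times
    t0, t1, y0, y1 = t[i - 1], t[i], y[i - 1], y[i]
    if y1 == y0:
        return float(t1)
    return float(t0 + (level - y0) * (t1 - t0) / (y1 - y0))


def metrics(
    times_s: np.ndarray,
    delivery: np.ndarray,
    set_rate: float,
    total_flow_mlh: np.ndarray | None = None,
    set_total_mlh: float | None = None,
    direction: str = "rising",
    sustained: bool = False,
) -> DeliveryMetrics:
    """Delivery-kinetics metrics from a fixed-cadence series.

    For ``direction="falling"`` (cessation) the levels are fractions of
    ``set_rate`` interpreted as the prior delivery rate, and t10 is the
    *last* metric reached (t90 the first).
    """
    t = np.asarray(times_s, float)
    y = np.asarray(delivery, float)
    if set_rate <= 0:
        raise ValueError("set rate must be positive")
    fracs = (0.1, 0.5, 0.9)
    cross = {f: _first_crossing(t, y, f * set_rate, direction, sustained) for f in fracs}
    overshoot = float(np.max(y) / set_rate - 1.0)
    excess = 0.0
    if total_flow_mlh is not None and set_total_mlh is not None:
        t_end = cross[0.9] if direction == "rising" else None
        mask = t <= t_end if t_end is not None else np.ones_like(t, bool)
        if mask.sum() >= 2:
            ex_flow = np.clip(np.asarray(total_flow_mlh, float)[mask] - set_total_mlh, 0.0, None)
            excess = float(np.trapezoid(ex_flow, t[mask]) / 3600.0)
    return DeliveryMetrics(
        t10_min=None if cross[0.1] is None else cross[0.1] / 60.0,
        t50_min=None if cross[0.5] is None else cross[0.5] / 60.0,
        t90_min=None if cross[0.9] is None else cross[0.9] / 60.0,
        overshoot=overshoot,
        excess_ml=excess,
        horizon_min=float(t[-1] / 60.0),
        direction=direction,
    )


# ------------------------------------------------------------ open loop ops
def _run_scripted(
    manifold,
    drugs: dict[int, DrugSpec],
    set_rates: tuple[float, dict[int, float]],
    grid: GridSpec,
    horizon_s: float,
    controller,
    record_dt_s: float = 5.0,
    primed: bool = False,
) -> pd.DataFrame:
    """Drive the transport core with a callback ``controller(t, sim) -> (qc, qd)``."""
    sim = TransportSimulator(manifold, drugs, grid, set_rates)
    if primed:
        sim.prime_to_steady_state()
    rows = []
    t = 0.0
    dispensed = 0.0
    names = {p: drugs[p].name for p in sim.drug_ports}

    def record() -> None:
        row = {"time_s": t, "carrier_mlh": sim.carrier, "total_flow_mlh": sim.tip_flow_mlh,
               "dispensed_ml": dispensed}
        for k, p in enumerate(sim.drug_ports):
            nm = names[p]
            row[f"q_{nm}_mlh"] = sim.rates[p]
            row[f"c_tip_{nm}"] = sim.tip_concentration(k)
            row[f"chat_{nm}"] = sim.chat(k)
            row[f"delivery_{nm}"] = sim.tip_delivery_rate(k)
        rows.append(row)

    record()
    while t < horizon_s - 1e-9:
        qc, qd = controller(t, sim)
        sim.set_pump_rates(qc, qd)
        dt = min(record_dt_s, horizon_s - t)
        sim.advance(dt)
        dispensed += sim.tip_flow_mlh * dt / 3600.0
        t += dt
        record()
    return pd.DataFrame(rows)


def manual_adhoc(
    manifold,
    drugs: dict[int, DrugSpec],
    set_rates: tuple[float, dict[int, float]],
    grid: GridSpec,
    horizon_s: float,
    cadence_s: float = 120.0,
    reaction_delay_s: float = 30.0,
    step_frac: float = 0.25,
    max_factor: float = 5.0,
) -> pd.DataFrame:
    """Scripted clinician baseline: periodic ad-hoc rate nudges.

    Every ``cadence_s`` the (delayed) total delivery rate at the tip is
    compared to the set value and all pumps are scaled up or down by
    ``step_frac``, emulating the reactive bedside protocol of adjusting
    pumps toward a delivery target with only tip feedback.
    """
    qc0, qd0 = set_rates
    set_delivery = sum(qd0[p] * drugs[p].syringe_conc for p in qd0)
    state = {"factor": 1.0, "next": cadence_s, "log": []}

    def controller(t, sim):
        # record (time, delivery) so the delayed reading can be looked up
        state["log"].append((t, sum(sim.tip_delivery_rate(k) for k in range(len(sim.drug_ports)))))
        if t >= state["next"]:
            state["next"] += cadence_s
            t_read = t - reaction_delay_s
            past = [d for (tt, d) in state["log"] if tt <= t_read]
            seen = past[-1] if past else 0.0
            if seen < 0.9 * set_delivery:
                state["factor"] = min(state["factor"] * (1.0 + step_frac), max_factor)
            elif seen > 1.1 * set_delivery:
                state["factor"] = max(state["factor"] / (1.0 + step_frac), 1.0)
        f = state["factor"]
        return qc0 * f, {p: q * f for p, q in qd0.items()}

    return _run_scripted(manifold, drugs, set_rates, grid, horizon_s, controller)


def manual_bolus_step(
    manifold,
    drugs: dict[int, DrugSpec],
    set_rates: tuple[float, dict[int, float]],
    grid: GridSpec,
    horizon_s: float,
    bolus_factor: float = 3.0,
    bolus_duration_s: float = 600.0,
) -> pd.DataFrame:
    """Scripted clinician baseline: high-rate bolus, then step to set rates."""
    qc0, qd0 = set_rates

    def controller(t, sim):
        f = bolus_factor if t < bolus_duration_s else 1.0
        return qc0 * f, {p: q * f for p, q in qd0.items()}

    return _run_scripted(manifold, drugs, set_rates, grid, horizon_s, controller)


def syringe_change(
    manifold,
    drugs: dict[int, DrugSpec],
    set_rates: tuple[float, dict[int, float]],
    grid: GridSpec,
    swap_port: int,
    swap_start_s: float,
    swap_duration_s: float,
    horizon_s: float,
    compensate: bool = True,
) -> pd.DataFrame:
    """Syringe change: the swapped drug's pump pauses for the swap window.

    With compensation the carrier rate is raised by the paused drug's set
    rate so the total flow — and therefore every other drug's inlet
    concentration and delivery — is unchanged.  Starts from the steady
    profile at set rates.
    """
    qc0, qd0 = set_rates
    if swap_port not in qd0:
        raise KeyError(f"no drug at port {swap_port}")

    def controller(t, sim):
        in_window = swap_start_s <= t < swap_start_s + swap_duration_s
        qd = dict(qd0)
        qc = qc0
        if in_window:
            qd[swap_port] = 0.0
            if compensate:
                qc = qc0 + qd0[swap_port]
        return qc, qd

    return _run_scripted(manifold, drugs, set_rates, grid, horizon_s, controller, primed=True)


def cessation_with_flush(
    manifold,
    drugs: dict[int, DrugSpec],
    set_rates: tuple[float, dict[int, float]],
    grid: GridSpec,
    cease_port: int,
    params: ControlParams | None = None,
    horizon_s: float = 3600.0,
    flush: bool = True,
    washout_tol: float = 0.02,
) -> pd.DataFrame:
    """Cease one drug at t=0, optionally with a carrier flush.

    Starting from the steady profile, the ceased drug's pump goes to
    zero.  With ``flush=True`` the carrier jumps to its maximum and every
    remaining drug is scaled by the same factor, which leaves each
    remaining drug's inlet concentration — hence its manifold steady
    profile — exactly unchanged while the ceased drug washes out at the
    flush flow.  Once the ceased drug's concentration everywhere falls
    below ``washout_tol`` of its prior plateau, all rates return to set.
    Pump bounds and inlet-fraction constraints are respected throughout
    (the proportional scale preserves inlet fractions up to the ceased
    drug's share).
    """
    qc0, qd0 = set_rates
    if cease_port not in qd0 or qd0[cease_port] <= 0:
        raise ValueError(f"drug at port {cease_port} is not active")
    if params is None:
        params = ControlParams(
            qc_set=qc0, qd_set=dict(qd0), qc_max=5 * qc0,
            qd_max={p: 5 * q for p, q in qd0.items()},
        )
    total_old = qc0 + sum(qd0.values())
    rem = [p for p in qd0 if p != cease_port]
    if flush:
        # common scale on (carrier + ceased share) and the remaining drugs
        s = params.qc_max / (qc0 + qd0[cease_port])
        for p in rem:
            if qd0[p] > 0:
                s = min(s, params.qd_max.get(p, qd0[p]) / qd0[p])
        s = max(s, 1.0)
    else:
        s = 1.0

    # plateau of the ceased drug at set rates, for the washout criterion
    cs = drugs[cease_port].syringe_conc
    plateau = qd0[cease_port] * cs / total_old
    state = {"flushing": flush}

    def controller(t, sim):
        qd = {p: qd0[p] for p in qd0}
        qd[cease_port] = 0.0
        if not flush:
            return qc0, qd  # simple pump stop, nothing else changes
        if state["flushing"]:
            k = sim.drug_ports.index(cease_port)
            if float(np.max(sim.state.conc[k])) <= washout_tol * plateau:
                state["flushing"] = False
        if state["flushing"]:
            qc = s * (qc0 + qd0[cease_port])
            for p in rem:
                qd[p] = s * qd0[p]
            return qc, qd
        # post-flush: carrier absorbs the ceased share so the remaining
        # drugs' dilution stays at its set-point value
        return qc0 + qd0[cease_port], qd

    return _run_scripted(manifold, drugs, set_rates, grid, horizon_s, controller, primed=True)


# ------------------------------------------------------------------- PK
@dataclass(frozen=True)
class PKParams:
    """One-compartment pharmacokinetics: volume ``V`` (L) and elimination
    rate constant ``ke`` (1/s).  Defaults are literature-representative
    for a fast-acting vasopressor (phenylephrine-like: 5-min half-life,
    35 L distribution volume)."""

    volume_l: float = 35.0
    ke_per_s: float = float(np.log(2) / 300.0)

    def __post_init__(self) -> None:
        if self.volume_l <= 0 or self.ke_per_s <= 0:
            raise ValueError("PK parameters must be positive")


def pk_response(times_s: np.ndarray, delivery_per_h: np.ndarray, pk: PKParams) -> np.ndarray:
    """Plasma concentration for a one-compartment model, exactly integrated.

    Solves ``dCp/dt = u(t)/V - ke*Cp`` with ``Cp(0)=0`` and the input
    held piecewise-constant over each sample interval::

        Cp_{n+1} = Cp_n e^{-ke dt} + u_n / (V ke) (1 - e^{-ke dt})

    ``delivery_per_h`` is in (mass units)/h; the result is in
    (mass units)/L.
    """
    t = np.asarray(times_s, float)
    u = np.asarray(delivery_per_h, float) / 3600.0  # per second
    if not np.all(np.isfinite(u)):
        raise ValueError("delivery series must be finite")
    cp = np.zeros_like(t)
    for n in range(len(t) - 1):
        dt = t[n + 1] - t[n]
        decay = np.exp(-pk.ke_per_s * dt)
        cp[n + 1] = cp[n] * decay + u[n] / (pk.volume_l * pk.ke_per_s) * (1.0 - decay)
    return cp


# ----------------------------------------------------------- scenario spec
@dataclass(frozen=True)
class ScenarioSpec:
    """Declarative description of a runnable infusion scenario.

    ``drugs`` maps port index -> (DrugSpec, set rate mL/h); ``events``
    are time-ordered dicts like ``{"time_s": 600, "type": "cease",
    "port": 4}`` (types: start/stop/cease/swap with optional
    ``duration_s``).  ``mode`` picks the controller: none, manual_adhoc,
    manual_bolus_step or det.
    """

    name: str
    fixture: str
    carrier_mlh: float
    drugs: dict[int, tuple[DrugSpec, float]]
    manifold: tuple = ()  # optional explicit geometry: (segments, ports)
    mode: str = "none"
    wt: float = 1.0
    qmax_ratio: float = 5.0
    kappa: float = 0.25
    beta: float = 1.1
    interval_s: float = 5.0
    horizon_min: float = 30.0
    grid_dx_mm: float = 0.5
    grid_dt_s: float = 0.5
    events: tuple = ()

    def __post_init__(self) -> None:
        times = [e.get("time_s", 0.0) for e in self.events]
        if times != sorted(times):
            raise ValueError("events must be time-ordered")
        if len(self.drugs) != len({p for p in self.drugs}):
            raise ValueError("ports must be unique per drug")
        if self.mode not in ("none", "manual_adhoc", "manual_bolus_step", "det", "rl"):
            raise ValueError(f"unknown control mode {self.mode!r}")

    # -------------------------------------------------------------- build
    def build(self):
        """Instantiate (manifold, drugs, set_rates, params, grid).

        Explicit geometry in the scenario (``manifold:`` section with
        ``segments: [{length_mm, radius_mm, label}]`` and
        ``ports: {index: position_mm}``) overrides the named fixture.
        """
        from .fixtures import manifold_fixture

        if self.manifold:
            from .manifold import PortMap, SegmentSpec, build_manifold

            segments, ports = self.manifold
            man = build_manifold(
                [SegmentSpec(float(sd["length_mm"]), float(sd["radius_mm"]),
                             str(sd.get("label", ""))) for sd in segments],
                PortMap({int(k): float(v) for k, v in ports.items()}),
            )
        else:
            man = manifold_fixture(self.fixture)
        drugs = {p: spec for p, (spec, _) in self.drugs.items()}
        qd = {p: rate for p, (_, rate) in self.drugs.items()}
        params = ControlParams(
            qc_set=self.carrier_mlh, qd_set=qd,
            qc_max=self.qmax_ratio * self.carrier_mlh,
            qd_max={p: self.qmax_ratio * q for p, q in qd.items()},
            wt=self.wt, kappa=self.kappa, beta=self.beta,
            control_interval_s=self.interval_s,
        )
        grid = GridSpec(dx_mm=self.grid_dx_mm, dt_s=self.grid_dt_s)
        return man, drugs, (self.carrier_mlh, qd), params, grid

    def run(self) -> pd.DataFrame:
        """Execute the scenario with its configured control mode."""
        from .policy import run_controlled
        from .transport import simulate

        man, drugs, set_rates, params, grid = self.build()
        horizon = self.horizon_min * 60.0
        if self.mode == "det":
            return run_controlled(man, drugs, params, grid, horizon)
        if self.mode == "manual_adhoc":
            return manual_adhoc(man, drugs, set_rates, grid, horizon,
                                max_factor=self.qmax_ratio)
        if self.mode == "manual_bolus_step":
            return manual_bolus_step(man, drugs, set_rates, grid, horizon,
                                     bolus_factor=min(3.0, self.qmax_ratio))
        schedule = [(0.0, set_rates[0], dict(set_rates[1]))]
        for ev in self.events:
            if ev["type"] in ("cease", "stop"):
                qd2 = dict(schedule[-1][2])
                qd2[ev["port"]] = 0.0
                schedule.append((float(ev["time_s"]), schedule[-1][1], qd2))
        return simulate(man, drugs, schedule, grid, horizon, set_rates=set_rates)

    # ---------------------------------------------------------------- yaml
    def to_dict(self) -> dict:
        d_man = {}
        if self.manifold:
            segments, ports = self.manifold
            d_man = {"manifold": {"segments": list(segments),
                                  "ports": {int(k): float(v) for k, v in ports.items()}}}
        return {
            "name": self.name,
            "fixture": self.fixture,
            "carrier_mlh": self.carrier_mlh,
            **d_man,
            "drugs": [
                {
                    "name": spec.name, "port": p, "rate_mlh": rate,
                    "syringe_conc": spec.syringe_conc,
                    "diffusivity_m2s": spec.diffusivity_m2s,
                    "tau_a_s": spec.tau_a_s,
                }
                for p, (spec, rate) in sorted(self.drugs.items())
            ],
            "control": {
                "mode": self.mode, "wt": self.wt, "qmax_ratio": self.qmax_ratio,
                "kappa": self.kappa, "beta": self.beta, "interval_s": self.interval_s,
            },
            "grid": {"dx_mm": self.grid_dx_mm, "dt_s": self.grid_dt_s},
            "horizon_min": self.horizon_min,
            "events": list(self.events),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        drugs = {
            int(item["port"]): (
                DrugSpec(
                    name=item["name"],
                    syringe_conc=float(item.get("syringe_conc", 1.0)),
                    diffusivity_m2s=float(item.get("diffusivity_m2s", 5e-10)),
                    tau_a_s=float(item.get("tau_a_s", 60.0)),
                ),
                float(item["rate_mlh"]),
            )
            for item in d["drugs"]
        }
        ctl = d.get("control", {})
        grid = d.get("grid", {})
        man = ()
        if "manifold" in d:
            man = (tuple(d["manifold"]["segments"]),
                   {int(k): float(v) for k, v in d["manifold"]["ports"].items()})
        return cls(
            name=d.get("name", "scenario"),
            fixture=d.get("fixture", "adult"),
            carrier_mlh=float(d["carrier_mlh"]),
            drugs=drugs,
            manifold=man,
            mode=ctl.get("mode", "none"),
            wt=float(ctl.get("wt", 1.0)),
            qmax_ratio=float(ctl.get("qmax_ratio", 5.0)),
            kappa=float(ctl.get("kappa", 0.25)),
            beta=float(ctl.get("beta", 1.1)),
            interval_s=float(ctl.get("interval_s", 5.0)),
            horizon_min=float(d.get("horizon_min", 30.0)),
            grid_dx_mm=float(grid.get("dx_mm", 0.5)),
            grid_dt_s=float(grid.get("dt_s", 0.5)),
            events=tuple(d.get("events", [])),
        )
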