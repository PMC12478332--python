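"""Deterministic synchronized pump-control policy.

Every control interval the policy observes the normalized tip
concentration of each drug (``Chat = c_tip / c_plateau``) and picks the
carrier rate ``qc`` and per-drug rates ``qd_i`` maximizing a myopic
reward: a delivery-error term (exponential penalty on the normalized
mismatch between the set total delivery rate and the actual tip
delivery ``(qc + sum qd) * Chat``) plus two concentration-gated carrier
terms that trade excess fluid for speed through the weight ``Wt``::

    R = -exp(mhat^2)
        - (1 + Cbar)^2 (1 - Wt) ((Qc    - qc) / s)^2
        - (1 - Cbar)^2 Wt       ((Qcmax - qc) / s)^2

with ``mhat_j = 1 - (qc + sum qd) Chat_j / (Qc + sum Qd)`` averaged over
active drugs and ``s`` the carrier headroom span (so the delivery-error
term dominates once the transient completes).  The excess headroom is
scaled linearly by ``Wt``: the effective pump bounds are
``Qset + Wt (Qmax - Qset)`` (and the mirror image below the set rate),
so ``Wt = 0`` collapses the feasible set to the set rates — no control —
and ``Wt = 1`` grants the full clinically safe range.

Constraints (checked by :func:`feasible` and enforced by the optimizer
and by :func:`guardrail`):

* pump bounds per channel;
* the inlet drug fraction ``qd_i / (qd_i + qc)`` stays within
  ``(1 ± kappa)`` of its set-point value ``Qd_i / (Qd_i + Qc)``;
* the tip delivery overshoot ``(qc + sum qd) * Chat_i`` never exceeds
  ``beta`` times the set total flow.

The constrained maximum is recovered by sequential quadratic
programming (scipy SLSQP) from a fixed multi-start set, with an
exhaustive feasible-grid argmax (:func:`brute_force_policy`) as the
reference oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "ControlParams",
    "PumpAction",
    "reward_det",
    "feasible",
    "to_nondim",
    "from_nondim",
    "solve_policy",
    "brute_force_policy",
    "guardrail",
    "run_controlled",
    "policy_heatmap",
]

_EPS = 1e-9


@dataclass(frozen=True)
class ControlParams:
    """Set/max/min pump rates and policy coefficients.

    Rates are mL/h; ``qd_*`` entries are keyed by port index.
    ``Wt`` in [0, 1] scales the excess-fluid headroom, ``kappa`` bounds
    inlet-fraction fluctuation, ``beta >= 1`` bounds delivery overshoot.
    """

    qc_set: float
    qd_set: dict[int, float]
    qc_max: float
    qd_max: dict[int, float]
    qc_min: float = 0.0
    qd_min: dict[int, float] = field(default_factory=dict)
    wt: float = 1.0
    kappa: float = 0.25
    beta: float = 1.1
    control_interval_s: float = 5.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.wt <= 1.0):
            raise ValueError("Wt must lie in [0, 1]")
        if self.kappa < 0 or self.beta < 1.0:
            raise ValueError("kappa must be >= 0 and beta >= 1")
        if not (self.qc_min <= self.qc_set <= self.qc_max):
            raise ValueError("carrier set rate outside [min, max]")
        for p, q in self.qd_set.items():
            lo = self.qd_min.get(p, 0.0)
            if not (lo <= q <= self.qd_max.get(p, q)):
                raise ValueError(f"drug set rate at port {p} outside [min, max]")

    @property
    def ports(self) -> list[int]:
        return sorted(self.qd_set)

    @property
    def set_total(self) -> float:
        return self.qc_set + sum(self.qd_set.values())

    # Wt-scaled effective bounds: no headroom at Wt=0, full range at Wt=1
    def qc_bounds_eff(self) -> tuple[float, float]:
        return (
            self.qc_set - self.wt * (self.qc_set - self.qc_min),
            self.qc_set + self.wt * (self.qc_max - self.qc_set),
        )

    def qd_bounds_eff(self, port: int) -> tuple[float, float]:
        s = self.qd_set[port]
        lo = self.qd_min.get(port, 0.0)
        hi = self.qd_max.get(port, s)
        return (s - self.wt * (s - lo), s + self.wt * (hi - s))


@dataclass(frozen=True)
class PumpAction:
    """Dimensional pump command: carrier and per-port drug rates (mL/h)."""

    qc: float
    qd: dict[int, float]

    @property
    def total(self) -> float:
        return self.qc + sum(self.qd.values())

    def as_vector(self, ports: list[int]) -> np.ndarray:
        return np.array([self.qc] + [self.qd[p] for p in ports])


def _chat_vec(chat: dict[int, float] | float, ports: list[int]) -> np.ndarray:
    if np.isscalar(chat):
        return np.full(len(ports), float(chat))
    return np.array([chat[p] for p in ports], dtype=float)


def reward_det(chat: dict[int, float] | float, action: PumpAction, params: ControlParams) -> float:
    """Myopic reward of a pump action at the observed tip concentrations."""
    ports = params.ports
    C = np.clip(_chat_vec(chat, ports), 0.0, None)
    S = params.set_total
    total = action.total
    mhat = 1.0 - total * C / S
    r1 = -float(np.mean(np.exp(mhat**2)))
    cbar = float(np.mean(C))
    qc_lo, qc_hi = params.qc_bounds_eff()
    # carrier terms measured against the available headroom so that the
    # delivery-error term dominates once the transient completes
    span = max(qc_hi - params.qc_set, params.qc_set - qc_lo, _EPS)
    t2 = (1.0 + cbar) ** 2 * (1.0 - params.wt) * ((params.qc_set - action.qc) / span) ** 2
    t3 = (1.0 - cbar) ** 2 * params.wt * ((qc_hi - action.qc) / span) ** 2
    return r1 - t2 - t3


def feasible(
    action: PumpAction,
    chat: dict[int, float] | float,
    params: ControlParams,
    rtol: float = 1e-7,
) -> tuple[bool, list[str]]:
    """Check the pump-bound, inlet-fraction and overshoot constraints.

    Returns (ok, list of violated constraint names).  The inlet-fraction
    band is vacuous for a channel with zero total junction flow.
    """
    bad: list[str] = []
    lo_c, hi_c = params.qc_bounds_eff()
    tol = rtol * max(1.0, params.set_total)
    if not (lo_c - tol <= action.qc <= hi_c + tol):
        bad.append("carrier_bounds")
    for p in params.ports:
        lo, hi = params.qd_bounds_eff(p)
        if not (lo - tol <= action.qd[p] <= hi + tol):
            bad.append(f"drug_bounds[{p}]")
    C = _chat_vec(chat, params.ports)
    for i, p in enumerate(params.ports):
        qd, qc = action.qd[p], action.qc
        denom = qd + qc
        set_frac = params.qd_set[p] / (params.qd_set[p] + params.qc_set)
        if denom > tol:
            frac = qd / denom
            if frac > (1.0 + params.kappa) * set_frac + rtol:
                bad.append(f"inlet_fraction_high[{p}]")
            if frac < (1.0 - params.kappa) * set_frac - rtol:
                bad.append(f"inlet_fraction_low[{p}]")
        if action.total * max(C[i], 0.0) > params.beta * params.set_total + tol:
            bad.append(f"overshoot[{p}]")
    return (not bad, bad)


# ------------------------------------------------------------------ nondim
def _map_nondim(q: float, q_set: float, q_min: float, q_max: float) -> float:
    if q > q_max + _EPS or q < q_min - _EPS:
        raise ValueError(f"rate {q} outside [{q_min}, {q_max}]")
    if q >= q_set:
        span = q_max - q_set
        return 0.0 if span <= 0 else (q - q_set) / span
    span = q_set - q_min
    return 0.0 if span <= 0 else (q - q_set) / span


def _unmap_nondim(qhat: float, q_set: float, q_min: float, q_max: float) -> float:
    qhat = float(np.clip(qhat, -1.0, 1.0))
    if qhat >= 0:
        return q_set + qhat * (q_max - q_set)
    return q_set + qhat * (q_set - q_min)


def to_nondim(action: PumpAction, params: ControlParams) -> np.ndarray:
    """Piecewise-linear map to [-1, 1]^n: -1 -> min, 0 -> set, 1 -> max.

    Vector layout: [carrier, drug ports ascending].  Uses the full
    (clinically safe) bounds, not the Wt-scaled ones.
    """
    out = [_map_nondim(action.qc, params.qc_set, params.qc_min, params.qc_max)]
    for p in params.ports:
        out.append(
            _map_nondim(
                action.qd[p], params.qd_set[p], params.qd_min.get(p, 0.0), params.qd_max[p]
            )
        )
    return np.array(out)


def from_nondim(vec: np.ndarray, params: ControlParams) -> PumpAction:
    """Inverse of :func:`to_nondim` (clips inputs to [-1, 1])."""
    qc = _unmap_nondim(vec[0], params.qc_set, params.qc_min, params.qc_max)
    qd = {
        p: _unmap_nondim(vec[1 + i], params.qd_set[p], params.qd_min.get(p, 0.0), params.qd_max[p])
        for i, p in enumerate(params.ports)
    }
    return PumpAction(qc=qc, qd=qd)


# ------------------------------------------------------------------- solve
def _candidates(params: ControlParams, prev: PumpAction | None) -> list[np.ndarray]:
    ports = params.ports
    set_x = np.array([params.qc_set] + [params.qd_set[p] for p in ports])
    hi_x = np.array([params.qc_bounds_eff()[1]] + [params.qd_bounds_eff(p)[1] for p in ports])
    starts = [set_x, hi_x]
    if prev is not None:
        starts.append(prev.as_vector(ports))
    return starts


def _pick(cands: list[tuple[float, PumpAction]], params: ControlParams) -> PumpAction:
    """Best reward; ties broken by lowest total flow, then by closeness to set."""
    best_r = max(r for r, _ in cands)
    tol = 1e-8 * max(1.0, abs(best_r))
    tied = [a for r, a in cands if r >= best_r - tol]
    set_vec = np.array([params.qc_set] + [params.qd_set[p] for p in params.ports])
    tied.sort(key=lambda a: (a.total, float(np.linalg.norm(a.as_vector(params.ports) - set_vec))))
    return tied[0]


def solve_policy(
    chat: dict[int, float] | float,
    params: ControlParams,
    prev_action: PumpAction | None = None,
) -> PumpAction:
    """Constrained reward maximization via multi-start SLSQP.

    Deterministic for fixed inputs: starts are {set rates, max rates,
    previous action} in fixed order; infeasible or failed solves fall
    back to the best feasible start, and finally to the set rates.
    """
    ports = params.ports
    C = np.clip(_chat_vec(chat, ports), 0.0, None)
    bounds = [params.qc_bounds_eff()] + [params.qd_bounds_eff(p) for p in ports]

    def vec_action(x: np.ndarray) -> PumpAction:
        return PumpAction(qc=float(x[0]), qd={p: float(x[1 + i]) for i, p in enumerate(ports)})

    def neg_reward(x: np.ndarray) -> float:
        return -reward_det(dict(zip(ports, C)), vec_action(x), params)

    cons = []
    for i, p in enumerate(ports):
        sf = params.qd_set[p] / (params.qd_set[p] + params.qc_set)
        kp, km = (1.0 + params.kappa) * sf, (1.0 - params.kappa) * sf

        def hi_c(x, i=i, kp=kp):
            return kp * (x[1 + i] + x[0]) - x[1 + i]

        def lo_c(x, i=i, km=km):
            return x[1 + i] - km * (x[1 + i] + x[0])

        cons += [{"type": "ineq", "fun": hi_c}, {"type": "ineq", "fun": lo_c}]
        if C[i] > 0:

            def over(x, ci=C[i]):
                return params.beta * params.set_total - ci * np.sum(x)

            cons.append({"type": "ineq", "fun": over})

    results: list[tuple[float, PumpAction]] = []
    for x0 in _candidates(params, prev_action):
        try:
            res = minimize(
                neg_reward, x0, method="SLSQP", bounds=bounds, constraints=cons,
                options={"maxiter": 200, "ftol": 1e-12},
            )
            act = vec_action(np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds]))
        except Exception:
            continue
        if feasible(act, dict(zip(ports, C)), params)[0]:
            results.append((reward_det(dict(zip(ports, C)), act, params), act))
        x0_act = vec_action(x0)
        if feasible(x0_act, dict(zip(ports, C)), params)[0]:
            results.append((reward_det(dict(zip(ports, C)), x0_act, params), x0_act))
    if not results:
        return PumpAction(qc=params.qc_set, qd=dict(params.qd_set))
    return _pick(results, params)


def brute_force_policy(
    chat: dict[int, float] | float,
    params: ControlParams,
    grid_n: int = 200,
) -> PumpAction:
    """Exhaustive feasible-grid argmax of :func:`reward_det` (oracle).

    Enumerates a regular grid over the effective bounds of every channel
    (practical for one or two drugs) with the same tie-breaking as
    :func:`solve_policy`.
    """
    if grid_n < 50:
        raise ValueError("grid_n must be >= 50")
    ports = params.ports
    C = dict(zip(ports, np.clip(_chat_vec(chat, ports), 0.0, None)))
    axes = [np.linspace(*params.qc_bounds_eff(), grid_n)]
    for p in ports:
        axes.append(np.linspace(*params.qd_bounds_eff(p), grid_n))
    mesh = np.meshgrid(*axes, indexing="ij")
    flat = np.stack([m.ravel() for m in mesh], axis=1)
    cands: list[tuple[float, PumpAction]] = []
    for x in flat:
        act = PumpAction(qc=float(x[0]), qd={p: float(x[1 + i]) for i, p in enumerate(ports)})
        if feasible(act, C, params)[0]:
            cands.append((reward_det(C, act, params), act))
    if not cands:
        return PumpAction(qc=params.qc_set, qd=dict(params.qd_set))
    return _pick(cands, params)


def policy_heatmap(
    params: ControlParams,
    n_chat: int = 41,
    n_qd: int = 41,
) -> "pandas.DataFrame":
    """State–action value grid for a single-drug setup.

    For each (Chat, qd-hat) pair the reward is maximized over the carrier
    axis; infeasible cells carry NaN.  Mirrors the published heatmap
    structure: normalized values with the greedy policy along the rows.
    """
    import pandas as pd

    ports = params.ports
    if len(ports) != 1:
        raise ValueError("heatmap is defined for a single drug")
    p = ports[0]
    chats = np.linspace(0.0, 1.2, n_chat)
    qd_lo, qd_hi = params.qd_bounds_eff(p)
    qds = np.linspace(qd_lo, qd_hi, n_qd)
    qcs = np.linspace(*params.qc_bounds_eff(), 101)
    rows = []
    for ch in chats:
        for qd in qds:
            best = np.nan
            for qc in qcs:
                act = PumpAction(qc=float(qc), qd={p: float(qd)})
                if feasible(act, ch, params)[0]:
                    r = reward_det(ch, act, params)
                    if not (best == best) or r > best:  # NaN-safe max
                        best = r
            rows.append({"chat": ch, "qd_mlh": qd, "value": best})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- guardrail
def guardrail(
    action: PumpAction,
    chat: dict[int, float] | float,
    params: ControlParams,
    max_iter: int = 10,
) -> PumpAction:
    """Project an arbitrary pump command onto the feasible set.

    Clip to the effective bounds, clip each drug rate into its
    inlet-fraction band given the carrier, then scale the whole command
    down (preserving fractions) until the overshoot bound holds.
    Idempotent; feasible actions are returned unchanged; the all-stop
    command is the final fallback.
    """
    ports = params.ports
    C = np.clip(_chat_vec(chat, ports), 0.0, None)
    qc, qd = action.qc, dict(action.qd)
    for _ in range(max_iter):
        lo_c, hi_c = params.qc_bounds_eff()
        qc = float(np.clip(qc, lo_c, hi_c))
        for p in ports:
            lo, hi = params.qd_bounds_eff(p)
            qd[p] = float(np.clip(qd.get(p, params.qd_set[p]), lo, hi))
            # inlet-fraction band given qc: solve qd/(qd+qc) within (1+-kappa)*sf
            sf = params.qd_set[p] / (params.qd_set[p] + params.qc_set)
            for k, is_hi in (((1.0 + params.kappa) * sf, True), ((1.0 - params.kappa) * sf, False)):
                if k >= 1.0:
                    continue
                edge = k * qc / (1.0 - k)
                qd[p] = min(qd[p], max(edge, lo)) if is_hi else max(qd[p], min(edge, hi))
            qd[p] = float(np.clip(qd[p], lo, hi))
        act = PumpAction(qc=qc, qd=qd)
        cmax = float(np.max(C)) if len(C) else 0.0
        if cmax > 0 and act.total * cmax > params.beta * params.set_total:
            s = params.beta * params.set_total / (cmax * act.total)
            qc *= s
            qd = {p: q * s for p, q in qd.items()}
            continue
        if feasible(act, dict(zip(ports, C)), params)[0]:
            return act
    zero = PumpAction(qc=0.0, qd={p: 0.0 for p in ports})
    if feasible(zero, dict(zip(ports, C)), params)[0]:
        return zero
    return PumpAction(qc=params.qc_set, qd=dict(params.qd_set))


# ------------------------------------------------------------- closed loop
def run_controlled(
    manifold,
    drugs,
    params: ControlParams,
    grid,
    horizon_s: float,
    mode: str = "det",
    record_dt_s: float | None = None,
) -> "pandas.DataFrame":
    """Closed-loop trajectory under the deterministic policy.

    Every control interval the tip ``Chat`` of each drug is read from the
    transport simulator, :func:`solve_policy` picks the pump rates, and
    the rates are held until the next interval.  Output schema matches
    :func:`infusekit.transport.simulate`.
    """
    import pandas as pd

    from .transport import TransportSimulator

    if mode not in ("det", "none"):
        raise ValueError("mode must be 'det' or 'none'")
    dt_ctl = params.control_interval_s
    if record_dt_s is None:
        record_dt_s = dt_ctl
    sim = TransportSimulator(manifold, drugs, grid, (params.qc_set, dict(params.qd_set)))
    rows = []
    t = 0.0
    dispensed = 0.0
    prev: PumpAction | None = None
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
        if mode == "det":
            chat = {p: sim.chat(k) for k, p in enumerate(sim.drug_ports)}
            act = solve_policy(chat, params, prev_action=prev)
            prev = act
            sim.set_pump_rates(act.qc, act.qd)
        dt = min(dt_ctl, horizon_s - t)
        sim.advance(dt)
        dispensed += sim.tip_flow_mlh * dt / 3600.0
        t += dt
        record()
    return pd.DataFrame(rows)
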