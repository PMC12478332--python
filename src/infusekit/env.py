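"""Gym-standard drug-infusion environment.

Wraps the reduced-order transport simulator in the familiar
``reset()`` / ``step(action)`` episode API (observation, reward,
terminated, truncated, info) with declared Box spaces, so standard
continuous-control agents can drive multidrug infusions.

* **Observation** (24-vector): six variables for each of the four ports,
  ports ordered 1..4 from the catheter tip — drug-present flag, the
  normalized 5%-front position ``x5``, the ``x5`` velocity (per control
  step, normalized by manifold length), the normalized tip concentration
  ``Chat``, the non-dimensional drug flow ``qhat_d`` and the headroom
  ratio ``Qdmax/Qd``.  Inactive ports are zero-filled.
* **Action** (4-vector in [-1, 1]): the non-dimensional drug flow rate
  per port — 1, 0, −1 map to the maximum, set and minimum allowed rates.
  The carrier pump is not part of the action space; it follows a
  deterministic complement rule (raised toward its maximum in proportion
  to the ``Wt``-weighted mean of the positive drug actions) so the total
  flow mirrors the deterministic policy's behavior.
* **Reward** (four parts, exact decomposition in ``info["reward_parts"]``):
  an action-change penalty, an overshoot penalty above a threshold, a
  reward for advancing the drug front toward the patient, and a reward
  for sitting at the desired delivery rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .policy import ControlParams, PumpAction, _unmap_nondim, guardrail, solve_policy, to_nondim
from .transport import DrugSpec, GridSpec, TransportSimulator

__all__ = ["Box", "RewardConfig", "EpisodeConfig", "InfusionEnv", "reward_rl", "expert_rollout"]

N_PORTS = 4
VARS_PER_PORT = 6


class Box:
    """Minimal continuous space: closed box with uniform sampling."""

    def __init__(self, low, high, shape: tuple[int, ...], dtype=np.float64):
        self.low = np.broadcast_to(np.asarray(low, dtype), shape).copy()
        self.high = np.broadcast_to(np.asarray(high, dtype), shape).copy()
        self.shape = shape
        self.dtype = dtype

    def contains(self, x) -> bool:
        x = np.asarray(x)
        return (
            x.shape == self.shape
            and bool(np.all(x >= self.low - 1e-9))
            and bool(np.all(x <= self.high + 1e-9))
        )

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.low, self.high).astype(self.dtype)


@dataclass(frozen=True)
class RewardConfig:
    """Weights of the four reward parts (all >= 0).

    ``overshoot_threshold`` is in normalized-delivery units (>= 1);
    ``attainment_band`` is the |Dhat - 1| half-width (Dhat = delivery
    rate / set delivery rate) that counts as "at the desired rate".
    """

    w_action: float = 0.1
    w_overshoot: float = 1.0
    w_front: float = 1.0
    w_target: float = 2.0
    overshoot_threshold: float = 1.1
    attainment_band: float = 0.05

    def __post_init__(self) -> None:
        if min(self.w_action, self.w_overshoot, self.w_front, self.w_target) < 0:
            raise ValueError("reward weights must be >= 0")
        if self.overshoot_threshold < 1.0:
            raise ValueError("overshoot threshold must be >= 1")


@dataclass(frozen=True)
class EpisodeConfig:
    max_steps: int = 120
    target_dwell_steps: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.max_steps <= 0:
            raise ValueError("max_steps must be > 0")


def reward_rl(
    prev_action: np.ndarray,
    action: np.ndarray,
    delivery_hat: np.ndarray,
    d_x5: np.ndarray,
    config: RewardConfig,
    active: np.ndarray,
) -> tuple[float, dict[str, float]]:
    """Four-part step reward with an exact per-term breakdown.

    r = - w1 * sum_active (da)^2  - w2 * sum max(0, Dhat - thr)^2
        + w3 * sum max(0, dx5)    + w4 * 1[all active |Dhat - 1| <= band]

    ``delivery_hat`` is the tip delivery rate normalized by its set value
    (flow x concentration): under dilution control the tip concentration
    deliberately sits below its set-rate plateau while the delivery rate
    is on target, so target attainment and overshoot are judged on
    delivery, which coincides with ``Chat`` at set flows.
    """
    da2 = float(np.sum(((action - prev_action) ** 2)[active]))
    over = float(np.sum(np.maximum(0.0, delivery_hat[active] - config.overshoot_threshold) ** 2))
    prog = float(np.sum(np.maximum(0.0, d_x5[active])))
    at = float(np.all(np.abs(delivery_hat[active] - 1.0) <= config.attainment_band)) if active.any() else 0.0
    parts = {
        "action_change": -config.w_action * da2,
        "overshoot": -config.w_overshoot * over,
        "front_progress": config.w_front * prog,
        "attainment": config.w_target * at,
    }
    return float(sum(parts.values())), parts


class InfusionEnv:
    """Drug-infusion episode driven by the reduced-order transport core."""

    def __init__(
        self,
        manifold,
        drugs: dict[int, DrugSpec],
        params: ControlParams,
        grid: GridSpec | None = None,
        reward_config: RewardConfig | None = None,
        episode_config: EpisodeConfig | None = None,
        guardrail_actions: bool = False,
    ):
        self.manifold = manifold
        self.drugs = drugs
        self.params = params
        self.grid = grid or GridSpec()
        self.reward_config = reward_config or RewardConfig(overshoot_threshold=params.beta)
        self.episode_config = episode_config or EpisodeConfig()
        self.guardrail_actions = guardrail_actions
        self.observation_space = Box(
            low=np.tile([0.0, 0.0, -1.0, 0.0, -1.0, 0.0], N_PORTS),
            high=np.tile([1.0, 1.0, 1.0, np.inf, 1.0, np.inf], N_PORTS),
            shape=(N_PORTS * VARS_PER_PORT,),
        )
        self.action_space = Box(-1.0, 1.0, shape=(N_PORTS,))
        self._rng = np.random.default_rng(self.episode_config.seed)
        self.sim: TransportSimulator | None = None

    # ------------------------------------------------------------------ api
    def reset(self, seed: int | None = None):
        """Fresh drug-free manifold primed with carrier; returns (obs, info)."""
        if seed is not None:
            self._rng = np.random.default_rng(seed)
        self.sim = TransportSimulator(
            self.manifold, self.drugs, self.grid,
            (self.params.qc_set, dict(self.params.qd_set)),
        )
        self._step_count = 0
        self._dwell = 0
        self._prev_action = np.zeros(N_PORTS)
        self._prev_x5 = self._x5_vector()
        obs = self._observe()
        return obs, {"t_s": 0.0}

    def step(self, action, carrier_override_mlh: float | None = None):
        """Apply a 4-vector action, evolve one control interval.

        ``carrier_override_mlh`` lets the deterministic expert drive its
        own carrier rate during demonstration rollouts; RL steps leave it
        ``None`` and use the complement rule.
        """
        if self.sim is None:
            raise RuntimeError("call reset() before step()")
        action = np.asarray(action, dtype=float).reshape(N_PORTS)
        if not np.all(np.isfinite(action)):
            raise ValueError("action contains NaN/inf")
        action = np.clip(action, -1.0, 1.0)
        act = self._dimensionalize(action, carrier_override_mlh)
        if self.guardrail_actions:
            chat = {p: self.sim.chat(k) for k, p in enumerate(self.sim.drug_ports)}
            act = guardrail(act, chat, self.params)
        self.sim.set_pump_rates(act.qc, act.qd)
        self.sim.advance(self.params.control_interval_s)
        self._step_count += 1

        dhat_vec = self._delivery_hat_vector()
        x5 = self._x5_vector()
        r, parts = reward_rl(
            self._prev_action, action, dhat_vec, x5 - self._prev_x5,
            self.reward_config, self._active_mask(),
        )
        in_band = bool(parts["attainment"] > 0)
        self._dwell = self._dwell + 1 if in_band else 0
        terminated = self._dwell >= self.episode_config.target_dwell_steps
        truncated = self._step_count >= self.episode_config.max_steps and not terminated
        self._prev_action = action
        self._prev_x5 = x5
        obs = self._observe()
        info = {
            "t_s": self.sim.state.clock_s,
            "reward_parts": parts,
            "carrier_mlh": self.sim.carrier,
            "drug_rates_mlh": dict(self.sim.rates),
            "delivery": {
                self.drugs[p].name: self.sim.tip_delivery_rate(k)
                for k, p in enumerate(self.sim.drug_ports)
            },
            "total_flow_mlh": self.sim.tip_flow_mlh,
        }
        return obs, r, bool(terminated), bool(truncated), info

    def render(self, path: str | None = None):
        """Concentration-profile snapshot as a DataFrame (optionally CSV)."""
        import pandas as pd

        df = pd.DataFrame({"x_mm": self.sim.x_center})
        for k, p in enumerate(self.sim.drug_ports):
            df[f"c_{self.drugs[p].name}"] = self.sim.state.conc[k]
        if path is not None:
            df.to_csv(path, index=False)
        return df

    # ------------------------------------------------------------- internals
    def _active_mask(self) -> np.ndarray:
        mask = np.zeros(N_PORTS, dtype=bool)
        for p in self.sim.drug_ports:
            if self.params.qd_set.get(p, 0.0) > 0:
                mask[p - 1] = True
        return mask

    def _chat_vector(self) -> np.ndarray:
        out = np.zeros(N_PORTS)
        for k, p in enumerate(self.sim.drug_ports):
            out[p - 1] = self.sim.chat(k)
        return out

    def _delivery_hat_vector(self) -> np.ndarray:
        """Tip delivery rate normalized by the set delivery rate, per port."""
        out = np.zeros(N_PORTS)
        for k, p in enumerate(self.sim.drug_ports):
            sd = self.sim.set_delivery_rate(k)
            if sd > 0:
                out[p - 1] = self.sim.tip_delivery_rate(k) / sd
        return out

    def _x5_vector(self) -> np.ndarray:
        out = np.zeros(N_PORTS)
        for k, p in enumerate(self.sim.drug_ports):
            out[p - 1] = self.sim.front_position(k)
        return out

    def _dimensionalize(self, action: np.ndarray, carrier_override: float | None) -> PumpAction:
        qd = {}
        for p in self.sim.drug_ports:
            qd[p] = _unmap_nondim(
                action[p - 1], self.params.qd_set[p],
                self.params.qd_min.get(p, 0.0), self.params.qd_max[p],
            )
        if carrier_override is not None:
            qc = float(carrier_override)
        else:
            active = self._active_mask()
            drive = float(np.mean(np.maximum(action[active], 0.0))) if active.any() else 0.0
            qc = self.params.qc_set + self.params.wt * drive * (
                self.params.qc_max - self.params.qc_set
            )
        return PumpAction(qc=qc, qd=qd)

    def _observe(self) -> np.ndarray:
        obs = np.zeros(N_PORTS * VARS_PER_PORT)
        x5 = self._x5_vector()
        dt_steps = 1.0  # velocity per control step, normalized by manifold length
        for k, p in enumerate(self.sim.drug_ports):
            if self.params.qd_set.get(p, 0.0) <= 0:
                continue
            j = (p - 1) * VARS_PER_PORT
            qhat = np.clip(
                (self.sim.rates[p] - self.params.qd_set[p])
                / max(self.params.qd_max[p] - self.params.qd_set[p], 1e-12),
                -1.0, 1.0,
            ) if self.sim.rates[p] >= self.params.qd_set[p] else np.clip(
                (self.sim.rates[p] - self.params.qd_set[p])
                / max(self.params.qd_set[p] - self.params.qd_min.get(p, 0.0), 1e-12),
                -1.0, 1.0,
            )
            obs[j] = 1.0
            obs[j + 1] = x5[p - 1]
            obs[j + 2] = np.clip((x5[p - 1] - self._prev_x5[p - 1]) / dt_steps, -1.0, 1.0)
            obs[j + 3] = self.sim.chat(k)
            obs[j + 4] = qhat
            obs[j + 5] = self.params.qd_max[p] / self.params.qd_set[p]
        return obs


def expert_rollout(env: InfusionEnv, params: ControlParams | None = None) -> list:
    """Demonstration episode from the deterministic policy.

    Runs :func:`infusekit.policy.solve_policy` in the gym loop (the
    expert drives its own carrier via the override), converting the
    chosen drug rates to non-dimensional 4-vector actions.  Returns
    :class:`infusekit.rl.buffer.Transition` objects tagged ``expert``.
    """
    from .rl.buffer import Transition

    params = params or env.params
    obs, _ = env.reset()
    out = []
    prev: PumpAction | None = None
    done = False
    while not done:
        chat = {p: env.sim.chat(k) for k, p in enumerate(env.sim.drug_ports)}
        act = solve_policy(chat, params, prev_action=prev)
        prev = act
        vec = to_nondim(act, params)
        a4 = np.zeros(N_PORTS)
        for i, p in enumerate(params.ports):
            a4[p - 1] = vec[1 + i]
        nxt, r, term, trunc, info = env.step(a4, carrier_override_mlh=act.qc)
        out.append(Transition(obs=obs, action=a4.copy(), reward=r, next_obs=nxt,
                              done=term, source="expert"))
        obs = nxt
        done = term or trunc
    return out
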