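"""Twin Delayed Deep Deterministic policy gradient (TD3) agent.

Standard TD3: twin critics with clipped double-Q targets, delayed actor
updates, target-policy smoothing noise and Polyak-averaged target
networks.  Batches are drawn from the dual expert/experience buffer
(:mod:`infusekit.rl.buffer`), which is the one departure from vanilla
TD3: 20% of every batch replays demonstrations from the deterministic
policy, which bootstraps the critic landscape around clinically sound
behavior early in training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .buffer import DualBuffer, Transition
from .nets import MLP, Adam

__all__ = ["TD3Config", "TD3Agent", "train", "act", "evaluate"]


@dataclass(frozen=True)
class TD3Config:
    gamma: float = 0.99
    hidden: tuple[int, int] = (64, 64)
    actor_lr: float = 1e-3
    critic_lr: float = 1e-3
    tau: float = 0.005
    policy_delay: int = 2
    target_noise: float = 0.2
    target_noise_clip: float = 0.5
    exploration_noise: float = 0.1
    batch_size: int = 128
    steps: int = 5000
    warmup_steps: int = 200
    eval_every: int = 500
    eval_episodes: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma < 1.0):
            raise ValueError("gamma must lie in (0, 1)")
        if min(self.hidden) <= 0 or self.batch_size <= 0 or self.steps <= 0:
            raise ValueError("sizes must be positive")


class TD3Agent:
    """Actor + twin critics with their target copies."""

    def __init__(self, obs_dim: int, act_dim: int, config: TD3Config):
        self.config = config
        rng = np.random.default_rng(config.seed)
        h = list(config.hidden)
        self.actor = MLP([obs_dim] + h + [act_dim], tanh_out=True, rng=rng)
        self.q1 = MLP([obs_dim + act_dim] + h + [1], rng=rng)
        self.q2 = MLP([obs_dim + act_dim] + h + [1], rng=rng)
        self.actor_t = self.actor.copy()
        self.q1_t = self.q1.copy()
        self.q2_t = self.q2.copy()
        self.opt_actor = Adam(self.actor.parameters(), lr=config.actor_lr)
        self.opt_q1 = Adam(self.q1.parameters(), lr=config.critic_lr)
        self.opt_q2 = Adam(self.q2.parameters(), lr=config.critic_lr)

    def act(self, obs: np.ndarray, explore: bool = False,
            rng: np.random.Generator | None = None) -> np.ndarray:
        """Deterministic actor output in [-1, 1]; Gaussian noise if exploring."""
        a = self.actor(np.asarray(obs, float))[0]
        if explore:
            rng = rng or np.random.default_rng()
            a = a + rng.normal(0.0, self.config.exploration_noise, size=a.shape)
        return np.clip(a, -1.0, 1.0)

    # ------------------------------------------------------------- updates
    def update(self, batch: list[Transition], step: int,
               rng: np.random.Generator) -> dict[str, float]:
        cfg = self.config
        S = np.stack([t.obs for t in batch])
        A = np.stack([t.action for t in batch])
        R = np.array([t.reward for t in batch])[:, None]
        S2 = np.stack([t.next_obs for t in batch])
        D = np.array([float(t.done) for t in batch])[:, None]

        # clipped double-Q target with smoothing noise
        noise = np.clip(
            rng.normal(0.0, cfg.target_noise, size=A.shape),
            -cfg.target_noise_clip, cfg.target_noise_clip,
        )
        A2 = np.clip(self.actor_t(S2) + noise, -1.0, 1.0)
        X2 = np.concatenate([S2, A2], axis=1)
        q_min = np.minimum(self.q1_t(X2), self.q2_t(X2))
        y = R + cfg.gamma * (1.0 - D) * q_min

        X = np.concatenate([S, A], axis=1)
        losses = {}
        for name, q, opt in (("q1", self.q1, self.opt_q1), ("q2", self.q2, self.opt_q2)):
            pred = q(X)
            err = pred - y
            losses[name] = float(np.mean(err**2))
            grads, _ = q.backward(2.0 * err / len(batch))
            opt.step(grads)
        if not np.isfinite(losses["q1"]) or not np.isfinite(losses["q2"]):
            raise FloatingPointError("critic loss diverged (NaN/inf)")

        if step % cfg.policy_delay == 0:
            # actor ascent on Q1(s, pi(s))
            Api = self.actor(S)
            Xpi = np.concatenate([S, Api], axis=1)
            self.q1(Xpi)
            _, gx = self.q1.backward(-np.ones((len(batch), 1)) / len(batch))
            ga = gx[:, S.shape[1]:]
            grads, _ = self.actor.backward(ga)
            self.opt_actor.step(grads)
            losses["actor"] = float(-np.mean(self.q1(np.concatenate([S, self.actor(S)], axis=1))))
            for t_net, net in ((self.actor_t, self.actor), (self.q1_t, self.q1), (self.q2_t, self.q2)):
                t_net.polyak_from(net, cfg.tau)
        return losses


def act(agent: TD3Agent, observation: np.ndarray, explore: bool = False,
        rng: np.random.Generator | None = None) -> np.ndarray:
    """Module-level convenience wrapper around :meth:`TD3Agent.act`."""
    return agent.act(observation, explore=explore, rng=rng)


def evaluate(env, agent: TD3Agent, episodes: int = 1) -> dict[str, float]:
    """Deterministic evaluation episodes; mean return and delivery t90."""
    returns = []
    t90s = []
    for _ in range(episodes):
        obs, _ = env.reset()
        total = 0.0
        t90 = None
        done = False
        while not done:
            obs, r, term, trunc, info = env.step(agent.act(obs))
            total += r
            if t90 is None:
                del_ok = all(
                    d >= 0.9 * env.params.qd_set[p] * env.drugs[p].syringe_conc
                    for p in env.sim.drug_ports
                    for d in [info["delivery"][env.drugs[p].name]]
                )
                if del_ok:
                    t90 = info["t_s"]
            done = term or trunc
        returns.append(total)
        t90s.append(t90 if t90 is not None else np.inf)
    return {"return": float(np.mean(returns)), "t90_s": float(np.mean(t90s))}


def train(env, config: TD3Config, buffer: DualBuffer):
    """Run TD3 on an infusion environment with the dual buffer.

    The expert store must be pre-filled (and is sealed here).  Returns
    ``(agent, learning_curve)`` where the learning curve is a list of
    dicts with step, evaluation return and evaluation t90.  Fully
    deterministic for a fixed (config, env) pair.
    """
    rng = np.random.default_rng(config.seed)
    obs, _ = env.reset()
    obs_dim = obs.shape[0]
    act_dim = env.action_space.shape[0]
    agent = TD3Agent(obs_dim, act_dim, config)
    buffer.seal_expert()
    curve = []
    for step in range(1, config.steps + 1):
        if step <= config.warmup_steps:
            a = env.action_space.sample(rng)
        else:
            a = agent.act(obs, explore=True, rng=rng)
        nxt, r, term, trunc, _ = env.step(a)
        buffer.add(Transition(obs=obs, action=np.asarray(a, float), reward=r,
                              next_obs=nxt, done=term, source="experience"))
        obs = nxt
        if term or trunc:
            obs, _ = env.reset()
        if len(buffer.expert) or len(buffer.experience) >= config.batch_size:
            batch = buffer.sample(config.batch_size, rng)
            agent.update(batch, step, rng)
        if step % config.eval_every == 0 or step == config.steps:
            ev = evaluate(env, agent, config.eval_episodes)
            curve.append({"step": step, **ev})
            obs, _ = env.reset()
    return agent, curve
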