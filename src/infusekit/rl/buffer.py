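"""Dual replay buffer: persistent expert store + FIFO experience store.

Training batches mix demonstration transitions from the deterministic
policy with the agent's own experience at a fixed 20:80 (expert :
experience) count split — exact counts per batch, not Bernoulli, for
reproducibility.  The expert store is never evicted; the experience
store is a bounded FIFO.  Until the experience store holds at least one
full batch, batches are drawn entirely from the expert store (cold
start).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

__all__ = ["Transition", "DualBuffer", "sample_dual"]


@dataclass(frozen=True)
class Transition:
    obs: np.ndarray
    action: np.ndarray
    reward: float
    next_obs: np.ndarray
    done: bool
    source: str = "experience"  # {"expert", "experience"}

    def __post_init__(self) -> None:
        if not np.isfinite(self.reward):
            raise ValueError("reward must be finite")
        if self.source not in ("expert", "experience"):
            raise ValueError(f"unknown source {self.source!r}")


class DualBuffer:
    """Expert store (persistent) + experience store (FIFO), 20:80 sampling."""

    def __init__(self, experience_capacity: int = 100_000, expert_fraction: float = 0.20):
        if not (0.0 <= expert_fraction <= 1.0):
            raise ValueError("expert fraction must lie in [0, 1]")
        self.expert: list[Transition] = []
        self.experience: deque[Transition] = deque(maxlen=int(experience_capacity))
        self.expert_fraction = expert_fraction
        self._expert_sealed = False

    def add_expert(self, transitions) -> None:
        if self._expert_sealed:
            raise RuntimeError("expert store is read-only after sealing")
        for tr in transitions:
            if tr.source != "expert":
                raise ValueError("expert store accepts only expert transitions")
            self.expert.append(tr)

    def seal_expert(self) -> None:
        """Freeze the expert store (read-only for the rest of training)."""
        self._expert_sealed = True

    def add(self, tr: Transition) -> None:
        if tr.source != "experience":
            raise ValueError("experience store accepts only experience transitions")
        self.experience.append(tr)

    def __len__(self) -> int:
        return len(self.expert) + len(self.experience)

    def sample(self, batch: int, rng: np.random.Generator) -> list[Transition]:
        return sample_dual(self, batch, rng)


def sample_dual(buffer: DualBuffer, batch: int, rng: np.random.Generator) -> list[Transition]:
    """Draw a batch with exactly ``round(f * batch)`` expert transitions.

    Cold-start rule: while the experience store holds fewer than one
    batch, the whole batch comes from the expert store.
    """
    if batch <= 0:
        raise ValueError("batch size must be positive")
    if len(buffer.experience) < batch:
        if not buffer.expert:
            raise RuntimeError("both stores empty (or experience short with no expert)")
        idx = rng.integers(0, len(buffer.expert), size=batch)
        return [buffer.expert[i] for i in idx]
    n_expert = int(round(buffer.expert_fraction * batch)) if buffer.expert else 0
    n_exp = batch - n_expert
    out: list[Transition] = []
    if n_expert:
        idx = rng.integers(0, len(buffer.expert), size=n_expert)
        out += [buffer.expert[i] for i in idx]
    idx = rng.integers(0, len(buffer.experience), size=n_exp)
    out += [buffer.experience[i] for i in idx]
    return out
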