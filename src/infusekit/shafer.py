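"""The Shafer number: is an infusion transport-limited?

Two timescales govern how quickly an infused drug acts: the therapeutic
action timescale ``tau_a`` (time to act on cellular targets once in the
body) and the manifold transport timescale ``tau_p = Vdead / Qtot``
(time for the drug to traverse the dead volume to the catheter tip).
Their ratio is the Shafer number,

    Sh = tau_a * Qtot / Vdead.

When ``Sh < 1`` the transport time throttles the therapeutic response —
the infusion is *transport-limited* and benefits from active delivery
management; at ``Sh >= 1`` the drug's own action time dominates and
there is nothing for pump control to win.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ShaferInput", "shafer_number", "classify"]

TRANSPORT_LIMITED = "transport_limited"
ACTION_LIMITED = "action_limited"


@dataclass(frozen=True)
class ShaferInput:
    """Inputs to the Shafer number (strictly positive).

    tau_a_s : therapeutic action timescale, seconds
    q_tot_mlh : total set flow (carrier + drugs), mL/h
    v_dead_ml : dead volume from the drug's port to the tip, mL
    """

    tau_a_s: float
    q_tot_mlh: float
    v_dead_ml: float

    def __post_init__(self) -> None:
        if self.tau_a_s <= 0 or self.q_tot_mlh <= 0 or self.v_dead_ml <= 0:
            raise ValueError("Shafer inputs must be strictly positive")


def shafer_number(inp: ShaferInput) -> float:
    """``Sh = tau_a * Qtot / Vdead`` (dimensionless; h<->s handled here)."""
    q_tot_mls = inp.q_tot_mlh / 3600.0
    return inp.tau_a_s * q_tot_mls / inp.v_dead_ml


def classify(sh: float) -> str:
    """Transport-limited iff ``Sh < 1`` (boundary counts as action-limited)."""
    if sh <= 0:
        raise ValueError("Sh must be positive")
    return TRANSPORT_LIMITED if sh < 1.0 else ACTION_LIMITED
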