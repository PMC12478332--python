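"""Geometry of stopcock–catheter infusion manifolds.

The assembly is modelled as an ordered chain of piecewise-continuous
cylindrical units running from the carrier inlet (manifold entrance,
``x = 0``) to the catheter tip (``x = L``).  Drug pumps tee in at ports
located along the chain; by clinical convention ports are numbered from
the catheter tip (port 1 is the most tip-ward).  The *dead volume* of a
port is the fluid volume between that port and the tip — the volume a
drug must traverse before it reaches the patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SegmentSpec",
    "PortMap",
    "ManifoldSpec",
    "build_manifold",
    "dead_volume",
    "segment_flows",
]

#: mm^3 per mL
_MM3_PER_ML = 1000.0


@dataclass(frozen=True)
class SegmentSpec:
    """One cylindrical unit of the manifold chain.

    Parameters
    ----------
    length_mm : float
        Axial length in mm.
    radius_mm : float
        Internal radius ``a`` in mm.
    label : str
        Free-text label (e.g. ``"stopcock_2"``, ``"catheter"``).
    """

    length_mm: float
    radius_mm: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.length_mm <= 0:
            raise ValueError(f"segment length must be > 0, got {self.length_mm}")
        if self.radius_mm <= 0:
            raise ValueError(f"segment radius must be > 0, got {self.radius_mm}")

    @property
    def area_mm2(self) -> float:
        """Cross-sectional area ``pi * a**2`` in mm^2."""
        return float(np.pi * self.radius_mm**2)

    @property
    def volume_mm3(self) -> float:
        return self.area_mm2 * self.length_mm


class PortMap(dict):
    """Mapping ``port index -> axial position`` (mm from the entrance).

    Port 1 is nearest the catheter tip; indices run 1..4.  Positions must
    be strictly inside the manifold and pairwise distinct.
    """

    def __init__(self, positions_mm: dict[int, float]):
        super().__init__({int(k): float(v) for k, v in positions_mm.items()})
        if not self:
            raise ValueError("at least one port is required")
        for idx in self:
            if idx < 1 or idx > 4:
                raise ValueError(f"port indices must be 1..4, got {idx}")
        vals = list(self.values())
        if len(set(vals)) != len(vals):
            raise ValueError("port positions must be distinct")
        # port 1 is nearest the tip, i.e. largest x in the entrance->tip frame
        order = sorted(self, key=lambda k: self[k])
        if order != sorted(self, reverse=True):
            raise ValueError(
                "port numbering must decrease with distance from the tip "
                "(port 1 nearest the tip)"
            )


@dataclass(frozen=True)
class ManifoldSpec:
    """Validated manifold: segments (entrance → tip) plus drug ports."""

    segments: tuple[SegmentSpec, ...]
    ports: dict[int, float] = field(default_factory=dict)

    @property
    def total_length_mm(self) -> float:
        return float(sum(s.length_mm for s in self.segments))

    @property
    def boundaries_mm(self) -> np.ndarray:
        """Cumulative axial coordinate of segment boundaries, length n+1."""
        return np.concatenate([[0.0], np.cumsum([s.length_mm for s in self.segments])])

    @property
    def total_volume_mm3(self) -> float:
        return float(sum(s.volume_mm3 for s in self.segments))

    def segment_at(self, x_mm: float) -> int:
        """Index of the segment containing axial position ``x_mm``."""
        b = self.boundaries_mm
        if x_mm < 0 or x_mm > b[-1]:
            raise ValueError(f"x={x_mm} outside manifold [0, {b[-1]}]")
        return int(min(np.searchsorted(b, x_mm, side="right") - 1, len(self.segments) - 1))

    def area_at(self, x_mm: float) -> float:
        return self.segments[self.segment_at(x_mm)].area_mm2

    def radius_at(self, x_mm: float) -> float:
        return self.segments[self.segment_at(x_mm)].radius_mm


def build_manifold(segments: list[SegmentSpec], ports: PortMap | dict[int, float]) -> ManifoldSpec:
    """Validate and assemble a :class:`ManifoldSpec`.

    Raises
    ------
    ValueError
        If a port lies outside the manifold, on the entrance/tip boundary,
        or two ports coincide.
    """
    if not segments:
        raise ValueError("segment list must be non-empty")
    if not isinstance(ports, PortMap):
        ports = PortMap(ports)
    total = sum(s.length_mm for s in segments)
    for idx, x in ports.items():
        if not (0.0 <= x < total):
            raise ValueError(f"port {idx} at x={x} mm outside manifold [0, {total})")
    return ManifoldSpec(segments=tuple(segments), ports=dict(ports))


def dead_volume(manifold: ManifoldSpec, port_index: int) -> float:
    """Fluid volume (mL) between a port and the catheter tip.

    Additive over segments, independent of any grid.  Monotone
    non-increasing as the port moves toward the tip.
    """
    if port_index not in manifold.ports:
        raise KeyError(f"unknown port {port_index}")
    x0 = manifold.ports[port_index]
    b = manifold.boundaries_mm
    vol = 0.0
    for i, seg in enumerate(manifold.segments):
        lo, hi = b[i], b[i + 1]
        if hi <= x0:
            continue
        vol += seg.area_mm2 * (hi - max(lo, x0))
    return vol / _MM3_PER_ML


def segment_flows(
    manifold: ManifoldSpec,
    carrier_rate: float,
    drug_rates: dict[int, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment volumetric flow (mL/h) and mean velocity (mm/s).

    Flow in a segment is the carrier rate plus all drug rates whose ports
    lie at or upstream of the segment's upstream boundary; it is
    non-decreasing toward the tip and the tip flow equals the sum of all
    pump rates exactly.
    """
    if carrier_rate < 0:
        raise ValueError("carrier rate must be >= 0")
    for idx, q in drug_rates.items():
        if q < 0:
            raise ValueError(f"drug rate at port {idx} must be >= 0")
        if idx not in manifold.ports:
            raise KeyError(f"unknown port {idx}")
    b = manifold.boundaries_mm
    flows = np.full(len(manifold.segments), float(carrier_rate))
    for idx, q in drug_rates.items():
        x = manifold.ports[idx]
        # the drug enters every segment whose upstream boundary is >= x
        flows[b[:-1] >= x - 1e-12] += q
    areas = np.array([s.area_mm2 for s in manifold.segments])
    # mL/h -> mm^3/s, then / mm^2 -> mm/s
    vel = flows * _MM3_PER_ML / 3600.0 / areas
    return flows, vel
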