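"""Reduced-order axial transport of drugs through an infusion manifold.

Each drug is a passive scalar advected by the hydrodynamically coupled
pump flows and dispersed axially with the time-dependent
Gill–Sankarasubramanian coefficient (:mod:`infusekit.dispersion`).  The
manifold network is discretized as a single 1D finite-volume chain with
per-segment cross sections; segment junctions carry matched
outlet–inlet (flux-continuous) conditions by construction and drug
ports enter as point sources at grid faces where the volumetric flow
steps up.

Time stepping is Crank–Nicolson (second order, tridiagonal solves via
banded LU), with a backward-Euler first step after every flow or
concentration discontinuity to damp oscillations at sharp fronts.
Internal substepping keeps the cell Courant number below a configured
bound at the current flows.

Internal units: mm, s, mm^3; pump rates are accepted in mL/h and
diffusivities in m^2/s at the public surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from .dispersion import dispersion_coefficient
from .manifold import ManifoldSpec, _MM3_PER_ML

__all__ = [
    "DrugSpec",
    "GridSpec",
    "TransportState",
    "TransportSimulator",
    "inlet_mixing",
    "simulate",
]

_MLH_TO_MM3S = _MM3_PER_ML / 3600.0

#: clip floor for Crank–Nicolson undershoot (absolute concentration)
_NEG_CLIP = -1e-10


@dataclass(frozen=True)
class DrugSpec:
    """A drug as seen by the transport model.

    Parameters
    ----------
    name : str
    syringe_conc : float
        Concentration in the syringe, arbitrary mass/mL units.
    diffusivity_m2s : float
        Molecular diffusivity (m^2/s); small-molecule drugs in saline are
        around 5e-10.
    tau_a_s : float
        Therapeutic action timescale (s), used by the Shafer number.
    """

    name: str
    syringe_conc: float = 1.0
    diffusivity_m2s: float = 5e-10
    tau_a_s: float = 40.0

    def __post_init__(self) -> None:
        if self.syringe_conc <= 0 or self.diffusivity_m2s <= 0 or self.tau_a_s <= 0:
            raise ValueError("drug parameters must be positive")

    @property
    def diffusivity_mm2s(self) -> float:
        return self.diffusivity_m2s * 1e6


@dataclass(frozen=True)
class GridSpec:
    """Numerical grid and stepping parameters."""

    dx_mm: float = 0.25
    dt_s: float = 0.1
    courant_max: float = 1.0
    backward_euler_first_step: bool = True
    min_cells_per_segment: int = 3

    def __post_init__(self) -> None:
        if self.dx_mm <= 0 or self.dt_s <= 0 or self.courant_max <= 0:
            raise ValueError("grid parameters must be positive")


@dataclass
class TransportState:
    """Axial mean-concentration fields plus clocks."""

    conc: np.ndarray          # (n_drugs, n_cells)
    epoch_time_s: np.ndarray  # (n_drugs,) time since each drug's infusion epoch began
    clock_s: float = 0.0
    neg_clip_events: int = 0

    def copy(self) -> "TransportState":
        return TransportState(
            conc=self.conc.copy(),
            epoch_time_s=self.epoch_time_s.copy(),
            clock_s=self.clock_s,
            neg_clip_events=self.neg_clip_events,
        )


def inlet_mixing(
    carrier_rate: float,
    drug_rates: dict[int, float],
    drugs: dict[int, DrugSpec],
    port: int,
    upstream_conc: dict[str, float] | None = None,
) -> dict[str, float]:
    """Flux-weighted concentration of every drug just downstream of a port.

    ``downstream c_j = (Q_up * c_up,j + q_d,j * Cs_j * [j enters here]) / Q_down``
    — conserves the advective mass flux across the junction exactly.
    """
    upstream_conc = upstream_conc or {}
    ports_sorted = sorted(drugs, key=lambda p: -p)  # port 4 (entrance-most) first
    if port not in drugs:
        raise KeyError(f"no drug at port {port}")
    q_up = carrier_rate + sum(
        drug_rates.get(p, 0.0) for p in ports_sorted if p > port
    )
    q_in = drug_rates.get(port, 0.0)
    q_down = q_up + q_in
    if q_down <= 0:
        raise ZeroDivisionError("zero total flow at an injection junction (stalled infusion)")
    out: dict[str, float] = {}
    for p, spec in drugs.items():
        up = upstream_conc.get(spec.name, 0.0)
        inj = q_in * spec.syringe_conc if p == port else 0.0
        out[spec.name] = (q_up * up + inj) / q_down
    return out


class TransportSimulator:
    """Finite-volume network solver for multidrug transport.

    Parameters
    ----------
    manifold : ManifoldSpec
    drugs : dict[int, DrugSpec]
        Drug per port index.
    grid : GridSpec
    set_rates : (carrier, {port: rate}) in mL/h
        Nominal set rates; used for plateau normalization (``Chat``) and
        front-position thresholds.  Commanded rates start here.
    """

    def __init__(
        self,
        manifold: ManifoldSpec,
        drugs: dict[int, DrugSpec],
        grid: GridSpec,
        set_rates: tuple[float, dict[int, float]],
    ):
        self.manifold = manifold
        self.grid = grid
        self.drug_ports = sorted(drugs)            # ascending port index
        self.drugs = {p: drugs[p] for p in self.drug_ports}
        self.set_carrier, set_drug = set_rates
        self.set_drug = {p: float(set_drug.get(p, 0.0)) for p in self.drug_ports}

        self._build_grid()
        n = len(self.drug_ports)
        self.state = TransportState(
            conc=np.zeros((n, self.n_cells)),
            epoch_time_s=np.zeros(n),
        )
        self.carrier = float(self.set_carrier)
        self.rates = dict(self.set_drug)
        self._event_pending = True  # first step after construction uses BE
        self._last_rates_nonzero = {p: self.rates[p] > 0 for p in self.drug_ports}
        # per-drug cumulative mass ledgers (for conservation checks)
        self.mass_in = np.zeros(n)
        self.mass_out = np.zeros(n)
        self._update_flows()

    # ---------------------------------------------------------------- grid
    def _build_grid(self) -> None:
        m = self.manifold
        dxs, areas, radii, seg_idx = [], [], [], []
        for i, seg in enumerate(m.segments):
            ncell = max(self.grid.min_cells_per_segment, round(seg.length_mm / self.grid.dx_mm))
            dx = seg.length_mm / ncell
            dxs += [dx] * ncell
            areas += [seg.area_mm2] * ncell
            radii += [seg.radius_mm] * ncell
            seg_idx += [i] * ncell
        self.dx = np.asarray(dxs)
        self.area = np.asarray(areas)
        self.radius = np.asarray(radii)
        self.n_cells = len(self.dx)
        self.x_face = np.concatenate([[0.0], np.cumsum(self.dx)])
        self.x_center = 0.5 * (self.x_face[:-1] + self.x_face[1:])
        self.cell_vol = self.area * self.dx
        # snap each port to the nearest interior face
        self.port_face = {
            p: int(np.clip(np.argmin(np.abs(self.x_face - m.ports[p])), 0, self.n_cells - 1))
            for p in self.drug_ports
        }

    # --------------------------------------------------------------- flows
    def set_pump_rates(self, carrier: float, drug_rates: dict[int, float]) -> None:
        """Command new pump rates (mL/h); flags a discontinuity event."""
        if carrier < 0 or any(q < 0 for q in drug_rates.values()):
            raise ValueError("pump rates must be >= 0")
        new = {p: float(drug_rates.get(p, 0.0)) for p in self.drug_ports}
        changed = (carrier != self.carrier) or (new != self.rates)
        for k, p in enumerate(self.drug_ports):
            was_on = self._last_rates_nonzero[p]
            now_on = new[p] > 0
            if now_on and not was_on:
                self.state.epoch_time_s[k] = 0.0  # new infusion epoch
            self._last_rates_nonzero[p] = now_on
        self.carrier = float(carrier)
        self.rates = new
        if changed:
            self._event_pending = True
        self._update_flows()

    def _update_flows(self) -> None:
        """Face and cell volumetric flows (mm^3/s) from current pump rates."""
        qf = np.full(self.n_cells + 1, self.carrier * _MLH_TO_MM3S)
        for p in self.drug_ports:
            f = self.port_face[p]
            qf[f + 1:] += self.rates[p] * _MLH_TO_MM3S
        self.q_face = qf
        self.q_cell = qf[1:]           # flow at the downstream face of each cell
        self.u_cell = self.q_cell / self.area

    @property
    def tip_flow_mlh(self) -> float:
        return float(self.q_face[-1] / _MLH_TO_MM3S)

    # ------------------------------------------------------------- stepping
    def _k2_profile(self, k: int, t_offset: float = 0.0) -> np.ndarray:
        """Per-cell effective dispersion (mm^2/s) for drug k (quasi-steady Pe)."""
        spec = self.drugs[self.drug_ports[k]]
        D = spec.diffusivity_mm2s
        t_ep = self.state.epoch_time_s[k] + t_offset
        K2 = np.empty(self.n_cells)
        # group by (radius, velocity): piecewise constant, few unique values
        key = self.radius * 1e6 + self.u_cell
        for val in np.unique(key):
            idx = key == val
            a = self.radius[idx][0]
            U = self.u_cell[idx][0]
            K2[idx] = dispersion_coefficient(D, a, U, max(t_ep, 0.0))
        return K2

    def _operator(self, k: int, t_offset: float = 0.0) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Tridiagonal spatial operator A (d(Vc)/dt = A c + S) for drug k.

        Returns (lower, diag, upper, source) with ``(A c)_i`` the net flux
        into cell i.  Faces: zero total flux at the entrance (Danckwerts
        with drug-free carrier feed), central advection + transmissibility
        dispersion at interior faces, upwind advective outflow with zero
        dispersive gradient at the tip.
        """
        n = self.n_cells
        K2 = self._k2_profile(k, t_offset)
        AK = self.area * K2
        lo = np.zeros(n)
        di = np.zeros(n)
        up = np.zeros(n)
        # interior faces f = 1..n-1 between cells f-1 (L) and f (R)
        Qf = self.q_face[1:-1]
        T = 1.0 / (self.dx[:-1] / (2 * AK[:-1]) + self.dx[1:] / (2 * AK[1:]))
        # flux F_f = Qf*(cL+cR)/2 - T*(cR-cL); into L: -F_f, into R: +F_f
        # cell i receives +F_i (face i) and -F_{i+1} (face i+1)
        # face f contributions:
        #   to cell f-1 (as its downstream face): -(Qf/2) cL - (Qf/2) cR + T cR - T cL
        #   to cell f   (as its upstream face):   +(Qf/2) cL + (Qf/2) cR - T cR + T cL
        di[:-1] += -Qf / 2.0 - T
        up[:-1] += -Qf / 2.0 + T        # coupling of cell f-1 to cell f
        lo[1:] += Qf / 2.0 + T          # coupling of cell f to cell f-1
        di[1:] += Qf / 2.0 - T
        # tip face: F_n = Q_n * c_{n-1}
        di[-1] += -self.q_face[-1]
        # injection source for this drug at its port face -> cell at that face
        p = self.drug_ports[k]
        src = np.zeros(n)
        src[self.port_face[p]] = self.rates[p] * _MLH_TO_MM3S * self.drugs[p].syringe_conc
        return lo, di, up, src

    def advance(self, dt: float) -> None:
        """Evolve all drugs by ``dt`` seconds (with internal substepping)."""
        if dt <= 0:
            raise ValueError("dt must be > 0")
        umax_over_dx = float(np.max(self.u_cell / self.dx)) if self.n_cells else 0.0
        dt_sub = self.grid.dt_s
        if umax_over_dx > 0:
            dt_sub = min(dt_sub, self.grid.courant_max / umax_over_dx)
        n_sub = max(1, int(np.ceil(dt / dt_sub - 1e-12)))
        h = dt / n_sub
        for _ in range(n_sub):
            theta = 1.0 if (self._event_pending and self.grid.backward_euler_first_step) else 0.5
            self._event_pending = False
            self._step(h, theta)

    def _step(self, h: float, theta: float) -> None:
        st = self.state
        for k in range(len(self.drug_ports)):
            # operator at the half step keeps the theta scheme second order
            # under the time-dependent dispersion coefficient
            lo, di, up, src = self._operator(k, t_offset=0.5 * h)
            c = st.conc[k]
            V_h = self.cell_vol / h
            # (V/h - theta A) c_new = (V/h + (1-theta) A) c_old + S
            rhs = V_h * c + (1 - theta) * (
                np.r_[0.0, lo[1:] * c[:-1]] + di * c + np.r_[up[:-1] * c[1:], 0.0]
            ) + src
            ab = np.zeros((3, self.n_cells))
            ab[0, 1:] = -theta * up[:-1]
            ab[1, :] = V_h - theta * di
            ab[2, :-1] = -theta * lo[1:]
            c_new = solve_banded((1, 1), ab, rhs)
            if not np.all(np.isfinite(c_new)):
                raise FloatingPointError("transport solve diverged")
            neg = c_new < 0.0
            if neg.any():
                if (c_new < _NEG_CLIP * 1e4).any():
                    st.neg_clip_events += int(np.sum(c_new < _NEG_CLIP * 1e4))
                # conservative clip: debit the clipped (negative) mass from
                # the positive cells so the step stays exactly mass-balanced
                clipped_mass = -float(np.sum(c_new[neg] * self.cell_vol[neg]))
                c_new = np.clip(c_new, 0.0, None)
                pos_mass = float(np.sum(c_new * self.cell_vol))
                if pos_mass > clipped_mass > 0:
                    c_new *= 1.0 - clipped_mass / pos_mass
            # mass ledgers: influx is the source; outflux theta-weighted tip flux
            out_flux = self.q_face[-1] * (theta * c_new[-1] + (1 - theta) * c[-1])
            self.mass_in[k] += src.sum() * h
            self.mass_out[k] += out_flux * h
            st.conc[k] = c_new
        st.clock_s += h
        st.epoch_time_s += h

    # ------------------------------------------------------------- readouts
    def mass_in_domain(self) -> np.ndarray:
        return self.state.conc @ self.cell_vol

    def plateau_conc(self, k: int) -> float:
        """Steady tip concentration at set rates: Qd*Cs/Qtot."""
        p = self.drug_ports[k]
        q_tot = self.set_carrier + sum(self.set_drug.values())
        if self.set_drug[p] <= 0:
            return float("nan")
        return self.set_drug[p] * self.drugs[p].syringe_conc / q_tot

    def tip_concentration(self, k: int) -> float:
        return float(self.state.conc[k, -1])

    def chat(self, k: int) -> float:
        """Normalized tip concentration ``c_tip / c_plateau``."""
        cp = self.plateau_conc(k)
        return float(self.state.conc[k, -1] / cp) if np.isfinite(cp) else 0.0

    def tip_delivery_rate(self, k: int) -> float:
        """Delivery rate at the tip, (mass units) / h."""
        return self.tip_flow_mlh * self.tip_concentration(k)

    def set_delivery_rate(self, k: int) -> float:
        p = self.drug_ports[k]
        return self.set_drug[p] * self.drugs[p].syringe_conc

    def front_position(self, k: int) -> float:
        """Normalized 5%-of-set front position ``x5`` in [0, 1].

        Most tip-ward location where the concentration reaches 5% of the
        set plateau, measured from the drug's port and normalized by the
        port-to-tip distance.  0 when the drug is absent, 1 at plateau.
        """
        cp = self.plateau_conc(k)
        if not np.isfinite(cp) or cp <= 0:
            cp = self.drugs[self.drug_ports[k]].syringe_conc * 0.05  # fallback scale
        thresh = 0.05 * cp
        above = np.nonzero(self.state.conc[k] >= thresh)[0]
        if len(above) == 0:
            return 0.0
        x = self.x_center[above[-1]]
        x_port = self.x_face[self.port_face[self.drug_ports[k]]]
        L = self.x_face[-1]
        if L - x_port <= 0:
            return 1.0
        return float(np.clip((x - x_port) / (L - x_port), 0.0, 1.0))

    def prime_to_steady_state(self) -> None:
        """Set the concentration fields to the steady profile at set rates.

        Solves the discrete steady balance ``A c = -S`` per drug (the
        exact stationary state of the scheme, including the local
        numerical transition at each injection face), with fully
        developed dispersion.
        """
        self.set_pump_rates(self.set_carrier, self.set_drug)
        self.state.epoch_time_s[:] = 1e9  # fully developed dispersion
        for k in range(len(self.drug_ports)):
            lo, di, up, src = self._operator(k)
            ab = np.zeros((3, self.n_cells))
            ab[0, 1:] = up[:-1]
            ab[1, :] = di
            ab[2, :-1] = lo[1:]
            self.state.conc[k] = np.clip(solve_banded((1, 1), ab, -src), 0.0, None)
        self._event_pending = True


def simulate(
    manifold: ManifoldSpec,
    drugs: dict[int, DrugSpec],
    schedule: list[tuple[float, float, dict[int, float]]],
    grid: GridSpec,
    horizon_s: float,
    set_rates: tuple[float, dict[int, float]] | None = None,
    record_dt_s: float = 5.0,
) -> "pandas.DataFrame":
    """Open-loop trajectory under a pump schedule.

    Parameters
    ----------
    schedule : list of (time_s, carrier_mlh, {port: rate_mlh})
        Sorted events; rates hold between events.
    horizon_s : float
        Total simulated time (> 0).
    set_rates : optional
        Nominal set rates for normalization; defaults to the first event's.

    Returns
    -------
    pandas.DataFrame with time, commanded flows, tip concentrations
    (raw and normalized), delivery rates and dispensed volume.
    """
    import pandas as pd

    if horizon_s <= 0:
        raise ValueError("horizon must be > 0")
    if schedule != sorted(schedule, key=lambda e: e[0]):
        raise ValueError("schedule events must be sorted in time")
    if set_rates is None:
        if schedule:
            set_rates = (schedule[0][1], schedule[0][2])
        else:
            set_rates = (0.0, {p: 0.0 for p in drugs})
    sim = TransportSimulator(manifold, drugs, grid, set_rates)
    if schedule and schedule[0][0] <= 0:
        sim.set_pump_rates(schedule[0][1], schedule[0][2])
        schedule = schedule[1:]
    else:
        sim.set_pump_rates(0.0, {p: 0.0 for p in drugs})
    rows = []
    t = 0.0
    dispensed = 0.0
    events = list(schedule)
    names = [drugs[p].name for p in sim.drug_ports]

    def record() -> None:
        row = {"time_s": t, "carrier_mlh": sim.carrier, "total_flow_mlh": sim.tip_flow_mlh,
               "dispensed_ml": dispensed}
        for k, p in enumerate(sim.drug_ports):
            nm = names[k]
            row[f"q_{nm}_mlh"] = sim.rates[p]
            row[f"c_tip_{nm}"] = sim.tip_concentration(k)
            row[f"chat_{nm}"] = sim.chat(k)
            row[f"delivery_{nm}"] = sim.tip_delivery_rate(k)
        rows.append(row)

    record()
    while t < horizon_s - 1e-9:
        t_next_event = events[0][0] if events else np.inf
        t_next = min(t + record_dt_s, t_next_event, horizon_s)
        dt = t_next - t
        if dt > 1e-12:
            sim.advance(dt)
            dispensed += sim.tip_flow_mlh * dt / 3600.0
            t = t_next
        if events and abs(t - events[0][0]) < 1e-9:
            _, qc, qd = events.pop(0)
            sim.set_pump_rates(qc, qd)
        record()
    return pd.DataFrame(rows)
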