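"""Brute-force 2D axisymmetric advection–diffusion oracle.

Radially resolved finite-difference solver for a passive scalar in
laminar Poiseuille tube flow — no dispersion closure of any kind.  Used
as the independent reference the reduced-order (area-averaged) model is
checked against.  Everything is non-dimensional: lengths in tube radii,
time as tau = D t / a^2, velocity profile u(r) = 2 Pe (1 - r^2).

Explicit FTCS stepping (central advection, conservative radial Laplacian
with no-flux walls), time step limited by the radial diffusion number.
"""

from __future__ import annotations

import numpy as np


def breakthrough_curve(
    pe: float,
    tau_end: float,
    x_obs: float,
    length: float | None = None,
    n_r: int = 32,
    dx: float = 0.1,
    n_out: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Area-averaged concentration at ``x_obs`` after a step inlet.

    Inlet c=1 across the section at x=0 for tau>0; zero initial field;
    zero-gradient outflow.  Returns (tau grid, mean concentration).
    """
    length = length if length is not None else max(2.0 * x_obs, 2.0 * pe * tau_end)
    nx = int(round(length / dx))
    r_face = np.linspace(0.0, 1.0, n_r + 1)
    r_cent = 0.5 * (r_face[:-1] + r_face[1:])
    dr = r_face[1] - r_face[0]
    u = 2.0 * pe * (1.0 - r_cent**2)  # axial velocity per ring

    dtau = 0.2 * dr * dr  # radial diffusion stability with margin
    dtau = min(dtau, 0.4 * dx * dx, 0.5 * dx / max(u.max(), 1e-12))
    n_steps = int(np.ceil(tau_end / dtau))
    dtau = tau_end / n_steps

    c = np.zeros((n_r, nx))
    # ring weights for area averaging: 2 r dr
    w = 2.0 * r_cent * dr
    w = w / w.sum()
    i_obs = min(int(round(x_obs / dx)), nx - 1)

    out_tau = np.linspace(0.0, tau_end, n_out)
    out_c = np.zeros(n_out)
    i_out = 1  # tau=0 -> 0
    # radial operator coefficients (conservative, no-flux at r=0 and r=1)
    rp = r_face[1:]
    rm = r_face[:-1]
    ap = rp / (r_cent * dr * dr)
    am = rm / (r_cent * dr * dr)
    ap[-1] = 0.0  # wall
    am[0] = 0.0   # axis

    tau = 0.0
    for _ in range(n_steps):
        cl = np.empty_like(c)
        cl[:, 0] = 1.0  # Dirichlet inlet ghost
        cl[:, 1:] = c[:, :-1]
        cr = np.empty_like(c)
        cr[:, -1] = c[:, -1]  # zero-gradient outflow
        cr[:, :-1] = c[:, 1:]
        adv = -u[:, None] * (cr - cl) / (2.0 * dx)
        dxx = (cr - 2.0 * c + cl) / (dx * dx)
        cup = np.vstack([c[1:, :], c[-1, :]])
        cdn = np.vstack([c[0, :], c[:-1, :]])
        drr = ap[:, None] * (cup - c) + am[:, None] * (cdn - c)
        c = c + dtau * (adv + dxx + drr)
        tau += dtau
        while i_out < n_out and out_tau[i_out] <= tau + 1e-12:
            out_c[i_out] = float(w @ c[:, i_obs])
            i_out += 1
    while i_out < n_out:
        out_c[i_out] = float(w @ c[:, i_obs])
        i_out += 1
    return out_tau, out_c
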