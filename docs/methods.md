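# Methods

## Physical model

Drug transport in a stopcock–catheter manifold is modelled as 1D
advection–dispersion of passive scalars along a chain of cylindrical
segments. For each drug `i` the cross-sectionally averaged concentration
`c_i(x, t)` obeys

    ∂(A c_i)/∂t + ∂(Q c_i)/∂x = ∂/∂x ( A K2_i ∂c_i/∂x ) + s_i(x, t)

with `A(x)` the local cross-section, `Q(x, t)` the local volumetric flow
(carrier plus all drug pumps entering upstream of `x`; this is the
hydrodynamic coupling — any pump change shifts `Q` everywhere
downstream), and `s_i` a point source at the drug's port delivering
`q_d,i · Cs,i` (pump rate × syringe concentration). Assumptions: fully
developed laminar Poiseuille flow in every segment (Reynolds numbers
are ≪ 1 at clinical flows), constant isotropic molecular diffusivity,
passive non-interacting solutes, rigid tubing, incompressible fluid.

### Shear dispersion

The effective axial dispersion uses the generalized (time-dependent)
dispersion closure for a circular tube:

    K2(t) = D · (1 + Pe² g(τ)),   τ = D t / a²,   Pe = a U / D,
    g(τ)  = Σ_j B_j (1 − e^{−μ_j² τ}),   Σ_j B_j = 1/48,

where `μ_j` are the zeros of `J1` (radial Neumann modes) and the weights
`B_j` follow from projecting the Poiseuille velocity excess on those
modes; the package computes them once by Bessel quadrature and caches
them. `K2(0) = D` and `K2(∞) = D(1 + Pe²/48)`, the Taylor–Aris limit.
The time-dependent form matters because infusion transients start as
sharp fronts whose spreading the long-time closure overestimates
(the bare Taylor–Aris value is only accurate for `τ ≳ 0.2`).

The series is truncated at N = 10 terms with an early exit when a
term's relative weight falls below 1e−8; at N = 10 the weight sum
matches 1/48 to ~4e−6 relative, far below the 3% tolerance the test
suite enforces on the recovered Taylor–Aris limit.

**Epoch clock.** `K2`'s time argument restarts whenever a drug's pump
switches from zero to nonzero (a fresh transient); under continuously
varying flows the local Péclet number is evaluated quasi-steadily at the
current flow with the current epoch time. Exact treatment of dispersion
memory under arbitrary flow schedules has no closed form; this choice
reproduces both limits and the intermediate-time behaviour checked
against the radially resolved oracle (below).

## Numerics

Finite-volume discretization on a per-segment uniform grid (default
Δx = 0.25 mm; the closed-loop and training studies use 0.5–1 mm, which
grid-refinement tests show is converged for the delivery metrics).
Fluxes: central advection and transmissibility-averaged dispersion at
interior faces; zero total flux at the entrance for drugs (Danckwerts
inlet with drug-free carrier feed); upwind advective outflow with zero
dispersive gradient at the tip — which makes the steady tip
concentration exactly the flux-weighted inlet mix, independent of grid.
Ports snap to the nearest grid face; the flow steps up across that face
and the injection enters the adjacent cell as a source.

Time stepping is the θ-scheme with θ = ½ (Crank–Nicolson, tridiagonal
banded solves) and θ = 1 (backward Euler) for the first step after any
commanded flow discontinuity, which damps the start-up oscillation of
CN at sharp fronts. The spatial operator is evaluated at the half-step
epoch time so the time-dependent `K2` does not degrade the observed
second-order convergence (the suite requires observed temporal order
≥ 1.8 on a smooth pulse). Internal substepping caps the cell Courant
number at 1 at the current flows. Default Δt = 0.1 s; long slow runs
use 0.5–1 s, still Courant-limited internally.

Two safeguards: (1) residual CN undershoots are clipped at zero with the
clipped (negative) mass debited proportionally from the positive cells,
so every step balances mass exactly (the suite checks per-step
conservation to 1e−8 relative; the scheme delivers ~1e−14); clip events
are counted on the state. (2) `prime_to_steady_state` solves the
discrete stationary system `A c = −S` directly rather than writing the
analytic plateau profile, because the discrete steady state carries a
local numerical transition at each injection face; priming with the
analytic profile caused a spurious percent-level relaxation transient.

### Validation oracle

An independent brute-force reference — a 2D axisymmetric
finite-difference solver with the radially resolved Poiseuille profile
and *no* dispersion closure — lives in the test suite. Area-averaged
breakthrough curves of the reduced model agree with it within 5% (L∞,
plateau units) over `τ ∈ [0.01, 1]` at Pe = 20, and the variance growth
of a pulse reproduces both the eigenseries at intermediate times and the
Taylor–Aris limit at late times.

## Shafer number

`Sh = τa Qtot / Vdead` with `τa` the drug's therapeutic action
timescale, `Qtot` the total set flow (carrier + drugs — the transit time
of the combined stream) and `Vdead` the port-to-tip dead volume.
`Sh < 1` (strict) classifies an infusion as transport-limited. The
bundled drug roster marks which `τa` values are printed in the source
literature (propofol-like, 40 s) and which are representative
order-of-magnitude entries.

## Deterministic policy

Per control interval (default 5 s) the policy maximizes

    R = −exp(m̂²)
        − (1 + C̄)² (1 − Wt) ((Qc − qc)/s)²
        − (1 − C̄)² Wt ((Qcmax_eff − qc)/s)²

over the carrier rate `qc` and drug rates `qd,i`, where
`m̂_j = 1 − (qc + Σqd) Ĉ_j / (Qc + ΣQd)` is the normalized mismatch
between actual tip delivery and the set total (averaged over active
drugs), `Ĉ_j = c_tip,j / c_plateau,j` and `C̄` its mean. Constraints:
pump bounds; the inlet drug fraction `qd,i/(qd,i + qc)` within
`(1 ± κ)` of its set-point value; tip delivery overshoot
`(qc + Σqd)·Ĉ_j ≤ β (Qc + ΣQd)`.

Design choices where the formulation was open:

* **Squared mismatch in the exponential.** A signed mismatch would
  reward unbounded overshoot; the symmetric form makes the on-target
  state (`Ĉ = 1`, set rates) the stationary optimum, which the suite
  pins.
* **`Wt` as headroom scaling.** "No control at Wt = 0, maximum control
  at Wt = 1" is realized by effective bounds
  `Qmax_eff = Qset + Wt (Qmax − Qset)` (mirror image below): at
  `Wt = 0` the feasible set collapses to the set rates and the
  controlled trajectory is bit-identical to the uncontrolled baseline.
* **Headroom normalization `s = Qcmax_eff − Qc` of the carrier terms.**
  Normalizing by the set flow leaves a spurious closed-loop fixed point
  near `β ×` set delivery (the concentration gate stays below 1 while
  excess carrier flows, and the carrier term keeps winning); with
  headroom normalization the delivery-error term dominates late in the
  transient and the loop settles within 2% of set delivery.
* **Defaults** `κ = 0.25`, `β = 1.1`, interval 5 s, mins at 0 — all
  config-exposed calibration knobs chosen to produce the qualitative
  policy structure (flush at the ceiling when the tip is empty, ride
  the overshoot bound as drug arrives, return to set rates on target).
* **Tie-breaks**: lowest total flow among reward-equal optima, then
  smallest distance to the set rates (needed at `Ĉ = 1`, where all
  actions on the set-delivery line are reward-equal).

The optimizer is multi-start SLSQP (starts: set rates, effective max
rates, previous action; fixed order, deterministic), with linearized
fraction/overshoot constraints, falling back to the best feasible start
and finally the set rates. An exhaustive feasible-grid argmax serves as
the oracle; the suite requires the SQP reward within 1e−3 relative of
the grid optimum on randomized states.

The closed loop is myopic by design (no lookahead). Known consequence:
delivery can transiently exceed `β ×` set between decisions, because
the overshoot bound is enforced at decision time while the tip
concentration keeps rising within the interval.

## Infusion environment and TD3

The gym-standard environment exposes a 24-vector observation (per port:
drug-present flag, normalized 5%-front position `x5`, its per-step
velocity, `Ĉd`, non-dimensional drug rate, `Qdmax/Qd` ratio; inactive
ports zero-filled, ports numbered 1–4 from the catheter tip) and a
4-vector action of non-dimensional drug rates (1/0/−1 → max/set/min via
the piecewise-linear pump maps). The carrier is not part of the action
space; it follows a complement rule — raised toward `Qcmax` in
proportion to the `Wt`-weighted mean of the positive drug actions — so
total-flow behaviour mirrors the deterministic policy. Expert
demonstration rollouts drive their own carrier through an explicit
override so they reproduce the deterministic closed loop exactly.

Reward (exact per-term breakdown in `info`):
`r = −w₁ Σ(Δa)² − w₂ Σ max(0, D̂ − thr)² + w₃ Σ max(0, Δx5) + w₄·1[all |D̂ − 1| ≤ band]`
with default weights (0.1, 1.0, 1.0, 2.0), threshold `β`, band ±5%,
termination after 10 consecutive in-band steps. Attainment and
overshoot are judged on the normalized *delivery rate*
`D̂ = (flow × concentration)/set` rather than on `Ĉd` alone: under
dilution control the tip concentration deliberately sits below its
set-rate plateau while delivery is on target; the two coincide at set
flows.

The TD3 agent (twin critics, delayed actor, target smoothing, Polyak
targets, Adam) is implemented directly in NumPy with explicit
backpropagation — networks are small (2×64 default) and the gradient
implementation is verified against finite differences in the suite.
Replay uses the dual buffer: a persistent, sealed expert store filled
from deterministic-policy rollouts and a FIFO experience store, sampled
at an exact 20:80 expert:experience count split per batch (cold start:
all-expert until the experience store holds one batch). Deployment
wraps the actor in the guardrail — clip to bounds, clip into the
inlet-fraction band, scale the whole command down to the overshoot
bound — which is idempotent and leaves feasible actions untouched.

## Scenario operations

* **Metrics.** `tXX` is the first crossing of XX% of the set (onset) or
  prior (cessation) delivery rate, linearly interpolated between
  samples; a sustained-crossing variant is available by flag. Overshoot
  is `max(rate)/set − 1`; excess fluid integrates the positive part of
  (total flow − set total flow) from start to t90.
* **Manual baselines.** Ad-hoc: every 2 min, scale all pumps ±25%
  toward the target using 30 s-delayed tip feedback (fixture
  conventions for an inherently unparameterized bedside protocol);
  bolus-step: all rates at a factor for a fixed duration, then set.
* **Syringe change.** The swapped drug pauses; compensation raises the
  carrier by exactly the paused set rate so total flow — hence every
  other drug's dilution and delivery — is unchanged identically.
* **Cessation with flush.** The ceased pump stops; the carrier jumps to
  `Qcmax` with the ceased drug's flow share folded into it, and every
  remaining drug scales by the same factor. This is the unique rule
  that keeps the remaining drugs' inlet concentration — and therefore
  their manifold profile — exactly unchanged while the ceased drug
  washes out at the flush flow. The flush ends when the ceased drug's
  concentration falls below 2% of its prior plateau everywhere, after
  which the carrier continues to absorb the ceased share. The flush
  valve is modelled as a carrier-rate override (no waste diversion), so
  the remaining drugs' *delivery rate* necessarily overshoots by the
  flush factor during the flush even as their concentration holds; pump
  bounds and fraction constraints are respected throughout.
* **Pharmacokinetics.** One-compartment model
  `dCp/dt = u(t)/V − ke·Cp` integrated exactly per sample interval
  (piecewise-constant input). Defaults are literature-representative
  for a fast-acting vasopressor: `V = 35 L`, `ke = ln2/300 s⁻¹`
  (5-minute half-life); both config-exposed.

## Fixtures and what they do (and do not) emulate

The bundled adult (carrier 10 mL/h, `Vdead` 1.2 mL) and pediatric
(1.5 mL/h, 0.7 mL) envelopes use four stopcock units feeding one
catheter lumen; published assemblies report only aggregate dead
volumes, so the catheter radius is solved to hit the envelope's dead
volume exactly and the per-segment split is a documented free
calibration. Drug diffusivities default to 5e−10 m²/s (representative
small molecules). Multi-lumen catheters are represented by the single
lumen carrying the controlled stream.

Deliberately absent from the reduced-order model: stagnant stopcock
side volumes and junction recirculation (which lengthen real washout
tails — the model's uncontrolled onset and cessation tails are
therefore somewhat shorter than bench measurements), secondary flows,
tubing compliance, non-Newtonian rheology, and drug–drug chemistry.
Passing tests demonstrate fidelity to the stated 1D physics and to the
radially resolved laminar oracle, not to bench assemblies with
unmodelled stagnant zones.

## Problem sizes

The test suite and the acceptance script run desk-scale configurations
chosen as converged-but-small: Δx = 0.5 mm / Δt = 0.5 s for closed-loop
studies (grid refinement changes the delivery metrics by well under a
percent), Δx = 1 mm for RL training episodes (60 control steps of 5 s),
TD3 at 3000 environment steps × 3 seeds for the scaled-down learning
study, and the 2D oracle at 32 radial × 300 axial cells, Pe = 20.
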