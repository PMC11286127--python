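# Methods

## Discrete model

One realization lives on a `W × H` square lattice with spacing `Δ` (one
cell diameter, 20 μm in the physical calibration). Site `(i, j)` carries a
binary occupancy `U_{i,j}` and a non-dimensional substrate density
`S_{i,j} ∈ [0, 1]` (substrate normalized by the per-site saturation
amount). A time step of duration `τ` is a random sequential update with
three phases, in this order:

1. **Motility.** With `N` the agent count at phase start, `N` draws are
   made uniformly with replacement over those agents. A drawn agent at
   `(i, j)` attempts a move with probability `P·g(S_{i,j})`, reading the
   substrate at its *current* site at draw time (substrate is static within
   a step, but occupancy is not: later draws see earlier moves). The target
   is uniform over the 4 nearest neighbours; the move succeeds iff the
   target is inside the lattice and vacant. All four boundaries reflect, in
   the sense that an off-lattice target aborts the attempt.
2. **Proliferation** (skipped when `Q = 0`). Another `N` draws with
   replacement over the agents present at phase start. A drawn agent
   divides with probability `Q` — independent of substrate — placing a
   daughter on a uniform nearest neighbour iff vacant (crowding aborts).
   Daughters placed mid-phase block later placements but are not themselves
   selectable until the next step; `N` is updated at phase end.
3. **Deposition.** Every occupied site gains `Γ` of substrate, clamped at
   the saturation density 1: `S ← min(1, S + Γ)`. The per-step increment is
   `Γ` (not `Γτ`); this is the convention consistent with the continuum
   rate `γ = Γ/τ`.

The ordering of proliferation before deposition is a modelling choice (the
two phases commute except that daughters deposit from their birth step);
deposition closes the step so that `N` and the substrate are both
up-to-date when the step counter increments.

**Randomness and reproducibility.** Each realization owns a
`numpy.random.Generator` seeded `base_seed + m`. Per phase it consumes
exactly three arrays in a fixed order — agent indices, attempt uniforms,
direction codes — and phases that cannot act (no agents, `P = 0`, `Q = 0`)
consume nothing. The inner loops are numba kernels that are deterministic
given those arrays, so `(config, seed)` fixes the trajectory bit-for-bit.

**Motility response.** `g` must map `[0,1]` into `[0,1]` and be
non-decreasing (validated by sampling). The kernel evaluates `g` through a
4097-point lookup table with linear interpolation — exact for the default
identity response and accurate to ~1e-7 for smooth alternatives like
`g(s) = sⁿ` — so arbitrary Python callables cost nothing in the inner loop.

**Averaging.** The column-average estimator is
`⟨U_i⟩ = (1/HM) Σ_{m=1}^{M} Σ_{j=1}^{H} U_{i,j}^m`, with resolution
(smallest representable change) `1/(HM)`. Its per-column Monte-Carlo
standard error near density `u` is `√(u(1−u)/(HM))`; site occupancies in
the simple-exclusion regime are Bernoulli with negligible in-column
correlation, so this binomial expression is the right scale.

## Continuum limit

Identifying ensemble-averaged occupancy and substrate with smooth fields
and assuming neighbouring-site independence (mean-field), the rules above
coarse-grain to

    ∂u/∂t = D ∇·[ g(s) ∇u + g′(s) u(1−u) ∇s ] + λ u(1−u)
    ∂s/∂t = γ u  (s < 1),   ∂s/∂t = 0  (s = 1)

with `D = PΔ²/(4τ)`, `γ = Γ/τ`, `λ = Q/τ`. In the default lattice units
(`Δ = τ = 1`) the PDE grid aligns cell-for-column with the lattice:
`D = P/4`, `γ = Γ`, `λ = Q` per step. The saturation rule makes the
boundary `η(t)` between saturated (Region 1, pure linear diffusion) and
unsaturated substrate (Region 2) an emergent moving boundary.

### Numerical scheme (1D coupled system)

Cell-centred conservative finite volumes on a uniform grid with zero-flux
boundary faces. Face values of `s`, `u` and `u(1−u)` are arithmetic means
of the adjacent cells; fluxes are

    Jd = -D g(s_f) δu/h,   Ja = -D g′(s_f) [u(1−u)]_f δs/h,

and the update is `u_i ← u_i − (Δt/h)(J_{i+1/2} − J_{i−1/2})`, which makes
total mass exact to round-off when `λ = 0`. Three further choices:

* **Time step.** Explicit, `Δt = 0.25 h²/(D·max(1, max g))` by default
  (configurable). At the default lattice resolution this is one lattice
  step per PDE step.
* **Logistic source.** Lie splitting with the *exact* logistic map over
  each `Δt`: after the flux update,
  `u ← u e^{λΔt} / (1 + u(e^{λΔt} − 1))`. Spatially uniform initial data
  therefore follow the logistic closed form to machine precision, and the
  splitting error for non-uniform data is O(Δt) in the commutator — far
  below the flux discretization error at the rates used here
  (`λ ≤ 1/500` per step).
* **Saturation.** `s` is advanced by an unclamped Euler increment
  `s ← s + Δt γ u` (using the pre-update `u`) and clamped at 1. For
  `u ≥ 0` this is equivalent to the piecewise rule and lets the interface
  `η(t)` emerge without explicit tracking.

The scheme does not limit fluxes; the solution is monitored and the run
aborts if `u` leaves `[−1e−6, 1+1e−6]`, which at the parameter ranges used
here only happens when the caller forces an unstable `Δt`.

**Convergence.** Behind the interface the solution is smooth and halving
`h` (with `Δt ∝ h²`) reduces the max-norm difference at second order or
better. At the leading edge, for small `γ`, the advective term
`−D u(1−u) ∂s/∂x` — a traffic-flow-type flux — steepens the profile into a
near-discontinuity at `ξ(t)`; no scheme converges in max norm across such
an edge, and refinement there sharpens rather than shrinks the
cell-to-cell jump. Front *positions* converge at first order in `h`.

### Reference 2D solvers

Five-point conservative scheme on an `n × n` square grid, zero-flux
boundaries, for `∂u/∂t = ∇·(D_eff ∇u)` with `D_eff = D` (linear) or
`D_eff = D·(uⁿ)_f` with arithmetic-mean face values (degenerate, default
`n = 1`). The time step is `0.2 h²/max(D_eff)`, recomputed each step for
the degenerate model. The barrier-assay baseline uses a 10 mm square with
201×201 cells, a disc of radius 3 mm at density 1, `D₁ = 2100 μm² h⁻¹` for
the linear model, and `D₂ = 2 D₁` for the degenerate model — the unique
value satisfying the spreading-matching condition
`∫₀¹ D₁ du = ∫₀¹ D₂ u du`.

### Validation oracles

Independent closed forms used in tests only: the zero-flux Fourier cosine
series for linear diffusion of a step; the 2D heat kernel acting on a
Gaussian; the 2D Barenblatt self-similar solution of
`∂u/∂t = D ∇·(u∇u)` (mass `8πC²`, front radius `4√C (Dt/2)^{1/4}`); and
the logistic closed form. The numerical solvers never call these.

## Front analysis

On a uniform profile grid: `η` is the largest `x` with `s ≥ 1 − ε_s`, `ξ`
the largest `x` with `u ≥ ε_u`, both linearly interpolated between cells;
`w = ξ − η`; `u* = u(η)`. Defaults `ε_u = ε_s = 1e−6` for PDE fields; for
column-averaged stochastic profiles the front threshold is the estimator's
resolution floor `1/(2HM)`. `η` is reported as NaN when the substrate is
saturated nowhere or everywhere (no two-region structure). A *dip* is an
interior local minimum with a local maximum nearer the front exceeding it
by at least `min_depth` (0.01 for PDE output, 0.02 for stochastic averages,
both above discretization/Monte-Carlo noise at the standard `H`, `M`); the
deepest qualifying minimum is reported.

One caveat on threshold-based widths: for large `γ` the solution tends to
linear diffusion, whose tail is smooth, so `w` measured at `ε = 1e−6`
levels decays only logarithmically in `γ` (≈9 cells at `γ = 100` per step
after 4 days) even though the two-region structure itself collapses. `w`
is non-increasing in `γ`, which is the robust statement.

## Experiment recipes and study conditions

The generator defaults are the study conditions and are not tuned:

| quantity | value | note |
|---|---|---|
| lattice, disc | 500×500, radius 150 sites | 3 mm barrier at Δ = 20 μm |
| seeding probability | 30000/70686 ≈ 0.424 | expected 30 000 agents; 70686 = round(π·150²) |
| lattice, strip | W = 300, H = 20, columns ≤ 150 occupied | deterministic step |
| P, τ | 1, 24/500 h | 500 steps/day; D = 2083 μm² h⁻¹ |
| Q (proliferative runs) | 1/500 | λ = 1/24 h⁻¹, doubling time ≈ 16.6 h |
| Γ sweep | 10², 10¹, 10⁰, 10⁻¹, 10⁻² per step | smooth → sharp fronts |
| M (averaged strip) | 100 (20 in `fast` mode) | recorded at days 0–4 |

Both disc-size conventions are exposed: the exact lattice-point count
(70681 sites at radius 150) and the rounded continuum area (70686); the
seeding probability uses the rounded-area convention.

## What the synthetic setups do and do not show

The simulator *is* the object of study, so "synthetic data" here means the
model's own in-silico assays, not emulation of microscope output. Passing
tests show that the discrete rules, their continuum limit and the front
phenomenology are mutually consistent; they do not show that real cells
deposit substrate linearly, move with `g(s) = s`, or divide
substrate-independently, and nothing here models cell death, biased
migration, substrate decay/diffusion, or image-derived quantities.

## Known limitations

* **Mean-field error at sharp fronts.** The PDE's leading edge at small
  `γ` is near-discontinuous, while the ensemble-averaged discrete front is
  smeared over a few sites by realization-to-realization fluctuations of
  the front position; the max-abs column discrepancy at `Γ = 10⁻²` is
  therefore ~0.07–0.11 even for large `M`, concentrated in 2–3 columns,
  although RMS agreement is ~0.02.
* **Proliferation ahead of the front.** Daughters need no substrate, so
  the discrete population invades virgin territory by birth hops — a
  pulled-front mechanism of speed ~`2√(λ·QΔ²/4τ)` that the strict
  continuum limit drops (it vanishes as `Δ → 0`). At `Q = 1/500` and
  `Γ = 10⁻²` the discrete front leads the PDE by ~4–6 sites after 4 days.
* **Explicit time stepping only** — adequate at the study parameters;
  stiff response functions would need smaller steps, not a better
  integrator.
* The disc geometry is analysed by ensemble statistics only; no
  radial-coordinate continuum solver is provided (the strip exists
  precisely to make the 1D comparison clean).
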