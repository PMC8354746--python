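# Methods

`reefsph` couples a two-dimensional weakly-compressible smoothed particle
hydrodynamics (WCSPH) solver to an agent-style ecological rule set in which
fluid particles become living coral where the local current is "just right",
and living coral starved of such currents turns into dead framework. This
note records the governing equations as implemented, the numerical choices,
the parameters with their defaults and rationale, and known limitations.

## Fluid model

**Kernel.** The Wendland C2 kernel in two dimensions,

```
W(r, h) = (α / h²) (1 − q/2)⁴ (1 + 2q),   q = r/h ≤ 2,   α = 7/(4π),
```

with compact support `2h` and smoothing length `h = 1.3 Δx` by default. The
gradient has the closed form `∇W = −(5α/h⁴)(1 − q/2)³ · r_vec`, which also
supplies `(1/r) ∂W/∂r` for the viscous term. The normalisation
`∫ W dA = 1` is verified by quadrature in the test suite.

**Equation of state.** Pressure follows the Tait form

```
p = B[(ρ/ρ₀)^γ − 1],   B = ρ₀ cs² / γ,   γ = 7,
```

with reference density `ρ₀ = 1000 kg/m³`. Choosing the artificial sound
speed `cs` at least ten times the fastest flow speed bounds density
fluctuations near 1 % — the weak-compressibility regime. This bound is an
acceptance target and is measured, not assumed.

**Continuity.** Density evolves by the SPH divergence sum
`Dρᵢ/Dt = Σⱼ mⱼ (vᵢ − vⱼ) · ∇ᵢWᵢⱼ`.

**Momentum.** Acceleration combines the symmetric pressure gradient, the
Morris laminar viscosity, and an optional body force:

```
Dvᵢ/Dt = − Σⱼ mⱼ (pⱼ/ρⱼ² + pᵢ/ρᵢ²) ∇ᵢWᵢⱼ
        + Σⱼ mⱼ (μᵢ + μⱼ)/(ρᵢ ρⱼ) · (1/r ∂W/∂r) (vᵢ − vⱼ)
        + F/ρᵢ .
```

**Density smoothing.** Every step (by default) the density field is
filtered with

```
ρ̃ᵢ = ρᵢ − ε Σⱼ mⱼ (ρᵢ − ρⱼ) Wᵢⱼ / (½(ρᵢ + ρⱼ)),   ε = 0.01,
```

which suppresses the acoustic checkerboard noise endemic to WCSPH.

## Numerics

**Neighbour search.** Pairs within the kernel support come from a k-d tree
(`scipy.spatial.cKDTree`); periodic-in-x domains use the tree's torus
topology with a padded y extent. A Verlet skin of `0.5 Δx` lets the pair
list persist until any particle drifts more than half the skin. A
brute-force all-pairs oracle validates the tree path in the tests.

**Time integration.** A Verlet scheme (`v^{n+1} = v^{n−1} + 2Δt aⁿ`,
positions by `Δt v + ½Δt² a`) with a plain Euler corrector applied on the
first step and every `n_euler` steps thereafter. The time step is

```
Δt = C · min( h/(cs + v_max),  0.25 h² ρ_min / μ_max,  √(h/|F/ρ|_max) ),
C = 0.25.
```

The viscous-cap prefactor is 0.25 rather than the common 0.5 because the
Verlet velocity update spans `2Δt`, which must stay inside the diffusion
stability region. In the stiff low-Reynolds validation regimes the
leapfrog's parasitic (odd–even) mode is unstable at the cell Fourier
numbers involved, so the analytic validation cases run with `n_euler = 1`
(an Euler corrector every step); scenario runs use `n_euler = 10`.

**Boundaries.** Walls are dynamic boundary particles: their densities
evolve through the continuity equation (so they exert pressure) but their
positions are fixed and velocities prescribed. The seabed is static; the
ceiling rows carry the lid velocity so the upper current enters the SPH
sums. In the driven channel the top rows of *fluid* adjacent to the lid
are also velocity-prescribed (the lid band). Outflow through the periodic
seam is recycled: a particle leaving at `x ≥ width` re-enters at
`x mod width`, keeping the total particle count exactly constant. With
`inlet_rows > 0` recycled and inlet-band particles are forced onto the
parabolic inlet profile `u(y) = u_peak (y/H)(2 − y/H)`; with
`inlet_rows = 0` the channel is purely periodic and recycled particles
keep their own velocity.

In the Poiseuille validation the wall rows carry mirror (ghost)
velocities — wall row k holds the negative of fluid row k's mean
streamwise velocity — which pins the no-slip plane at the wall surface
instead of half a particle spacing inside it. Without this, dynamic
boundary particles produce a systematic slip error of tens of percent at
coarse resolution.

## Ecological rules

Both rules are evaluated at scheduled growth events, after the flow has
re-settled for `settle_steps` solver steps, using per-particle speeds
averaged over the trailing `avg_window` steps. Conversions are decided
from the pre-event snapshot and applied simultaneously; particles only
change phase (`FLUID → LIVE_CORAL → DEAD_CORAL`), so the particle count is
invariant for the whole run.

* **Growth.** A fluid particle within `1.5 Δx` of any coral particle
  (live or dead — new polyps settle on dead framework) whose mean speed
  lies in the optimal feeding band `[0.03, 0.06] m/s` becomes live coral.
* **Death.** A live coral particle that sees *no* adjacent fluid in the
  band for `K` consecutive events (its energetic reserve, `death_interval`)
  becomes dead framework. Interior coral with no adjacent fluid at all is
  suboptimal by construction. One optimal evaluation resets the streak.
  `K = None` disables death entirely.

## Scale mapping for the reduced scenario

The full-scale scenario (10 × 5 m, 0.5 m/s lid, 20 000 fluid particles)
needs hours per run. Tests and examples use a desk-scale analogue,
`reefsph.validation.reduced_scenario`: 1.2 × 0.6 m, `Δx = 0.025 m`,
seed radius 0.1 m, lid 0.15 m/s, `μ = 1 Pa·s`, `cs = 3 m/s`, purely
periodic in x with the fluid initialised on the parabolic profile.

The mapping preserves the *ecology*, not the Reynolds number:

* The optimal band is an absolute speed range, so the lid speed is chosen
  to place band-speed flow at seed-crest height. At this domain height a
  0.5 m/s lid would put every speed near the seed either above or below
  the band and nothing would ever grow; 0.15 m/s restores the full-scale
  geometry of the band shell.
* `cs = 3 m/s` keeps a wide margin over all observed speeds (weakly
  compressible, and robust to the velocity transients that phase
  conversions inject).
* The channel is purely periodic (`inlet_rows = 0`) because the colony
  eventually spans most of the domain width; forcing an inlet profile onto
  recycled particles would fire them into stationary coral at the seam.
  The parabolic initial condition substitutes for the viscous spin-up,
  which at this viscosity would dwarf the simulated interval.
* The compact width lets the colony saturate its own optimal-flow layer
  within a test-budget run, which is the mechanism behind total colony
  death at short energetic reserve: the framework grows until the flow
  over its entire surface is suboptimal, after which live cover collapses
  while the dead framework persists.

With this mapping the qualitative regimes reproduce on one CPU in under a
minute each: no-death (`K = ∞`) monotone colony growth; short reserve
(`K = 2`) extinction with persisting framework; intermediate reserves
showing live coral stratified above dead framework; and final live cover
monotonically non-decreasing in `K` across {5, 15, 30}.

## Parameters (defaults)

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| `rho0` | 1000 | kg/m³ | reference water density |
| `gamma` | 7 | – | standard Tait exponent for water |
| `cs` | 10 (full scale) | m/s | ≥ 10× max speed → ≤ 1 % density error |
| `mu` | 1e-3 (full), 1.0 (reduced) | Pa·s | sea water; elevated at desk scale |
| `epsilon` | 0.01 | – | density-smoothing strength |
| `h_over_dx` | 1.3 | – | common WCSPH ratio; ~20 neighbours in 2D |
| `cfl_coeff` | 0.25 | – | stability margin across all three Δt caps |
| `v_opt_min`, `v_opt_max` | 0.03, 0.06 | m/s | optimal feeding band |
| `proximity_dx` | 1.5 | Δx | adjacency radius for both rules |
| `death_interval` (K) | None | events | energetic reserve; None = no death |

## Validation

* **Poiseuille channel** — body-force-driven laminar channel vs the
  analytic parabola `u(y) = (g/2ν) y (H − y)`; relative L2 error < 5 %
  and non-increasing under resolution doubling.
* **Hydrostatic tank** — water column at rest initialised on the
  Tait-consistent density profile and relaxed under elevated viscosity
  (free-surface ringing is undamped at sea-water viscosity); mid-depth
  pressure within 10 % of `ρ₀ g d`.
* **Weak compressibility** — the scaled channel with `cs = 10 × u_peak`
  holds max density deviation ≤ 1 % (measured ≈ 0.04 %).
* **Rule surface** — a frozen hand-laid fixture with oracle-computed
  expected outcomes, committed as CSV and regenerable via
  `reefsph fixtures`.

## Limitations

* 2D only; no surface tension, turbulence model, or free-surface handling.
* Dynamic boundary particles exhibit half-spacing slip unless mirror
  velocities are applied (done only in the validation cases; scenario
  walls accept the small slip).
* The Verlet integrator requires an Euler-corrector cadence matched to the
  viscous stiffness of the regime; it is not unconditionally stable.
* The ecological rules are deliberately minimal: no nutrient transport,
  light field, or carbonate chemistry — flow speed is the only driver.
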