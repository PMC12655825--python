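# Methods

## Model

A single star polymer is `n` arms of `N` beads each, bonded to one central
monomer (`n·N + 1` beads in total; `n = 2` is a linear chain).  Beads carry
unit mass and evolve by underdamped Langevin dynamics in open, unbounded
3-D space:

    m r̈ᵢ + γ ṙᵢ = −∇U(r) + Fᵃᵢ + Fʳᵢ

with translational friction γ and Gaussian white-noise forces obeying the
fluctuation–dissipation relation ⟨Fʳᵢ(t)·Fʳⱼ(t′)⟩ = 6 k_BT γ δᵢⱼ δ(t−t′)
(per Cartesian component, variance 2 k_BT γ/dt on a grid of step dt).
There is no solvent, no hydrodynamic interaction and no periodic box;
positions stay unwrapped because centre-of-mass motion is itself an
observable.

**Bonded interactions.** Harmonic wells U_b = ½ K_B (l − l₀)² with
K_B = 10⁴ and l₀ = 1.  The stiff spring pins bond lengths near σ, so the
polymer is freely jointed to a good approximation.

**Excluded volume.** The Weeks–Chandler–Andersen potential — Lennard-Jones
with ε = σ = 1, truncated at 2^{1/6} σ and shifted up by ε so energy and
force vanish continuously at the cutoff.  This is the canonical purely
repulsive core; an un-truncated form would add attraction and change the
physics.  By default WCA is skipped for directly bonded pairs (whose
distance is pinned by the bond anyway); `wca_excludes_bonded=False`
switches it on for all pairs, and a test verifies both routes.

**Activity models.**

* *Active Brownian particles (ABP, uncorrelated).*  Each bead carries a
  director nᵢ with Fᵃᵢ = f_a nᵢ.  The director performs rotational
  diffusion with D_r = 3 D/l₀², D = k_BT/γ, tying the propulsion
  persistence to the thermal diffusivity.  One Euler–Maruyama step per
  timestep: n ← normalize(n + √(2 D_r dt) ξ × n), ξ standard Gaussian,
  giving angular variance 2 D_r dt per perpendicular axis and the
  autocorrelation ⟨n(0)·n(t)⟩ = e^{−2 D_r t}, which a simulation test
  enforces.  The discretisation error is O(dt) and negligible at the
  D_r·dt ≤ 10⁻³ used here; D_r·dt > 0.1 is rejected.
* *Velocity-aligned (correlated).*  Fᵃᵢ = f_a vᵢ/|vᵢ|: propulsion follows
  the bead's own instantaneous velocity, so collisions and bond forces —
  which reshape velocities directly — correlate the activity of
  neighbouring beads.  Below a floor speed `v_floor = 10⁻¹²` the force is
  zeroed (the direction is undefined at v = 0; a measure-zero event with
  no statistical effect).

**Activity scale.**  All sweeps fix f_a = 1 and lower k_BT from 1 to
0.0033, spanning f_a/(k_BT) from ~1 to 300; the strictly passive reference
is f_a = 0, k_BT = 1.  The package takes (f_a, k_BT) explicitly, with
`kBT_for_ratio` mapping a requested ratio to a temperature.

## Integrator

Velocity-Verlet with one force evaluation per step, the convention of
common MD Langevin thermostats: the stored total force closes one step and
opens the next, and every evaluation sums conservative + active + friction
(−γv) + fresh random force.  Friction and the velocity-aligned active
force use the half-kicked, post-drift velocity available at evaluation
time.  For a free particle this discretisation reproduces D = k_BT/γ
exactly in the limit of the step sizes used; the stiffest bond mode
(ω dt ≈ 0.14 at dt = 10⁻³) runs a few percent hot, the standard behaviour
of this scheme, which the equipartition test budget allows for.

Timesteps follow the sweep convention dt = 10⁻³ for f_a/(k_BT) ≤ 150 and
5×10⁻⁴ above (faster, stiffer effective dynamics at high activity); a cap
of dt ≤ 10⁻³ is enforced unless explicitly overridden.  The compiled
(numba) kernel advances the system in chunks of `sample_every` steps; the
pure-numpy `step` function is the readable reference implementation, and a
test pins the two force routes together to 10⁻¹².

**RNG and reproducibility.**  One `SeedSequence` per run derives a child
seed per chunk, which feeds the kernel's internal generator.  Runs are
bit-for-bit reproducible for a fixed seed and sampling stride, and a
checkpoint (state + stored force + chunk index) continues a run
identically — both are contract tests.  Non-finite positions or velocities
abort with the step index, offending bead and maximum force.

**Initial conformations.**  Steady states, not transients, are the object
of study, so initial conditions only need to avoid pathological overlap:
arms grow from the centre as random walks rejecting placements closer than
0.8 σ, followed by a capped-displacement push-off with exact bond
re-projection; velocities are Maxwell–Boltzmann at the run temperature.
Everything is deterministic given the seed.  Burn-in (default: the leading
10% of a series, more for slowly equilibrating cases) is a parameter of
the analysis, not of the dynamics.

## Observables

* **Radius of gyration** — RMS distance of beads from the centre of mass;
  its distribution is examined for multimodality with a
  prominence-filtered peak count on a mildly smoothed histogram.
* **Scaling exponent** — least-squares slope of log Rg versus log total
  bead count.  Fitting against arm length instead changes only the
  intercept at fixed n.
* **Shape factor g(n)** = Rg²(star)/Rg²(linear chain with the same total
  bead count, centre included) — that reading of "same number of monomers"
  makes g(2) = 1 exact.  Reference chains with an even bead count cannot
  be equal-arm stars, so `build_chain` allows a mid-chain "centre" with
  arms differing by one bead.
* **Velocity–bond order parameter** — per bead, the mean over incident
  bonds of |cos α| between velocity and bond, averaged over beads (per-arm
  variants exclude the centre).  The absolute value is what makes
  isotropic velocities give E|cos θ| = ½ and maps "along the contour" to 1
  and "perpendicular" to 0; beads slower than `v_floor` are excluded, and
  a frame with no eligible beads has an undefined order parameter.
* **Arm states** — per-arm order series are smoothed with a 25-frame
  boxcar and thresholded at 0.25/0.75 into perpendicular / undecided /
  parallel; the count k of parallel arms labels the n+1 exchangeable
  collective states.  State counting applies a dwell filter (default 100
  frames) to ignore transition transients; a peak count on the order
  histogram is the independent route to the same number.
* **Centre-of-mass MSD** — averaged over all time origins at log-spaced
  lags.  Because the dynamics is underdamped, MSD = 6D(t − τ_m(1 −
  e^{−t/τ_m})) with τ_m = m/γ; diffusivities are therefore estimated from
  the slope of MSD versus lag well beyond τ_m (and beyond the propulsion
  persistence time for active runs), never from MSD/6t at a single lag.
* **Swelling ratio** — time-averaged Rg at a given activity over the
  passive (f_a = 0, k_BT = 1) reference of the same topology.

## Scenarios and scale

Registered presets resolve the figure-level experiments (scaling curves,
Rg distributions, swelling sweeps, g(n), order-parameter states) to
runnable parameter sets: N = 100 (N = 50 for the ABP g(n) sweep), n = 2–6,
activity grids spanning 0–300, 3 replicate seeds, and full-scale run
lengths of 5×10⁸ steps.  A reduction factor r divides arm length and run
length by r and thins the activity grid, never touching physical
constants.

The tests and the acceptance script run desk-scale variants chosen once:
arm lengths 10–40, runs of 10⁶–2×10⁷ steps (10³–10⁴ time units), 1–3
replicates.  These sizes resolve passive and ABP steady states well.  For
the velocity-aligned model they resolve the swelling rise above
f_a/(k_BT) ≈ 100 and the g(n) slope steepening, but **not** the
spontaneous nucleation of the discrete ordered states: at N ≤ 30 the
ordered states are only marginally stable and first-passage times out of
the disordered basin exceed desk-scale runs by orders of magnitude (the
full-scale experiments integrate 10⁵–10⁶ time units at N = 100).  Tests of
the multistate machinery therefore combine synthetic, exactly ordered
velocity fields (unit-testing the full analysis stack) with the reduced
simulations; passing them shows the dynamics, observables and
classification are correct at the stated scales, not that every full-scale
phenomenon re-emerges at desk scale.

A second finite-size effect worth naming: at f_a/(k_BT) = 150 the ABP
propulsion persistence length (≈ f_a/(γ) · 1/(2D_r) = 25 σ) is comparable
to the whole molecule at N ≤ 40, so the effective Rg-versus-size exponent
fitted over N = 10–40 comes out near 0.7 rather than the ≈ 0.6 the same
model shows when N reaches 100: the smallest stars sit below the
asymptotic scaling line and the window is a crossover region.  The
acceptance script reports the desk-scale value as computed.

## Numerical choices and limitations

* All-pairs WCA evaluation (no cell lists): molecules here are ≤ a few
  hundred beads, where the O(n²) loop beats list maintenance.
* `v_floor = 10⁻¹²`, state thresholds 0.25/0.75, boxcar window 25, dwell
  filter 100 samples, burn-in 10–40% depending on relaxation speed — all
  exposed as parameters.
* Velocity-aligned activity injects energy without bound only through the
  propulsion term; kinetic energy stays bounded near ½m(f_a/γ)² per bead,
  asserted over 10⁶ steps.
* No hydrodynamics, no explicit solvent, single molecules only; no
  bending or torsional stiffness; no Vicsek/tangential activity variants.
* The ABP director noise is isotropic white rotational noise; finite-step
  renormalisation slightly biases very large D_r·dt, hence the 0.1 guard.
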