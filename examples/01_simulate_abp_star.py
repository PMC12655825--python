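"""Simulate a small active-Brownian-particle star and print its observables.

Builds a 3-arm star of 10 beads per arm, runs underdamped Langevin dynamics
with ABP activity at fa/(kBT) = 150, and reports the time-averaged radius of
gyration and velocity-bond order parameter.  For uncorrelated (ABP) activity
the order parameter stays near 0.5 — the isotropic baseline E|cos| = 1/2 —
while the star swells relative to the passive state.
"""

import activestar as ast

topology = ast.build_star(n_arms=3, arm_length=10)
params = ast.SimulationParams(
    activity=ast.ActivityParams(model="abp", fa=1.0, kBT=ast.kBT_for_ratio(150.0)),
    dt=5e-4,
    n_steps=400_000,
    sample_every=1_000,
    seed=42,
)

traj, _ = ast.run(params, topology)

rg = ast.time_average(traj.rg, burn_in=0.3)
order = ast.time_average(traj.order_global, burn_in=0.3)
print(f"star: n_arms=3, N=10 ({topology.n_beads} beads), fa/kBT=150 (ABP)")
print(f"time-averaged Rg     = {rg:.3f}  (passive reference is ~3.1)")
print(f"order parameter      = {order:.3f} (isotropic baseline: 0.5)")
print("ABP activity swells the star but produces no velocity-bond ordering.")
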