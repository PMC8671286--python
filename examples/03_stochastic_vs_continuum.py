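"""Exact stochastic simulation of the discrete reaction scheme and its
agreement with the continuum model.

An aggregate of typical size k0 is simulated as a continuous-time Markov
chain; the k0-scaled ensemble mean is compared with the ODE solution.
"""

import numpy as np

from p62agg import (
    ContinuumState,
    DiscreteAggregate,
    RateConstants,
    integrate,
    ssa_ensemble,
    ssa_run,
    to_discrete,
)

params = RateConstants(n=5, kappa1=1.0, kappa2=1.0, kappa3=1.0,
                       kappa_m1=1.0, kappa_m=0.2)

# one sample path, event by event
traj = ssa_run(DiscreteAggregate(2, 4, 3), to_discrete(params, 1.0), 5.0, seed=1)
print(f"single path: {len(traj) - 1} events in t <= 5, "
      f"final (i, j, k) = {tuple(int(x) for x in traj.states[-1])}, "
      f"termination: {traj.termination.value}")

# ensemble mean vs ODE at k0 = 200
k0 = 200
grid = np.linspace(0.0, 0.15, 4)
ens = ssa_ensemble(DiscreteAggregate(2 * k0, 4 * k0, 3 * k0),
                   to_discrete(params, k0), 0.15, grid,
                   replicates=200, seed=7, k0=k0)
ode = integrate(params, ContinuumState(2, 4, 3), 0.15, output_grid=grid)
print(f"{'t':>6} {'mean p':>8} {'ode p':>8} {'mean r':>8} {'ode r':>8}")
for m in range(len(grid)):
    print(f"{grid[m]:6.3f} {ens['mean_p'][m]:8.4f} {ode.p[m]:8.4f} "
          f"{ens['mean_r'][m]:8.4f} {ode.r[m]:8.4f}")

print()
print("The scaled ensemble mean follows the deterministic solution; the")
print("residual gap shrinks with k0 (see docs/methods.md for the one")
print("O(1) exception caused by the integer detachment load).")
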