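"""Structure-function scaling across movement regimes.

Simulates trajectories from each movement model, estimates the zeta(q)
scaling exponents of their displacement moments, and classifies the
diffusive regime from the replicate-mean summary slope: 0.5 is Brownian,
1 is ballistic, in between is superdiffusive.  Single short paths are
noisy estimators of the slope, so each regime is summarised over 25
replicates.
"""

import numpy as np

from urchinwalk import (
    SimulationConfig,
    classify_diffusion,
    moment_curve,
    simulate_trajectory,
    zeta_exponents,
)

MODELS = [
    ("brownian", {}),
    ("crw", {"persistence": 5.0}),
    ("ballistic", {}),
    ("levy", {"levy_exponent": 1.5}),
]
N_REP, N_STEPS = 25, 400

print(f"{'model':<12} {'mean slope':>10} {'sd':>7} {'regime of mean':>16}")
for model, kwargs in MODELS:
    slopes = []
    for rep in range(N_REP):
        traj = simulate_trajectory(
            SimulationConfig(model=model, n_steps=N_STEPS, seed=rep, **kwargs)
        )
        slopes.append(zeta_exponents(moment_curve(traj)).slope)
    mean = float(np.mean(slopes))
    regime = classify_diffusion(mean)
    print(f"{model:<12} {mean:>10.3f} {np.std(slopes):>7.3f} {regime.label:>16}")

print()
print("The uncorrelated walk averages slope ~0.5 (Brownian), the correlated")
print("random walk with kappa=5 sits between 0.5 and 1 (superdiffusive), and")
print("the straight-line path is at exactly 1 with zero spread (ballistic).")
print("The Levy walk with exponent 1.5 spends long runs on straight headings,")
print("so over these path lengths it hugs the ballistic line.")
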