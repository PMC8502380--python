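"""Path unpredictability and heading uniformity.

Compares the directional entropy of a tortuous versus a persistent
trajectory (Shannon H of turning angles binned at 0.05 rad), then runs
Rayleigh uniformity tests on the final headings of a simulated group —
the check that animals are not orienting to an arena artefact.
"""

import numpy as np

from urchinwalk import (
    SimulationConfig,
    directional_entropy,
    rayleigh_test,
    simulate_trajectory,
    turning_angles,
)
from urchinwalk.kinematics import final_heading

for label, kappa in [("tortuous (kappa=0.5)", 0.5), ("persistent (kappa=40)", 40.0)]:
    traj = simulate_trajectory(
        SimulationConfig(model="crw", n_steps=150, persistence=kappa, seed=2)
    )
    res = directional_entropy(turning_angles(traj))
    print(f"{label:<22} H = {res.H:.3f} nats over {res.n_angles} angles "
          f"(max possible ln {res.n_bins} = {np.log(res.n_bins):.3f})")

print()
headings = [
    final_heading(simulate_trajectory(
        SimulationConfig(model="crw", n_steps=80, persistence=3.0, seed=s)))
    for s in range(29)
]
r = rayleigh_test(headings)
print(f"Rayleigh test on {r.n} final headings: "
      f"R-bar = {r.mean_resultant_length:.3f}, z = {r.z:.2f}, p = {r.p_value:.3f}")
print()
print("The tortuous walk occupies many turning-angle bins (high H); the")
print("persistent one concentrates near zero turning (low H).  Headings of")
print("independently simulated animals are uniform, so the Rayleigh test")
print("does not reject (p > 0.05): no shared directional bias.")
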