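"""Round-trip calibration of the heterogeneity scale factors.

Simulates scenario periods from a known tau set, then calibrates fresh scale
factors against those periods and reports the residuals — the self-consistency
check behind the shipped calibration (which targets the published periods
instead; see docs/methods.md).
"""

import numpy as np

from roachclock.clockwork import calibrate_tau
from roachclock.synth import generate_clockwork_targets

true_tau = np.array([0.186, 0.184, 0.184, 0.184, 0.205, 0.205, 0.194, 0.194])
targets = generate_clockwork_targets(
    true_tau[:4], true_tau[4:], scenarios=("nominal", "PER"),
    duration=400.0, transient=200.0, sample_step=0.05,
)
print("targets simulated from the known tau set:",
      {k: round(v, 3) for k, v in targets.items()})

result = calibrate_tau(
    targets,
    parameterization="clustered",
    duration=400.0, transient=200.0, sample_step=0.05,
    initial_guess=true_tau[[0, 1, 4, 6]] * 1.01,
    max_evaluations=60,
    sync_weight=0.0, order_weight=0.0,
    raise_on_failure=False,
)
print("calibrated tau_Le:", [round(float(v), 4) for v in result.tau_Le])
print("calibrated tau_La:", [round(float(v), 4) for v in result.tau_La])
print("achieved periods:", {k: round(v, 3) for k, v in result.achieved.items()})
print("residuals (h):", {k: round(v, 4) for k, v in result.residuals.items()})
print("\nResiduals well under 0.05 h mean the optimizer recovers a parameter set")
print("reproducing the target periods — calibration is self-consistent.")
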