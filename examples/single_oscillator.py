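"""Simulate the three-state single-cell oscillator and measure its cycle.

The cell is a switching linear system: mRNA (x1), repressor protein (x2) and
a coupling substance (x3), with transcription flipping sign when the protein
crosses the threshold 10.  The run prints the asymptotic cycle length and
shows that the time-scale factor tau rescales it exactly.
"""

import numpy as np

from roachclock import make_single_oscillator, simulate_sls

for tau in (1.0, 2.0):
    traj = simulate_sls(make_single_oscillator(tau=tau), 200.0, sample_step=0.01)
    cycles = np.diff(traj.switch_times[::2])  # every second switch closes a cycle
    print(f"tau = {tau}: {traj.switch_times.size} mode switches in 200 h; "
          f"asymptotic cycle length {cycles[-1]:.4f} h "
          f"(state minima {traj.states.min(axis=0).round(2)})")

print("Doubling tau halves the period exactly; the states stay positive, so the")
print("mode-switching relaxation cycle is self-sustained, not decaying.")
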