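"""Step the closed-loop protocol engine with a scripted fish.

The fish sits in the CS zone for the first 30 s of training, then moves
to the non-CS zone and stays.  The engine delivers the first shock 7 s
after the training-start pattern update, repeats every 3 s while the
fish remains in the CS zone, and flips the pattern once the fish has
dwelt 48 s continuously in the non-CS zone.
"""

import numpy as np

from larvalearn import PhasePlan
from larvalearn.protocol import ProtocolEngine

plan = PhasePlan()
engine = ProtocolEngine(plan, "operant", np.random.default_rng(0))

leave_cs_at = plan.training_start + 30.0
shocks, updates = [], []
n_frames = int(700 * 10)  # baseline + first 100 s of training
for i in range(n_frames):
    t = i * 0.1
    in_cs = plan.training_start <= t < leave_cs_at
    for cmd in engine.step(in_cs):
        if cmd.kind == "shock":
            shocks.append(t)
        elif t >= plan.training_start:
            updates.append((t, cmd.cs_location))

print(f"training starts at t = {plan.training_start:.0f} s; fish sits in the CS zone")
print(f"shock times (s): {shocks}")
print(f"training pattern updates: {updates}")
print()
print("-> first shock 7 s after the update, then every 3 s until the fish")
print("   escapes at t = 630 s; after 48 s of continuous non-CS dwell")
print("   (t = 677.9 s on the frame clock) the pattern updates and the")
print("   cycle restarts.")
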