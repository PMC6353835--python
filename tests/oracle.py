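"""Independent brute-force replay of the training-phase stimulation rules.

Used to cross-check the protocol engine: given a scripted per-frame
CS-zone occupancy and the pattern-update times the engine emitted, this
replays the written rules directly — a 7 s decision delay after every
pattern update, an immediate shock for a fish in the CS zone once the
delay has passed (including on later entry), repeat shocks every 3 s
while it stays there — and returns the expected shock times.
"""

from __future__ import annotations

import numpy as np

DT = 0.1


def replay_training_shocks(in_cs: np.ndarray, update_times: list[float],
                           training_start: float, training_end: float,
                           dt: float = DT) -> list[float]:
    """Expected shock times for a scripted trajectory.

    ``in_cs[i]`` is the fish's CS-zone membership at frame time i*dt
    (absolute session time).  ``update_times`` are the training-phase
    pattern-update times, which must include the update at training start.
    """
    shocks: list[float] = []
    update_times = sorted(update_times)
    last_shock = None
    prev_in = False
    n = len(in_cs)
    for i in range(n):
        t = round(i * dt, 6)
        if not (training_start <= t < training_end):
            prev_in = False
            last_shock = None
            continue
        # most recent pattern update at or before t
        upds = [u for u in update_times if u <= t + 1e-9]
        if not upds:
            continue
        last_update = upds[-1]
        if t - last_update < 7.0 - 1e-9:
            # decision delay: no shocks; zone state still tracked
            prev_in = bool(in_cs[i])
            if not prev_in:
                last_shock = None
            continue
        if in_cs[i]:
            if last_shock is None or t - last_shock >= 3.0 - 1e-9:
                shocks.append(t)
                last_shock = t
        else:
            last_shock = None
        prev_in = bool(in_cs[i])
    return shocks
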