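"""Closed-loop protocol engine for the operant place-avoidance assay.

The engine is stepped once per 10 Hz video frame with the fish's current
CS-zone membership and emits pattern-update and shock commands:

* **baseline** (10 min) — the conditioned pattern flips between the top
  and bottom arena half at intervals drawn uniformly from [30, 45] s.
* **training** (20 min) — after every pattern update there is a 7 s
  decision delay with no shocks; afterwards, a fish in the CS zone is
  shocked immediately and then every 3 s until it leaves.  Once the fish
  has stayed in the non-CS zone for 48 s continuously, the pattern
  updates (CS top or bottom with probability 1/2 each) and all timers
  reset.
* **blackout** (1 min) — no stimulus, no commands.
* **test** (18 min) — the pattern interchanges every 120 s.

Protocol variants: ``self_control`` runs the same stimulus schedule with
shocks disabled; ``unpaired`` replaces closed-loop shocks with a
pre-drawn, position-independent schedule over the training phase.

All stochastic choices (flip intervals, CS sides, unpaired shock times)
come from one seeded NumPy generator, so a session is reproducible from
its seed.  Random intervals are quantised to the frame grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, TYPE_CHECKING

import numpy as np

from .session import (
    PhasePlan,
    PROTOCOLS,
    PatternEvent,
    Session,
    ShockEvent,
    Track,
    ValidationError,
    VisualPattern,
)

if TYPE_CHECKING:  # pragma: no cover
    from .simulator import VirtualLarva

__all__ = [
    "Command",
    "ProtocolState",
    "ProtocolEngine",
    "schedule_unpaired_shocks",
    "run_session",
    "DECISION_DELAY_S",
    "SHOCK_PERIOD_S",
    "NONCS_DWELL_S",
    "TEST_FLIP_S",
]

DECISION_DELAY_S = 7.0
SHOCK_PERIOD_S = 3.0
NONCS_DWELL_S = 48.0
BASELINE_FLIP_RANGE_S = (30.0, 45.0)
TEST_FLIP_S = 120.0

_EPS = 1e-9


@dataclass(frozen=True)
class Command:
    """An engine output: ``set_pattern`` (with the new CS half) or ``shock``."""

    kind: str  # 'set_pattern' | 'shock'
    cs_location: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "set_pattern", "shock"):
            raise ValidationError(f"unknown command kind {self.kind!r}")
        if self.kind == "set_pattern" and self.cs_location not in ("top", "bottom"):
            raise ValidationError("set_pattern command requires cs_location top/bottom")


@dataclass
class ProtocolState:
    """Mutable timers and bookkeeping of the engine."""

    phase: str = "baseline"
    t: float = 0.0
    t_since_pattern_update: float = 0.0
    t_in_noncs_continuous: float = 0.0
    t_last_shock: Optional[float] = None
    next_baseline_flip_at: float = 0.0
    next_test_flip_at: float = 0.0
    cs_location: Optional[str] = None


def _other(loc: str) -> str:
    return "bottom" if loc == "top" else "top"


def schedule_unpaired_shocks(n_shocks: int, training_s: float, min_gap_s: float,
                             rng: np.random.Generator) -> np.ndarray:
    """Draw ``n_shocks`` shock times uniformly over a training window of
    ``training_s`` seconds, subject to a minimum spacing.

    Sampling: draw ``n`` sorted uniforms on the gap-compressed interval and
    re-inflate, which is the uniform distribution on the constrained set.
    """
    if n_shocks < 1:
        raise ValidationError("n_shocks must be >= 1")
    if n_shocks * min_gap_s >= training_s:
        raise ValidationError(
            f"cannot place {n_shocks} shocks with {min_gap_s} s gaps in {training_s} s"
        )
    slack = training_s - (n_shocks - 1) * min_gap_s
    base = np.sort(rng.uniform(0.0, slack, size=n_shocks))
    return base + min_gap_s * np.arange(n_shocks)


class ProtocolEngine:
    """Step-by-step stimulus/shock controller for one session.

    Parameters
    ----------
    plan:
        Phase durations.
    protocol:
        'operant', 'self_control' or 'unpaired'.
    rng:
        Seeded generator for flip intervals and CS-side draws.
    frame_period_s:
        Step size; `step` must be called with this dt.
    n_unpaired_shocks:
        Number of randomly scheduled shocks for the unpaired variant.
    """

    def __init__(self, plan: PhasePlan, protocol: str, rng: np.random.Generator,
                 frame_period_s: float = 0.1, n_unpaired_shocks: int = 40,
                 unpaired_min_gap_s: float = SHOCK_PERIOD_S) -> None:
        if protocol not in PROTOCOLS:
            raise ValidationError(f"unknown protocol {protocol!r}")
        self.plan = plan
        self.protocol = protocol
        self.rng = rng
        self.frame_period_s = frame_period_s
        self.state = ProtocolState()
        self._started = False
        self._frame = 0  # integer clock; avoids drift from accumulating dt
        self._test_flips_done = 0
        if protocol == "unpaired":
            self.unpaired_times = plan.training_start + schedule_unpaired_shocks(
                n_unpaired_shocks, plan.training_s, unpaired_min_gap_s, rng)
            self._next_unpaired = 0
        else:
            self.unpaired_times = np.empty(0)
            self._next_unpaired = 0

    # -- helpers ---------------------------------------------------------

    def _draw_location(self) -> str:
        return "top" if self.rng.random() < 0.5 else "bottom"

    def _quantise(self, seconds: float) -> float:
        return np.floor(seconds / self.frame_period_s) * self.frame_period_s

    def _draw_baseline_interval(self) -> float:
        lo, hi = BASELINE_FLIP_RANGE_S
        return self._quantise(self.rng.uniform(lo, hi))

    def _set_pattern(self, loc: str, commands: list[Command]) -> None:
        st = self.state
        st.cs_location = loc
        st.t_since_pattern_update = 0.0
        st.t_in_noncs_continuous = 0.0
        st.t_last_shock = None
        commands.append(Command("set_pattern", loc))

    def _shocks_enabled(self) -> bool:
        return self.protocol == "operant"

    # -- stepping --------------------------------------------------------

    def step(self, fish_in_cs_zone: bool, dt: float | None = None) -> list[Command]:
        """Advance one frame; returns the commands issued at the current time."""
        if dt is None:
            dt = self.frame_period_s
        if dt <= 0:
            raise ValidationError(f"dt must be > 0, got {dt}")
        if abs(dt - self.frame_period_s) > 1e-9:
            raise ValidationError("dt must equal the engine frame period")
        st = self.state
        if st.t >= self.plan.total_s - _EPS:
            raise ValidationError("stepping past the end of the phase plan")

        phase = self.plan.phase_at(st.t)
        commands: list[Command] = []

        entering = phase != st.phase or not self._started
        if entering:
            st.phase = phase
            self._started = True
            if phase == "baseline":
                self._set_pattern(self._draw_location(), commands)
                st.next_baseline_flip_at = st.t + self._draw_baseline_interval()
            elif phase == "training":
                self._set_pattern(self._draw_location(), commands)
            elif phase == "blackout":
                st.cs_location = None
            elif phase == "test":
                self._set_pattern(self._draw_location(), commands)
                self._test_flips_done = 0
                st.next_test_flip_at = st.t + TEST_FLIP_S

        if phase == "baseline" and not entering:
            if st.t >= st.next_baseline_flip_at - _EPS:
                self._set_pattern(_other(st.cs_location), commands)
                st.next_baseline_flip_at = st.t + self._draw_baseline_interval()
        elif phase == "training":
            if fish_in_cs_zone:
                st.t_in_noncs_continuous = 0.0
            else:
                if not entering:
                    st.t_in_noncs_continuous += dt
                if st.t_in_noncs_continuous >= NONCS_DWELL_S - _EPS:
                    self._set_pattern(self._draw_location(), commands)
            if self._shocks_enabled() and fish_in_cs_zone \
                    and st.t_since_pattern_update >= DECISION_DELAY_S - _EPS:
                if st.t_last_shock is None or st.t - st.t_last_shock >= SHOCK_PERIOD_S - _EPS:
                    commands.append(Command("shock"))
                    st.t_last_shock = st.t
            if not fish_in_cs_zone:
                st.t_last_shock = None
            if self.protocol == "unpaired":
                while (self._next_unpaired < len(self.unpaired_times)
                       and st.t >= self.unpaired_times[self._next_unpaired] - _EPS):
                    commands.append(Command("shock"))
                    self._next_unpaired += 1
        elif phase == "test" and not entering:
            if st.t >= st.next_test_flip_at - _EPS:
                self._set_pattern(_other(st.cs_location), commands)
                self._test_flips_done += 1
                st.next_test_flip_at = self.plan.test_start + (self._test_flips_done + 1) * TEST_FLIP_S

        st.t_since_pattern_update += dt
        self._frame += 1
        st.t = self._frame * self.frame_period_s
        return commands


def run_session(agent: "VirtualLarva", plan: PhasePlan, protocol: str,
                rng: np.random.Generator, pattern: VisualPattern,
                fish_id: str = "sim000", strain: str = "synthetic",
                frame_rate_hz: float = 10.0,
                n_unpaired_shocks: int = 40) -> Session:
    """Run a position-generating agent through the closed loop and record a
    complete :class:`~larvalearn.session.Session`.

    Each frame the engine observes the agent's head position, issues
    commands, and the agent then advances one frame under the updated
    stimulus (and any shock just delivered).
    """
    dt = 1.0 / frame_rate_hz
    n_frames = int(round(plan.total_s * frame_rate_hz))
    engine = ProtocolEngine(plan, protocol, rng, frame_period_s=dt,
                            n_unpaired_shocks=n_unpaired_shocks)
    track = Track.empty(n_frames)
    cols = [track.t, track.head_x, track.head_y, track.center_x, track.center_y,
            track.tail_x, track.tail_y, track.heading]
    patterns: list[PatternEvent] = []
    shocks: list[ShockEvent] = []
    midline_y = agent.arena[1] / 2.0
    cs_location: Optional[str] = None

    for i in range(n_frames):
        t = i * dt
        # pose = (head_x, head_y, center_x, center_y, tail_x, tail_y, heading)
        pose = agent.pose()
        head_x, head_y = pose[0], pose[1]
        if not (0.0 <= head_x <= agent.arena[0] and 0.0 <= head_y <= agent.arena[1]):
            raise ValidationError(f"agent head left the arena at t={t:.1f} s")
        if cs_location is None:
            in_cs = False
        elif cs_location == "top":
            in_cs = head_y > midline_y
        else:
            in_cs = head_y < midline_y

        shocked = False
        for cmd in engine.step(in_cs, dt):
            if cmd.kind == "set_pattern":
                cs_location = cmd.cs_location
                patterns.append(PatternEvent(t=t, cs_location=cs_location, pattern=pattern))
            elif cmd.kind == "shock":
                shocked = True
                shocks.append(ShockEvent(t=t))
        if engine.state.phase == "blackout":
            cs_location = None

        cols[0][i] = t
        for c in range(7):
            cols[c + 1][i] = pose[c]
        agent.step(t, dt, cs_location, shocked, engine.state.phase)

    session = Session(
        fish_id=fish_id, strain=strain, protocol=protocol, track=track,
        patterns=patterns, shocks=shocks, phases=plan,
        frame_rate_hz=frame_rate_hz, arena=agent.arena,
        body_length_cm=agent.params.body_length_cm,
        metadata={"pattern_name": pattern.name},
    )
    session.validate()
    return session
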