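"""A stochastic virtual larva for generating synthetic sessions.

The agent swims in discrete bouts, the dominant locomotor mode of larval
zebrafish.  Its behavior carries the statistical structure the analysis
pipeline assumes:

* **bout kinematics** — bouts are initiated at exponentially distributed
  intervals, change heading by a Gaussian turn, and displace the fish by
  a Gamma-distributed step played out over a few frames; between bouts
  the fish drifts with small jitter, and occasional *freeze* episodes
  produce stationary runs that the data-quality pre-screen can catch.
* **innate phototaxis** — larvae prefer the brighter arena half, so the
  probability that a bout is directed toward the (brighter, pure-gray)
  non-CS half grows with the darkness of the conditioned pattern.
* **avoidance learning** — a latent memory A in [0, 1] saturates upward
  with every shock (A += eta (1 - A)) and biases bouts toward the non-CS
  half via an avoidance gain.
* **extinction** — in the test phase, where shocks are absent, A decays
  exponentially at rate lambda per second, so the learned place
  preference relaxes back to the innate baseline.

Per-bout direction choice: the probability of heading toward the non-CS
half is ``clamp(1/2 + b_p (-contrast/128) [CS darker] + b_a A, 0.05, 0.95)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .protocol import run_session
from .session import (
    ARENA_CM,
    DEFAULT_BODY_LENGTH_CM,
    PhasePlan,
    Session,
    TrackPoint,
    ValidationError,
    VisualPattern,
    resolve_pattern,
    wrap_angle_deg,
)

__all__ = [
    "AgentParams",
    "AvoidanceState",
    "update_memory",
    "noncs_probability",
    "next_bout",
    "VirtualLarva",
    "simulate_cohort",
]

_BOUT_DURATION_S = 0.3  # bouts play out over three 10 Hz frames
_JITTER_STEP_CM = 0.04  # inter-bout drift per frame; above the frozen eps


@dataclass(frozen=True)
class AgentParams:
    """Tunable knobs of the virtual larva.

    ``learning_rate`` (eta) is the per-shock saturating memory increment;
    ``extinction_decay`` (lambda, 1/s) acts only in the test phase;
    ``phototaxis_gain`` and ``avoidance_gain`` map normalised contrast and
    memory to the per-bout probability of heading to the non-CS half.
    """

    bout_rate_hz: float = 2.2
    bout_step_cm: float = 0.55
    turn_sd_deg: float = 40.0
    phototaxis_gain: float = 0.03
    learning_rate: float = 0.25
    extinction_decay: float = 0.002
    avoidance_gain: float = 0.4
    freeze_prob: float = 0.004
    freeze_dur_s: float = 2.0
    body_length_cm: float = DEFAULT_BODY_LENGTH_CM
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bout_rate_hz", "bout_step_cm", "turn_sd_deg", "phototaxis_gain",
                     "extinction_decay", "avoidance_gain", "freeze_dur_s", "body_length_cm"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("learning_rate", "freeze_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class AvoidanceState:
    """Latent avoidance memory; 0 = naive, 1 = fully conditioned."""

    A: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.A <= 1.0):
            raise ValidationError(f"memory A={self.A} outside [0, 1]")


def update_memory(A: float, event: str, dt: float, params: AgentParams,
                  in_test: bool = False) -> float:
    """One memory update: a shock drives A toward 1 by the learning rate;
    absent shocks A decays exponentially, but only in the test phase."""
    if event == "shock":
        return A + params.learning_rate * (1.0 - A)
    if event == "no_shock":
        if in_test:
            return A * math.exp(-params.extinction_decay * dt)
        return A
    raise ValidationError(f"unknown memory event {event!r}")


def noncs_probability(contrast: int, A: float, params: AgentParams) -> float:
    """Per-bout probability of heading toward the non-CS half.

    The phototaxis term is active only when the CS is darker than the
    background (negative contrast); it vanishes at zero contrast, e.g. for
    the white-black checkerboard whose mean grayscale equals the
    background's.
    """
    p = 0.5 + params.avoidance_gain * A
    if contrast < 0:
        p += params.phototaxis_gain * (-contrast / 128.0)
    return float(np.clip(p, 0.05, 0.95))


def _fold(x: float, lo: float, hi: float) -> float:
    """Reflect a coordinate into [lo, hi]."""
    width = hi - lo
    x = (x - lo) % (2.0 * width)
    if x > width:
        x = 2.0 * width - x
    return x + lo


def next_bout(position: tuple[float, float], heading: float,
              pattern, A: float, params: AgentParams,
              rng: np.random.Generator,
              arena: tuple[float, float] = ARENA_CM,
              frame_rate_hz: float = 10.0) -> tuple[tuple[float, float], float, list[TrackPoint]]:
    """Plan one swim bout and its interpolated 10 Hz frames.

    ``pattern`` is the active :class:`PatternEvent` (or None during
    blackout, in which case the directional choice is unbiased).  Returns
    the end position, end heading, and the per-frame poses of the bout.
    """
    x, y = position
    w, h = arena
    if not (0.0 <= x <= w and 0.0 <= y <= h):
        raise ValidationError(f"bout start position ({x}, {y}) outside the arena")

    new_heading = float(wrap_angle_deg(heading + rng.normal(0.0, params.turn_sd_deg)))
    if pattern is not None:
        p_noncs = noncs_probability(pattern.pattern.contrast, A, params)
        toward_noncs = rng.random() < p_noncs
        noncs_is_top = pattern.cs_location == "bottom"
        target_top = noncs_is_top if toward_noncs else not noncs_is_top
        uy = math.sin(math.radians(new_heading))
        if (target_top and uy < 0.0) or (not target_top and uy > 0.0):
            new_heading = float(wrap_angle_deg(-new_heading))  # mirror across x-axis

    step = rng.gamma(2.0, params.bout_step_cm / 2.0)
    margin = 0.5 * params.body_length_cm
    nx = _fold(x + step * math.cos(math.radians(new_heading)), margin, w - margin)
    ny = _fold(y + step * math.sin(math.radians(new_heading)), margin, h - margin)

    n_frames = max(1, int(round(_BOUT_DURATION_S * frame_rate_hz)))
    dt = 1.0 / frame_rate_hz
    frames = []
    for k in range(1, n_frames + 1):
        f = k / n_frames
        cx = x + f * (nx - x)
        cy = y + f * (ny - y)
        frames.append(_pose_point(k * dt, cx, cy, new_heading, params.body_length_cm, arena))
    return (nx, ny), new_heading, frames


def _pose_point(t: float, cx: float, cy: float, heading: float,
                body_length_cm: float, arena: tuple[float, float]) -> TrackPoint:
    ux = math.cos(math.radians(heading))
    uy = math.sin(math.radians(heading))
    half = 0.5 * body_length_cm
    w, h = arena
    clip = lambda v, hi: min(max(v, 0.0), hi)
    return TrackPoint(
        t=t,
        head=(clip(cx + half * ux, w), clip(cy + half * uy, h)),
        center=(clip(cx, w), clip(cy, h)),
        tail=(clip(cx - half * ux, w), clip(cy - half * uy, h)),
        heading=float(wrap_angle_deg(heading)),
    )


class VirtualLarva:
    """Frame-steppable agent suitable for :func:`larvalearn.protocol.run_session`.

    The closed loop calls :meth:`pose` for the current frame and then
    :meth:`step` with the stimulus and shock feedback for that frame.
    """

    def __init__(self, params: AgentParams, rng: np.random.Generator | None = None,
                 arena: tuple[float, float] = ARENA_CM,
                 start: tuple[float, float] | None = None,
                 contrast: int = 0) -> None:
        self.params = params
        self.arena = arena
        self.contrast = contrast  # visual contrast of the CS pattern in play
        self.rng = rng if rng is not None else np.random.default_rng(params.seed)
        if start is None:
            margin = 0.5 + 0.5 * params.body_length_cm
            start = (float(self.rng.uniform(margin, arena[0] - margin)),
                     float(self.rng.uniform(margin, arena[1] - margin)))
        self.x, self.y = start
        self.heading = float(self.rng.uniform(-180.0, 180.0))
        self.memory = AvoidanceState(0.0)
        self._bout_frames: list[tuple[float, float, float]] = []
        self._next_bout_in = self._draw_interbout()
        self._freeze_left = 0.0
        self._current_pattern = None

    def _draw_interbout(self) -> float:
        if self.params.bout_rate_hz <= 0:
            return math.inf
        return float(self.rng.exponential(1.0 / self.params.bout_rate_hz))

    # -- interface used by run_session -----------------------------------

    def pose(self) -> tuple[float, float, float, float, float, float, float]:
        p = _pose_point(0.0, self.x, self.y, self.heading,
                        self.params.body_length_cm, self.arena)
        return (p.head[0], p.head[1], p.center[0], p.center[1],
                p.tail[0], p.tail[1], p.heading)

    def step(self, t: float, dt: float, cs_location: str | None,
             shocked: bool, phase: str) -> None:
        """Advance the agent by one frame given this frame's feedback."""
        params = self.params
        if shocked:
            self.memory.A = update_memory(self.memory.A, "shock", dt, params)
        else:
            self.memory.A = update_memory(self.memory.A, "no_shock", dt, params,
                                          in_test=phase == "test")

        if self._freeze_left > 0.0:
            self._freeze_left -= dt
            return

        if self._bout_frames:
            self.x, self.y, self.heading = self._bout_frames.pop(0)
            return

        self._next_bout_in -= dt
        if self._next_bout_in <= 0.0:
            if self.rng.random() < params.freeze_prob:
                self._freeze_left = 1.0 + float(self.rng.exponential(params.freeze_dur_s))
                self._next_bout_in = self._draw_interbout()
                return
            pattern = (_PatternView(cs_location, self.contrast)
                       if cs_location is not None else None)
            (nx, ny), new_heading, frames = next_bout(
                (self.x, self.y), self.heading, pattern, self.memory.A,
                params, self.rng, self.arena, frame_rate_hz=1.0 / dt)
            self._bout_frames = [(p.center[0], p.center[1], p.heading) for p in frames]
            self._next_bout_in = self._draw_interbout()
            self.x, self.y, self.heading = self._bout_frames.pop(0)
            return

        # inter-bout drift: isotropic jitter, reflected at the walls; the
        # direction is redrawn every frame so wall contact cannot pin the
        # fish into a spurious "frozen" run
        ang = float(self.rng.uniform(-180.0, 180.0))
        margin = 0.5 * params.body_length_cm
        self.x = _fold(self.x + _JITTER_STEP_CM * math.cos(math.radians(ang)),
                       margin, self.arena[0] - margin)
        self.y = _fold(self.y + _JITTER_STEP_CM * math.sin(math.radians(ang)),
                       margin, self.arena[1] - margin)

class _PatternView:
    """Minimal stand-in carrying what next_bout reads from a PatternEvent."""

    __slots__ = ("cs_location", "pattern")

    def __init__(self, cs_location: str, contrast: int = 0) -> None:
        self.cs_location = cs_location
        self.pattern = _ContrastView(contrast)


class _ContrastView:
    __slots__ = ("contrast",)

    def __init__(self, contrast: int) -> None:
        self.contrast = contrast


def simulate_cohort(n: int, learner_fraction: float, pattern, protocol: str,
                    params: AgentParams | None = None, seed: int = 0,
                    plan: PhasePlan | None = None,
                    n_unpaired_shocks: int = 40) -> list[Session]:
    """Simulate ``n`` independent fish; the first ``floor(f n)`` agents can
    learn (eta > 0), the rest have eta = 0.  Fully reproducible from ``seed``."""
    if n < 1:
        raise ValidationError("cohort size must be >= 1")
    if not (0.0 <= learner_fraction <= 1.0):
        raise ValidationError("learner_fraction must lie in [0, 1]")
    if params is None:
        params = AgentParams()
    pattern = resolve_pattern(pattern)
    if plan is None:
        plan = PhasePlan()
    n_learners = int(math.floor(learner_fraction * n))
    sessions = []
    streams = np.random.SeedSequence(seed).spawn(n)
    for i, ss in enumerate(streams):
        agent_rng, engine_rng = (np.random.default_rng(s) for s in ss.spawn(2))
        is_learner = i < n_learners
        p_i = params if is_learner else replace(params, learning_rate=0.0)
        agent = VirtualLarva(p_i, rng=agent_rng, contrast=pattern.contrast)
        session = run_session(agent, plan, protocol, engine_rng, pattern,
                              fish_id=f"sim{i:03d}", strain="synthetic",
                              n_unpaired_shocks=n_unpaired_shocks)
        session.metadata["planted_learner"] = bool(is_learner)
        session.metadata["seed"] = int(seed)
        sessions.append(session)
    return sessions
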