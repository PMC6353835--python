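"""Frame- and window-level behavioral statistics.

Implements the quantitative read-outs of the place-avoidance assay:

* visual-contrast arithmetic for the conditioned patterns,
* the data-quality pre-screen (fraction of non-frozen frames),
* the positional index (fraction of frames spent in the non-CS half),
* the signed distance of the head to the arena midline,
* escape-turn / return scoring and the turning index,
* epochization of a session into 2-min analysis windows.

The conditioned-stimulus (CS) zone is the arena half showing the
conditioned pattern; the other half shows the pure-gray background.  Zone
membership is decided by the head position relative to the horizontal
midline; a head exactly on the midline counts as non-CS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .contrast import pattern_grayscale, visual_contrast  # noqa: F401
from .session import (
    PatternEvent,
    Session,
    Track,
    TrackPoint,
    ValidationError,
)

__all__ = [
    "pattern_grayscale",
    "visual_contrast",
    "frozen_mask",
    "data_quality",
    "prescreen",
    "cs_location_per_frame",
    "in_cs_zone",
    "positional_index",
    "midline_distance",
    "TurnScore",
    "score_turns",
    "turning_index",
    "EpochSeries",
    "epochize",
    "DEFAULT_MOVE_EPS_CM",
    "DATA_QUALITY_THRESHOLD",
]

#: Per-frame center displacement below which the fish counts as not moving.
DEFAULT_MOVE_EPS_CM = 0.02
#: Minimum fraction of non-frozen frames for a session to enter analysis.
DATA_QUALITY_THRESHOLD = 0.95
#: A turning event is a wrapped heading change exceeding this, in degrees.
TURN_THRESHOLD_DEG = 15.0




# ---------------------------------------------------------------------------
# Pre-screening


def frozen_mask(track: Track, move_eps_cm: float = DEFAULT_MOVE_EPS_CM,
                frame_rate_hz: float | None = None) -> np.ndarray:
    """Boolean mask of frames inside stationary runs longer than 1 s.

    A frame is *stationary* when the center moved less than ``move_eps_cm``
    since the previous frame; a maximal run of stationary frames marks its
    frames frozen iff the run spans strictly more than 1 s.  The first
    frame has no predecessor and is never stationary.
    """
    n = len(track)
    if n == 0:
        return np.zeros(0, dtype=bool)
    if frame_rate_hz is None:
        frame_rate_hz = 1.0 / float(np.median(np.diff(track.t))) if n > 1 else 10.0
    dt = 1.0 / frame_rate_hz
    disp = np.hypot(np.diff(track.center_x), np.diff(track.center_y))
    stationary = np.concatenate([[False], disp < move_eps_cm])
    frozen = np.zeros(n, dtype=bool)
    # run-length scan over the stationary flags
    edges = np.flatnonzero(np.diff(stationary.astype(np.int8)))
    starts = np.concatenate([[0], edges + 1])
    ends = np.concatenate([edges + 1, [n]])
    for a, b in zip(starts, ends):
        if stationary[a] and (b - a) * dt > 1.0 + 1e-9:
            frozen[a:b] = True
    return frozen


def data_quality(track: Track, move_eps_cm: float = DEFAULT_MOVE_EPS_CM,
                 frame_rate_hz: float | None = None) -> float:
    """Fraction of non-frozen frames, in [0, 1]."""
    if len(track) == 0:
        raise ValidationError("data_quality requires a non-empty track")
    mask = frozen_mask(track, move_eps_cm, frame_rate_hz)
    return 1.0 - mask.sum() / len(track)


def prescreen(session: Session, move_eps_cm: float = DEFAULT_MOVE_EPS_CM,
              threshold: float = DATA_QUALITY_THRESHOLD) -> bool:
    """True when the session passes the health pre-screen (quality >= 0.95)."""
    return data_quality(session.track, move_eps_cm, session.frame_rate_hz) >= threshold


# ---------------------------------------------------------------------------
# Zone occupancy


def cs_location_per_frame(track: Track, patterns: Sequence[PatternEvent]) -> np.ndarray:
    """For each frame, the CS half active at that time: 1 = top, 0 = bottom,
    -1 = no pattern yet (before the first event)."""
    if not patterns:
        return np.full(len(track), -1, dtype=np.int8)
    ev_t = np.array([ev.t for ev in patterns])
    ev_loc = np.array([1 if ev.cs_location == "top" else 0 for ev in patterns], dtype=np.int8)
    idx = np.searchsorted(ev_t, track.t + 1e-9, side="right") - 1
    out = np.where(idx >= 0, ev_loc[np.clip(idx, 0, None)], -1).astype(np.int8)
    return out


def in_cs_zone(head_y: np.ndarray | float, cs_top: np.ndarray | bool,
               midline_y: float = 1.5) -> np.ndarray | bool:
    """Head-based CS-zone membership; a head exactly on the midline is non-CS."""
    head_y = np.asarray(head_y)
    cs_top = np.asarray(cs_top, dtype=bool)
    return np.where(cs_top, head_y > midline_y, head_y < midline_y)


def positional_index(track: Track, patterns: Sequence[PatternEvent],
                     window: tuple[float, float], midline_y: float = 1.5) -> float:
    """Fraction of in-window frames with the head in the non-CS half.

    ``window`` is a half-open time interval [start, end).  Every in-window
    frame must have an active pattern.
    """
    a, b = window
    sel = (track.t >= a - 1e-9) & (track.t < b - 1e-9)
    if not sel.any():
        raise ValidationError(f"window [{a}, {b}) contains no frames")
    loc = cs_location_per_frame(track, patterns)[sel]
    if np.any(loc < 0):
        raise ValidationError(f"window [{a}, {b}) has frames before the first pattern event")
    cs = in_cs_zone(track.head_y[sel], loc == 1, midline_y)
    return 1.0 - float(np.count_nonzero(cs)) / int(sel.sum())


def midline_distance(point: TrackPoint, pattern: PatternEvent,
                     midline_y: float = 1.5) -> float:
    """Signed distance (cm) of the head to the midline: positive in the
    non-CS zone, negative in the CS zone, zero on the midline."""
    d = abs(point.head[1] - midline_y)
    cs = bool(in_cs_zone(point.head[1], pattern.cs_location == "top", midline_y))
    return -d if cs else d


# ---------------------------------------------------------------------------
# Turn scoring


@dataclass(frozen=True)
class TurnScore:
    """Summed escape-turn (+1 each) and CS-return (-1 each) scores."""

    s_plus: int
    s_minus: int

    def __post_init__(self) -> None:
        if self.s_plus < 0:
            raise ValidationError("s_plus must be non-negative")
        if self.s_minus > 0:
            raise ValidationError("s_minus must be non-positive")


def turning_index(score: TurnScore) -> float:
    """1/2 + (s+ + s-) / (2 (|s+| + |s-|)); in [0, 1], NaN when both are zero."""
    total = abs(score.s_plus) + abs(score.s_minus)
    if total == 0:
        return float("nan")
    return 0.5 + (score.s_plus + score.s_minus) / (2.0 * total)


def score_turns(track: Track, patterns: Sequence[PatternEvent],
                window: tuple[float, float], body_length_cm: float,
                midline_y: float = 1.5,
                move_eps_cm: float = DEFAULT_MOVE_EPS_CM,
                frame_rate_hz: float | None = None) -> TurnScore:
    """Score escape turns and CS-zone returns within a time window.

    An *escape turn* (+1): while in the non-CS zone the head enters the band
    within twice the body length of the midline, at least one turning event
    (wrapped heading change > 15 deg) occurs inside the band, and the fish
    leaves the band away from the midline without having crossed it.  A
    *return* (-1): the head crosses from the non-CS into the CS zone.
    Crossings in the opposite direction are unscored.  Frozen frames are
    excluded; a pattern flip resets any band episode in progress.
    """
    if body_length_cm <= 0:
        raise ValidationError("body_length_cm must be > 0")
    a, b = window
    sel = np.flatnonzero((track.t >= a - 1e-9) & (track.t < b - 1e-9))
    if sel.size < 2:
        return TurnScore(0, 0)

    loc = cs_location_per_frame(track, patterns)[sel]
    head_y = track.head_y[sel]
    cs = np.asarray(in_cs_zone(head_y, loc == 1, midline_y))
    dist = np.abs(head_y - midline_y)
    band = (~cs) & (dist < 2.0 * body_length_cm)
    frozen = frozen_mask(track, move_eps_cm, frame_rate_hz)[sel]

    heading = track.heading[sel]
    dh = np.abs((np.diff(heading) + 180.0) % 360.0 - 180.0)
    turn = np.concatenate([[False], dh > TURN_THRESHOLD_DEG])
    turn &= ~frozen

    s_plus = 0
    s_minus = 0
    in_episode = bool(band[0])  # a window opening mid-band counts as an approach
    episode_turned = False
    blocked = False  # in the band but entered from the CS side: not an approach
    prev_cs = bool(cs[0])
    for i in range(1, len(sel)):
        if loc[i] != loc[i - 1]:  # pattern flip: zone identities changed
            in_episode = episode_turned = blocked = False
            prev_cs = bool(cs[i])
            continue
        if frozen[i]:
            continue
        if cs[i]:
            if not prev_cs:
                s_minus -= 1
            in_episode = episode_turned = blocked = False
        elif band[i]:
            if in_episode:
                if turn[i]:
                    episode_turned = True
            elif not blocked:
                if prev_cs:
                    blocked = True  # re-entered the non-CS side right at the midline
                else:
                    in_episode = True
                    episode_turned = bool(turn[i])
        else:
            if in_episode and episode_turned:
                s_plus += 1  # retreated from the band without crossing
            in_episode = episode_turned = blocked = False
        prev_cs = bool(cs[i])
    return TurnScore(s_plus, s_minus)


# ---------------------------------------------------------------------------
# Epochization


@dataclass
class EpochSeries:
    """Per-2-min-epoch indices across baseline, training and test phases.

    The blackout phase contributes no epoch; with the default phase plan
    there are 24 epochs labelled 5 x baseline, 10 x training, 9 x test.
    ``turning`` is NaN where an epoch had no scored turn events.
    """

    positional: np.ndarray
    turning: np.ndarray
    phase_of_epoch: list[str]
    epoch_start_s: np.ndarray
    epoch_s: float = 120.0

    def __len__(self) -> int:
        return len(self.positional)

    def phase_values(self, phase: str, which: str = "positional") -> np.ndarray:
        vals = getattr(self, which)
        mask = np.array([p == phase for p in self.phase_of_epoch])
        return vals[mask]


def epochize(session: Session, epoch_s: float = 120.0) -> EpochSeries:
    """Split a session into contiguous 2-min epochs and compute per-epoch
    positional and turning indices.  Phase durations (except blackout) must
    be divisible by the epoch length."""
    plan = session.phases
    spans = []
    for phase, start, dur in (
        ("baseline", 0.0, plan.baseline_s),
        ("training", plan.training_start, plan.training_s),
        ("test", plan.test_start, plan.test_s),
    ):
        n, rem = divmod(dur, epoch_s)
        if rem > 1e-9:
            raise ValidationError(
                f"{phase} duration {dur} s is not divisible by the {epoch_s} s epoch"
            )
        spans.extend((phase, start + k * epoch_s) for k in range(int(n)))

    positional = np.empty(len(spans))
    turning = np.empty(len(spans))
    for i, (phase, start) in enumerate(spans):
        window = (start, start + epoch_s)
        positional[i] = positional_index(session.track, session.patterns, window)
        score = score_turns(session.track, session.patterns, window,
                            session.body_length_cm,
                            frame_rate_hz=session.frame_rate_hz)
        turning[i] = turning_index(score)
    return EpochSeries(
        positional=positional,
        turning=turning,
        phase_of_epoch=[phase for phase, _ in spans],
        epoch_start_s=np.array([start for _, start in spans]),
        epoch_s=epoch_s,
    )
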