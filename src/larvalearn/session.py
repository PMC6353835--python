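"""Domain model for operant-conditioning sessions of single larval zebrafish.

A *session* is one fish's complete experiment in a 3 x 3 cm arena: a
10 Hz kinematic track (head / center / tail positions and heading angle),
the history of visual-pattern updates (which half of the arena shows the
conditioned pattern), the electroshock deliveries, and the phase timeline
(baseline, training, blackout, test).

Coordinates are in centimeters with the origin at the arena's bottom-left
corner and y increasing upward.  Headings are degrees counterclockwise
from the +x axis, wrapped to [-180, 180).  The arena midline is the
horizontal line y = height / 2 that separates the two stimulus halves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ARENA_CM",
    "FRAME_RATE_HZ",
    "DEFAULT_BODY_LENGTH_CM",
    "PROTOCOLS",
    "ValidationError",
    "SchemaError",
    "VisualPattern",
    "TABLE_PATTERNS",
    "resolve_pattern",
    "TrackPoint",
    "Track",
    "PatternEvent",
    "ShockEvent",
    "PhasePlan",
    "Session",
    "wrap_angle_deg",
]

ARENA_CM: tuple[float, float] = (3.0, 3.0)
FRAME_RATE_HZ: float = 10.0
#: Typical body length of a 7-10 dpf larva, used for pose layout and the
#: "within twice body length of the midline" escape-turn band.
DEFAULT_BODY_LENGTH_CM: float = 0.4

PROTOCOLS = ("operant", "self_control", "unpaired")

BACKGROUND_GRAYSCALE = 128


class ValidationError(ValueError):
    """An object violates a session-model invariant."""


class SchemaError(KeyError):
    """A session file does not follow the documented schema."""


def wrap_angle_deg(angle: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angle in degrees to the interval [-180, 180)."""
    return (np.asarray(angle) + 180.0) % 360.0 - 180.0 if isinstance(angle, np.ndarray) else ((angle + 180.0) % 360.0) - 180.0


# ---------------------------------------------------------------------------
# Visual patterns


@dataclass(frozen=True)
class VisualPattern:
    """A half-arena conditioned stimulus pattern.

    ``grayscale`` is the rounded arithmetic mean of the three RGB channels
    and ``contrast`` is the grayscale difference to the pure-gray
    (grayscale-128) background shown on the other half.
    """

    name: str
    mean_rgb: tuple[int, int, int]
    grayscale: int
    contrast: int

    def __post_init__(self) -> None:
        from .contrast import pattern_grayscale, visual_contrast

        if len(self.mean_rgb) != 3:
            raise ValidationError(f"mean_rgb must have 3 channels, got {self.mean_rgb}")
        expected_gray = pattern_grayscale(self.mean_rgb)
        if self.grayscale != expected_gray:
            raise ValidationError(
                f"pattern {self.name!r}: grayscale {self.grayscale} does not match "
                f"rounded channel mean {expected_gray}"
            )
        expected_contrast = visual_contrast(self.grayscale)
        if self.contrast != expected_contrast:
            raise ValidationError(
                f"pattern {self.name!r}: contrast {self.contrast} does not match "
                f"grayscale - 128 = {expected_contrast}"
            )

    @classmethod
    def from_mean_rgb(cls, name: str, mean_rgb: Sequence[int]) -> "VisualPattern":
        """Build a pattern, deriving grayscale and contrast from the RGB mean."""
        from .contrast import pattern_grayscale, visual_contrast

        rgb = tuple(int(c) for c in mean_rgb)
        gray = pattern_grayscale(rgb)
        return cls(name=name, mean_rgb=rgb, grayscale=gray, contrast=visual_contrast(gray))


def _build_table_patterns() -> dict[str, VisualPattern]:
    specs = {
        "grayscale-0": (0, 0, 0),
        "grayscale-32": (32, 32, 32),
        "grayscale-43": (43, 43, 43),
        "grayscale-64": (64, 64, 64),
        "grayscale-96": (96, 96, 96),
        "red-black-checkerboard": (128, 0, 0),
        "white-black-checkerboard": (128, 128, 128),
        "background": (128, 128, 128),
    }
    return {name: VisualPattern.from_mean_rgb(name, rgb) for name, rgb in specs.items()}


#: The standard conditioned patterns (plus the pure-gray background).
TABLE_PATTERNS: dict[str, VisualPattern] = _build_table_patterns()


def resolve_pattern(spec: "str | int | VisualPattern") -> VisualPattern:
    """Look up a pattern by name, build a uniform one from a grayscale int,
    or pass a :class:`VisualPattern` through unchanged."""
    if isinstance(spec, VisualPattern):
        return spec
    if isinstance(spec, int) or (isinstance(spec, str) and spec.lstrip("-").isdigit()):
        g = int(spec)
        return VisualPattern.from_mean_rgb(f"grayscale-{g}", (g, g, g))
    if spec in TABLE_PATTERNS:
        return TABLE_PATTERNS[spec]
    raise KeyError(f"unknown visual pattern {spec!r}; known: {sorted(TABLE_PATTERNS)}")


# ---------------------------------------------------------------------------
# Kinematics


@dataclass(frozen=True)
class TrackPoint:
    """One 10 Hz video frame's fish pose."""

    t: float
    head: tuple[float, float]
    center: tuple[float, float]
    tail: tuple[float, float]
    heading: float  # degrees CCW from +x, in [-180, 180)

    def validate(self, arena: tuple[float, float] = ARENA_CM) -> None:
        w, h = arena
        for label, (x, y) in (("head", self.head), ("center", self.center), ("tail", self.tail)):
            if not (0.0 <= x <= w and 0.0 <= y <= h):
                raise ValidationError(f"{label} position ({x}, {y}) outside arena {arena}")
        if not (-180.0 <= self.heading < 180.0 + 1e-9):
            raise ValidationError(f"heading {self.heading} not wrapped to [-180, 180)")


@dataclass
class Track:
    """Column-wise storage of an ordered sequence of :class:`TrackPoint`.

    Arrays are float64 and share a common length; this is the in-memory
    twin of the column-wise YAML layout and is what the vectorised metrics
    operate on.
    """

    t: np.ndarray
    head_x: np.ndarray
    head_y: np.ndarray
    center_x: np.ndarray
    center_y: np.ndarray
    tail_x: np.ndarray
    tail_y: np.ndarray
    heading: np.ndarray

    _COLUMNS = ("t", "head_x", "head_y", "center_x", "center_y", "tail_x", "tail_y", "heading")

    def __post_init__(self) -> None:
        for name in self._COLUMNS:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.t)
        for name in self._COLUMNS:
            if len(getattr(self, name)) != n:
                raise ValidationError(f"track column {name!r} has length "
                                      f"{len(getattr(self, name))}, expected {n}")

    def __len__(self) -> int:
        return len(self.t)

    def point(self, i: int) -> TrackPoint:
        return TrackPoint(
            t=float(self.t[i]),
            head=(float(self.head_x[i]), float(self.head_y[i])),
            center=(float(self.center_x[i]), float(self.center_y[i])),
            tail=(float(self.tail_x[i]), float(self.tail_y[i])),
            heading=float(self.heading[i]),
        )

    def points(self) -> Iterable[TrackPoint]:
        return (self.point(i) for i in range(len(self)))

    @classmethod
    def from_points(cls, points: Sequence[TrackPoint]) -> "Track":
        return cls(
            t=np.array([p.t for p in points]),
            head_x=np.array([p.head[0] for p in points]),
            head_y=np.array([p.head[1] for p in points]),
            center_x=np.array([p.center[0] for p in points]),
            center_y=np.array([p.center[1] for p in points]),
            tail_x=np.array([p.tail[0] for p in points]),
            tail_y=np.array([p.tail[1] for p in points]),
            heading=np.array([p.heading for p in points]),
        )

    @classmethod
    def empty(cls, n: int) -> "Track":
        return cls(*(np.zeros(n) for _ in cls._COLUMNS))

    def validate(self, frame_rate_hz: float = FRAME_RATE_HZ,
                 arena: tuple[float, float] = ARENA_CM) -> None:
        if len(self) == 0:
            raise ValidationError("track is empty")
        w, h = arena
        for name in ("head_x", "center_x", "tail_x"):
            col = getattr(self, name)
            if col.min() < -1e-9 or col.max() > w + 1e-9:
                raise ValidationError(f"track column {name} outside [0, {w}] cm")
        for name in ("head_y", "center_y", "tail_y"):
            col = getattr(self, name)
            if col.min() < -1e-9 or col.max() > h + 1e-9:
                raise ValidationError(f"track column {name} outside [0, {h}] cm")
        if len(self) > 1:
            dts = np.diff(self.t)
            if np.any(dts <= 0):
                raise ValidationError("track timestamps are not strictly increasing")
            period = 1.0 / frame_rate_hz
            if np.any(np.abs(dts - period) > 0.2 * period):
                raise ValidationError(
                    f"frame spacing deviates from the {period:.3f} s frame period"
                )


# ---------------------------------------------------------------------------
# Events and phases


@dataclass(frozen=True)
class PatternEvent:
    """A visual-pattern update: which half ('top'/'bottom') shows the CS."""

    t: float
    cs_location: str
    pattern: VisualPattern

    def __post_init__(self) -> None:
        if self.cs_location not in ("top", "bottom"):
            raise ValidationError(f"cs_location must be 'top' or 'bottom', got {self.cs_location!r}")


@dataclass(frozen=True)
class ShockEvent:
    """One whole-arena electroshock pulse (100 ms, 9 V across the 3 cm arena)."""

    t: float
    duration_s: float = 0.1
    amplitude_volts: float = 9.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValidationError(f"shock duration must be > 0, got {self.duration_s}")


@dataclass(frozen=True)
class PhasePlan:
    """Durations of the four protocol phases, in seconds.

    Defaults follow the standard timeline: 10 min baseline, 20 min
    training, 1 min blackout, 18 min test (49 min total).
    """

    baseline_s: float = 600.0
    training_s: float = 1200.0
    blackout_s: float = 60.0
    test_s: float = 1080.0

    def __post_init__(self) -> None:
        for name in ("baseline_s", "training_s", "blackout_s", "test_s"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"phase duration {name} must be > 0")

    @property
    def total_s(self) -> float:
        return self.baseline_s + self.training_s + self.blackout_s + self.test_s

    @property
    def training_start(self) -> float:
        return self.baseline_s

    @property
    def blackout_start(self) -> float:
        return self.baseline_s + self.training_s

    @property
    def test_start(self) -> float:
        return self.baseline_s + self.training_s + self.blackout_s

    def phase_at(self, t: float) -> str:
        """Phase name at time ``t`` (phases are half-open intervals [start, end))."""
        if t < 0 or t >= self.total_s:
            raise ValidationError(f"t={t} outside the phase plan [0, {self.total_s})")
        if t < self.training_start:
            return "baseline"
        if t < self.blackout_start:
            return "training"
        if t < self.test_start:
            return "blackout"
        return "test"


# ---------------------------------------------------------------------------
# Session


@dataclass
class Session:
    """One fish's complete operant-conditioning experiment record."""

    fish_id: str
    strain: str
    protocol: str
    track: Track
    patterns: list[PatternEvent]
    shocks: list[ShockEvent]
    phases: PhasePlan = field(default_factory=PhasePlan)
    frame_rate_hz: float = FRAME_RATE_HZ
    arena: tuple[float, float] = ARENA_CM
    body_length_cm: float = DEFAULT_BODY_LENGTH_CM
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValidationError(f"unknown protocol {self.protocol!r}; expected one of {PROTOCOLS}")
        if self.body_length_cm <= 0:
            raise ValidationError("body_length_cm must be > 0")
        self.track.validate(self.frame_rate_hz, self.arena)
        span = self.track.t[-1] - self.track.t[0]
        period = 1.0 / self.frame_rate_hz
        if span + period < self.phases.total_s - 1e-6:
            raise ValidationError(
                f"track spans {span + period:.1f} s but the phase plan requires "
                f"{self.phases.total_s:.1f} s"
            )
        if self.protocol == "self_control" and self.shocks:
            raise ValidationError("self_control sessions must contain no shock events")
        for events, label in ((self.patterns, "pattern"), (self.shocks, "shock")):
            ts = [e.t for e in events]
            if any(b <= a for a, b in zip(ts, ts[1:])):
                raise ValidationError(f"{label} events are not strictly time-ordered")
        if self.protocol == "operant":
            lo, hi = self.phases.training_start, self.phases.blackout_start
            for s in self.shocks:
                if not (lo <= s.t < hi):
                    raise ValidationError(
                        f"operant shock at t={s.t:.1f} s outside the training phase"
                    )

    def equals(self, other: "Session", t_tol: float = 1e-3, pos_tol: float = 1e-4,
               angle_tol: float = 1e-3) -> bool:
        """Field-by-field equality with numeric tolerances (timestamps to 1 ms)."""
        if (self.fish_id, self.strain, self.protocol) != (other.fish_id, other.strain, other.protocol):
            return False
        if self.phases != other.phases or self.metadata != other.metadata:
            return False
        if abs(self.frame_rate_hz - other.frame_rate_hz) > 1e-9:
            return False
        if self.arena != other.arena or abs(self.body_length_cm - other.body_length_cm) > 1e-9:
            return False
        if len(self.track) != len(other.track):
            return False
        if not np.allclose(self.track.t, other.track.t, atol=t_tol, rtol=0):
            return False
        for name in ("head_x", "head_y", "center_x", "center_y", "tail_x", "tail_y"):
            if not np.allclose(getattr(self.track, name), getattr(other.track, name),
                               atol=pos_tol, rtol=0):
                return False
        if not np.allclose(self.track.heading, other.track.heading, atol=angle_tol, rtol=0):
            return False
        if len(self.patterns) != len(other.patterns) or len(self.shocks) != len(other.shocks):
            return False
        for a, b in zip(self.patterns, other.patterns):
            if abs(a.t - b.t) > t_tol or a.cs_location != b.cs_location or a.pattern != b.pattern:
                return False
        for a, b in zip(self.shocks, other.shocks):
            if abs(a.t - b.t) > t_tol or abs(a.duration_s - b.duration_s) > 1e-9 \
                    or abs(a.amplitude_volts - b.amplitude_volts) > 1e-9:
                return False
        return True
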