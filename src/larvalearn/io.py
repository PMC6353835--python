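"""Reading and writing session files.

Sessions are stored as single human-diffable YAML documents with top-level
keys ``metadata``, ``phases``, ``track``, ``patterns`` and ``shocks``.  The
track is stored column-wise (one list per kinematic column) which keeps a
49-min, 10 Hz session compact and fast to parse.  Unknown extra keys under
``metadata`` are preserved on a round trip.

Floats are rounded on write (timestamps to 0.1 ms, positions to 0.1 um)
so ``read_session(write_session(s))`` equals ``s`` at the documented
tolerances.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import yaml

from .session import (
    PatternEvent,
    PhasePlan,
    SchemaError,
    Session,
    ShockEvent,
    Track,
    ValidationError,
    VisualPattern,
)

if TYPE_CHECKING:  # pragma: no cover
    from .learning import LearnerResult

__all__ = ["read_session", "write_session", "export_summary"]

try:  # libyaml-backed loader/dumper when available
    _Loader = yaml.CSafeLoader
    _Dumper = yaml.CSafeDumper
except AttributeError:  # pragma: no cover
    _Loader = yaml.SafeLoader
    _Dumper = yaml.SafeDumper

_TRACK_COLUMNS = Track._COLUMNS
_META_KEYS = ("fish_id", "strain", "protocol", "frame_rate_hz", "arena", "body_length_cm")


def _require(mapping: dict, key: str, where: str):
    if key not in mapping:
        raise SchemaError(f"session file is missing required key {where}{key!r}")
    return mapping[key]


def read_session(path: str | Path) -> Session:
    """Read and validate a session YAML file.

    Raises :class:`~larvalearn.session.SchemaError` when a required key is
    absent and :class:`~larvalearn.session.ValidationError` when the parsed
    session violates a model invariant (e.g. non-monotonic timestamps).
    """
    with open(path) as fh:
        doc = yaml.load(fh, Loader=_Loader)
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: top level is not a mapping")

    meta = dict(_require(doc, "metadata", ""))
    phases_doc = _require(doc, "phases", "")
    track_doc = _require(doc, "track", "")
    patterns_doc = _require(doc, "patterns", "")
    shocks_doc = doc.get("shocks", [])

    fields = {}
    for key in _META_KEYS:
        fields[key] = _require(meta, key, "metadata.")
        del meta[key]
    fields["arena"] = tuple(float(v) for v in fields["arena"])

    columns = {name: np.asarray(_require(track_doc, name, "track."), dtype=float)
               for name in _TRACK_COLUMNS}
    track = Track(**columns)

    phases = PhasePlan(**{k: float(_require(phases_doc, k, "phases."))
                          for k in ("baseline_s", "training_s", "blackout_s", "test_s")})

    patterns = []
    for ev in patterns_doc:
        pat = _require(ev, "pattern", "patterns[].")
        patterns.append(PatternEvent(
            t=float(_require(ev, "t", "patterns[].")),
            cs_location=_require(ev, "cs_location", "patterns[]."),
            pattern=VisualPattern(
                name=_require(pat, "name", "patterns[].pattern."),
                mean_rgb=tuple(int(c) for c in _require(pat, "mean_rgb", "patterns[].pattern.")),
                grayscale=int(_require(pat, "grayscale", "patterns[].pattern.")),
                contrast=int(_require(pat, "contrast", "patterns[].pattern.")),
            ),
        ))

    shocks = [ShockEvent(t=float(_require(ev, "t", "shocks[].")),
                         duration_s=float(ev.get("duration_s", 0.1)),
                         amplitude_volts=float(ev.get("amplitude_volts", 9.0)))
              for ev in shocks_doc]

    session = Session(track=track, patterns=patterns, shocks=shocks, phases=phases,
                      metadata=meta, **fields)
    session.validate()
    return session


def _round_list(arr: np.ndarray, decimals: int) -> list[float]:
    return [float(v) for v in np.round(np.asarray(arr, dtype=float), decimals)]


def write_session(session: Session, path: str | Path) -> None:
    """Validate ``session`` and write it to ``path`` as YAML (round-trip stable)."""
    session.validate()
    doc = {
        "metadata": {
            "fish_id": session.fish_id,
            "strain": session.strain,
            "protocol": session.protocol,
            "frame_rate_hz": float(session.frame_rate_hz),
            "arena": [float(v) for v in session.arena],
            "body_length_cm": float(session.body_length_cm),
            **session.metadata,
        },
        "phases": {
            "baseline_s": float(session.phases.baseline_s),
            "training_s": float(session.phases.training_s),
            "blackout_s": float(session.phases.blackout_s),
            "test_s": float(session.phases.test_s),
        },
        "track": {
            "t": _round_list(session.track.t, 4),
            **{name: _round_list(getattr(session.track, name), 5)
               for name in _TRACK_COLUMNS if name not in ("t", "heading")},
            "heading": _round_list(session.track.heading, 4),
        },
        "patterns": [
            {
                "t": round(float(ev.t), 4),
                "cs_location": ev.cs_location,
                "pattern": {
                    "name": ev.pattern.name,
                    "mean_rgb": list(ev.pattern.mean_rgb),
                    "grayscale": int(ev.pattern.grayscale),
                    "contrast": int(ev.pattern.contrast),
                },
            }
            for ev in session.patterns
        ],
        "shocks": [
            {
                "t": round(float(ev.t), 4),
                "duration_s": float(ev.duration_s),
                "amplitude_volts": float(ev.amplitude_volts),
            }
            for ev in session.shocks
        ],
    }
    with open(path, "w") as fh:
        yaml.dump(doc, fh, Dumper=_Dumper, default_flow_style=True, sort_keys=False, width=100000)


_SUMMARY_HEADER = ("fish_id", "strain", "pattern", "is_learner", "p_value",
                   "memory_length_s", "category", "pi_increase", "ti_increase")


def export_summary(results: "Sequence[LearnerResult] | Iterable[LearnerResult]",
                   path: str | Path) -> None:
    """Write one CSV row per fish with its classification and memory statistics."""
    results = list(results)
    if not results:
        raise ValidationError("export_summary requires a non-empty result collection")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SUMMARY_HEADER)
        for r in results:
            writer.writerow([
                r.fish_id,
                r.strain,
                r.pattern_name,
                int(r.is_learner),
                "" if r.p_value is None or np.isnan(r.p_value) else f"{r.p_value:.6g}",
                f"{r.memory_length_s:.1f}",
                r.category,
                f"{r.pi_increase:.6g}",
                "" if np.isnan(r.ti_increase) else f"{r.ti_increase:.6g}",
            ])
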