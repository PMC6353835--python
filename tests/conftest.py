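"""Shared fixtures: small hand-built tracks and one reusable simulated cohort."""

from __future__ import annotations

import numpy as np
import pytest

from larvalearn import (
    PatternEvent,
    PhasePlan,
    Session,
    Track,
    TABLE_PATTERNS,
    simulate_cohort,
)

RBC = TABLE_PATTERNS["red-black-checkerboard"]


def make_track(head_y, head_x=None, headings=None, dt=0.1, moving=True):
    """Build a Track from per-frame head-y positions; center follows head.

    When ``moving`` the x coordinate advances every frame so no frame
    counts as frozen.
    """
    head_y = np.asarray(head_y, dtype=float)
    n = len(head_y)
    t = np.arange(n) * dt
    if head_x is None:
        if moving:
            head_x = 0.2 + 0.05 * (np.arange(n) % 40)
        else:
            head_x = np.full(n, 1.5)
    else:
        head_x = np.asarray(head_x, dtype=float)
    heading = np.zeros(n) if headings is None else np.asarray(headings, dtype=float)
    return Track(t=t, head_x=head_x, head_y=head_y,
                 center_x=head_x, center_y=head_y,
                 tail_x=head_x, tail_y=head_y, heading=heading)


def single_pattern(cs_location="bottom", t=0.0, pattern=RBC):
    return [PatternEvent(t=t, cs_location=cs_location, pattern=pattern)]


@pytest.fixture(scope="session")
def small_plan():
    """A short phase plan (epoch-divisible) for fast session-level tests."""
    return PhasePlan(baseline_s=240.0, training_s=240.0, blackout_s=60.0, test_s=240.0)


@pytest.fixture(scope="session")
def sim_session():
    """One default-plan operant session from a learning-capable agent."""
    return simulate_cohort(1, 1.0, "red-black-checkerboard", "operant", seed=101)[0]


@pytest.fixture(scope="session")
def small_cohort():
    """Twelve fish, half learning-capable, default plan; reused across tests."""
    return simulate_cohort(12, 0.5, "red-black-checkerboard", "operant", seed=42)
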