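"""Unit and property tests for the behavioral statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from larvalearn import (
    TABLE_PATTERNS,
    PatternEvent,
    TurnScore,
    ValidationError,
    data_quality,
    frozen_mask,
    midline_distance,
    pattern_grayscale,
    positional_index,
    score_turns,
    turning_index,
    visual_contrast,
)
from larvalearn.metrics import epochize, in_cs_zone
from larvalearn.session import TrackPoint

from conftest import RBC, make_track, single_pattern


# ---------------------------------------------------------------------------
# Visual contrast


@pytest.mark.parametrize("rgb, expected", [
    ((128, 0, 0), 43),
    ((128, 128, 128), 128),
    ((0, 0, 0), 0),
    ((32, 32, 32), 32),
    ((43, 43, 43), 43),
])
def test_pattern_grayscale_is_rounded_channel_mean(rgb, expected):
    assert pattern_grayscale(rgb) == expected


def test_pattern_grayscale_rejects_out_of_range_channels():
    with pytest.raises(ValueError):
        pattern_grayscale((300, 0, 0))


@pytest.mark.parametrize("gray, expected", [
    (32, -96), (96, -32), (128, 0), (0, -128), (43, -85), (64, -64),
])
def test_visual_contrast_against_gray_background(gray, expected):
    assert visual_contrast(gray) == expected


def test_table_patterns_satisfy_their_invariants():
    for pat in TABLE_PATTERNS.values():
        assert pat.grayscale == pattern_grayscale(pat.mean_rgb)
        assert pat.contrast == pat.grayscale - 128
    assert TABLE_PATTERNS["white-black-checkerboard"].contrast == 0
    assert TABLE_PATTERNS["red-black-checkerboard"].grayscale == 43


# ---------------------------------------------------------------------------
# Frozen-frame detection and pre-screening


def test_constant_position_marks_frames_frozen():
    # 30 s stationary between moving stretches
    y = np.concatenate([np.linspace(0.5, 1.0, 20), np.full(300, 1.0),
                        np.linspace(1.0, 0.5, 20)])
    x = np.concatenate([np.linspace(0.5, 1.0, 20), np.full(300, 1.0),
                        np.linspace(1.0, 0.5, 20)])
    track = make_track(y, head_x=x)
    mask = frozen_mask(track, frame_rate_hz=10)
    assert mask[21:320].all()
    assert not mask[:20].any() and not mask[321:].any()


def test_moving_every_frame_has_no_frozen_frames():
    y = 0.5 + 0.1 * np.arange(100) % 2.0
    track = make_track(np.clip(y, 0, 3))
    assert not frozen_mask(track, frame_rate_hz=10).any()


def test_sub_second_stationary_run_is_not_frozen():
    # 9 stationary transitions = 0.9 s: not "over 1 s"
    y = np.concatenate([np.linspace(0.5, 1.5, 30), np.full(9, 1.5),
                        np.linspace(1.5, 0.5, 30)])
    x = np.concatenate([np.linspace(0.5, 1.5, 30), np.full(9, 1.5),
                        np.linspace(1.5, 0.5, 30)])
    track = make_track(y, head_x=x)
    assert not frozen_mask(track, frame_rate_hz=10).any()


@pytest.mark.parametrize("n, run, kept", [
    (220, 11, True),   # exactly 5% frozen: quality 0.95, kept
    (350, 21, False),  # 6% frozen: quality 0.94, excluded
])
def test_data_quality_threshold_boundary(n, run, kept):
    # run+1 equal positions -> run stationary transitions -> run frozen frames
    x = 0.2 + 0.05 * np.arange(n)
    x[50:51 + run] = x[50]
    x[51 + run:] = x[50] + 0.05 * np.arange(1, n - 51 - run + 1)
    track = make_track(np.full(n, 1.0), head_x=0.1 + (x % 2.8))
    q = data_quality(track, frame_rate_hz=10)
    assert np.isclose(q, 1.0 - run / n)
    assert (q >= 0.95) == kept


# ---------------------------------------------------------------------------
# Positional index and midline distance


def test_positional_index_all_noncs_is_one():
    track = make_track(np.full(120, 2.5))  # top half
    pats = single_pattern("bottom")
    assert positional_index(track, pats, (0.0, 12.0)) == 1.0


def test_positional_index_alternating_pattern_equal_dwell():
    track = make_track(np.full(240, 2.5))  # parked top
    pats = [PatternEvent(0.0, "top", RBC), PatternEvent(12.0, "bottom", RBC)]
    assert positional_index(track, pats, (0.0, 24.0)) == pytest.approx(0.5)


def test_positional_index_direct_count():
    y = np.full(120, 2.5)
    y[:30] = 0.5  # 30 of 120 frames in the CS (bottom) zone
    track = make_track(y)
    assert positional_index(track, single_pattern("bottom"), (0.0, 12.0)) == 0.75


def test_positional_index_plus_cs_fraction_is_one():
    rng = np.random.default_rng(3)
    y = rng.uniform(0.1, 2.9, 200)
    track = make_track(y)
    pats = single_pattern("top")
    pi = positional_index(track, pats, (0.0, 20.0))
    cs_frac = np.mean(y > 1.5)
    assert pi + cs_frac == pytest.approx(1.0)


def test_positional_index_empty_window_errors():
    track = make_track(np.full(10, 2.5))
    with pytest.raises(ValidationError):
        positional_index(track, single_pattern(), (5.0, 5.0))


def test_head_on_midline_counts_as_noncs():
    assert not in_cs_zone(1.5, True)
    assert not in_cs_zone(1.5, False)


def _point(y):
    return TrackPoint(t=0.0, head=(1.0, y), center=(1.0, y), tail=(1.0, y), heading=0.0)


def test_midline_distance_sign_and_antisymmetry():
    bottom = PatternEvent(0.0, "bottom", RBC)
    top = PatternEvent(0.0, "top", RBC)
    assert midline_distance(_point(1.5), bottom) == 0.0
    assert midline_distance(_point(0.5), bottom) == -1.0  # 1 cm into CS zone
    for y in (0.3, 1.2, 2.9):
        assert midline_distance(_point(y), top) == -midline_distance(_point(y), bottom)


# ---------------------------------------------------------------------------
# Turn scoring and the turning index


def test_escape_turn_scores_plus_one():
    # approach the midline band from the non-CS (top) side, turn, retreat
    y = np.concatenate([np.linspace(2.8, 1.7, 12), np.linspace(1.75, 2.8, 12)])
    headings = np.zeros(24)
    headings[12:] = 170.0  # > 15 deg heading change at the turn
    track = make_track(y, headings=headings)
    score = score_turns(track, single_pattern("bottom"), (0.0, 2.4), 0.4)
    assert (score.s_plus, score.s_minus) == (1, 0)


def test_two_cs_returns_score_minus_two():
    y = np.concatenate([
        np.linspace(2.5, 1.0, 10), np.linspace(1.0, 2.5, 10),
        np.linspace(2.5, 1.0, 10), np.linspace(1.0, 2.5, 10),
    ])
    track = make_track(y)
    score = score_turns(track, single_pattern("bottom"), (0.0, 4.0), 0.4)
    assert (score.s_plus, score.s_minus) == (0, -2)


def test_fish_far_from_midline_scores_nothing():
    track = make_track(np.full(100, 2.9))
    score = score_turns(track, single_pattern("bottom"), (0.0, 10.0), 0.4)
    assert (score.s_plus, score.s_minus) == (0, 0)


def test_band_visit_without_turn_scores_nothing():
    y = np.concatenate([np.linspace(2.8, 1.7, 12), np.linspace(1.75, 2.8, 12)])
    track = make_track(y)  # heading constant: no turn event
    score = score_turns(track, single_pattern("bottom"), (0.0, 2.4), 0.4)
    assert (score.s_plus, score.s_minus) == (0, 0)


@pytest.mark.parametrize("s_plus, s_minus, expected", [
    (5, 0, 1.0),
    (3, -3, 0.5),
    (3, -1, 0.75),
    (0, -4, 0.0),
])
def test_turning_index_formula(s_plus, s_minus, expected):
    assert turning_index(TurnScore(s_plus, s_minus)) == pytest.approx(expected)


def test_turning_index_undefined_for_zero_scores():
    assert np.isnan(turning_index(TurnScore(0, 0)))


@given(s_plus=st.integers(0, 500), s_minus=st.integers(0, 500))
@settings(max_examples=200, deadline=None)
def test_turning_index_bounds_and_extremes(s_plus, s_minus):
    if s_plus == 0 and s_minus == 0:
        return
    ti = turning_index(TurnScore(s_plus, -s_minus))
    assert 0.0 <= ti <= 1.0
    assert (ti == 1.0) == (s_minus == 0)
    assert (ti == 0.0) == (s_plus == 0)


def test_turn_score_sign_invariants():
    with pytest.raises(ValidationError):
        TurnScore(-1, 0)
    with pytest.raises(ValidationError):
        TurnScore(0, 1)


# ---------------------------------------------------------------------------
# Epochization


def test_epochize_default_plan_structure(sim_session):
    series = epochize(sim_session)
    assert len(series) == 24
    labels = series.phase_of_epoch
    assert labels.count("baseline") == 5
    assert labels.count("training") == 10
    assert labels.count("test") == 9
    # blackout (1800-1860 s) falls in no epoch
    starts = series.epoch_start_s
    assert not np.any((starts >= 1800.0) & (starts < 1860.0))
    assert set(starts[labels.index("test"):]) == set(1860.0 + 120.0 * np.arange(9))
    assert np.all(np.isfinite(series.positional))
    assert np.all((series.positional >= 0) & (series.positional <= 1))


def test_epochize_all_noncs_trajectory_gives_unit_index(small_plan):
    n = int(small_plan.total_s * 10)
    track = make_track(np.full(n, 2.5))
    session_patterns = single_pattern("bottom")
    from larvalearn import Session
    session = Session(fish_id="f", strain="s", protocol="self_control",
                      track=track, patterns=session_patterns, shocks=[],
                      phases=small_plan)
    series = epochize(session)
    assert np.allclose(series.positional, 1.0)
    assert len(series) == (240 + 240 + 240) / 120


def test_epochize_rejects_non_divisible_plan(sim_session):
    import copy
    from dataclasses import replace

    s2 = copy.copy(sim_session)
    s2.phases = replace(sim_session.phases, baseline_s=500.0)
    with pytest.raises(ValidationError):
        epochize(s2)
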