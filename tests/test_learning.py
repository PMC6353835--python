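"""Learner classification, extinction and group statistics tests."""

import numpy as np
import pytest

from larvalearn import (
    ValidationError,
    analyze_cohort,
    baseline_mean,
    classify_learner,
    extinction_point,
    group_extinction,
    group_phase_tests,
    learner_percentage,
    memory_length,
)
from larvalearn.metrics import EpochSeries


def mk_series(base, training=None, test=None):
    """Assemble an EpochSeries from explicit per-phase positional indices."""
    base = list(base)
    training = list(training) if training is not None else [0.5] * 10
    test = list(test) if test is not None else [0.5] * 9
    vals = np.array(base + training + test, dtype=float)
    labels = (["baseline"] * len(base) + ["training"] * len(training)
              + ["test"] * len(test))
    starts = np.arange(len(vals)) * 120.0
    return EpochSeries(positional=vals, turning=np.full(len(vals), np.nan),
                       phase_of_epoch=labels, epoch_start_s=starts)


# ---------------------------------------------------------------------------
# Baseline and extinction point


def test_baseline_mean_examples():
    assert baseline_mean(mk_series([0.5] * 5)) == 0.5
    assert baseline_mean(mk_series([0.4, 0.6, 0.5, 0.5, 0.5])) == pytest.approx(0.5)
    assert baseline_mean(mk_series([0.7])) == 0.7


def test_extinction_point_first_below_scan():
    s = mk_series([0.5] * 5, test=[0.9, 0.8, 0.45, 0.9, 0.9, 0.9, 0.9, 0.9, 0.9])
    assert extinction_point(s, 0.5) == 3


def test_extinction_point_none_when_never_below():
    s = mk_series([0.5] * 5, test=[0.9] * 9)
    assert extinction_point(s, 0.5) is None


def test_extinction_point_first_epoch_boundary():
    s = mk_series([0.5] * 5, test=[0.3] + [0.9] * 8)
    assert extinction_point(s, 0.5) == 1


def test_extinction_uses_strict_inequality():
    s = mk_series([0.5] * 5, test=[0.5] * 9)  # equal is not "below"
    assert extinction_point(s, 0.5) is None


# ---------------------------------------------------------------------------
# Memory length and categories


@pytest.mark.parametrize("ext, expected_s, expected_cat", [
    (3, 240.0, "short"),
    (None, 1080.0, "no_extinction"),
    (6, 600.0, "mid"),
    (9, 960.0, "mid"),
    (2, 120.0, "sub_threshold"),
    (5, 480.0, "short"),
])
def test_memory_length_and_category(ext, expected_s, expected_cat):
    length, cat = memory_length(ext)
    assert length == expected_s
    assert cat == expected_cat


# ---------------------------------------------------------------------------
# Learner classification


def test_clear_learner_is_classified():
    rng = np.random.default_rng(0)
    base = 0.50 + 0.02 * rng.standard_normal(5)
    test = 0.95 + 0.02 * rng.standard_normal(9)
    res = classify_learner(mk_series(base, test=test), fish_id="f")
    assert res.is_learner
    assert res.p_value < 0.05
    assert res.pi_increase > 0.3


def test_recall_identical_to_baseline_is_not_learner():
    s = mk_series([0.5, 0.52, 0.48, 0.5, 0.5], test=[0.51] * 9)
    res = classify_learner(s)
    assert not res.is_learner


def test_one_epoch_recall_is_excluded_regardless_of_values():
    # extinction at test epoch 2: recall period is a single epoch
    s = mk_series([0.5] * 5, test=[0.99, 0.1] + [0.9] * 7)
    res = classify_learner(s)
    assert not res.is_learner
    assert "shorter than two epochs" in res.reason
    assert np.isnan(res.p_value)


def test_recall_equal_to_baseline_mean_is_not_learner():
    """Recall epochs exactly at the baseline mean (the only way a recall
    period avoids extinction without exceeding baseline) never classify."""
    s = mk_series([0.5] * 5, test=[0.5] * 9)
    res = classify_learner(s)
    assert not res.is_learner
    assert res.extinction_epoch is None  # equal is not strictly below


def test_every_classified_learner_has_positive_pi_increase(small_cohort):
    results, _, _ = analyze_cohort(small_cohort)
    learners = [r for r in results if r.is_learner]
    assert learners, "cohort should contain at least one classified learner"
    assert all(r.pi_increase > 0 for r in learners)
    assert all(r.memory_length_s >= 240.0 for r in learners)


# ---------------------------------------------------------------------------
# Group extinction


def test_group_extinction_rate_formula():
    # mean curve peaks at 0.9, extinguishes below baseline 0.5 at epoch 6,
    # with the nearest valley at 0.6
    test = [0.9, 0.85, 0.8, 0.7, 0.6, 0.45, 0.7, 0.7, 0.7]
    s = mk_series([0.5] * 5, test=test)
    g = group_extinction([s])
    assert g.pi1 == pytest.approx(0.9)
    assert g.extinction_epoch == 6
    assert g.memory_length_min == pytest.approx(10.0)
    assert g.pi2 == pytest.approx(0.45)
    assert g.rate_per_min == pytest.approx((0.9 - 0.45) / 10.0)


def test_group_extinction_flat_high_curve_has_zero_rate():
    s = mk_series([0.5] * 5, test=[0.9] * 9)
    g = group_extinction([s])
    assert g.extinction_epoch is None
    assert g.memory_length_min == pytest.approx(18.0)
    assert g.rate_per_min == pytest.approx(0.0)


def test_group_extinction_single_learner_is_its_own_curve():
    test = [0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.4, 0.4, 0.4]
    s = mk_series([0.55] * 5, test=test)
    g = group_extinction([s])
    assert np.allclose(g.mean_curve, test)


def test_group_extinction_invariant_to_adding_mean_curve():
    t1 = [0.95, 0.9, 0.8, 0.6, 0.4, 0.4, 0.5, 0.5, 0.5]
    t2 = [0.85, 0.8, 0.7, 0.7, 0.5, 0.3, 0.4, 0.6, 0.5]
    s1 = mk_series([0.5] * 5, test=t1)
    s2 = mk_series([0.5] * 5, test=t2)
    g2 = group_extinction([s1, s2])
    mean_curve = np.mean([t1, t2], axis=0)
    s3 = mk_series([0.5] * 5, test=mean_curve)
    g3 = group_extinction([s1, s2, s3])
    assert g3.rate_per_min == pytest.approx(g2.rate_per_min)
    assert g3.pi1 == pytest.approx(g2.pi1)
    assert g3.pi2 == pytest.approx(g2.pi2)


def test_group_extinction_requires_learners():
    with pytest.raises(ValidationError):
        group_extinction([])


# ---------------------------------------------------------------------------
# Group phase tests


def test_identical_phases_give_null_paired_result():
    series = [mk_series([v] * 5, test=[v] * 9)
              for v in (0.4, 0.5, 0.6, 0.55)]
    report = group_phase_tests(series)
    assert report.paired_p == pytest.approx(1.0)
    assert report.n == 4


def test_planted_effect_is_detected(small_cohort):
    results, series, _ = analyze_cohort(small_cohort)
    learner_series = [s for s, r in zip(series, results) if r.is_learner]
    assert len(learner_series) >= 2
    report = group_phase_tests(learner_series)
    assert report.paired_p < 0.05
    assert report.recall_mean > report.baseline_mean


def test_unpaired_comparison_against_control():
    rng = np.random.default_rng(2)
    treated = [mk_series(0.5 + 0.02 * rng.standard_normal(5),
                         test=0.9 + 0.02 * rng.standard_normal(9)) for _ in range(8)]
    control = [mk_series(0.5 + 0.02 * rng.standard_normal(5),
                         test=0.5 + 0.02 * rng.standard_normal(9)) for _ in range(8)]
    report = group_phase_tests(treated, control)
    assert report.unpaired_p < 0.01
    assert report.control_n == 8


def test_null_unpaired_rejection_rate_near_alpha():
    """Two cohorts from the same null generator: the between-group test
    rejects at roughly the nominal rate."""
    rng = np.random.default_rng(3)
    rejections = 0
    n_rep = 200
    for _ in range(n_rep):
        a = [mk_series(0.5 + 0.05 * rng.standard_normal(5),
                       test=0.5 + 0.05 * rng.standard_normal(9)) for _ in range(6)]
        b = [mk_series(0.5 + 0.05 * rng.standard_normal(5),
                       test=0.5 + 0.05 * rng.standard_normal(9)) for _ in range(6)]
        if group_phase_tests(a, b).unpaired_p < 0.05:
            rejections += 1
    assert rejections / n_rep < 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / n_rep)


def test_group_phase_tests_require_two_fish():
    with pytest.raises(ValidationError):
        group_phase_tests([mk_series([0.5] * 5)])


# ---------------------------------------------------------------------------
# Learner percentage


@pytest.mark.parametrize("n, total, expected", [
    (27, 104, 26),
    (21, 44, 48),  # exact rounding; not forced to a published 50%
    (0, 10, 0),
    (21, 42, 50),
    (1, 33, 3),
])
def test_learner_percentage_rounded(n, total, expected):
    assert learner_percentage(n, total) == expected


def test_learner_percentage_input_validation():
    with pytest.raises(ValidationError):
        learner_percentage(1, 0)
    with pytest.raises(ValidationError):
        learner_percentage(5, 3)
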