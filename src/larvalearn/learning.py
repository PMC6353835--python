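"""Learner classification, memory extinction and group-level statistics.

A fish is a *learner* when its positional index during the recall period
(test-phase epochs before the extinction point) is significantly higher
than during the baseline epochs (Welch two-sample t-test, with the
difference in the learned direction), and the recall period spans at
least two epochs — fish whose index drops below baseline
almost immediately (e.g. fish parked in the non-CS zone) are excluded.

The *extinction point* is the first test epoch whose positional index
falls strictly below the baseline mean; *memory length* is the test time
elapsed up to that epoch, and learners are binned into short-term
(240-500 s), mid-term (500-1000 s) and no-extinction categories.  The
group *extinction rate* is (PI1 - PI2) / memory-length on the learner-mean
curve, in 1/min, where PI1 is the first peak at the start of the test
phase and PI2 the valley nearest the group extinction point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .metrics import EpochSeries, epochize, prescreen
from .session import Session, ValidationError

__all__ = [
    "LearnerResult",
    "GroupExtinction",
    "PhaseTestReport",
    "baseline_mean",
    "extinction_point",
    "memory_length",
    "classify_learner",
    "group_extinction",
    "group_phase_tests",
    "learner_percentage",
    "analyze_cohort",
    "CATEGORY_SHORT_S",
    "CATEGORY_MID_S",
]

#: Memory-length category bins, in seconds: short [240, 500), mid [500, 1000).
CATEGORY_SHORT_S = (240.0, 500.0)
CATEGORY_MID_S = (500.0, 1000.0)
MIN_RECALL_EPOCHS = 2


@dataclass
class LearnerResult:
    """Per-fish classification and memory statistics."""

    fish_id: str
    is_learner: bool
    p_value: float
    extinction_epoch: Optional[int]  # 1-based within the test phase, None = no extinction
    memory_length_s: float
    category: str  # 'short' | 'mid' | 'no_extinction' | 'sub_threshold'
    pi_increase: float
    ti_increase: float
    strain: str = ""
    pattern_name: str = ""
    reason: str = ""


@dataclass
class GroupExtinction:
    """Extinction statistics of the learner-mean test-phase curve."""

    pi1: float
    pi2: float
    memory_length_min: float
    rate_per_min: float
    extinction_epoch: Optional[int]
    mean_curve: np.ndarray


@dataclass
class PhaseTestReport:
    """Paired within-group and unpaired between-group t-test summary."""

    paired_t: float
    paired_p: float
    baseline_mean: float
    baseline_sem: float
    recall_mean: float
    recall_sem: float
    n: int
    unpaired_t: Optional[float] = None
    unpaired_p: Optional[float] = None
    control_n: Optional[int] = None


def baseline_mean(series: EpochSeries) -> float:
    """Mean positional index over the baseline epochs."""
    vals = series.phase_values("baseline")
    if vals.size == 0:
        raise ValidationError("series has no baseline epochs")
    return float(vals.mean())


def extinction_point(series: EpochSeries, baseline: float) -> Optional[int]:
    """1-based ordinal of the first test epoch with positional index
    strictly below the baseline mean, or None when no epoch drops below."""
    test = series.phase_values("test")
    below = np.flatnonzero(test < baseline)
    return int(below[0]) + 1 if below.size else None


def memory_length(ext_epoch: Optional[int], test_s: float = 1080.0,
                  epoch_s: float = 120.0) -> tuple[float, str]:
    """Memory length in seconds plus its category.

    The recall period runs from the start of the test phase to the
    extinction point, so extinction at test epoch k means (k - 1) full
    epochs of retained memory; no extinction spans the whole test phase.
    """
    if ext_epoch is None:
        return test_s, "no_extinction"
    length = (ext_epoch - 1) * epoch_s
    if length < CATEGORY_SHORT_S[0]:
        return length, "sub_threshold"
    if length < CATEGORY_SHORT_S[1]:
        return length, "short"
    if length < CATEGORY_MID_S[1]:
        return length, "mid"
    return length, "no_extinction"


def classify_learner(series: EpochSeries, alpha: float = 0.05,
                     fish_id: str = "", strain: str = "",
                     pattern_name: str = "") -> LearnerResult:
    """Classify one fish from its epoch series.

    Learner criteria: the recall period spans at least two epochs, and a
    Welch two-sample t-test finds the recall positional indices
    significantly different from the baseline ones at level ``alpha``
    with the recall mean above the baseline mean.
    """
    base_vals = series.phase_values("baseline")
    test_pi = series.phase_values("test")
    base = float(base_vals.mean())
    ext = extinction_point(series, base)
    test_s = test_pi.size * series.epoch_s
    mem_s, category = memory_length(ext, test_s=test_s, epoch_s=series.epoch_s)

    n_recall = (ext - 1) if ext is not None else test_pi.size
    recall_pi = test_pi[:n_recall]
    base_ti = series.phase_values("baseline", "turning")
    recall_ti = series.phase_values("test", "turning")[:n_recall]

    pi_increase = float(recall_pi.mean() - base) if recall_pi.size else float("nan")
    ti_ok = base_ti[~np.isnan(base_ti)]
    ti_recall_ok = recall_ti[~np.isnan(recall_ti)]
    ti_increase = (float(ti_recall_ok.mean() - ti_ok.mean())
                   if ti_ok.size and ti_recall_ok.size else float("nan"))

    if n_recall < MIN_RECALL_EPOCHS:
        return LearnerResult(
            fish_id=fish_id, is_learner=False, p_value=float("nan"),
            extinction_epoch=ext, memory_length_s=mem_s, category=category,
            pi_increase=pi_increase, ti_increase=ti_increase, strain=strain,
            pattern_name=pattern_name,
            reason=f"recall period of {n_recall} epoch(s) is shorter than two epochs",
        )

    # Welch two-sample t-test; "significantly higher" = two-sided
    # significance together with a positive recall-minus-baseline mean
    with warnings.catch_warnings():
        # constant epoch series (degenerate but valid input) trip a
        # precision warning inside scipy's moment calculation
        warnings.simplefilter("ignore", RuntimeWarning)
        t_stat, p = stats.ttest_ind(recall_pi, base_vals, equal_var=False)
    is_learner = bool(p < alpha and recall_pi.mean() > base)
    return LearnerResult(
        fish_id=fish_id, is_learner=is_learner, p_value=float(p),
        extinction_epoch=ext, memory_length_s=mem_s, category=category,
        pi_increase=pi_increase, ti_increase=ti_increase, strain=strain,
        pattern_name=pattern_name,
        reason="" if is_learner else "recall not significantly above baseline",
    )


def _first_peak(curve: np.ndarray) -> int:
    """Index of the first local maximum (plateaus resolve to the earliest
    epoch; the first epoch counts if it exceeds its successor)."""
    for i in range(len(curve) - 1):
        if curve[i] >= curve[i + 1]:
            return i
    return len(curve) - 1


def _local_minima(curve: np.ndarray) -> np.ndarray:
    n = len(curve)
    if n == 1:
        return np.array([0])
    minima = []
    for i in range(n):
        left_ok = i == 0 or curve[i] <= curve[i - 1]
        right_ok = i == n - 1 or curve[i] <= curve[i + 1]
        if left_ok and right_ok:
            minima.append(i)
    return np.asarray(minima)


def group_extinction(learner_series: Sequence[EpochSeries]) -> GroupExtinction:
    """Extinction statistics on the mean learning curve of the learners."""
    if not learner_series:
        raise ValidationError("group_extinction requires at least one learner")
    test_curves = np.vstack([s.phase_values("test") for s in learner_series])
    curve = test_curves.mean(axis=0)
    base = float(np.mean([baseline_mean(s) for s in learner_series]))
    epoch_s = learner_series[0].epoch_s

    i_peak = _first_peak(curve)
    pi1 = float(curve[i_peak])
    below = np.flatnonzero(curve < base)
    ext_epoch = int(below[0]) + 1 if below.size else None
    if ext_epoch is not None:
        mem_s = (ext_epoch - 1) * epoch_s
        anchor = ext_epoch - 1
    else:
        mem_s = curve.size * epoch_s
        anchor = curve.size - 1
    minima = _local_minima(curve)
    i_valley = int(minima[np.argmin(np.abs(minima - anchor))])
    pi2 = float(curve[i_valley])
    mem_min = mem_s / 60.0
    rate = (pi1 - pi2) / mem_min if mem_min > 0 else float("nan")
    return GroupExtinction(pi1=pi1, pi2=pi2, memory_length_min=mem_min,
                           rate_per_min=rate, extinction_epoch=ext_epoch,
                           mean_curve=curve)


def group_phase_tests(cohort: Sequence[EpochSeries],
                      control_cohort: Sequence[EpochSeries] | None = None,
                      alpha: float = 0.05) -> PhaseTestReport:
    """Group statistics: a paired t-test of per-fish baseline vs recall
    mean positional indices, and optionally an unpaired t-test of the
    per-fish index increases against a control cohort."""
    if len(cohort) < 2:
        raise ValidationError("group_phase_tests requires at least two fish")

    def _means(series_list):
        base, recall, increase = [], [], []
        for s in series_list:
            b = baseline_mean(s)
            ext = extinction_point(s, b)
            test_pi = s.phase_values("test")
            n_recall = (ext - 1) if ext is not None else test_pi.size
            r = float(test_pi[:max(n_recall, 1)].mean())
            base.append(b)
            recall.append(r)
            increase.append(r - b)
        return np.array(base), np.array(recall), np.array(increase)

    base, recall, increase = _means(cohort)
    if np.allclose(recall, base):
        t_stat, p = 0.0, 1.0  # no within-fish change at all
    else:
        t_stat, p = stats.ttest_rel(recall, base)
    report = PhaseTestReport(
        paired_t=float(t_stat), paired_p=float(p),
        baseline_mean=float(base.mean()), baseline_sem=float(stats.sem(base)),
        recall_mean=float(recall.mean()), recall_sem=float(stats.sem(recall)),
        n=len(cohort),
    )
    if control_cohort is not None:
        if len(control_cohort) < 2:
            raise ValidationError("control cohort requires at least two fish")
        _, _, control_increase = _means(control_cohort)
        t2, p2 = stats.ttest_ind(increase, control_increase, equal_var=False)
        report.unpaired_t = float(t2)
        report.unpaired_p = float(p2)
        report.control_n = len(control_cohort)
    return report


def learner_percentage(n_learners: int, n_total: int) -> int:
    """Percentage of learners, rounded to the nearest integer percent."""
    if n_total <= 0:
        raise ValidationError("n_total must be > 0")
    if not (0 <= n_learners <= n_total):
        raise ValidationError("n_learners must lie in [0, n_total]")
    return round(100.0 * n_learners / n_total)


def analyze_cohort(sessions: Sequence[Session], alpha: float = 0.05,
                   apply_prescreen: bool = True,
                   ) -> tuple[list[LearnerResult], list[EpochSeries], list[Session]]:
    """Pre-screen, epochize and classify a cohort of sessions.

    Returns (results, epoch series, retained sessions); excluded sessions
    appear in none of the three.
    """
    results: list[LearnerResult] = []
    series_list: list[EpochSeries] = []
    kept: list[Session] = []
    for session in sessions:
        if apply_prescreen and not prescreen(session):
            continue
        series = epochize(session)
        result = classify_learner(
            series, alpha=alpha, fish_id=session.fish_id, strain=session.strain,
            pattern_name=session.metadata.get("pattern_name",
                                              session.patterns[0].pattern.name
                                              if session.patterns else ""),
        )
        results.append(result)
        series_list.append(series)
        kept.append(session)
    return results, series_list, kept
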