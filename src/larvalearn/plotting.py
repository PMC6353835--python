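"""Figures: learning curves and single-fish behavioral traces."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import matplotlib.pyplot as plt

from .learning import LearnerResult
from .metrics import EpochSeries, cs_location_per_frame, in_cs_zone
from .session import Session

__all__ = ["plot_learning_curves", "plot_behavioral_trace"]

_PHASE_SPANS = ("baseline", "training", "test")


def plot_learning_curves(series_list: Sequence[EpochSeries],
                         is_learner: Sequence[bool],
                         which: str = "positional",
                         ax: Optional[plt.Axes] = None) -> plt.Figure:
    """Mean +- SEM learning curves of learners vs non-learners over the
    24 two-minute epochs (blackout contributes no epoch)."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(7, 4))
    else:
        fig = ax.figure
    is_learner = np.asarray(is_learner, dtype=bool)
    epochs = np.arange(1, len(series_list[0]) + 1)
    for mask, color, label_txt in ((is_learner, "tab:red", "learners"),
                                   (~is_learner, "tab:green", "non-learners")):
        if not mask.any():
            continue
        curves = np.vstack([getattr(s, which) for s, m in zip(series_list, mask) if m])
        mean = np.nanmean(curves, axis=0)
        sem = np.nanstd(curves, axis=0, ddof=1) / np.sqrt(curves.shape[0]) \
            if curves.shape[0] > 1 else np.zeros_like(mean)
        ax.plot(epochs, mean, color=color, label=f"{label_txt} (n={curves.shape[0]})")
        ax.fill_between(epochs, mean - sem, mean + sem, color=color, alpha=0.25)
    s0 = series_list[0]
    n_base = s0.phase_of_epoch.count("baseline")
    n_train = s0.phase_of_epoch.count("training")
    for x in (n_base + 0.5, n_base + n_train + 0.5):
        ax.axvline(x, color="gray", linestyle=":", linewidth=1)
    ax.set_xlabel("epoch (2 min each; baseline | training | test)")
    ax.set_ylabel(f"{which} index")
    ax.set_ylim(0, 1)
    ax.legend(loc="lower right")
    fig.tight_layout()
    return fig


def plot_behavioral_trace(session: Session, result: Optional[LearnerResult] = None,
                          ax: Optional[plt.Axes] = None) -> plt.Figure:
    """Signed head-to-midline distance over time, with shock deliveries as
    red dots and, when available, the extinction point as a blue marker."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(9, 3.5))
    else:
        fig = ax.figure
    track = session.track
    midline = session.arena[1] / 2.0
    loc = cs_location_per_frame(track, session.patterns)
    dist = np.abs(track.head_y - midline)
    cs = np.asarray(in_cs_zone(track.head_y, loc == 1, midline))
    signed = np.where(cs, -dist, dist)
    signed[loc < 0] = np.nan  # frames before the first pattern (none in practice)
    minutes = track.t / 60.0
    ax.plot(minutes, signed, linewidth=0.5, color="black")
    ax.axhline(0.0, color="gray", linewidth=0.8)
    if session.shocks:
        shock_min = np.array([s.t for s in session.shocks]) / 60.0
        idx = np.searchsorted(track.t, shock_min * 60.0)
        idx = np.clip(idx, 0, len(track) - 1)
        ax.plot(shock_min, signed[idx], "r.", markersize=4, label="shock")
    for t_edge in (session.phases.training_start, session.phases.blackout_start,
                   session.phases.test_start):
        ax.axvline(t_edge / 60.0, color="gray", linestyle=":", linewidth=1)
    if result is not None and result.extinction_epoch is not None:
        t_ext = (session.phases.test_start
                 + (result.extinction_epoch - 1) * 120.0) / 60.0
        ax.plot([t_ext], [session.arena[1] / 2.0 * 0.9], marker="v", color="tab:blue",
                markersize=9, linestyle="none", label="extinction point")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("distance to midline (cm)\n+ non-CS / - CS")
    ax.set_xlim(0, session.phases.total_s / 60.0)
    ax.set_ylim(-midline, midline)
    if session.shocks or (result is not None and result.extinction_epoch is not None):
        ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    return fig
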