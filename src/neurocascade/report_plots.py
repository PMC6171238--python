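"""Report figures for the cascade analysis.

Each function draws onto a fresh matplotlib figure and returns it; callers
decide whether to save or show.  Uses the non-interactive Agg backend safely
(no display required).
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from neurocascade.cascade import CascadeReport
from neurocascade.variable_selection import VariableSet


def plot_eer_curve(scores: np.ndarray, labels: np.ndarray, n_points: int = 200):
    """Sensitivity and specificity of the screener as functions of its
    threshold; their crossing is the equal-error-rate point."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    ts = np.linspace(0, 1, n_points)
    n_pos = (labels == 1).sum()
    n_neg = (labels == 0).sum()
    sens = [(scores[labels == 1] >= t).sum() / n_pos for t in ts]
    spec = [(scores[labels == 0] < t).sum() / n_neg for t in ts]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(ts, sens, label="sensitivity")
    ax.plot(ts, spec, label="specificity")
    ax.set_xlabel("stage-1 threshold")
    ax.set_ylabel("rate")
    ax.legend()
    fig.tight_layout()
    return fig

def plot_cost_performance(report: CascadeReport):
    """Cost and F1 along the threshold sweep, with the selected point."""
    ts = report.curve.column("threshold")
    fig, ax1 = plt.subplots(figsize=(5.5, 3.5))
    ax1.plot(ts, report.curve.column("f1"), color="tab:blue", label="F1")
    ax1.set_xlabel("stage-1 threshold")
    ax1.set_ylabel("F1", color="tab:blue")
    ax2 = ax1.twinx()
    ax2.plot(ts, report.curve.column("cost"), color="tab:red", label="cost")
    ax2.set_ylabel("cost (USD)", color="tab:red")
    ax1.axvline(report.selected_threshold, ls="--", color="gray")
    fig.tight_layout()
    return fig


def plot_screener_score_histogram(
    screener_scores: np.ndarray, gated_mask: np.ndarray, bins: int = 30
):
    """Distribution of a screener variable (e.g. the MMSE total score) split
    by whether the subject was gated to the confirmatory battery."""
    screener_scores = np.asarray(screener_scores, dtype=float)
    gated_mask = np.asarray(gated_mask, dtype=bool)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(screener_scores[~gated_mask], bins=bins, alpha=0.6, label="stage 1 only")
    ax.hist(screener_scores[gated_mask], bins=bins, alpha=0.6, label="gated to stage 2")
    ax.set_xlabel("screener score")
    ax.set_ylabel("subjects")
    ax.legend()
    fig.tight_layout()
    return fig


def plot_auc_vs_set_size(sets: list[VariableSet], alpha: float = 0.05):
    """Cross-validated AUC against nested variable-set size; sets that differ
    significantly from the best set are greyed out."""
    fig, ax = plt.subplots(figsize=(5.5, 3.5))
    xs = [s.i for s in sets]
    ys = [s.auc_mean for s in sets]
    errs = [s.auc_std for s in sets]
    colors = ["tab:blue" if s.delong_p >= alpha else "lightgray" for s in sets]
    best = max(sets, key=lambda s: s.auc_mean)
    ax.errorbar(xs, ys, yerr=errs, fmt="none", ecolor="lightgray", zorder=1)
    ax.scatter(xs, ys, c=colors, s=18, zorder=2)
    ax.scatter([best.i], [best.auc_mean], c="tab:red", s=30, zorder=3, label="best set")
    ax.set_xlabel("variables included (ranking order)")
    ax.set_ylabel("cross-validated AUC")
    ax.legend()
    fig.tight_layout()
    return fig
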