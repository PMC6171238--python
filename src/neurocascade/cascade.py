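"""Two-stage screening cascade: gate, cost model, EER, and threshold choice.

A cheap screening test (stage 1) scores every subject; only subjects whose
screener score reaches the gate threshold proceed to the expensive
confirmatory battery (stage 2).  Non-gated subjects are labelled negative.
Total cost is

    cost = n_all * c_screen + n_2 * c_battery,

where n_2 is the number of gated subjects.  Raising the threshold sends
fewer subjects to stage 2, so both n_2 and cost are non-increasing in the
threshold.  The sweep is bounded above by the screener's equal-error-rate
threshold, and the selected operating point is the largest (cheapest)
threshold whose F1 matches the threshold-0 reference — i.e. maximal saving
with no measurable performance loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from neurocascade.metrics import confusion, diagnostic_report


@dataclass(frozen=True)
class CostModel:
    """Per-subject fees and gate counts for one operating point."""

    c_screen: float
    c_battery: float
    n_all: int
    n_2: int

    def __post_init__(self) -> None:
        if self.c_screen < 0 or self.c_battery < 0:
            raise ValueError("fees must be nonnegative")
        if not 0 <= self.n_2 <= self.n_all:
            raise ValueError("n_2 must lie in [0, n_all]")


def cost(model: CostModel) -> float:
    """Cascade cost: every subject pays the screening fee, gated subjects
    additionally pay the battery fee."""
    return model.n_all * model.c_screen + model.n_2 * model.c_battery


def battery_alone_cost(n_all: int, c_battery: float) -> float:
    """Comparator convention: battery for everyone, no screening fee."""
    return n_all * c_battery


def saving(full_cost: float, cascade_cost: float) -> tuple[float, float]:
    """Absolute and percentage saving of the cascade vs the comparator."""
    absolute = full_cost - cascade_cost
    percent = 100.0 * absolute / full_cost if full_cost > 0 else float("nan")
    return absolute, percent


@dataclass
class CascadeDecision:
    threshold: float
    gated_mask: np.ndarray
    final_scores: np.ndarray
    final_labels: np.ndarray

    @property
    def n_2(self) -> int:
        return int(self.gated_mask.sum())


def cascade_predict(
    stage1_scores: np.ndarray,
    stage2_scores: np.ndarray,
    threshold: float,
    stage2_cut: float = 0.5,
) -> CascadeDecision:
    """Apply the gate: subjects with stage-1 score >= threshold take stage 2;
    the rest are labelled negative with their stage-1 score retained."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    s1 = np.asarray(stage1_scores, dtype=float)
    s2 = np.asarray(stage2_scores, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("stage score vectors must cover the same subjects")
    for s in (s1, s2):
        if np.any(s < 0) or np.any(s > 1):
            raise ValueError("scores must lie in [0, 1]")
    gated = s1 >= threshold
    final_scores = np.where(gated, s2, s1)
    final_labels = np.where(gated, (s2 >= stage2_cut).astype(int), 0)
    return CascadeDecision(
        threshold=threshold,
        gated_mask=gated,
        final_scores=final_scores,
        final_labels=final_labels,
    )


def equal_error_rate(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Threshold minimising |sensitivity - specificity| over the empirical
    score set, and the equal error rate there.

    Candidate thresholds are midpoints between consecutive distinct scores
    (plus the extremes), so a perfectly separating gap returns its midpoint.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    candidates = np.concatenate(
        [[uniq[0] - 1e-9], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1e-9]]
    )
    best_t, best_gap, best_eer = candidates[0], np.inf, 0.5
    for t in candidates:
        pred = scores >= t
        sens = np.sum(pred & (labels == 1)) / n_pos
        spec = np.sum(~pred & (labels == 0)) / n_neg
        gap = abs(sens - spec)
        if gap < best_gap - 1e-12:
            best_gap = gap
            best_t = t
            best_eer = ((1 - sens) + (1 - spec)) / 2.0
    return float(np.clip(best_t, 0.0, 1.0)), float(best_eer)


@dataclass
class CostCurve:
    thresholds: np.ndarray
    records: list[dict] = field(default_factory=list)  # per-threshold metrics

    def column(self, key: str) -> np.ndarray:
        return np.array([r[key] for r in self.records])


def sweep_thresholds(
    stage1_scores: np.ndarray,
    stage2_scores: np.ndarray,
    labels: np.ndarray,
    cost_model: CostModel,
    grid: np.ndarray,
) -> CostCurve:
    """Evaluate the cascade at every gate threshold in ``grid``.

    Each record holds (threshold, n_2, cost, accuracy, f1, sensitivity,
    specificity).  n_2 and cost are non-increasing along an ascending grid.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid must be nonempty")
    labels = np.asarray(labels)
    records = []
    for t in np.sort(grid):
        decision = cascade_predict(stage1_scores, stage2_scores, float(t))
        rep = diagnostic_report(confusion(labels, decision.final_labels))
        c = cost(
            CostModel(
                c_screen=cost_model.c_screen,
                c_battery=cost_model.c_battery,
                n_all=len(labels),
                n_2=decision.n_2,
            )
        )
        records.append(
            {
                "threshold": float(t),
                "n_2": decision.n_2,
                "cost": c,
                "accuracy": rep.accuracy,
                "f1": rep.f1,
                "sensitivity": rep.sensitivity,
                "specificity": rep.specificity,
            }
        )
    return CostCurve(thresholds=np.sort(grid), records=records)


def select_threshold(curve: CostCurve, reference_f1: float, f1_slack: float = 0.0) -> float:
    """Largest (cheapest) threshold whose F1 has not dropped below the
    threshold-0 reference (minus an optional slack).  Threshold 0 always
    qualifies, so a result exists."""
    best = 0.0
    for r in curve.records:
        f1 = r["f1"]
        if np.isnan(f1):
            continue
        if f1 >= reference_f1 - f1_slack and r["threshold"] >= best:
            best = r["threshold"]
    return best


@dataclass
class CascadeReport:
    eer_threshold: float
    eer: float
    selected_threshold: float
    reference_f1: float
    curve: CostCurve
    full_cost: float
    cascade_cost: float
    saving_abs: float
    saving_pct: float
    decision: CascadeDecision

    def as_dict(self) -> dict:
        return {
            "eer_threshold": self.eer_threshold,
            "eer": self.eer,
            "selected_threshold": self.selected_threshold,
            "reference_f1": self.reference_f1,
            "full_cost": self.full_cost,
            "cascade_cost": self.cascade_cost,
            "saving_abs": self.saving_abs,
            "saving_pct": self.saving_pct,
            "curve": [dict(r) for r in self.curve.records],
        }


def run_cascade(
    stage1_scores: np.ndarray,
    stage2_scores: np.ndarray,
    labels: np.ndarray,
    c_screen: float = 10.0,
    c_battery: float = 180.0,
    grid_points: int = 500,
    f1_slack: float = 0.0,
) -> CascadeReport:
    """Full operating-point selection: EER bound, threshold sweep in
    [0, t_EER], cheapest threshold without F1 loss, and the cost ledger."""
    labels = np.asarray(labels)
    t_eer, eer = equal_error_rate(stage1_scores, labels)
    grid = np.linspace(0.0, max(t_eer, 0.0), grid_points)
    cm = CostModel(c_screen=c_screen, c_battery=c_battery, n_all=len(labels), n_2=len(labels))
    curve = sweep_thresholds(stage1_scores, stage2_scores, labels, cm, grid)
    reference_f1 = curve.records[0]["f1"]
    t_star = select_threshold(curve, reference_f1, f1_slack=f1_slack)
    decision = cascade_predict(stage1_scores, stage2_scores, t_star)
    cascade_cost = cost(
        CostModel(c_screen=c_screen, c_battery=c_battery, n_all=len(labels), n_2=decision.n_2)
    )
    full_cost = battery_alone_cost(len(labels), c_battery)
    absolute, percent = saving(full_cost, cascade_cost)
    return CascadeReport(
        eer_threshold=t_eer,
        eer=eer,
        selected_threshold=t_star,
        reference_f1=reference_f1,
        curve=curve,
        full_cost=full_cost,
        cascade_cost=cascade_cost,
        saving_abs=absolute,
        saving_pct=percent,
        decision=decision,
    )
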