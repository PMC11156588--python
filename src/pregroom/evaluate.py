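"""Event-anchored scoring of decision streams.

Each grooming event defines an early-detection period (Ep) running from 2 s
before onset to half the bout's duration after onset.  Decisions on the
200-ms grid are scored per bin: positives inside an Ep are true positives,
negatives inside an Ep are false negatives, and bins outside Ep and outside
grooming are true negatives / false positives.  Bins inside a grooming
event but past its Ep end are excluded from all counts — with this
convention a Bernoulli(0.5) classifier scores ~50% on sensitivity,
specificity and accuracy regardless of the annotation.  Missed events
(no positive bin in an event's Ep) are reported separately.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .closed_loop import CL, OFF, ON_CONT, RANDOM, StimulationEvent, TrialSchedule, stimulation_time
from .signal_io import BehaviorAnnotation


@dataclass
class EarlyDetectionPeriod:
    """Per-event scoring intervals ``[onset - 2, onset + duration/2]``."""

    intervals: list[tuple[float, float]]

    def __post_init__(self) -> None:
        for a, b in self.intervals:
            if not b > a:
                raise ValueError("each Ep interval must have end > start")

    @property
    def total_s(self) -> float:
        return float(sum(b - a for a, b in self.intervals))

    def __len__(self) -> int:
        return len(self.intervals)


def compute_ep(ann: BehaviorAnnotation, pre_s: float = 2.0) -> EarlyDetectionPeriod:
    """Early-detection periods of all grooming events, clipped to the session."""
    intervals = []
    for e in ann.grooming_events:
        a = max(e.onset_s - pre_s, 0.0)
        b = min(e.onset_s + e.duration_s / 2.0, ann.session_duration_s)
        if b > a:
            intervals.append((a, b))
    return EarlyDetectionPeriod(intervals)


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0
    excluded: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN, self.excluded) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN + self.excluded


def _in_any(t: np.ndarray, intervals: list[tuple[float, float]]) -> np.ndarray:
    """Membership of each time in the union of half-open intervals [a, b)."""
    mask = np.zeros(len(t), dtype=bool)
    for a, b in intervals:
        mask |= (t >= a) & (t < b)
    return mask


def score_decisions(
    t_s: np.ndarray,
    positive: np.ndarray,
    ann: BehaviorAnnotation,
    ep: EarlyDetectionPeriod | None = None,
) -> ConfusionCounts:
    """Bin-level confusion counts for one decision stream."""
    t_s = np.asarray(t_s, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    if t_s.shape != positive.shape:
        raise ValueError("t_s and positive must have the same shape")
    ep = compute_ep(ann) if ep is None else ep
    in_ep = _in_any(t_s, ep.intervals)
    in_groom = _in_any(t_s, [(e.onset_s, e.offset_s) for e in ann.grooming_events])
    excluded = in_groom & ~in_ep
    return ConfusionCounts(
        TP=int(np.sum(positive & in_ep)),
        FN=int(np.sum(~positive & in_ep)),
        FP=int(np.sum(positive & ~in_ep & ~excluded)),
        TN=int(np.sum(~positive & ~in_ep & ~excluded)),
        excluded=int(np.sum(excluded)),
    )


def missed_events(
    t_s: np.ndarray,
    positive: np.ndarray,
    ann: BehaviorAnnotation,
) -> int:
    """Events with no positive decision anywhere in their Ep (event-level FN)."""
    t_s = np.asarray(t_s, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    n = 0
    for a, b in compute_ep(ann).intervals:
        m = (t_s >= a) & (t_s < b)
        if m.any() and not positive[m].any():
            n += 1
    return n


@dataclass
class MetricReport:
    """The four classification metrics, in percent.

    Ratios with zero denominators are reported as ``None`` (missing), never
    coerced to 0 or 100.
    """

    accuracy: float | None
    sensitivity: float | None
    precision: float | None
    specificity: float | None

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "specificity": self.specificity,
        }


def _ratio(num: float, den: float, name: str) -> float | None:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as missing")
        return None
    return 100.0 * num / den

def metrics(c: ConfusionCounts) -> MetricReport:
    return MetricReport(
        accuracy=_ratio(c.TP + c.TN, c.TP + c.TN + c.FP + c.FN, "accuracy"),
        sensitivity=_ratio(c.TP, c.TP + c.FN, "sensitivity"),
        precision=_ratio(c.TP, c.TP + c.FP, "precision"),
        specificity=_ratio(c.TN, c.TN + c.FP, "specificity"),
    )


def average_metrics(reports: list[MetricReport]) -> MetricReport:
    def _mean(vals):
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else None

    return MetricReport(
        accuracy=_mean([r.accuracy for r in reports]),
        sensitivity=_mean([r.sensitivity for r in reports]),
        precision=_mean([r.precision for r in reports]),
        specificity=_mean([r.specificity for r in reports]),
    )


def pseudorandom_baseline(
    ann: BehaviorAnnotation,
    interval_s: float = 0.2,
    n_runs: int = 5,
    seed: int | None = None,
    p: float = 0.5,
) -> MetricReport:
    """Uniform pseudorandom classifier baseline at the decision cadence.

    Emits Bernoulli(``p``) decisions every ``interval_s`` over the session,
    scores them against the Ep scheme, and averages the metrics over
    ``n_runs`` repetitions.
    """
    if not ann.grooming_events:
        raise ValueError("annotation must contain at least one grooming event")
    rng = np.random.default_rng(seed)
    n_bins = int(np.floor(ann.session_duration_s / interval_s + 1e-9))
    t = np.arange(1, n_bins + 1) * interval_s
    ep = compute_ep(ann)
    reports = [
        metrics(score_decisions(t, rng.random(n_bins) < p, ann, ep))
        for _ in range(n_runs)
    ]
    return average_metrics(reports)


# ---------------------------------------------------------------------------
# Behavioral endpoints
# ---------------------------------------------------------------------------


def grooming_reduction(
    off_bouts: float,
    off_duration_s: float,
    treated_bouts: float,
    treated_duration_s: float,
) -> tuple[float, float]:
    """Percent reduction of bouts and grooming time vs the OFF baseline:
    ``100 - treated * 100 / off`` for each quantity."""
    if off_bouts <= 0 or off_duration_s <= 0:
        raise ValueError("OFF baselines must be positive")
    return (
        100.0 - treated_bouts * 100.0 / off_bouts,
        100.0 - treated_duration_s * 100.0 / off_duration_s,
    )


def interrater_error(expert_value: float, naive_value: float) -> float:
    """Signed percent disagreement: ``(expert - naive) / expert * 100``."""
    if expert_value == 0:
        raise ValueError("expert value must be nonzero")
    return (expert_value - naive_value) / expert_value * 100.0


# ---------------------------------------------------------------------------
# Session assembly
# ---------------------------------------------------------------------------


@dataclass
class SessionReport:
    confusion: ConfusionCounts
    metric_report: MetricReport
    missed_events: int
    grooming_by_condition: dict[str, dict[str, float]]
    stimulation: dict | None = None

    def to_dict(self) -> dict:
        out = {
            "confusion": vars(self.confusion),
            "metrics": self.metric_report.as_dict(),
            "missed_events": self.missed_events,
            "grooming_by_condition": self.grooming_by_condition,
        }
        if self.stimulation is not None:
            out["stimulation"] = self.stimulation
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=2)


def grooming_by_condition(
    ann: BehaviorAnnotation, schedule: TrialSchedule
) -> dict[str, dict[str, float]]:
    """Grooming bout counts and total durations per trial condition
    (events are assigned to the block containing their onset)."""
    out: dict[str, dict[str, float]] = {}
    for b in schedule.blocks:
        d = out.setdefault(b.condition, {"bouts": 0, "duration_s": 0.0})
        for e in ann.grooming_events:
            if b.t_start_s <= e.onset_s < b.t_end_s:
                d["bouts"] += 1
                d["duration_s"] += e.duration_s
    return out


def evaluate_session(
    decisions: pd.DataFrame,
    ann: BehaviorAnnotation,
    schedule: TrialSchedule | None = None,
    stim_events: list[StimulationEvent] | None = None,
) -> SessionReport:
    """Assemble the full scoring report for one session."""
    t = decisions["t_s"].to_numpy()
    pos = decisions["triggered"].to_numpy(dtype=bool)
    counts = score_decisions(t, pos, ann)
    stim = None
    by_cond: dict[str, dict[str, float]] = {}
    if schedule is not None:
        by_cond = grooming_by_condition(ann, schedule)
        if stim_events:
            rep = stimulation_time(schedule, stim_events)
            stim = {
                "per_condition_s": rep.per_condition_s,
                "percent_of_session": rep.percent_of_session,
                "percent_reduction_vs_continuous": rep.percent_reduction_vs_continuous,
            }
    return SessionReport(
        confusion=counts,
        metric_report=metrics(counts),
        missed_events=missed_events(t, pos, ann),
        grooming_by_condition=by_cond,
        stimulation=stim,
    )
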