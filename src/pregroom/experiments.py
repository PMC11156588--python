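"""Canned study-reproduction workflows.

These functions wire the generator, feature/classifier stack, closed-loop
engine and scoring layer into the experiments the package is validated
against: training a detector on synthetic sessions, scoring held-out
sessions with the early-detection-period metrics, the pseudorandom
baseline, and the closed-loop stimulation cohort with the OFF / CL /
randomized trial comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import VotingGroomingDetector
from .closed_loop import CL, OFF, RANDOM, build_schedule, run_closed_loop, run_detector, stimulation_time
from .evaluate import (
    MetricReport,
    average_metrics,
    compute_ep,
    metrics,
    missed_events,
    pseudorandom_baseline,
    score_decisions,
)
from .signal_io import BehaviorAnnotation
from .simulate import (
    BehaviorModel,
    BiomarkerModel,
    StimulationResponseModel,
    apply_stimulation_effect,
    build_labeled_dataset,
    simulate_behavior,
    simulate_lfp,
)


def _seeds(seed: int | None, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def train_grooming_detector(
    seed: int | None = 0,
    n_sessions: int = 3,
    session_duration_s: float = 1200.0,
    n_channels: int = 32,
    biomarker: BiomarkerModel | None = None,
    behavior: BehaviorModel | None = None,
):
    """Simulate annotated training sessions and fit the voting detector.

    Returns ``(detector, held_out_window_set)`` where the window set is the
    30% test split of the labeled dataset.
    """
    bm = biomarker or BiomarkerModel()
    ss = _seeds(seed, 2 * n_sessions + 2)
    recs, anns = [], []
    for i in range(n_sessions):
        behavior_model = behavior or BehaviorModel()
        ann = simulate_behavior(
            BehaviorModel(**{**vars(behavior_model), "session_duration_s": session_duration_s}),
            seed=ss[2 * i],
        )
        recs.append(simulate_lfp(ann, bm, n_channels=n_channels, seed=ss[2 * i + 1]))
        anns.append(ann)
    train_set, test_set = build_labeled_dataset(recs, anns, seed=ss[-2])
    detector = VotingGroomingDetector(random_state=ss[-1]).fit(train_set.X, train_set.y)
    return detector, test_set


@dataclass
class HeldOutScore:
    metric_report: MetricReport
    missed_events: int
    n_events: int
    n_ep_bins: int


def score_heldout_sessions(
    detector,
    seed: int | None = 0,
    n_sessions: int = 2,
    session_duration_s: float = 600.0,
    n_channels: int = 32,
    biomarker: BiomarkerModel | None = None,
) -> list[HeldOutScore]:
    """Continuous no-stimulation scoring of fresh synthetic sessions.

    Mirrors the offline assessment design: 10-min recordings, one decision
    every 200 ms, scored per bin against the early-detection periods.
    """
    bm = biomarker or BiomarkerModel()
    ss = _seeds(seed, 2 * n_sessions)
    out = []
    for i in range(n_sessions):
        ann = simulate_behavior(
            BehaviorModel(session_duration_s=session_duration_s), seed=ss[2 * i]
        )
        rec = simulate_lfp(ann, bm, n_channels=n_channels, seed=ss[2 * i + 1])
        dec = run_detector(rec, detector)
        t = dec["t_s"].to_numpy()
        pos = dec["triggered"].to_numpy(dtype=bool)
        counts = score_decisions(t, pos, ann)
        out.append(
            HeldOutScore(
                metric_report=metrics(counts),
                missed_events=missed_events(t, pos, ann),
                n_events=len(ann.grooming_events),
                n_ep_bins=counts.TP + counts.FN,
            )
        )
    return out


def pseudorandom_experiment(
    seed: int | None = 0,
    n_seeds: int = 20,
    n_runs: int = 5,
    session_duration_s: float = 600.0,
) -> tuple[MetricReport, int]:
    """The chance-level reference: Bernoulli(0.5) decisions at 200-ms bins
    on simulated 10-min annotations, 5-run averages across ``n_seeds``
    sessions.  Returns the grand-average report and the total bin count."""
    reports = []
    n_bins = 0
    for s_ann, s_run in zip(_seeds(seed, n_seeds), _seeds((seed or 0) + 1, n_seeds)):
        ann = simulate_behavior(
            BehaviorModel(session_duration_s=session_duration_s), seed=s_ann
        )
        reports.append(pseudorandom_baseline(ann, n_runs=n_runs, seed=s_run))
        n_bins += int(session_duration_s / 0.2)
    return average_metrics(reports), n_bins


@dataclass
class CohortResult:
    counts: dict[str, int]
    ordered: bool
    cl_stim_s_per_session: float
    n_sessions: int


def closed_loop_cohort(
    detector,
    seed: int | None = 0,
    n_subjects: int = 5,
    n_days: int = 3,
    n_channels: int = 32,
    biomarker: BiomarkerModel | None = None,
    stim_response: StimulationResponseModel | None = None,
) -> CohortResult:
    """One full closed-loop experiment: ``n_subjects`` x ``n_days`` 36-min
    sessions under the OFF/CL/RANDOM protocol, with stimulation acting back
    on behavior through the suppression model.  Grooming bout counts are
    aggregated per condition over the cohort."""
    bm = biomarker or BiomarkerModel()
    srm = stim_response or StimulationResponseModel()
    schedule = build_schedule("closed_loop")
    ss = _seeds(seed, 4 * n_subjects * n_days)
    totals = {OFF: 0, CL: 0, RANDOM: 0}
    cl_time = 0.0
    n_sessions = n_subjects * n_days
    for i in range(n_sessions):
        s0, s1, s2, s3 = ss[4 * i : 4 * i + 4]
        ann = simulate_behavior(
            BehaviorModel(session_duration_s=schedule.total_duration_s), seed=s0
        )
        rec = simulate_lfp(ann, bm, n_channels=n_channels, seed=s1)
        _, stims = run_closed_loop(rec, detector, schedule, seed=s2)
        treated = apply_stimulation_effect(ann, stims, srm, seed=s3)
        for b in schedule.blocks:
            totals[b.condition] += sum(
                1
                for e in treated.grooming_events
                if b.t_start_s <= e.onset_s < b.t_end_s
            )
        cl_time += stimulation_time(schedule, stims).per_condition_s.get(CL, 0.0)
    return CohortResult(
        counts=dict(totals),
        ordered=totals[CL] < totals[RANDOM] < totals[OFF],
        cl_stim_s_per_session=cl_time / n_sessions,
        n_sessions=n_sessions,
    )
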