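"""Closed-loop decision engine and stimulation protocol scheduling.

Decisions happen on a 200-ms grid.  In closed-loop (CL) trials a positive
vote triggers a 4-s stimulation during which no further decisions are made;
randomized ("yoked") trials receive the same number of stimulations as the
preceding CL trial but at random times; OFF trials never stimulate.  The
engine still logs (non-acting) decisions in OFF and randomized trials so
sessions can be scored offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signal_io import FeatureConfig, Recording
from .features import SpectralFeaturizer
from .spectral import to_analysis_rate

OFF = "OFF"
ON_CONT = "ON_CONT"
CL = "CL"
RANDOM = "RANDOM"


@dataclass
class StimulationEvent:
    """One light-pulse train: 4 s of 5-ms pulses at 20 Hz, 10 mW by default."""

    t_start_s: float
    duration_s: float = 4.0
    pulse_rate_hz: float = 20.0
    pulse_width_s: float = 0.005
    power_mw: float = 10.0
    condition: str = CL

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.pulse_width_s * self.pulse_rate_hz > 1:
            raise ValueError("pulse width x rate exceeds 100% duty cycle")

    @property
    def t_end_s(self) -> float:
        return self.t_start_s + self.duration_s


def duty_cycle(stim: StimulationEvent) -> float:
    """Percent of time the light is on within the pulse train."""
    return 100.0 * stim.pulse_width_s * stim.pulse_rate_hz


@dataclass
class TrialBlock:
    condition: str
    t_start_s: float
    duration_s: float = 180.0

    @property
    def t_end_s(self) -> float:
        return self.t_start_s + self.duration_s


@dataclass
class TrialSchedule:
    blocks: list[TrialBlock]
    habituation_s: float = 0.0  # metadata only, not simulated

    def __post_init__(self) -> None:
        t = self.blocks[0].t_start_s if self.blocks else 0.0
        for b in self.blocks:
            if abs(b.t_start_s - t) > 1e-9:
                raise ValueError("trial blocks must be contiguous and non-overlapping")
            t = b.t_end_s

    @property
    def total_duration_s(self) -> float:
        return self.blocks[-1].t_end_s if self.blocks else 0.0

    def condition_at(self, t_s: float) -> str | None:
        for b in self.blocks:
            if b.t_start_s < t_s <= b.t_end_s:
                return b.condition
        return None


def build_schedule(protocol: str, trial_duration_s: float = 180.0) -> TrialSchedule:
    """The paper-defined protocols.

    ``closed_loop``: 4 cycles of (OFF, CL, RANDOM), 12 trials, 36 min.
    ``continuous``: 5 alternating (OFF, ON_CONT) pairs, 10 trials, 30 min.
    """
    if protocol == "closed_loop":
        pattern = [OFF, CL, RANDOM] * 4
    elif protocol == "continuous":
        pattern = [OFF, ON_CONT] * 5
    else:
        raise ValueError(f"unknown protocol {protocol!r}")
    blocks = [
        TrialBlock(cond, i * trial_duration_s, trial_duration_s)
        for i, cond in enumerate(pattern)
    ]
    return TrialSchedule(blocks)


def assign_random_stims(
    n: int,
    block: TrialBlock,
    seed: int | None = None,
    stim_duration_s: float = 4.0,
) -> list[StimulationEvent]:
    """Pre-assign ``n`` non-overlapping stimulations uniformly within a trial."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return []
    if n * stim_duration_s >= block.duration_s:
        raise ValueError(
            f"{n} stimulations of {stim_duration_s}s cannot be placed without "
            f"overlap in a {block.duration_s}s trial"
        )
    rng = np.random.default_rng(seed)
    # uniform over non-overlapping configurations: drop n points into the
    # slack left after reserving n stimulation slots, then re-inflate
    slack = block.duration_s - n * stim_duration_s
    u = np.sort(rng.uniform(0.0, slack, size=n))
    starts = u + np.arange(n) * stim_duration_s
    return [
        StimulationEvent(
            block.t_start_s + float(s), duration_s=stim_duration_s, condition=RANDOM
        )
        for s in starts
    ]


# ---------------------------------------------------------------------------
# Streaming decisions
# ---------------------------------------------------------------------------


def run_detector(
    rec: Recording,
    detector,
    feature_cfg: FeatureConfig | None = None,
    interval_s: float = 0.2,
    analysis_rate_hz: float = 125.0,
) -> pd.DataFrame:
    """Sliding-window decisions over a whole recording, no stimulation.

    One decision per ``interval_s`` tick (t = k * interval, k >= 1); ticks
    whose feature history is incomplete are logged as forced-negative
    "warmup" decisions.  Columns: ``t_s, positive_fraction, triggered,
    warmup``.
    """
    cfg = feature_cfg or FeatureConfig()
    rec_a = to_analysis_rate(rec, analysis_rate_hz)
    feat = SpectralFeaturizer(cfg, rec_a.rate_hz)
    n_ticks = int(np.floor(rec_a.duration_s / interval_s + 1e-9))
    t_all = np.arange(1, n_ticks + 1) * interval_s
    valid = t_all >= cfg.warmup_s - 1e-9

    frac = np.zeros(n_ticks)
    if valid.any():
        X = feat.matrix_features(rec_a.samples, t_all[valid])
        frac[valid] = detector.positive_fraction(X)
    thr = getattr(detector, "threshold_fraction", 0.5)
    return pd.DataFrame(
        {
            "t_s": t_all,
            "positive_fraction": frac,
            "triggered": (frac > thr) & valid,
            "warmup": ~valid,
        }
    )


def run_closed_loop(
    rec: Recording,
    detector,
    schedule: TrialSchedule,
    seed: int | None = None,
    feature_cfg: FeatureConfig | None = None,
    interval_s: float = 0.2,
    stim_duration_s: float = 4.0,
    analysis_rate_hz: float = 125.0,
) -> tuple[pd.DataFrame, list[StimulationEvent]]:
    """Run the full protocol engine over a recording.

    Within CL blocks a triggered decision emits a 4-s stimulation and locks
    out further decisions until it ends.  OFF and RANDOM blocks log
    (non-acting) decisions; RANDOM blocks receive the same number of
    pre-assigned stimulations as the immediately preceding CL trial, placed
    uniformly at random.  Deterministic given inputs and seed.
    """
    if rec.duration_s + 1e-6 < schedule.total_duration_s:
        raise ValueError("recording shorter than the trial schedule")
    stream = run_detector(rec, detector, feature_cfg, interval_s, analysis_rate_hz)
    rng = np.random.default_rng(seed)

    rows = []
    stims: list[StimulationEvent] = []
    prev_cl_count = 0
    i = 0
    t_all = stream["t_s"].to_numpy()
    triggered = stream["triggered"].to_numpy()
    frac = stream["positive_fraction"].to_numpy()
    warmup = stream["warmup"].to_numpy()
    lockout_until = -np.inf

    for block in schedule.blocks:
        if block.condition == RANDOM:
            stims.extend(
                assign_random_stims(
                    prev_cl_count,
                    block,
                    seed=int(rng.integers(2**31)),
                    stim_duration_s=stim_duration_s,
                )
            )
        cl_count = 0
        while i < len(t_all) and t_all[i] <= block.t_end_s + 1e-9:
            t = t_all[i]
            if t <= lockout_until + 1e-9:
                i += 1
                continue
            acted = False
            if block.condition == CL and triggered[i]:
                stims.append(
                    StimulationEvent(t, duration_s=stim_duration_s, condition=CL)
                )
                lockout_until = t + stim_duration_s
                cl_count += 1
                acted = True
            rows.append(
                (t, block.condition, frac[i], bool(triggered[i]), warmup[i], acted)
            )
            i += 1
        if block.condition == CL:
            prev_cl_count = cl_count

    decisions = pd.DataFrame(
        rows,
        columns=["t_s", "condition", "positive_fraction", "triggered", "warmup", "acted"],
    )
    stims.sort(key=lambda s: s.t_start_s)
    return decisions, stims


# ---------------------------------------------------------------------------
# Stimulation-time bookkeeping
# ---------------------------------------------------------------------------

CONTINUOUS_REFERENCE_S = 900.0  # 5 ON trials x 180 s in the continuous protocol


@dataclass
class StimulationTimeReport:
    per_condition_s: dict[str, float]
    percent_of_session: float
    percent_reduction_vs_continuous: float


def stimulation_time(
    schedule: TrialSchedule, stim_events: list[StimulationEvent]
) -> StimulationTimeReport:
    """Stimulation seconds per condition and the saving vs continuous ON.

    Continuous ON trials count their full block time as stimulation; CL and
    RANDOM conditions count the summed durations of their discrete events.
    """
    per: dict[str, float] = {}
    for b in schedule.blocks:
        if b.condition == ON_CONT:
            per[ON_CONT] = per.get(ON_CONT, 0.0) + b.duration_s
    for s in stim_events:
        if s.condition != ON_CONT:
            per[s.condition] = per.get(s.condition, 0.0) + s.duration_s
    total = sum(per.values())
    cl_time = per.get(CL, 0.0)
    return StimulationTimeReport(
        per_condition_s=per,
        percent_of_session=100.0 * total / schedule.total_duration_s,
        percent_reduction_vs_continuous=100.0 * (1.0 - cl_time / CONTINUOUS_REFERENCE_S),
    )
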