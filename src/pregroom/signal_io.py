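"""Session containers and on-disk formats.

A recording session is stored as an HDF5 container holding the multi-channel
LFP (``/lfp/data``, channels x samples, with ``rate_hz`` and ``channel_ids``
attributes) plus a sidecar CSV event table (``label,onset_s,offset_s``) that
stays human-editable.  Times are seconds from session start and intervals are
half-open ``[onset, offset)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

GROOMING = "grooming"
#: Controlled behavior vocabulary.  "resting" is the only passive label; the
#: rest count as active motor behaviors for the pre-onset exclusion rule.
BEHAVIOR_LABELS = frozenset(
    {GROOMING, "walking", "rearing", "resting", "scratching", "standing", "other"}
)
ACTIVE_LABELS = frozenset(BEHAVIOR_LABELS - {GROOMING, "resting"})


class FormatError(ValueError):
    """Raised when an on-disk container is structurally invalid."""


@dataclass
class Recording:
    """Multi-channel extracellular signal.

    Parameters
    ----------
    samples
        Array of shape ``(n_channels, n_samples)``; amplitude units are
        arbitrary (the detection pipeline is scale-robust).
    rate_hz
        Sampling frequency in Hz.
    channel_ids
        Ordered channel labels; generated as ``ch00, ch01, ...`` if omitted.
    t0
        Session start time in seconds (default 0).
    """

    samples: np.ndarray
    rate_hz: float
    channel_ids: list[str] | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples))
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x samples) array")
        if not self.rate_hz > 0:
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")
        if self.channel_ids is None:
            self.channel_ids = [f"ch{i:02d}" for i in range(self.samples.shape[0])]
        if len(self.channel_ids) != self.samples.shape[0]:
            raise ValueError("channel_ids length does not match channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz


@dataclass(frozen=True)
class BehaviorEvent:
    label: str
    onset_s: float
    offset_s: float

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class BehaviorAnnotation:
    """Labeled behavior intervals over one session, sorted by onset."""

    events: list[BehaviorEvent]
    session_duration_s: float

    def __post_init__(self) -> None:
        events = [
            e if isinstance(e, BehaviorEvent) else BehaviorEvent(*e) for e in self.events
        ]
        for i, e in enumerate(events):
            if e.label not in BEHAVIOR_LABELS:
                raise ValueError(
                    f"event {i}: unknown label {e.label!r}; "
                    f"expected one of {sorted(BEHAVIOR_LABELS)}"
                )
            if not e.onset_s < e.offset_s:
                raise ValueError(
                    f"event {i} ({e.label!r}): onset {e.onset_s} must be < "
                    f"offset {e.offset_s}"
                )
            if e.onset_s < 0 or e.offset_s > self.session_duration_s + 1e-9:
                raise ValueError(
                    f"event {i} ({e.label!r}): [{e.onset_s}, {e.offset_s}) outside "
                    f"session [0, {self.session_duration_s})"
                )
        self.events = sorted(events, key=lambda e: (e.onset_s, e.offset_s))

    def with_label(self, label: str) -> list[BehaviorEvent]:
        return [e for e in self.events if e.label == label]

    @property
    def grooming_events(self) -> list[BehaviorEvent]:
        return self.with_label(GROOMING)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.label, e.onset_s, e.offset_s) for e in self.events],
            columns=["label", "onset_s", "offset_s"],
        )

    def __len__(self) -> int:
        return len(self.events)


def clean_grooming_events(
    ann: BehaviorAnnotation,
    min_gap_s: float = 1.0,
    min_duration_s: float = 1.0,
) -> BehaviorAnnotation:
    """Apply the grooming-bout scoring rules to an annotation.

    A grooming interruption shorter than ``min_gap_s`` does not end the bout,
    so consecutive grooming events separated by gaps < 1 s are merged first;
    grooming-like phases shorter than ``min_duration_s`` are then discarded.
    Other labels are untouched.  Idempotent.
    """
    grooming = ann.grooming_events
    merged: list[list[float]] = []
    for e in grooming:
        if merged and e.onset_s - merged[-1][1] < min_gap_s:
            merged[-1][1] = max(merged[-1][1], e.offset_s)
        else:
            merged.append([e.onset_s, e.offset_s])
    kept = [
        BehaviorEvent(GROOMING, a, b) for a, b in merged if b - a >= min_duration_s
    ]
    others = [e for e in ann.events if e.label != GROOMING]
    return BehaviorAnnotation(others + kept, ann.session_duration_s)


# ---------------------------------------------------------------------------
# HDF5 recording container
# ---------------------------------------------------------------------------


def write_recording(path: str | Path, rec: Recording, meta: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("/lfp/data", data=rec.samples)
        d.attrs["rate_hz"] = rec.rate_hz
        d.attrs["channel_ids"] = [str(c) for c in rec.channel_ids]
        d.attrs["t0"] = rec.t0
        f.create_group("/meta")
        f["/meta"].attrs["session"] = json.dumps(meta or {})


def read_recording(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        if "/lfp/data" not in f:
            raise FormatError(f"{path}: missing /lfp/data dataset")
        d = f["/lfp/data"]
        if "rate_hz" not in d.attrs:
            raise FormatError(f"{path}: /lfp/data lacks 'rate_hz' attribute")
        if d.ndim != 2:
            raise ValueError(f"{path}: /lfp/data must be 2-D (channels x samples)")
        return Recording(
            samples=d[()],
            rate_hz=float(d.attrs["rate_hz"]),
            channel_ids=[str(c) for c in d.attrs.get("channel_ids", [])] or None,
            t0=float(d.attrs.get("t0", 0.0)),
        )


def read_session_meta(path: str | Path) -> dict:
    with h5py.File(path, "r") as f:
        raw = f["/meta"].attrs.get("session", "{}") if "/meta" in f else "{}"
    return json.loads(raw)


# ---------------------------------------------------------------------------
# CSV event table
# ---------------------------------------------------------------------------


def write_annotation(path: str | Path, ann: BehaviorAnnotation) -> None:
    ann.to_frame().to_csv(path, index=False)


def read_annotation(path: str | Path, session_duration_s: float | None = None) -> BehaviorAnnotation:
    """Read a ``label,onset_s,offset_s`` table; rows are validated and sorted.

    If ``session_duration_s`` is not given it is taken as the largest offset.
    """
    df = pd.read_csv(path)
    required = {"label", "onset_s", "offset_s"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: event table needs columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    bad = df.index[df["onset_s"] >= df["offset_s"]].tolist()
    if bad:
        raise ValueError(f"{path}: onset >= offset in row(s) {bad}")
    duration = (
        session_duration_s
        if session_duration_s is not None
        else (float(df["offset_s"].max()) if len(df) else 0.0)
    )
    events = [
        BehaviorEvent(str(r.label), float(r.onset_s), float(r.offset_s))
        for r in df.itertuples()
    ]
    return BehaviorAnnotation(events, duration)


# ---------------------------------------------------------------------------
# Session configuration
# ---------------------------------------------------------------------------


@dataclass
class FeatureConfig:
    """Parameters of the filterbank feature-reduction stage.

    ``M`` triangular filters between ``f_A_hz`` and ``f_B_hz`` concentrated
    around the principal frequency ``F_hz``; ``P`` successive 1-s analysis
    windows, shifted by ``shift_s``, make up one M x P decision matrix.
    """

    M: int = 7
    P: int = 5
    F_hz: float = 2.5
    f_A_hz: float = 1.0
    f_B_hz: float = 10.0
    log_energies: bool = True
    window_s: float = 1.0
    shift_s: float = 0.2
    grid_df_hz: float = 0.25

    def __post_init__(self) -> None:
        if not (self.f_A_hz < self.F_hz < self.f_B_hz):
            raise ValueError("need f_A_hz < F_hz < f_B_hz")
        if self.M < 1 or self.P < 1:
            raise ValueError("M and P must be >= 1")
        if min(self.window_s, self.shift_s, self.grid_df_hz) <= 0:
            raise ValueError("window_s, shift_s and grid_df_hz must be positive")

    @property
    def n_features(self) -> int:
        return self.M * self.P

    @property
    def warmup_s(self) -> float:
        """History needed before the first decision (1.8 s at defaults)."""
        return self.window_s + (self.P - 1) * self.shift_s


@dataclass
class ClassifierConfig:
    hidden_layer_sizes: tuple[int, int] = (16, 8)
    activation: str = "logistic"
    alpha: float = 1e-4
    max_iter: int = 400
    early_stopping: bool = True
    validation_fraction: float = 0.15
    n_iter_no_change: int = 20
    threshold_fraction: float = 0.5


@dataclass
class ProtocolConfig:
    stim_duration_s: float = 4.0
    pulse_rate_hz: float = 20.0
    pulse_width_s: float = 0.005
    power_mw: float = 10.0
    trial_duration_s: float = 180.0
    n_cycles: int = 4


@dataclass
class SessionConfig:
    """Top-level configuration of a closed-loop session."""

    decision_interval_s: float = 0.2
    window_s: float = 1.0
    n_channels: int = 32
    rate_hz: float = 20000.0
    analysis_rate_hz: float = 125.0
    features: FeatureConfig = field(default_factory=FeatureConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.decision_interval_s > self.window_s:
            raise ValueError("decision_interval_s must be <= window_s")
        if min(self.decision_interval_s, self.window_s, self.rate_hz) <= 0:
            raise ValueError("durations and rates must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        d = dict(d)
        for key, sub in (
            ("features", FeatureConfig),
            ("classifier", ClassifierConfig),
            ("protocol", ProtocolConfig),
        ):
            if key in d and isinstance(d[key], dict):
                sd = dict(d[key])
                if key == "classifier" and "hidden_layer_sizes" in sd:
                    sd["hidden_layer_sizes"] = tuple(sd["hidden_layer_sizes"])
                d[key] = sub(**sd)
        return cls(**d)


def load_config(path: str | Path) -> SessionConfig:
    with open(path) as f:
        return SessionConfig.from_dict(yaml.safe_load(f) or {})


def save_config(path: str | Path, cfg: SessionConfig) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(cfg.to_dict(), f, sort_keys=False)
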