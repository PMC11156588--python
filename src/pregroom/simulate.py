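"""Synthetic behavior and LFP generation.

The generator emulates the statistical structure the detector assumes:
grooming bouts from a gamma-renewal process (~12.9 bouts per 10 min, mean
bout ~4 s), other behaviors tiled by a semi-Markov chain, and multi-channel
LFP made of 1/f background noise plus, before every grooming onset, an
amplitude-ramped narrowband (~2 Hz) stochastic oscillation.  A simple
stimulation-response model lets closed-loop protocols act back on behavior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .signal_io import (
    GROOMING,
    BehaviorAnnotation,
    BehaviorEvent,
    FeatureConfig,
    Recording,
)

_OTHER_MENU_DEFAULT = {
    "walking": 8.0,
    "rearing": 5.0,
    "resting": 20.0,
    "scratching": 6.0,
    "other": 4.0,
}


@dataclass
class BehaviorModel:
    """Grooming/behavior statistics of one session.

    ``bout_duration_lognormal`` is (mu, sigma) in log-seconds; the default
    (1.2606, 0.5) gives a mean bout of ~4 s.  Inter-bout onsets follow a
    shape-2 gamma renewal process (plus a 1-s refractory gap) calibrated so
    the expected bout count matches ``grooming_rate_per_10min``.
    """

    grooming_rate_per_10min: float = 12.9
    bout_duration_lognormal: tuple[float, float] = (1.2606, 0.5)
    other_behavior_menu: dict[str, float] = field(
        default_factory=lambda: dict(_OTHER_MENU_DEFAULT)
    )
    session_duration_s: float = 600.0
    min_gap_s: float = 1.0
    min_bout_s: float = 1.0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.grooming_rate_per_10min < 0:
            raise ValueError("grooming rate must be >= 0")
        if self.session_duration_s <= 0:
            raise ValueError("session duration must be positive")
        if any(v <= 0 for v in self.other_behavior_menu.values()):
            raise ValueError("dwell means must be positive")

    @property
    def mean_bout_s(self) -> float:
        mu, sigma = self.bout_duration_lognormal
        return float(np.exp(mu + sigma**2 / 2))


def _draw_bout_duration(model: BehaviorModel, rng: np.random.Generator) -> float:
    mu, sigma = model.bout_duration_lognormal
    for _ in range(1000):
        d = float(rng.lognormal(mu, sigma))
        if d >= model.min_bout_s:
            return d
    return model.min_bout_s


def simulate_behavior(
    model: BehaviorModel, seed: int | None = None
) -> BehaviorAnnotation:
    """Draw one session's behavior annotation.

    Grooming onsets come from a shape-2 gamma renewal process (avoiding
    unrealistically short inter-bout intervals), bout durations from a
    truncated lognormal, and all remaining time is tiled with non-grooming
    behaviors.  The result passes :func:`~pregroom.signal_io.clean_grooming_events`
    unchanged (all bouts >= 1 s, all gaps >= 1 s).
    """
    rng = np.random.default_rng(model.rng_seed if seed is None else seed)
    T = model.session_duration_s
    bouts: list[tuple[float, float]] = []
    if model.grooming_rate_per_10min > 0:
        mean_cycle = 600.0 / model.grooming_rate_per_10min
        gamma_scale = (mean_cycle - model.mean_bout_s - model.min_gap_s) / 2.0
        if gamma_scale <= 0:
            raise ValueError(
                "grooming rate too high for the configured bout duration"
            )
        if T < model.mean_bout_s:
            warnings.warn(
                "session shorter than one mean grooming bout; annotation may be empty"
            )
        t = float(rng.gamma(2.0, gamma_scale))
        while t < T:
            dur = _draw_bout_duration(model, rng)
            offset = min(t + dur, T)
            if offset - t >= model.min_bout_s:
                bouts.append((t, offset))
            t = offset + model.min_gap_s + float(rng.gamma(2.0, gamma_scale))

    events = [BehaviorEvent(GROOMING, a, b) for a, b in bouts]
    events += _tile_other_behaviors(bouts, T, model, rng)
    return BehaviorAnnotation(events, T)


def _tile_other_behaviors(
    bouts: list[tuple[float, float]],
    T: float,
    model: BehaviorModel,
    rng: np.random.Generator,
) -> list[BehaviorEvent]:
    """Fill non-grooming time with a semi-Markov chain over the label menu."""
    labels = list(model.other_behavior_menu)
    gaps: list[tuple[float, float]] = []
    prev_end = 0.0
    for a, b in bouts:
        if a > prev_end:
            gaps.append((prev_end, a))
        prev_end = b
    if T > prev_end:
        gaps.append((prev_end, T))

    events: list[BehaviorEvent] = []
    prev_label: str | None = None
    for a, b in gaps:
        t = a
        while t < b - 1e-6:
            choices = [l for l in labels if l != prev_label] or labels
            label = str(rng.choice(choices))
            dwell = float(rng.exponential(model.other_behavior_menu[label]))
            end = min(t + max(dwell, 0.05), b)
            events.append(BehaviorEvent(label, t, end))
            prev_label = label
            t = end
    return events


# ---------------------------------------------------------------------------
# LFP synthesis
# ---------------------------------------------------------------------------


@dataclass
class BiomarkerModel:
    """Spectral model of the pre-grooming LFP biomarker.

    Each channel carries 1/f^alpha Gaussian background noise; before every
    grooming onset a narrowband stochastic oscillation centered on
    ``ramp_peak_freq_hz`` ramps up linearly over ``ramp_start_s_before_onset``
    seconds, holds through ``ramp_hold_s`` after onset, then stops.
    ``ramp_amplitude_rel`` is the full-envelope RMS of that component relative
    to the background RMS within the ramp band.  The default 6.0 makes the
    ramp clearly detectable at the single-window level (a 1-s band-power
    estimate has only ~3 spectral degrees of freedom, so an order-of-
    magnitude contrast is needed for per-window discriminability); it yields
    a pre-onset ([-1 s, onset]) to resting band-power ratio of ~12.
    """

    ramp_start_s_before_onset: float = 0.9
    ramp_peak_freq_hz: float = 2.0
    ramp_bandwidth_hz: float = 2.0
    ramp_amplitude_rel: float = 6.0
    ramp_hold_s: float = 0.5
    background_exponent: float = 1.0
    channel_jitter: float = 0.1
    rate_hz: float = 1000.0
    f_floor_hz: float = 0.5
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.ramp_start_s_before_onset <= 0:
            raise ValueError("ramp_start_s_before_onset must be positive")
        if not (0 < self.ramp_peak_freq_hz < self.rate_hz / 2):
            raise ValueError("ramp_peak_freq_hz must lie in (0, rate/2)")


def _colored_noise(
    n: int, rate_hz: float, exponent: float, f_floor_hz: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-variance 1/f^alpha noise plus its (relative) spectral weights."""
    freqs = np.fft.rfftfreq(n, 1.0 / rate_hz)
    shape = np.zeros_like(freqs)
    shape[1:] = np.maximum(freqs[1:], f_floor_hz) ** (-exponent)
    amp = np.sqrt(shape)
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n)
    x /= x.std()
    return x, shape


def _narrowband_noise(
    n: int, rate_hz: float, f0: float, bw: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance stochastic oscillation with a triangular spectral bump."""
    freqs = np.fft.rfftfreq(n, 1.0 / rate_hz)
    weight = np.clip(1.0 - np.abs(freqs - f0) / (bw / 2.0), 0.0, None)
    spec = weight * (
        rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    )
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_lfp(
    ann: BehaviorAnnotation,
    model: BiomarkerModel,
    n_channels: int = 32,
    seed: int | None = None,
    dtype=np.float32,
) -> Recording:
    """Synthesize a multi-channel LFP for one annotated session.

    Channels share the grooming-event timing but carry independent noise
    (background and narrowband) and per-channel amplitude jitter.
    """
    if model.ramp_peak_freq_hz + model.ramp_bandwidth_hz / 2 >= model.rate_hz / 2:
        raise ValueError("ramp band exceeds the Nyquist frequency")
    rng = np.random.default_rng(model.rng_seed if seed is None else seed)
    rate = model.rate_hz
    n = int(round(ann.session_duration_s * rate))

    env = np.zeros(n)
    for e in ann.grooming_events:
        t_on = e.onset_s
        i0 = max(int(round((t_on - model.ramp_start_s_before_onset) * rate)), 0)
        i1 = min(int(round(t_on * rate)), n)
        i2 = min(int(round((t_on + model.ramp_hold_s) * rate)), n)
        if i1 > i0:
            tt = np.arange(i0, i1) / rate
            rise = 1.0 - (t_on - tt) / model.ramp_start_s_before_onset
            env[i0:i1] = np.maximum(env[i0:i1], np.clip(rise, 0.0, 1.0))
        if i2 > i1:
            env[i1:i2] = 1.0

    samples = np.empty((n_channels, n), dtype=dtype)
    band_lo = model.ramp_peak_freq_hz - model.ramp_bandwidth_hz / 2
    band_hi = model.ramp_peak_freq_hz + model.ramp_bandwidth_hz / 2
    for c in range(n_channels):
        bg, shape = _colored_noise(
            n, rate, model.background_exponent, model.f_floor_hz, rng
        )
        freqs = np.fft.rfftfreq(n, 1.0 / rate)
        in_band = (freqs >= band_lo) & (freqs <= band_hi)
        sigma_band = float(np.sqrt(shape[in_band].sum() / shape.sum()))
        amp = model.ramp_amplitude_rel * sigma_band
        amp *= max(1.0 + model.channel_jitter * rng.standard_normal(), 0.1)
        if model.ramp_amplitude_rel > 0 and env.any():
            nb = _narrowband_noise(
                n, rate, model.ramp_peak_freq_hz, model.ramp_bandwidth_hz, rng
            )
            samples[c] = bg + amp * nb * env
        else:
            samples[c] = bg
    return Recording(samples=samples, rate_hz=rate)


# ---------------------------------------------------------------------------
# Stimulation response
# ---------------------------------------------------------------------------


@dataclass
class StimulationResponseModel:
    """Probabilistic effect of stimulation on upcoming grooming bouts.

    A bout whose pre-onset window ``[onset - suppression_window_s, onset]``
    overlaps any stimulation interval is cancelled with probability
    ``p_suppress``.  Non-grooming events are conserved exactly.
    """

    suppression_window_s: float = 2.0
    p_suppress: float = 0.7
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_suppress <= 1:
            raise ValueError("p_suppress must lie in [0, 1]")


def _stim_interval(ev) -> tuple[float, float]:
    if hasattr(ev, "t_start_s"):
        return float(ev.t_start_s), float(ev.t_start_s) + float(ev.duration_s)
    a, d = ev
    return float(a), float(a) + float(d)


def apply_stimulation_effect(
    ann: BehaviorAnnotation,
    stim_events,
    model: StimulationResponseModel,
    seed: int | None = None,
) -> BehaviorAnnotation:
    """Remove grooming bouts whose pre-onset window was covered by stimulation."""
    rng = np.random.default_rng(model.rng_seed if seed is None else seed)
    intervals = [_stim_interval(ev) for ev in stim_events]
    kept: list[BehaviorEvent] = []
    for e in ann.events:
        if e.label == GROOMING:
            lo = e.onset_s - model.suppression_window_s
            covered = any(a < e.onset_s and b > lo for a, b in intervals)
            if covered and rng.random() < model.p_suppress:
                continue
        kept.append(e)
    return BehaviorAnnotation(kept, ann.session_duration_s)


# ---------------------------------------------------------------------------
# Labeled window dataset
# ---------------------------------------------------------------------------


@dataclass
class WindowDataset:
    """Per-decision feature windows with provenance.

    ``X`` has shape ``(n_windows, n_channels, M * P)``; ``y`` holds 1 for
    "pregrooming" and 0 for "other"; ``t_s`` and ``session`` record where
    each window came from.
    """

    X: np.ndarray
    y: np.ndarray
    t_s: np.ndarray
    session: np.ndarray

    def __len__(self) -> int:
        return len(self.y)


def build_labeled_dataset(
    recordings,
    annotations,
    feature_cfg: FeatureConfig | None = None,
    split: tuple[float, float] = (0.7, 0.3),
    seed: int | None = None,
    analysis_rate_hz: float = 125.0,
    min_windows: int = 100,
    neg_pos_ratio: float = 2.0,
) -> tuple[WindowDataset, WindowDataset]:
    """Extract labeled windows and split them 70/30 into train/test.

    "Pregrooming" windows are 1-s analysis windows inside ``[onset - 2 s,
    onset]`` of each grooming event; "other" windows are drawn from annotated
    non-grooming behaviors well clear of any grooming event.  Non-grooming
    windows are drawn at ``neg_pos_ratio`` times the positive count
    (default 2), reflecting the predominance of non-grooming behavior in a
    session and biasing the trained boundary toward conservative (low
    false-positive) stimulation.  Windows are shuffled and split disjointly;
    identical seeds give identical splits.
    """
    from .features import SpectralFeaturizer
    from .spectral import to_analysis_rate

    cfg = feature_cfg or FeatureConfig()
    rng = np.random.default_rng(seed)
    if abs(split[0] + split[1] - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")

    X_parts, y_parts, t_parts, s_parts = [], [], [], []
    for s_idx, (rec, ann) in enumerate(zip(recordings, annotations)):
        rec_a = to_analysis_rate(rec, analysis_rate_hz)
        feat = SpectralFeaturizer(cfg, rec_a.rate_hz)
        dur = rec_a.duration_s
        shift = cfg.shift_s

        pos_ends: list[float] = []
        n_per_event = int(round((2.0 - cfg.window_s) / shift)) + 1
        for e in ann.grooming_events:
            ends = [e.onset_s - k * shift for k in range(n_per_event)]
            pos_ends.extend(t for t in ends if cfg.warmup_s <= t <= dur)
        if not pos_ends:
            raise ValueError("no pregrooming windows available")

        guards = [
            (e.onset_s - 2.0 - shift, e.offset_s + cfg.window_s)
            for e in ann.grooming_events
        ]
        grid = np.arange(cfg.warmup_s, dur + 1e-9, shift)
        span = cfg.warmup_s
        clear = np.ones(len(grid), dtype=bool)
        for a, b in guards:
            clear &= ~((grid > a) & (grid - span < b))
        neg_candidates = grid[clear]
        n_neg = min(int(round(neg_pos_ratio * len(pos_ends))), len(neg_candidates))
        neg_ends = rng.choice(neg_candidates, size=n_neg, replace=False)

        ends = np.concatenate([np.asarray(pos_ends), neg_ends])
        labels = np.concatenate(
            [np.ones(len(pos_ends), dtype=int), np.zeros(n_neg, dtype=int)]
        )
        X_parts.append(feat.matrix_features(rec_a.samples, ends))
        y_parts.append(labels)
        t_parts.append(ends)
        s_parts.append(np.full(len(ends), s_idx))

    X = np.concatenate(X_parts)
    y = np.concatenate(y_parts)
    t_s = np.concatenate(t_parts)
    session = np.concatenate(s_parts)
    if len(y) < min_windows:
        raise ValueError(
            f"only {len(y)} labeled windows available (need >= {min_windows}); "
            "simulate longer or more sessions"
        )
    perm = rng.permutation(len(y))
    n_train = int(round(split[0] * len(y)))
    tr, te = perm[:n_train], perm[n_train:]
    mk = lambda i: WindowDataset(X[i], y[i], t_s[i], session[i])
    return mk(tr), mk(te)
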