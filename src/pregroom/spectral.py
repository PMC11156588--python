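"""Offline spectral characterization of the pre-grooming biomarker.

Covers the decimation/low-pass preprocessing, single-window power spectral
densities, event-anchored Morse-wavelet spectrograms, the rising-point
detector for the 1.5-4 Hz band-power curve, and the paired pregrooming vs
resting band-power contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
import scipy.fft
import scipy.signal

from .signal_io import ACTIVE_LABELS, BehaviorAnnotation, Recording


@dataclass
class SpectralEstimate:
    """One-sided power spectral density of a single analysis window."""

    freqs_hz: np.ndarray
    power: np.ndarray
    t_start_s: float | None = None
    duration_s: float | None = None
    channel: str | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("frequency grid must be strictly ascending")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")

    def band_power(self, band: tuple[float, float]) -> float:
        lo, hi = band
        m = (self.freqs_hz >= lo) & (self.freqs_hz <= hi)
        df = self.freqs_hz[1] - self.freqs_hz[0]
        return float(self.power[m].sum() * df)


@dataclass
class Spectrogram:
    """Event-averaged wavelet power; ``times_s`` are relative to event onset."""

    times_s: np.ndarray
    freqs_hz: np.ndarray
    power: np.ndarray  # (n_freqs, n_times)
    gamma: float
    time_bandwidth: float
    n_events: int = 1

    def __post_init__(self) -> None:
        if self.power.shape != (len(self.freqs_hz), len(self.times_s)):
            raise ValueError("power shape must be (n_freqs, n_times)")

    def band_curve(self, band: tuple[float, float] = (1.5, 4.0)) -> np.ndarray:
        m = (self.freqs_hz >= band[0]) & (self.freqs_hz <= band[1])
        return self.power[m].mean(axis=0)


@dataclass
class RampSummary:
    """Rising point and peak frequency of the pre-onset power ramp.

    ``rising_point_s`` is relative to onset (expected negative); ``None``
    means no ramp was detectable (flat curve).
    """

    rising_point_s: float | None
    freq_at_max_power_hz: float | None
    band: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.band[0] < self.band[1]:
            raise ValueError("band low must be < band high")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def preprocess_lowfreq(
    rec: Recording,
    factor: int = 40,
    cutoff_hz: float = 10.0,
    order: int = 10,
) -> Recording:
    """Decimate by ``factor`` then low-pass with a zero-phase Butterworth.

    With the 20-kHz acquisition default the output rate is 500 Hz; the
    anti-aliased decimation uses a polyphase FIR and the Butterworth
    (order ``order``, cutoff ``cutoff_hz``) is applied forward-backward.
    """
    new_rate = rec.rate_hz / factor
    if cutoff_hz >= new_rate / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz >= Nyquist {new_rate / 2} Hz after decimation"
        )
    x = scipy.signal.resample_poly(np.asarray(rec.samples, dtype=float), 1, factor, axis=1)
    sos = scipy.signal.butter(order, cutoff_hz, fs=new_rate, output="sos")
    x = scipy.signal.sosfiltfilt(sos, x, axis=1)
    return Recording(samples=x, rate_hz=new_rate, channel_ids=list(rec.channel_ids), t0=rec.t0)


def to_analysis_rate(rec: Recording, analysis_rate_hz: float = 125.0) -> Recording:
    """Resample a recording to the (lower) online analysis rate."""
    if abs(rec.rate_hz - analysis_rate_hz) < 1e-9:
        return rec
    if analysis_rate_hz > rec.rate_hz:
        raise ValueError("analysis rate must not exceed the recording rate")
    frac = Fraction(analysis_rate_hz / rec.rate_hz).limit_denominator(10000)
    x = scipy.signal.resample_poly(
        np.asarray(rec.samples, dtype=float), frac.numerator, frac.denominator, axis=1
    )
    return Recording(samples=x, rate_hz=analysis_rate_hz, channel_ids=list(rec.channel_ids), t0=rec.t0)


# ---------------------------------------------------------------------------
# Power spectral density
# ---------------------------------------------------------------------------


def compute_psd(
    x: np.ndarray,
    rate_hz: float,
    grid_df_hz: float = 0.25,
    window: str = "hann",
    **meta,
) -> SpectralEstimate:
    """Hann-tapered, zero-padded periodogram of one analysis window.

    Zero-padding brings the grid to at least ``grid_df_hz`` resolution (the
    1-4 Hz filterbank needs a fine grid, and single 1-s windows preclude
    Welch averaging).  The mean is removed before tapering.
    """
    x = np.asarray(x, dtype=float)
    nfft = max(len(x), int(round(rate_hz / grid_df_hz)))
    freqs, p = scipy.signal.periodogram(
        x, fs=rate_hz, window=window, nfft=nfft, detrend="constant", scaling="density"
    )
    return SpectralEstimate(freqs_hz=freqs, power=p, **meta)


# ---------------------------------------------------------------------------
# Generalized Morse wavelet transform
# ---------------------------------------------------------------------------


def morse_cwt(
    x: np.ndarray,
    rate_hz: float,
    freqs_hz: np.ndarray,
    gamma: float = 3.0,
    beta: float = 20.0,
) -> np.ndarray:
    """Continuous wavelet transform with a generalized Morse wavelet.

    The wavelet is defined in the frequency domain as
    ``Psi(w) ~ w^beta * exp(-w^gamma)`` for ``w > 0`` (analytic), peak-
    normalized, with asymmetry ``gamma`` and time-bandwidth product
    ``gamma * beta`` (defaults gamma=3, beta=20, i.e. product 60).  Returns
    complex coefficients of shape ``(len(freqs_hz), len(x))``.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    nfft = scipy.fft.next_fast_len(n)
    X = scipy.fft.fft(x - x.mean(), nfft)
    omega = 2 * np.pi * np.fft.fftfreq(nfft)  # rad/sample
    w_peak = (beta / gamma) ** (1.0 / gamma)
    log_peak = beta * np.log(w_peak) - w_peak**gamma

    out = np.empty((len(freqs_hz), n), dtype=complex)
    pos = omega > 0
    for i, f in enumerate(np.asarray(freqs_hz, dtype=float)):
        scale = w_peak / (2 * np.pi * f / rate_hz)
        sw = scale * omega[pos]
        psi = np.zeros(nfft)
        psi[pos] = 2.0 * np.exp(beta * np.log(sw) - sw**gamma - log_peak)
        out[i] = scipy.fft.ifft(X * psi)[:n]
    return out


def default_wavelet_freqs(
    f_min: float = 0.5, f_max: float = 20.0, voices_per_octave: int = 16
) -> np.ndarray:
    n = int(np.ceil(np.log2(f_max / f_min) * voices_per_octave)) + 1
    return f_min * 2 ** (np.arange(n) / voices_per_octave)


def event_spectrogram(
    rec: Recording,
    ann: BehaviorAnnotation,
    span: tuple[float, float] = (-4.0, 4.0),
    freqs_hz: np.ndarray | None = None,
    gamma: float = 3.0,
    beta: float = 20.0,
    channels: list[int] | None = None,
) -> Spectrogram:
    """Average wavelet power around grooming onsets.

    The CWT is computed once per channel over the whole (preprocessed)
    recording and sliced per event; events too close to the session edge are
    skipped with a warning.
    """
    freqs = default_wavelet_freqs() if freqs_hz is None else np.asarray(freqs_hz)
    rate = rec.rate_hz
    i_lo = int(round(span[0] * rate))
    i_hi = int(round(span[1] * rate))
    n_t = i_hi - i_lo
    chans = list(range(rec.n_channels)) if channels is None else channels

    onsets = []
    for e in ann.grooming_events:
        i_on = int(round(e.onset_s * rate))
        if i_on + i_lo < 0 or i_on + i_hi > rec.n_samples:
            warnings.warn(f"grooming event at {e.onset_s:.2f}s too close to edge; skipped")
            continue
        onsets.append(i_on)
    if not onsets:
        raise ValueError("no grooming event lies fully within the analysis span")

    acc = np.zeros((len(freqs), n_t))
    for c in chans:
        power = np.abs(morse_cwt(rec.samples[c], rate, freqs, gamma, beta)) ** 2
        for i_on in onsets:
            acc += power[:, i_on + i_lo : i_on + i_hi]
    acc /= len(onsets) * len(chans)
    times = np.arange(i_lo, i_hi) / rate
    return Spectrogram(
        times_s=times,
        freqs_hz=freqs,
        power=acc,
        gamma=gamma,
        time_bandwidth=gamma * beta,
        n_events=len(onsets),
    )


# ---------------------------------------------------------------------------
# Rising point
# ---------------------------------------------------------------------------


def detect_rising_point(
    times_s: np.ndarray,
    curve: np.ndarray,
    baseline_span: tuple[float, float] = (-4.0, -2.0),
    threshold_frac: float = 0.2,
    band: tuple[float, float] = (1.5, 4.0),
) -> RampSummary:
    """Find where the band-power curve begins its sustained pre-onset rise.

    The rising point is the earliest time ``t*`` in ``[baseline end, 0]`` at
    which the curve exceeds ``baseline + threshold_frac * (peak - baseline)``
    and remains above through onset (t = 0); the baseline is the curve mean
    over ``baseline_span``.  A flat curve (peak <= baseline) yields the
    "no ramp" sentinel (``rising_point_s=None``).
    """
    times_s = np.asarray(times_s, dtype=float)
    curve = np.asarray(curve, dtype=float)
    base_m = (times_s >= baseline_span[0]) & (times_s < baseline_span[1])
    if not base_m.any():
        raise ValueError("curve does not cover the baseline span")
    baseline = curve[base_m].mean()
    peak = curve.max()
    if peak <= baseline or not np.isfinite(peak - baseline) or peak == baseline:
        return RampSummary(None, None, band)
    thr = baseline + threshold_frac * (peak - baseline)

    i0 = int(np.searchsorted(times_s, 0.0))
    i0 = min(i0, len(times_s) - 1)
    if curve[i0] < thr:
        return RampSummary(None, None, band)
    i = i0
    lo_lim = baseline_span[0]
    while i > 0 and curve[i - 1] >= thr and times_s[i - 1] >= lo_lim:
        i -= 1
    return RampSummary(float(times_s[i]), None, band)


def ramp_summary(
    spg: Spectrogram,
    band: tuple[float, float] = (1.5, 4.0),
    **kwargs,
) -> RampSummary:
    """Rising point of the band-power curve plus the spectrogram peak frequency."""
    curve = spg.band_curve(band)
    rp = detect_rising_point(spg.times_s, curve, band=band, **kwargs)
    i_f, _ = np.unravel_index(int(np.argmax(spg.power)), spg.power.shape)
    return replace(rp, freq_at_max_power_hz=float(spg.freqs_hz[i_f]))


# ---------------------------------------------------------------------------
# Band-power contrast
# ---------------------------------------------------------------------------


@dataclass
class PairedBandPower:
    pregrooming: np.ndarray
    resting: np.ndarray
    band: tuple[float, float]

    @property
    def median_difference(self) -> float:
        return float(np.median(self.pregrooming - self.resting))


def band_power_contrast(
    rec: Recording,
    ann: BehaviorAnnotation,
    band: tuple[float, float] = (1.5, 3.0),
    pre_window_s: float = 1.0,
    n_events: int = 15,
    exclusion_s: float = 3.0,
    seed: int | None = None,
) -> PairedBandPower:
    """Paired pregrooming ([-1 s, onset]) vs resting band powers.

    Pregrooming epochs are restricted to grooming events with no annotated
    active behavior in the ``exclusion_s`` seconds before onset (movement
    confounders); resting epochs are 1-s windows inside "resting" intervals
    well clear of any grooming event.  Band power is averaged over channels.
    """
    rng = np.random.default_rng(seed)
    active = [
        (e.onset_s, e.offset_s) for e in ann.events if e.label in ACTIVE_LABELS
    ]
    groom = ann.grooming_events

    pre_windows = []
    for e in groom:
        a, b = e.onset_s - exclusion_s, e.onset_s
        if any(x < b and y > a for x, y in active):
            continue
        if e.onset_s - pre_window_s >= 0:
            pre_windows.append((e.onset_s - pre_window_s, e.onset_s))

    guard = [(e.onset_s - exclusion_s, e.offset_s + 1.0) for e in groom]
    rest_windows = []
    for e in ann.with_label("resting"):
        t = e.onset_s
        while t + pre_window_s <= e.offset_s:
            w = (t, t + pre_window_s)
            if not any(x < w[1] and y > w[0] for x, y in guard):
                rest_windows.append(w)
            t += pre_window_s

    if len(pre_windows) < n_events or len(rest_windows) < n_events:
        raise ValueError(
            f"need {n_events} clean epochs per condition, found "
            f"{len(pre_windows)} pregrooming and {len(rest_windows)} resting"
        )
    pre_windows = [pre_windows[i] for i in rng.choice(len(pre_windows), n_events, replace=False)]
    rest_windows = [rest_windows[i] for i in rng.choice(len(rest_windows), n_events, replace=False)]

    def _bp(win: tuple[float, float]) -> float:
        i0, i1 = (int(round(t * rec.rate_hz)) for t in win)
        vals = [
            compute_psd(rec.samples[c, i0:i1], rec.rate_hz).band_power(band)
            for c in range(rec.n_channels)
        ]
        return float(np.mean(vals))

    return PairedBandPower(
        pregrooming=np.array([_bp(w) for w in pre_windows]),
        resting=np.array([_bp(w) for w in rest_windows]),
        band=band,
    )
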