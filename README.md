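# pregroom

Closed-loop detection of grooming-onset LFP biomarkers: triangular-filterbank
feature reduction, per-electrode neural networks with majority voting,
on-demand stimulation protocol simulation, and event-anchored evaluation.

## The problem

Compulsive-like self-grooming in the Sapap3-knockout mouse model is preceded
by a predictive electrophysiological signature: a delta-band (1–4 Hz) power
ramp in lateral orbitofrontal cortex LFPs that begins roughly one second
before grooming onset and peaks near 2 Hz. A closed-loop system that detects
this ramp in real time can trigger brief optogenetic stimulation of striatal
parvalbumin interneurons *before* the bout starts, suppressing grooming with
a fraction of the light delivered by continuous stimulation. This package
re-implements that detection and control pipeline as a tested library + CLI
for computational neuroscientists working on adaptive neuromodulation, and
pairs it with a synthetic LFP/behavior generator so the entire loop can be
exercised, validated and benchmarked without animal data.

## The method

Every 200 ms, for each of *N* electrodes, the most recent 1-s window `x` is
reduced to a handful of coefficients:

1. **PSD** — Hann-tapered, zero-padded periodogram `P(f)` on a 0.25-Hz grid;
2. **Filterbank** — `M = 7` triangular filters `w_m(f)` on `[f_A, f_B] =
   [1, 10]` Hz, concentrated around the principal frequency `F = 2.5` Hz:
   `e_m = log( Σ_f w_m(f) P(f) + ε )`;
3. **Decorrelation** — orthonormal DCT-II across filters,
   `c = DCT(e)` (cepstral-style);
4. **Feature matrix** — the `P = 5` most recent windows (200-ms shift) form
   an `M × P = 35`-feature matrix per electrode, a ≥ 99.99% reduction of the
   raw 1-s, 32-channel, 20-kHz input;
5. **Classification** — one minimal feedforward network per electrode
   (35 → 16 → 8 → 2, logistic activations, z-scored inputs) labels the
   matrix "pregrooming" or "other";
6. **Voting** — stimulation (4 s of 5-ms pulses at 20 Hz; 10% duty cycle)
   fires only when a strict majority (> 50%) of electrodes votes
   "pregrooming", after which the decision grid pauses for the 4-s train.

Sessions are scored against per-event **early-detection periods**
`Ep = [onset − 2 s, onset + duration/2]`: positive 200-ms bins inside an Ep
are true positives, negative ones false negatives, bins in a grooming event
past its Ep are excluded, and everything else is a true negative / false
positive. `accuracy = (TP+TN)/(TP+TN+FP+FN)`, `sensitivity = TP/(TP+FN)`,
`precision = TP/(TP+FP)`, `specificity = TN/(TN+FP)`; a uniform pseudorandom
classifier at the same cadence scores ≈ 50% on sensitivity, specificity and
accuracy under this scheme, which is the chance reference.

The offline characterization side reproduces the biomarker analyses:
decimate + zero-phase Butterworth low-pass preprocessing, generalized Morse
wavelet spectrograms (γ = 3, time-bandwidth 60), pregrooming-vs-resting
band-power contrasts, and a sustained-crossing rising-point detector for the
1.5–4 Hz band curve. See `docs/methods.md` for models, parameters, and
numerical choices.

## Worked example

Train a detector on synthetic sessions and score a held-out session:

```python
from pregroom.experiments import train_grooming_detector, score_heldout_sessions

detector, window_set = train_grooming_detector(
    seed=0, n_sessions=2, session_duration_s=900, n_channels=8
)
print(f"held-out window accuracy: "
      f"{100 * (detector.predict(window_set.X) == window_set.y).mean():.1f}%")

(score,) = score_heldout_sessions(detector, seed=1, n_sessions=1, n_channels=8)
m = score.metric_report
print(f"bin-level: accuracy {m.accuracy:.1f}%  sensitivity {m.sensitivity:.1f}%  "
      f"precision {m.precision:.1f}%  specificity {m.specificity:.1f}%")
print(f"missed events: {score.missed_events}/{score.n_events}")
```

```
held-out window accuracy: 70.2%
bin-level: accuracy 88.5%  sensitivity 23.9%  precision 29.4%  specificity 94.6%
missed events: 0/12
```

Every grooming bout is caught (0 missed events — each event has triggers
inside its early-detection period). This quick example uses only 8
electrodes to stay fast; the full 32-electrode vote (the validation
configuration in `tests/test_acceptance.py`) pushes specificity above 99%
and precision above 90%. Bin-level sensitivity is structurally modest
under the early-detection-period convention: Ep bins earlier than ~1 s
before onset predate the biomarker itself, so no detector can label them
positive from the signal (see `docs/methods.md`).

The same flow is available from the shell:

```bash
pregroom simulate --duration 600 --channels 32 --seed 1 \
    --out-recording session.h5 --out-events events.csv
pregroom spectral --recording session.h5 --events events.csv --out biomarker.json
pregroom train --recording session.h5 --events events.csv --seed 7 --out model.h5
pregroom run --recording session.h5 --model model.h5 --protocol closed_loop \
    --seed 3 --out-prefix session
pregroom evaluate --decisions session_decisions.csv --stims session_stims.csv \
    --events events.csv --out report.json
```

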