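# Methods

`pregroom` implements a complete closed-loop neuromodulation pipeline for
predicting the onset of compulsive-like self-grooming from orbitofrontal
local field potentials (LFPs), together with a synthetic data generator
that lets every stage be exercised and validated without animal recordings.
This note documents the models, the parameters that matter, the numerical
choices, and what the synthetic validation does and does not establish.

## The detection pipeline

**Biomarker.** Grooming onsets in the Sapap3-knockout mouse model are
preceded by a low-frequency (delta, 1–4 Hz) LFP power ramp in the lateral
orbitofrontal cortex: band power begins rising roughly 1 s before the first
front-limb movement and peaks near 2 Hz around onset. The pipeline turns
this into a real-time trigger.

**Feature reduction.** Every 200 ms, each electrode's most recent 1-s
window is converted to a Hann-tapered, zero-padded periodogram (0.25-Hz
grid). A bank of `M = 7` triangular filters spanning `f_A = 1` Hz to
`f_B = 10` Hz summarizes the spectrum; filter centers are placed uniformly
in a symmetric logarithmic warp around the principal frequency
`F = 2.5` Hz, so spectral resolution is finest at the biomarker band and
decays gradually toward the band edges. Adjacent triangles cross at 50%
height and each is peak-normalized. Filter energies are log-compressed and
decorrelated with an orthonormal type-II cosine transform (the standard
cepstral construction; log compression makes all coefficients but the first
invariant to the absolute amplitude scale, which is arbitrary in chronic
recordings). The `P = 5` most recent windows (200-ms shift, 1.8 s of
history) form an `M × P = 35`-coefficient matrix per electrode —
a ≥ 99.99% reduction of the nominal 1-s, 32-channel, 20-kHz input.

Open choices resolved here: energies are log-transformed and filters
peak-normalized (both exposed as configuration); the P iterations are the
five most recent sliding windows rather than five subsegments of one
window, matching the 2-s pregrooming labeling span.

**Classification and voting.** Each electrode has its own small feedforward
network (35 inputs, hidden layers 16 and 8, logistic activations, two-class
output) trained on per-feature z-scored inputs. Networks are trained with
L-BFGS and L2 regularization (`alpha = 0.01`); for networks this small,
full-batch quasi-Newton optimization is both faster and more reliable than
stochastic gradient variants, which we found collapse to constant
predictions on few-hundred-window training sets, and it makes training
bit-reproducible given the seed. sklearn parameterizes the two-class output
as a single sigmoid unit — the exact reparameterization of a two-neuron
softmax; both class scores are exposed and sum to 1. Stimulation is
triggered only when a strict majority (> 50%) of electrodes predicts
"pregrooming"; all ties (a 0.5/0.5 score or an exact 50% vote) resolve to
the negative outcome, the conservative choice for a stimulation policy.

**Closed loop.** Decisions fall on a 200-ms grid (one per tick; ticks whose
1.8-s feature history is incomplete are logged as forced-negative "warmup"
decisions, so a 12 × 3-min session always yields exactly 10,800 decisions
when nothing triggers). In CL trials a trigger emits a 4-s stimulation
(5-ms pulses at 20 Hz, 10 mW — a 10% duty cycle) during which no further
decisions are made; the tick grid resumes 4 s later, so a block with *n*
stimulations contains `(180 − 4n)/0.2` decisions. Randomized ("yoked")
trials receive the number of stimulations of the immediately preceding CL
trial at uniformly random non-overlapping times (drawn exactly, by placing
the events' slack uniformly). OFF and randomized trials still log
decisions for offline audit, but only CL triggers stimulate. Feature
history crosses block boundaries, since the recording is continuous.

**Online analysis rate.** The feature stage runs on a stream decimated to
125 Hz (anti-aliased polyphase resampling). The filterbank tops out near
13 Hz, so nothing the classifier sees is affected, and the decimation is
what makes 10,800-decision sessions cheap to simulate; the reduction-ratio
bookkeeping is still computed against the nominal 32 × 20 kHz input.

## Offline spectral characterization

`preprocess_lowfreq` mirrors the offline analysis chain: decimation by 40
(20 kHz → 500 Hz) followed by a zero-phase 10th-order Butterworth low-pass
at 10 Hz. Event-anchored spectrograms use a generalized Morse wavelet
(asymmetry γ = 3, time-bandwidth product 60, i.e. β = 20), implemented in
the frequency domain on a logarithmic grid of 16 voices/octave over
0.5–20 Hz; analysis is performed after mean removal, making power invariant
to constant offsets.

The **rising point** of the 1.5–4 Hz band-power curve is defined here
(no published algorithm exists for it) as the earliest time in [−4, 0] s at
which the curve exceeds `baseline + 20% × (peak − baseline)` and stays
above through onset, with the baseline taken over [−4, −2] s. A flat curve
returns an explicit "no ramp" sentinel. The 20% sustained-crossing rule is
validated by parameter recovery: on 200 synthetic events with a ramp
starting 1.0 s before onset, the detector recovers the start with a mean
absolute error of ~0.21 s and the peak-frequency estimate has its median
within 1.7–3.7 Hz of the generator's 2 Hz. Both threshold and baseline
span are configurable. The "no preceding motor behaviors" exclusion used
by the pregrooming/resting band-power contrast is operationalized as
"no annotated active behavior within 3 s before onset".

## The synthetic generator

**Behavior.** Grooming onsets follow a shape-2 gamma renewal process with a
1-s refractory gap, calibrated so the expected count is 12.9 bouts per
10 min; bout durations are lognormal (`μ = 1.2606`, `σ = 0.5` log-s, mean
≈ 4 s, truncated at the 1-s scoring minimum). This also reproduces
≈ 50 s of early-detection-period time per 10-min session. The remaining
time is tiled by a semi-Markov chain over walking / rearing / resting /
scratching / other with exponential dwells (means 8/5/20/6/4 s) and no
immediate self-transitions. Generated annotations pass the bout-cleaning
rules (merge < 1-s interruptions, drop < 1-s bouts) unchanged.

**LFP.** Each channel is unit-variance 1/f Gaussian background noise
(spectrum flattened below 0.5 Hz), synthesized by spectral shaping.
Before each onset, a narrowband stochastic oscillation (triangular spectral
bump centered at 2 Hz, 2 Hz wide) is added with a linear amplitude envelope
rising from zero at `onset − 0.9 s` (the empirically observed mean rising
point) to full amplitude at onset, held until `onset + 0.5 s` (the power
peak sits near/after onset). Channels share event timing but have
independent noise realizations and ~10% amplitude jitter.

`ramp_amplitude_rel` — the full-envelope RMS of the narrowband component
relative to the background RMS in its band — defaults to **6.0**. A 1-s
band-power estimate over a ~2-Hz band carries only ≈ 3 spectral degrees of
freedom (log-domain standard deviation ≈ 1), so an order-of-magnitude
power contrast (ratio ≈ 1 + 0.3 · rel² ≈ 12 over the final pre-onset
second) is what "clearly detectable at the single-decision level" requires;
weaker settings leave individual windows statistically indistinguishable
regardless of classifier. The generator is therefore a *high-SNR testbed
for the machinery*, not a model of the real effect size (the published
pregrooming/resting contrast is far smaller and is only detectable after
averaging over events and channels).

**Stimulation response.** The generator closes the loop with a
deliberately simple model (the underlying biology provides none): a bout
whose pre-onset window `[onset − 2 s, onset]` overlaps a stimulation
interval is cancelled with probability `p_suppress = 0.7`; non-grooming
events are conserved exactly.

**Labeled datasets.** "Pregrooming" windows are the six 1-s windows ending
on the 200-ms grid within `[onset − 2 s, onset]`; "other" windows are grid
windows whose full 1.8-s feature span avoids all grooming events (with
guard margins). Negatives are drawn at twice the positive count: most of a
session is non-grooming, and the higher negative prior places the decision
boundary conservatively — important because positives are label-diluted
(windows ending ≳ 1 s before onset precede the biomarker entirely).
Windows are shuffled and split 70/30 into disjoint train/test sets with
full provenance.

## What the synthetic validation shows — and does not

The end-to-end runs demonstrate that the pipeline detects essentially every
grooming bout (0 missed events across held-out sessions: every event has
triggers inside its early-detection period), with specificity and accuracy
in the mid-90s and high precision. Bin-level sensitivity, however, sits
near 30–45%, far below the published ~89%: under the bin-level
false-negative convention, every 200-ms bin of the early-detection period
counts separately, and the bins from −2 s to about −1 s *precede the
biomarker itself* (the ramp starts ~0.9 s before onset), making them
undetectable in principle; bins later than ~2.3 s after onset likewise
outlive the ramp plus the feature history. The published definition counts
false negatives at the *event* level ("missed grooming events"), under
which the pipeline here scores ~100%; the bin-level convention is
nevertheless used for the headline metrics because it is the only one under
which the pseudorandom baseline lands at the published ~50% sensitivity.
Both numbers are reported.

Features of real data the generator does not emulate: movement and
chewing artifacts, cross-channel correlated noise, non-stationary
background spectra, behavior-specific oscillations, electrode drift, and
any LFP consequence of the stimulation itself. Passing these tests
validates the algorithmic machinery and its bookkeeping, not in-vivo
performance.

## Scaled study designs used in validation

All sizes were chosen to keep the full validation within desk-scale compute
(single CPU, minutes):

- **Pseudorandom baseline:** 20 simulated 10-min sessions, Bernoulli(0.5)
  decisions at 200-ms bins, 5 runs averaged per session.
- **End-to-end detector:** trained on three 20-min, 32-channel sessions
  (≈ 1,100 labeled windows) at the generator's native 1 kHz; scored on two
  held-out 10-min sessions.
- **Parameter recovery:** 200 regularly spaced events, one channel.
- **Stimulation-policy cohorts:** per seed, one full experiment of
  5 subjects × 3 days of the 36-min OFF/CL/randomized protocol
  (15 sessions), with 16-channel sessions generated directly at the 125-Hz
  analysis rate; 10 seeds. Strict ordering of integer bout counts across
  three conditions is noisy at the single-session level, so the ordering
  is evaluated at the cohort level, mirroring the published group-level
  ordered-alternatives analysis.

## Known limitations

- The rising-point rule and the stimulation-response model are this
  package's operationalizations; both are configurable and should be
  re-examined against real data.
- The per-electrode networks are deliberately minimal; no architecture
  search was performed, and hidden sizes are configuration, not findings.
- Undefined metric ratios (zero denominators) are reported as missing
  values, never as 0 or 100; averages skip them.
- Real-time latency, hardware I/O and vendor acquisition formats are out
  of scope; the HDF5/CSV session container is the interchange format.
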