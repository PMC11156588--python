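"""Synthetic behavior/LFP generator: calibration, invariants, dataset split."""

import numpy as np
import pytest

from pregroom.signal_io import BehaviorAnnotation, BehaviorEvent, clean_grooming_events
from pregroom.simulate import (
    BehaviorModel,
    BiomarkerModel,
    StimulationResponseModel,
    apply_stimulation_effect,
    build_labeled_dataset,
    simulate_behavior,
    simulate_lfp,
)
from pregroom.spectral import compute_psd


class TestSimulateBehavior:
    def test_zero_rate_gives_no_grooming(self):
        ann = simulate_behavior(BehaviorModel(grooming_rate_per_10min=0.0), seed=0)
        assert ann.grooming_events == []
        assert len(ann.events) > 0  # other behaviors still tile the session

    def test_bout_rate_calibration(self):
        """Monte-Carlo mean bout count within 5% of the configured 12.9/10 min."""
        model = BehaviorModel()
        counts = [
            len(simulate_behavior(model, seed=s).grooming_events) for s in range(1000)
        ]
        assert abs(np.mean(counts) - 12.9) / 12.9 < 0.05

    def test_passes_cleaning_unchanged(self):
        for s in range(20):
            ann = simulate_behavior(BehaviorModel(), seed=s)
            assert clean_grooming_events(ann).grooming_events == ann.grooming_events
            for e in ann.grooming_events:
                assert e.duration_s >= 1.0

    def test_same_seed_reproducible(self):
        a = simulate_behavior(BehaviorModel(), seed=3)
        b = simulate_behavior(BehaviorModel(), seed=3)
        assert a.events == b.events

    def test_short_session_warns(self):
        with pytest.warns(UserWarning, match="shorter"):
            simulate_behavior(BehaviorModel(session_duration_s=2.0), seed=0)


class TestSimulateLfp:
    def test_duration_and_shape(self, short_annotation):
        rec = simulate_lfp(
            short_annotation, BiomarkerModel(rate_hz=250.0), n_channels=3, seed=0
        )
        assert rec.samples.shape == (3, int(250 * short_annotation.session_duration_s))
        assert rec.duration_s == short_annotation.session_duration_s

    def test_nyquist_violation_rejected(self, short_annotation):
        with pytest.raises(ValueError, match="[Nn]yquist"):
            simulate_lfp(
                short_annotation, BiomarkerModel(rate_hz=5.0), n_channels=1, seed=0
            )

    def test_zero_amplitude_band_ratio_near_one(self, event_train_annotation):
        """With no injected ramp, pregrooming and resting band powers agree."""
        model = BiomarkerModel(ramp_amplitude_rel=0.0, rate_hz=250.0)
        ratios = []
        for s in range(4):
            rec = simulate_lfp(event_train_annotation, model, n_channels=2, seed=s)
            pre, rest = _paired_band_powers(rec, event_train_annotation)
            ratios.append(np.median(pre) / np.median(rest))
        assert abs(np.mean(ratios) - 1.0) < 0.15

    def test_strong_ramp_dominates_resting(self, event_train_annotation):
        """Pre-onset 1.5-3 Hz power exceeds resting power in >95% of events."""
        model = BiomarkerModel(rate_hz=250.0)  # clearly-detectable default
        exceed, n = 0, 0
        for s in range(2):
            rec = simulate_lfp(event_train_annotation, model, n_channels=4, seed=s)
            pre, rest = _paired_band_powers(rec, event_train_annotation)
            exceed += int(np.sum(pre > rest))
            n += len(pre)
        assert n >= 100
        assert exceed / n > 0.95

    def test_same_seed_bitwise_identical(self, short_annotation):
        m = BiomarkerModel(rate_hz=250.0)
        a = simulate_lfp(short_annotation, m, n_channels=2, seed=5)
        b = simulate_lfp(short_annotation, m, n_channels=2, seed=5)
        np.testing.assert_array_equal(a.samples, b.samples)


def _paired_band_powers(rec, ann, band=(1.5, 3.0)):
    """Per-event channel-averaged band power: [-1 s, onset] vs a matched
    resting window 7 s earlier (events are spaced widely in the fixture)."""
    rate = rec.rate_hz
    pre, rest = [], []
    for e in ann.grooming_events:
        for out, t0 in ((pre, e.onset_s - 1.0), (rest, e.onset_s - 8.0)):
            i0 = int(round(t0 * rate))
            vals = [
                compute_psd(rec.samples[c, i0 : i0 + int(rate)], rate).band_power(band)
                for c in range(rec.n_channels)
            ]
            out.append(np.mean(vals))
    return np.array(pre), np.array(rest)


class TestStimulationEffect:
    def _groom_ann(self, n=40, spacing=15.0):
        events = [
            BehaviorEvent("grooming", 10 + i * spacing, 13 + i * spacing)
            for i in range(n)
        ]
        return BehaviorAnnotation(events, 10 + n * spacing + 5)

    def test_zero_probability_is_identity(self):
        ann = self._groom_ann()
        stims = [(e.onset_s - 1.0, 4.0) for e in ann.grooming_events]
        out = apply_stimulation_effect(
            ann, stims, StimulationResponseModel(p_suppress=0.0), seed=0
        )
        assert out.events == ann.events

    def test_full_coverage_full_probability_removes_all(self):
        ann = self._groom_ann()
        stims = [(e.onset_s - 1.0, 4.0) for e in ann.grooming_events]
        out = apply_stimulation_effect(
            ann, stims, StimulationResponseModel(p_suppress=1.0), seed=0
        )
        assert out.grooming_events == []

    def test_binomial_survival_rate(self):
        """p_suppress = 0.6 over many covered bouts: ~40% survive."""
        ann = self._groom_ann(n=50)
        stims = [(e.onset_s - 1.0, 4.0) for e in ann.grooming_events]
        model = StimulationResponseModel(p_suppress=0.6)
        survived = sum(
            len(apply_stimulation_effect(ann, stims, model, seed=s).grooming_events)
            for s in range(20)
        )
        n_total = 50 * 20
        se = np.sqrt(n_total * 0.6 * 0.4)
        assert abs(survived - 0.4 * n_total) < 4 * se

    def test_uncovered_bouts_and_other_events_conserved(self):
        ann = simulate_behavior(BehaviorModel(), seed=11)
        stims = [(5.0, 4.0)]
        out = apply_stimulation_effect(
            ann, stims, StimulationResponseModel(p_suppress=1.0), seed=0
        )
        others = lambda a: [e for e in a.events if e.label != "grooming"]
        assert others(out) == others(ann)
        kept = [
            e
            for e in ann.grooming_events
            if not (5.0 < e.onset_s and 9.0 > e.onset_s - 2.0)
        ]
        assert out.grooming_events == kept


@pytest.fixture(scope="module")
def sessions():
    model = BiomarkerModel(rate_hz=250.0)
    recs, anns = [], []
    for s in range(2):
        ann = simulate_behavior(BehaviorModel(), seed=30 + s)
        recs.append(simulate_lfp(ann, model, n_channels=2, seed=40 + s))
        anns.append(ann)
    return recs, anns


class TestLabeledDataset:
    def test_split_sizes_and_disjointness(self, sessions):
        recs, anns = sessions
        train, test = build_labeled_dataset(recs, anns, seed=1)
        n = len(train) + len(test)
        assert n >= 100
        assert len(train) == round(0.7 * n)
        key = lambda ds: {(int(s), round(float(t), 3)) for s, t in zip(ds.session, ds.t_s)}
        assert not (key(train) & key(test))

    def test_same_seed_same_split(self, sessions):
        recs, anns = sessions
        a_train, _ = build_labeled_dataset(recs, anns, seed=5)
        b_train, _ = build_labeled_dataset(recs, anns, seed=5)
        np.testing.assert_array_equal(a_train.X, b_train.X)
        np.testing.assert_array_equal(a_train.y, b_train.y)

    def test_feature_dimension_is_m_times_p(self, sessions):
        recs, anns = sessions
        train, _ = build_labeled_dataset(recs, anns, seed=1)
        assert train.X.shape[1:] == (2, 35)

    def test_no_grooming_events_is_error(self, sessions):
        recs, _ = sessions
        empty = BehaviorAnnotation(
            [BehaviorEvent("resting", 0.0, 600.0)], 600.0
        )
        with pytest.raises(ValueError, match="no pregrooming"):
            build_labeled_dataset(recs[:1], [empty], seed=1)

    def test_too_few_windows_is_error(self):
        ann = BehaviorAnnotation(
            [
                BehaviorEvent("grooming", 20.0, 24.0),
                BehaviorEvent("resting", 0.0, 20.0),
                BehaviorEvent("resting", 24.0, 60.0),
            ],
            60.0,
        )
        rec = simulate_lfp(ann, BiomarkerModel(rate_hz=250.0), n_channels=1, seed=0)
        with pytest.raises(ValueError, match="simulate longer"):
            build_labeled_dataset([rec], [ann], seed=1)
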