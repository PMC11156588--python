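"""Event-anchored scoring: Ep construction, confusion counts, baselines."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pregroom.evaluate import (
    ConfusionCounts,
    average_metrics,
    compute_ep,
    grooming_reduction,
    interrater_error,
    metrics,
    missed_events,
    pseudorandom_baseline,
    score_decisions,
)
from pregroom.signal_io import BehaviorAnnotation, BehaviorEvent


def brute_force_score(t_s, positive, ann):
    """Independent per-bin tally straight from the scoring rules: positives
    in an Ep are TP, negatives in an Ep are FN; bins inside a grooming event
    past its Ep end are excluded; everything else is FP/TN."""
    eps = [(e.onset_s - 2.0, e.onset_s + e.duration_s / 2.0) for e in ann.grooming_events]
    eps = [(max(a, 0.0), min(b, ann.session_duration_s)) for a, b in eps]
    grooms = [(e.onset_s, e.offset_s) for e in ann.grooming_events]
    c = ConfusionCounts()
    for t, p in zip(t_s, positive):
        in_ep = any(a <= t < b for a, b in eps)
        in_groom = any(a <= t < b for a, b in grooms)
        if in_ep:
            if p:
                c.TP += 1
            else:
                c.FN += 1
        elif in_groom:
            c.excluded += 1
        elif p:
            c.FP += 1
        else:
            c.TN += 1
    return c


def _random_annotation(rng, duration=120.0):
    events, t = [], 0.0
    while True:
        t += rng.uniform(2.0, 20.0)
        d = rng.uniform(1.0, 8.0)
        if t + d >= duration:
            break
        events.append(BehaviorEvent("grooming", t, t + d))
        t += d
    return BehaviorAnnotation(events, duration)


class TestComputeEp:
    def test_ep_interval_arithmetic(self):
        ann = BehaviorAnnotation([BehaviorEvent("grooming", 10.0, 16.0)], 60.0)
        assert compute_ep(ann).intervals == [(8.0, 13.0)]

    def test_clipped_at_session_start(self):
        ann = BehaviorAnnotation([BehaviorEvent("grooming", 1.0, 5.0)], 60.0)
        assert compute_ep(ann).intervals == [(0.0, 3.0)]

    def test_no_grooming_no_intervals(self):
        ann = BehaviorAnnotation([BehaviorEvent("resting", 0.0, 60.0)], 60.0)
        assert len(compute_ep(ann)) == 0


class TestScoreDecisions:
    def _bins(self, duration, interval=0.2):
        n = int(duration / interval)
        return np.arange(1, n + 1) * interval

    def test_all_positive_decisions(self):
        ann = BehaviorAnnotation([BehaviorEvent("grooming", 10.0, 14.0)], 60.0)
        t = self._bins(60.0)
        c = score_decisions(t, np.ones_like(t, dtype=bool), ann)
        assert c.FN == 0 and c.TN == 0
        assert c.TP == brute_force_score(t, np.ones_like(t, dtype=bool), ann).TP

    def test_all_negative_decisions(self):
        ann = BehaviorAnnotation([BehaviorEvent("grooming", 10.0, 14.0)], 60.0)
        t = self._bins(60.0)
        c = score_decisions(t, np.zeros_like(t, dtype=bool), ann)
        assert c.TP == 0 and c.FP == 0
        assert c.FN == brute_force_score(t, np.zeros_like(t, dtype=bool), ann).FN

    def test_hand_built_twenty_bin_session(self):
        """A fully enumerable toy stream: one 2-s bout at 2.0 s in a 4-s
        session, scored bin by bin by hand."""
        ann = BehaviorAnnotation([BehaviorEvent("grooming", 2.0, 4.0)], 4.0)
        t = self._bins(4.0)  # 0.2 ... 4.0
        pos = np.zeros(20, dtype=bool)
        pos[[0, 5, 10]] = True  # t = 0.2 (Ep), 1.2 (Ep), 2.2 (Ep)
        c = score_decisions(t, pos, ann)
        # Ep = [0, 3): bins 0.2..2.8 -> 14 bins; grooming tail [3, 4) excluded
        assert vars(c) == dict(TP=3, FN=11, excluded=5, FP=0, TN=1)

    def test_matches_brute_force_on_random_sessions(self, rng):
        for _ in range(200):
            ann = _random_annotation(rng)
            t = self._bins(120.0)
            pos = rng.random(len(t)) < rng.uniform(0.1, 0.9)
            got = score_decisions(t, pos, ann)
            assert vars(got) == vars(brute_force_score(t, pos, ann))

    @given(st.integers(0, 2**32 - 1))
    def test_bin_conservation(self, seed):
        rng = np.random.default_rng(seed)
        ann = _random_annotation(rng, duration=60.0)
        t = self._bins(60.0)
        pos = rng.random(len(t)) < 0.5
        c = score_decisions(t, pos, ann)
        assert c.total == len(t)

    def test_sensitivity_depends_only_on_ep_bins(self, rng):
        ann = _random_annotation(rng)
        t = self._bins(120.0)
        ep = compute_ep(ann)
        in_ep = np.zeros(len(t), dtype=bool)
        for a, b in ep.intervals:
            in_ep |= (t >= a) & (t < b)
        pos = rng.random(len(t)) < 0.5
        flipped = pos ^ ~in_ep  # change decisions only outside Ep
        m0 = metrics(score_decisions(t, pos, ann))
        m1 = metrics(score_decisions(t, flipped, ann))
        assert m0.sensitivity == m1.sensitivity
        flipped_in = pos ^ in_ep  # change decisions only inside Ep
        m2 = metrics(score_decisions(t, flipped_in, ann))
        assert m0.specificity == m2.specificity

    def test_missed_events_counts_event_level_misses(self):
        ann = BehaviorAnnotation(
            [BehaviorEvent("grooming", 10.0, 14.0), BehaviorEvent("grooming", 30.0, 34.0)],
            60.0,
        )
        t = self._bins(60.0)
        pos = (t > 9.0) & (t < 10.0)  # hits only the first event's Ep
        assert missed_events(t, pos, ann) == 1


class TestMetrics:
    def test_textbook_arithmetic(self):
        m = metrics(ConfusionCounts(TP=5, FN=45, TN=45, FP=5))
        assert m.sensitivity == pytest.approx(10.0)
        assert m.specificity == pytest.approx(90.0)
        assert m.accuracy == pytest.approx(50.0)
        assert m.precision == pytest.approx(50.0)

    def test_perfect_precision(self):
        m = metrics(ConfusionCounts(TP=10, FP=0, TN=5, FN=5))
        assert m.precision == 100.0

    def test_balanced_counts_all_fifty(self):
        m = metrics(ConfusionCounts(TP=25, FP=25, TN=25, FN=25))
        assert {m.accuracy, m.sensitivity, m.precision, m.specificity} == {50.0}

    def test_undefined_ratio_is_missing_not_zero(self):
        with pytest.warns(UserWarning, match="undefined"):
            m = metrics(ConfusionCounts(TP=0, FP=0, TN=10, FN=5))
        assert m.precision is None
        assert m.accuracy is not None

    def test_average_skips_missing(self):
        a = metrics(ConfusionCounts(TP=1, FP=1, TN=1, FN=1))
        with pytest.warns(UserWarning):
            b = metrics(ConfusionCounts(TP=0, FP=0, TN=10, FN=5))
        avg = average_metrics([a, b])
        assert avg.precision == 50.0


class TestPseudorandomBaseline:
    def test_converges_to_fifty_percent(self):
        """Bernoulli(0.5) decisions score ~50% on sensitivity, specificity
        and accuracy irrespective of the Ep layout (many bins, many runs)."""
        rng = np.random.default_rng(0)
        ann = _random_annotation(rng, duration=600.0)
        rep = pseudorandom_baseline(ann, n_runs=40, seed=1)
        for v in (rep.sensitivity, rep.specificity, rep.accuracy):
            assert v == pytest.approx(50.0, abs=2.0)

    def test_requires_grooming(self):
        ann = BehaviorAnnotation([BehaviorEvent("resting", 0.0, 60.0)], 60.0)
        with pytest.raises(ValueError, match="grooming"):
            pseudorandom_baseline(ann, seed=0)

    def test_deterministic_given_seed(self, short_annotation):
        a = pseudorandom_baseline(short_annotation, seed=4)
        b = pseudorandom_baseline(short_annotation, seed=4)
        assert a == b


class TestBehavioralEndpoints:
    @pytest.mark.parametrize(
        "off, treated, expected",
        [(20, 8, 60.0), (20, 20, 0.0), (20, 0, 100.0)],
    )
    def test_bout_reduction_formula(self, off, treated, expected):
        bouts, dur = grooming_reduction(off, 100.0, treated, 100.0 * treated / off)
        assert bouts == pytest.approx(expected)
        assert dur == pytest.approx(expected)

    def test_off_baseline_must_be_positive(self):
        with pytest.raises(ValueError):
            grooming_reduction(0, 10.0, 1, 1.0)

    @pytest.mark.parametrize(
        "expert, naive, expected", [(10, 9, 10.0), (10, 10, 0.0), (10, 11, -10.0)]
    )
    def test_interrater_error_signed(self, expert, naive, expected):
        assert interrater_error(expert, naive) == pytest.approx(expected)

    def test_interrater_zero_expert_rejected(self):
        with pytest.raises(ValueError):
            interrater_error(0, 1)
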