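"""Stall scoring: motion statistic, vote simulation, crowd pooling, triage."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import capiflow as cf
from capiflow import stalls as S
from helpers import auc


class TestMotionStatistic:
    def test_noise_free_separation(self, noise_free_stack):
        """Stalled segments score near zero; flowing ones exceed them by the
        generator's declared margin."""
        stack, truth = noise_free_stack
        stalled, flowing = [], []
        for seg in truth.segments:
            m = cf.motion_statistic(stack, seg)
            if np.isnan(m):
                continue
            (stalled if seg.state == "stalled" else flowing).append(m)
        assert stalled and flowing
        assert max(stalled) < min(flowing)
        assert min(flowing) - max(stalled) >= cf.SEPARATION_MARGIN
        assert min(flowing) >= cf.SEPARATION_MARGIN
        assert np.median(stalled) < 0.05

    def test_single_frame_segment_unscorable(self, noise_free_stack):
        stack, truth = noise_free_stack

        class Flat:
            # a segment pinned to a single plane midway between voxels is
            # never visible in two comparable frames
            centerline_um = np.column_stack([
                np.full(40, 200.0),  # far outside the imaged depth
                np.linspace(30, 60, 40),
                np.full(40, 50.0),
            ])
            diameter_um = 4.0

        assert np.isnan(cf.motion_statistic(stack, Flat()))

    def test_roc_degrades_with_noise(self):
        """AUC is high at default SNR and decreases (within tolerance) along
        an increasing-noise ladder."""
        aucs = []
        for read_noise in [2.0, 10.0, 20.0, 35.0, 60.0]:
            labels, scores = [], []
            for seed in range(5):
                cfg = cf.SimulationConfig(
                    seed=seed, stall_fraction=0.3, n_vessels=15,
                    noise_model=cf.NoiseModel(10.0, read_noise),
                )
                stack, truth = cf.simulate_stack(cfg)
                for seg in truth.segments:
                    m = cf.motion_statistic(stack, seg)
                    if not np.isnan(m):
                        labels.append(seg.state == "flowing")
                        scores.append(m)
            aucs.append(auc(labels, scores))
        assert aucs[0] >= 0.95
        for hi, lo in zip(aucs, aucs[1:]):
            assert lo <= hi + 0.02
        assert aucs[-1] < aucs[0]


class TestSimulateVotes:
    def _truth(self, n=40, frac=0.3, seed=0):
        cfg = cf.SimulationConfig(seed=seed, n_vessels=n, stall_fraction=frac,
                                  volume_extent=(120.0, 400.0, 400.0))
        return cf.simulate_ground_truth(cfg)

    def test_perfect_raters_match_truth(self):
        truth = self._truth()
        anns = [cf.Annotator(i, 1.0, 1.0) for i in range(5)]
        votes = cf.simulate_votes(truth, anns, votes_per_segment=3, seed=1)
        state = {s.segment_id: s.state for s in truth.segments}
        assert (votes["vote"] == votes["segment_id"].map(state)).all()

    def test_coin_flip_raters_half_agreement(self):
        truth = self._truth(n=100)
        anns = [cf.Annotator(i, 0.5, 0.5) for i in range(10)]
        votes = cf.simulate_votes(truth, anns, votes_per_segment=100, seed=2)
        state = {s.segment_id: s.state for s in truth.segments}
        agree = (votes["vote"] == votes["segment_id"].map(state)).mean()
        assert agree == pytest.approx(0.5, abs=0.02)

    def test_seed_reproducibility(self):
        truth = self._truth()
        anns = [cf.Annotator(i, 0.8, 0.9) for i in range(7)]
        v1 = cf.simulate_votes(truth, anns, seed=5)
        v2 = cf.simulate_votes(truth, anns, seed=5)
        assert v1.equals(v2)


class TestCrowdConfidence:
    def test_unanimous_bounds(self):
        anns = [cf.Annotator(0, 0.7, 0.9), cf.Annotator(1, 0.9, 0.8)]
        assert cf.crowd_confidence([(0, "stalled"), (1, "stalled")], anns) == 1.0
        assert cf.crowd_confidence([(0, "flowing"), (1, "flowing")], anns) == 0.0

    def test_hand_weighted_mean(self):
        anns = [cf.Annotator(0, 0.9, 0.5), cf.Annotator(1, 0.3, 0.5)]
        c = cf.crowd_confidence([(0, "stalled"), (1, "flowing")], anns)
        assert c == pytest.approx(0.9 / 1.2)

    def test_zero_weights_error(self):
        anns = [cf.Annotator(0, 0.0, 0.9)]
        with pytest.raises(ValueError, match="uninformative"):
            cf.crowd_confidence([(0, "stalled")], anns)

    @given(st.lists(st.tuples(st.floats(0.01, 1.0), st.booleans()),
                    min_size=1, max_size=25))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_bounded_and_monotone(self, weighted_votes):
        """The score is a weighted mean (bounded by 0 and 1) and flipping
        any single vote flowing -> stalled never decreases it."""
        anns = [cf.Annotator(i, w, 0.5) for i, (w, _) in enumerate(weighted_votes)]
        votes = [(i, "stalled" if s else "flowing")
                 for i, (_, s) in enumerate(weighted_votes)]
        c = cf.crowd_confidence(votes, anns)
        assert 0.0 <= c <= 1.0
        for k, (aid, v) in enumerate(votes):
            if v == "flowing":
                flipped = list(votes)
                flipped[k] = (aid, "stalled")
                assert cf.crowd_confidence(flipped, anns) >= c


class TestTriageAndValidate:
    def _records(self, confs):
        return [cf.StallRecord(segment_id=i, crowd_confidence=c)
                for i, c in enumerate(confs)]

    def test_all_below_threshold(self):
        recs, n = cf.triage_and_validate(self._records([0.1, 0.4, 0.49]),
                                         oracle=lambda s: "stalled")
        assert n == 0
        assert all(r.final_label == "flowing" for r in recs)

    def test_descending_validation_order(self):
        order = []
        recs, n = cf.triage_and_validate(
            self._records([0.95, 0.6, 0.4]),
            oracle=lambda sid: order.append(sid) or "stalled",
        )
        assert order == [0, 1]
        assert n == 2
        assert recs[2].final_label == "flowing"

    def test_threshold_inclusive(self):
        recs, n = cf.triage_and_validate(self._records([0.5]),
                                         oracle=lambda s: "stalled")
        assert n == 1 and recs[0].validated

    def test_triage_matches_exhaustive_validation(self):
        """With a perfect oracle, triage labels equal exhaustive validation
        whenever no true stall falls below the 0.5 confidence band."""
        cfg = cf.SimulationConfig(seed=4, n_vessels=400, stall_fraction=0.03,
                                  volume_extent=(150.0, 400.0, 400.0))
        truth = cf.simulate_ground_truth(cfg)
        rng = np.random.default_rng(8)
        anns = [cf.Annotator(i, s, p) for i, (s, p) in enumerate(
            zip(rng.uniform(0.7, 0.95, 20), rng.uniform(0.85, 0.98, 20)))]
        votes = cf.simulate_votes(truth, anns, votes_per_segment=20, seed=9)
        conf = cf.confidences_from_table(votes, anns)
        state = {s.segment_id: s.state for s in truth.segments}
        recs = [cf.StallRecord(segment_id=k, crowd_confidence=v)
                for k, v in conf.items()]
        recs, workload = cf.triage_and_validate(recs, oracle=lambda s: state[s])
        missed_stalls = [r for r in recs if state[r.segment_id] == "stalled"
                        and r.crowd_confidence < 0.5]
        if not missed_stalls:
            assert all(r.final_label == state[r.segment_id] for r in recs)
        assert workload < 0.2 * len(recs)


class TestStallDensity:
    def test_arithmetic(self):
        recs = [cf.StallRecord(segment_id=i, final_label="stalled")
                for i in range(3)]
        assert cf.stall_density(recs, 0.5) == 6.0

    def test_unscorable_excluded(self):
        recs = [
            cf.StallRecord(segment_id=0, final_label="stalled"),
            cf.StallRecord(segment_id=1, final_label="stalled", scorable=False),
        ]
        assert cf.stall_density(recs, 1.0) == 1.0

    def test_rejects_nonpositive_volume(self):
        with pytest.raises(ValueError):
            cf.stall_density([], -1.0)


class TestAnnotatorCalibration:
    def test_estimated_rates_match_generating_rates(self):
        cfg = cf.SimulationConfig(seed=6, n_vessels=600, stall_fraction=0.5,
                                  volume_extent=(200.0, 500.0, 500.0))
        truth = cf.simulate_ground_truth(cfg)
        anns = [cf.Annotator(0, 0.85, 0.92), cf.Annotator(1, 0.6, 0.7)]
        votes = cf.simulate_votes(truth, anns, votes_per_segment=4, seed=3)
        est = {a.annotator_id: a
               for a in cf.estimate_annotator_performance(votes, truth)}
        for a in anns:
            assert est[a.annotator_id].sensitivity == pytest.approx(
                a.sensitivity, abs=0.05)
            assert est[a.annotator_id].specificity == pytest.approx(
                a.specificity, abs=0.05)
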