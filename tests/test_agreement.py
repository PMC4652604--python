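"""Agreement statistics: binarisation, kappa/MCC/AGm, event matching."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score, matthews_corrcoef

from spindlecwt.agreement import (agreement_stats, binarize_timeline,
                                  event_overlap_sets, landis_koch_label,
                                  pearson, stage_bin_mask, weighted_average)
from spindlecwt.errors import ValidationError
from spindlecwt.io_formats import Hypnogram, Stage


class TestBinarize:
    def test_no_events_all_false(self):
        assert not binarize_timeline([], 10.0).any()

    def test_interval_arithmetic(self):
        v = binarize_timeline([(1.0, 1.5)], 3.0)
        assert list(np.nonzero(v)[0]) == [10, 11, 12, 13, 14]

    def test_partial_overlap_marks_bin(self):
        v = binarize_timeline([(0.95, 1.02)], 3.0)
        assert v[9] and v[10] and not v[8] and not v[11]

    def test_identical_events_identical_vectors(self):
        events = [(0.3, 1.1), (4.0, 5.2)]
        assert np.array_equal(binarize_timeline(events, 10.0),
                              binarize_timeline(list(events), 10.0))


class TestAgreementStats:
    def test_self_agreement_is_perfect(self):
        rng = np.random.default_rng(0)
        x = rng.random(500) < 0.2
        res = agreement_stats(x, x)
        assert res.kappa == pytest.approx(1.0)
        assert res.matthews == pytest.approx(1.0)

    def test_hand_computed_kappa(self):
        # TP=40 FP=10 FN=20 TN=130: p_o=0.85, p_e=0.6 -> kappa=0.625
        a = np.repeat([True, True, False, False], [40, 20, 10, 130])
        b = np.repeat([True, False, True, False], [40, 20, 10, 130])
        res = agreement_stats(a, b)
        assert (res.TP, res.FN, res.FP, res.TN) == (40, 20, 10, 130)
        assert res.kappa == pytest.approx(0.625)

    def test_matthews_equals_pearson_on_random_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            n = rng.integers(20, 200)
            a = rng.random(n) < rng.uniform(0.1, 0.9)
            b = rng.random(n) < rng.uniform(0.1, 0.9)
            if a.all() or (~a).all() or b.all() or (~b).all():
                continue  # correlation undefined for constant vectors
            res = agreement_stats(a, b)
            r = np.corrcoef(a.astype(float), b.astype(float))[0, 1]
            assert abs(res.matthews - r) < 1e-10

    def test_matches_sklearn_oracles(self):
        rng = np.random.default_rng(2)
        a = rng.random(2000) < 0.15
        b = a ^ (rng.random(2000) < 0.1)
        res = agreement_stats(a, b)
        assert res.kappa == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)
        assert res.matthews == pytest.approx(matthews_corrcoef(a, b), abs=1e-12)

    def test_symmetric_statistics_under_role_swap(self):
        rng = np.random.default_rng(3)
        a = rng.random(1000) < 0.2
        b = rng.random(1000) < 0.3
        r1, r2 = agreement_stats(a, b), agreement_stats(b, a)
        assert r1.kappa == pytest.approx(r2.kappa)
        assert r1.matthews == pytest.approx(r2.matthews)
        assert r1.sensitivity == pytest.approx(r2.precision)
        assert r1.precision == pytest.approx(r2.sensitivity)

    def test_adjusted_gmean_formula(self):
        a = np.repeat([True, True, False, False], [40, 20, 10, 130])
        b = np.repeat([True, False, True, False], [40, 20, 10, 130])
        res = agreement_stats(a, b)
        n_n = 140 / 200
        gm = np.sqrt(res.sensitivity * res.specificity)
        assert res.adjusted_gmean == pytest.approx((gm + res.specificity * n_n)
                                                   / (1 + n_n))

    def test_zero_sensitivity_gives_zero_agm(self):
        a = np.array([True, True, False, False])
        b = np.array([False, False, True, False])
        assert agreement_stats(a, b).adjusted_gmean == 0.0

    def test_empty_or_mismatched_vectors_invalid(self):
        with pytest.raises(ValidationError):
            agreement_stats(np.empty(0, bool), np.empty(0, bool))
        with pytest.raises(ValidationError):
            agreement_stats(np.zeros(5, bool), np.zeros(4, bool))


class TestLandisKoch:
    @pytest.mark.parametrize("kappa,label", [
        (0.1, "slight"), (0.3, "fair"), (0.45, "moderate"), (0.62, "substantial"),
        (0.95, "almost perfect"), (1.0, "almost perfect"), (0.60, "moderate"),
        (0.80, "substantial"), (-0.2, "poor"),
    ])
    def test_benchmarks(self, kappa, label):
        assert landis_koch_label(kappa) == label


class TestEventOverlap:
    def test_identical_events_all_consensus(self):
        ev = [(0.0, 1.0), (5.0, 6.2)]
        sets = event_overlap_sets(ev, list(ev))
        assert len(sets["consensus"]) == 2
        assert sets["only_a"] == [] and sets["only_b"] == []

    def test_below_min_overlap_unmatched(self):
        sets = event_overlap_sets([(0.0, 1.0)], [(0.8, 1.8)])  # 0.2 s overlap
        assert sets["consensus"] == []
        assert sets["only_a"] == [0] and sets["only_b"] == [0]

    def test_chain_overlap_04s_matched(self):
        sets = event_overlap_sets([(0.0, 1.0)], [(0.6, 1.6)])
        assert sets["consensus"] == [(0, 0)]

    def test_greedy_matching_is_one_to_one(self):
        a = [(0.0, 2.0)]
        b = [(0.0, 0.9), (1.0, 2.0)]  # both overlap a[0] by >= 0.3
        sets = event_overlap_sets(a, b)
        assert len(sets["consensus"]) == 1
        assert sets["consensus"][0] == (0, 1)  # larger overlap wins
        assert sets["only_b"] == [0]


class TestHelpers:
    def test_weighted_average_degenerate_cases(self):
        assert weighted_average([1.0, 2.0, 3.0]) == pytest.approx(2.0)
        assert weighted_average([1.0, 2.0, 3.0], [0, 0, 5]) == pytest.approx(3.0)

    def test_pearson_hand_computed(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        xc, yc = x - x.mean(), y - y.mean()
        oracle = np.sum(xc * yc) / np.sqrt(np.sum(xc ** 2) * np.sum(yc ** 2))
        assert pearson(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_stage_bin_mask_restriction(self):
        hyp = Hypnogram([Stage.S2, Stage.REM])
        keep = stage_bin_mask(hyp, {Stage.S2}, 60.0)
        assert keep[:300].all() and not keep[300:].any()
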