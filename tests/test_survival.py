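"""Survival estimators vs hand calculations, brute force and library oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mdsrisk import cuminc_competing, harrell_c, km_estimate


def brute_force_c(scores, times, events):
    """O(n^2) pair enumeration, straight from the definition."""
    n = len(scores)
    pairs = conc = tied = 0
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                pairs += 1
                if scores[i] > scores[j]:
                    conc += 1
                elif scores[i] == scores[j]:
                    tied += 1
    return (conc + 0.5 * tied) / pairs, pairs, conc, tied


class TestKaplanMeier:
    def test_hand_product_limit(self):
        curve = km_estimate([1.0, 2.0, 3.0], [1, 1, 0])
        assert curve.times.tolist() == [1.0, 2.0, 3.0]
        assert curve.estimate == pytest.approx([2 / 3, 1 / 3, 1 / 3])
        assert curve.at_risk.tolist() == [3, 2, 1]

    def test_all_censored_stays_at_one(self):
        curve = km_estimate([5.0, 8.0, 2.0], [0, 0, 0])
        assert np.all(curve.estimate == 1.0)

    def test_single_event_degenerate(self):
        curve = km_estimate([5.0], [1])
        assert curve.estimate == pytest.approx([0.0])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            km_estimate([], [])

    def test_ties_events_before_censorings(self):
        # at t=2: one event and one censoring; the censored subject still counts
        # as at risk for the event at the same time
        curve = km_estimate([2.0, 2.0, 3.0], [1, 0, 1])
        assert curve.estimate == pytest.approx([2 / 3, 0.0])

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, size=50)
        curve = km_estimate(t, np.ones(50, dtype=int))
        for tk, sk in zip(curve.times, curve.estimate):
            assert sk == pytest.approx(np.mean(t > tk))

    def test_against_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(2)
        t = rng.exponential(20, size=120)
        e = (rng.random(120) < 0.7).astype(int)
        curve = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for tk, sk in zip(curve.times, curve.estimate):
            assert sk == pytest.approx(kmf.predict(tk), abs=1e-9)

    def test_median(self):
        curve = km_estimate([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        assert curve.median() == 2.0
        censored = km_estimate([1.0, 2.0], [0, 0])
        assert censored.median() == float("inf")


class TestCumulativeIncidence:
    def test_reduces_to_one_minus_km_without_competing_events(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, size=60)
        e = (rng.random(60) < 0.6).astype(int)
        cif = cuminc_competing(t, e, np.zeros(60, dtype=int))
        km = km_estimate(t, e)
        assert cif.estimate == pytest.approx(1.0 - km.estimate, abs=1e-12)

    def test_all_competing_events_gives_zero_incidence(self):
        cif = cuminc_competing([1.0, 2.0, 3.0], [0, 0, 0], [1, 1, 1])
        assert np.all(cif.estimate == 0.0)

    def test_hand_computed_aalen_johansen(self):
        # t=1: event of interest (4 at risk)        -> CIF = 1/4
        # t=2: competing death (3 at risk)          -> CIF unchanged, S drops
        # t=3: event of interest (2 at risk), S(3-) = (3/4)(2/3) = 1/2
        #                                           -> CIF = 1/4 + 1/2 * 1/2 = 1/2
        # t=4: censored
        cif = cuminc_competing([1.0, 2.0, 3.0, 4.0], [1, 0, 1, 0], [0, 1, 0, 0])
        assert cif.estimate == pytest.approx([0.25, 0.25, 0.5, 0.5])

    def test_overlapping_indicators_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            cuminc_competing([1.0], [1], [1])

    def test_against_lifelines_aalen_johansen(self):
        from lifelines import AalenJohansenFitter

        rng = np.random.default_rng(4)
        n = 100
        t = rng.exponential(10, size=n).round(3)
        cause = rng.choice([0, 1, 2], size=n, p=[0.3, 0.4, 0.3])
        cif = cuminc_competing(t, (cause == 1).astype(int), (cause == 2).astype(int))
        ajf = AalenJohansenFitter(calculate_variance=False).fit(t, cause, event_of_interest=1)
        for tk, ck in zip(cif.times, cif.estimate):
            expected = float(ajf.cumulative_density_.loc[:tk].iloc[-1].iloc[0])
            assert ck == pytest.approx(expected, abs=1e-9)


class TestHarrellC:
    def test_perfect_concordance(self):
        res = harrell_c([3.0, 2.0, 1.0], [1.0, 2.0, 3.0], [1, 1, 1])
        assert res.c == 1.0
        assert res.n_comparable_pairs == 3

    def test_all_tied_scores(self):
        res = harrell_c([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [1, 1, 1])
        assert res.c == 0.5
        assert res.n_tied_score == res.n_comparable_pairs

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            harrell_c([1.0, 2.0], [5.0, 5.0], [0, 0])

    def test_bookkeeping_identity(self):
        rng = np.random.default_rng(5)
        res = harrell_c(rng.normal(size=80), rng.exponential(10, 80), (rng.random(80) < 0.7).astype(int))
        assert res.c == pytest.approx(
            (res.n_concordant + 0.5 * res.n_tied_score) / res.n_comparable_pairs
        )

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            n = 100
            s = rng.normal(size=n).round(1)  # rounding induces score ties
            t = rng.exponential(10, size=n)
            e = (rng.random(n) >= 0.3).astype(int)
            res = harrell_c(s, t, e)
            c, pairs, conc, tied = brute_force_c(s, t, e)
            assert res.c == c
            assert (res.n_comparable_pairs, res.n_concordant, res.n_tied_score) == (pairs, conc, tied)

    def test_matches_scikit_survival(self):
        from sksurv.metrics import concordance_index_censored

        rng = np.random.default_rng(7)
        n = 150
        s = rng.normal(size=n)  # continuous: no ties in scores or times
        t = rng.exponential(10, size=n)
        e = rng.random(n) < 0.7
        res = harrell_c(s, t, e.astype(int))
        expected = concordance_index_censored(e, t, s)[0]
        assert res.c == pytest.approx(expected, abs=1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_symmetry_without_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        s = rng.normal(size=n)
        t = rng.exponential(10, size=n)
        e = (rng.random(n) < 0.8).astype(int)
        if not e.any():
            return
        assert harrell_c(s, t, e).c + harrell_c(-s, t, e).c == pytest.approx(1.0)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_invariance_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        s = rng.normal(size=n)
        t = rng.exponential(10, size=n)
        e = (rng.random(n) < 0.8).astype(int)
        if not e.any():
            return
        assert harrell_c(np.exp(2 * s) + 1, t, e).c == harrell_c(s, t, e).c
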