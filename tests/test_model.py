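"""Resampling engine: emissions, pooling, medians, direction probability, calls."""

import math

import numpy as np
import pytest

from betasplice.errors import ConfigError, InputValidationError
from betasplice.events import CoverageScore, EventType, JunctionCounts, StudyDesign
from betasplice.model import (
    BetaSpliceModel,
    CallThresholds,
    condition_psi,
    differential_event,
    emit_psi,
    pooled_condition_values,
    prob_positive,
    run_differential,
)
from conftest import make_event
from oracles import exact_prob_beta_greater


class TestEmission:
    def test_length_and_determinism(self, rng):
        counts = JunctionCounts(10, 30)
        em = emit_psi(counts, 500, np.random.default_rng(7))
        em2 = emit_psi(counts, 500, np.random.default_rng(7))
        assert em.n_emit == 500
        assert (em.alpha, em.beta) == (11, 31)
        assert np.array_equal(em.values, em2.values)
        assert np.all((em.values > 0) & (em.values < 1))

    def test_zero_count_emission_is_uniform(self, rng):
        em = emit_psi(JunctionCounts(0, 0), 500, rng)
        se = 1 / math.sqrt(12 * 500)
        assert abs(em.values.mean() - 0.5) < 3 * se

    def test_mean_matches_beta_expectation(self, rng):
        em = emit_psi(JunctionCounts(10, 30), 20000, rng)
        mean = 11 / 42
        var = mean * (1 - mean) / 43
        assert abs(em.values.mean() - mean) < 3 * math.sqrt(var / 20000)

    def test_rejects_bad_n_emit(self, rng):
        with pytest.raises(InputValidationError):
            emit_psi(JunctionCounts(1, 1), 0, rng)


class TestPoolingAndMedian:
    def test_pooled_lengths(self, design_3v3, rng):
        counts = {s: (5, 5) for s in design_3v3.assignment}
        event = make_event(counts_by_sample=counts)
        pooled = pooled_condition_values(event, design_3v3, CallThresholds(n_emit=500), rng)
        assert {len(v) for v in pooled.values()} == {1500}

    def test_unbalanced_pooled_lengths(self, rng):
        design = StudyDesign(
            {"c1": "control", "c2": "control", "c3": "control", "k1": "knockdown",
             "k2": "knockdown"},
            reference="control",
        )
        event = make_event(counts_by_sample={s: (5, 5) for s in design.assignment})
        pooled = pooled_condition_values(event, design, CallThresholds(n_emit=500), rng)
        assert len(pooled["control"]) == 1500
        assert len(pooled["knockdown"]) == 1000

    def test_sample_missing_from_design_is_config_error(self, single_rep_design, rng):
        event = make_event(counts_by_sample={"c1": (5, 5), "mystery": (5, 5)})
        with pytest.raises(ConfigError):
            BetaSpliceModel([event], single_rep_design)

    @pytest.mark.parametrize(
        "values,expected",
        [((0.2, 0.4, 0.9), 0.4), ((0.2, 0.4, 0.6, 0.9), 0.5)],
    )
    def test_condition_psi_is_median(self, values, expected):
        assert condition_psi(values) == pytest.approx(expected)

    def test_condition_psi_rejects_empty(self):
        with pytest.raises(InputValidationError):
            condition_psi([])

    def test_symmetric_counts_give_psi_half(self, rng):
        em = emit_psi(JunctionCounts(5, 5), 20000, rng)
        se = math.sqrt(0.5 * 0.5 / 12) / math.sqrt(20000) * 4  # generous median SE
        assert condition_psi(em.values) == pytest.approx(0.5, abs=5 * se + 0.01)


class TestProbPositive:
    def test_exchangeable_inputs_give_half(self, rng):
        n = 20000
        a = emit_psi(JunctionCounts(5, 5), n, rng).values
        b = emit_psi(JunctionCounts(5, 5), n, rng).values
        p = prob_positive(a, b, rng)
        assert abs(p - 0.5) < 3 * math.sqrt(0.25 / n)

    def test_matches_exact_beta_oracle_on_known_case(self, rng):
        n = 20000
        a = emit_psi(JunctionCounts(2, 1), n, rng).values
        b = emit_psi(JunctionCounts(1, 2), n, rng).values
        p = prob_positive(a, b, rng)
        exact = exact_prob_beta_greater(3, 2, 2, 3)
        assert exact == pytest.approx(53 / 70, abs=1e-12)
        assert abs(p - exact) < 3 * math.sqrt(exact * (1 - exact) / n)

    def test_extreme_separation(self, rng):
        n = 20000
        a = emit_psi(JunctionCounts(50, 0), n, rng).values
        b = emit_psi(JunctionCounts(0, 50), n, rng).values
        assert prob_positive(a, b, rng) >= 0.999

    def test_complement_symmetry_same_values(self, rng):
        n = 20000
        a = emit_psi(JunctionCounts(8, 3), n, rng).values
        b = emit_psi(JunctionCounts(3, 8), n, rng).values
        p = prob_positive(a, b, np.random.default_rng(0))
        q = prob_positive(b, a, np.random.default_rng(1))
        # ties have probability ~0 with continuous emissions; pairings are
        # independent, so complementarity holds within Monte-Carlo error
        assert abs(p + q - 1.0) < 3 * math.sqrt(2 * 0.25 / n)

    def test_oracle_monotone_in_inc(self):
        """Expected direction probability never decreases as test inc grows."""
        vals = [exact_prob_beta_greater(inc + 1, 6, 4, 4) for inc in range(0, 12)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_rejects_empty(self, rng):
        with pytest.raises(InputValidationError):
            prob_positive(np.array([]), np.array([0.5]), rng)


class TestCalls:
    def _result(self, counts_kd, counts_ctrl, rng, thresholds=None):
        design = StudyDesign({"c1": "control", "k1": "knockdown"}, reference="control")
        event = make_event(counts_by_sample={"c1": counts_ctrl, "k1": counts_kd})
        return differential_event(event, design, thresholds or CallThresholds(), rng)

    def test_clear_shift_is_significant(self, rng):
        res = self._result((90, 10), (50, 50), rng)
        assert res.delta_psi == pytest.approx(res.psi_knockdown - res.psi_control)
        assert res.prob_differential == pytest.approx(
            max(res.prob_positive, 1 - res.prob_positive)
        )
        assert res.significant

    def test_negative_shift_called_via_complement(self, rng):
        res = self._result((10, 90), (50, 50), rng)
        assert res.delta_psi < -0.05
        assert res.prob_positive < 0.2
        assert res.significant

    def test_small_effect_not_called_even_when_certain(self, rng):
        res = self._result((5200, 4800), (5000, 5000), rng,
                           CallThresholds(n_emit=2000))
        # high depth: direction near-certain but |dPSI| ~ 2% < 5%
        assert res.prob_differential > 0.8
        assert abs(res.delta_psi) < 0.05
        assert not res.significant

    def test_uncertain_direction_not_called(self, rng):
        res = self._result((7, 5), (5, 7), rng)
        if res.prob_differential <= 0.8:
            assert not res.significant

    def test_no_call_violates_thresholds(self, rng):
        # range invariant over a batch of null events
        design = StudyDesign({"c1": "control", "k1": "knockdown"}, reference="control")
        events = [
            make_event(event_id=f"EV{i}", counts_by_sample={"c1": (10, 10), "k1": (10, 10)})
            for i in range(50)
        ]
        for res in run_differential(events, design, master_seed=1):
            assert 0.5 <= res.prob_differential <= 1.0
            if res.significant:
                assert res.prob_differential > 0.8
                assert abs(res.delta_psi) > 0.05


class TestRunner:
    def test_empty_input(self, design_3v3):
        assert run_differential([], design_3v3) == []

    def test_order_independent_given_seed(self, design_3v3):
        events = [
            make_event(event_id=f"EV{i}",
                       counts_by_sample={s: (10 + i, 10) for s in design_3v3.assignment})
            for i in range(10)
        ]
        fwd = run_differential(events, design_3v3, master_seed=99)
        rev = run_differential(events[::-1], design_3v3, master_seed=99)
        assert fwd == rev

    def test_duplicate_ids_rejected(self, design_3v3):
        events = [make_event(counts_by_sample={s: (1, 1) for s in design_3v3.assignment})] * 2
        with pytest.raises(InputValidationError):
            run_differential(events, design_3v3)


class TestModelObject:
    def test_fit_filters_coverage_and_reports(self, design_3v3):
        good = make_event(event_id="GOOD",
                          counts_by_sample={s: (30, 10) for s in design_3v3.assignment},
                          coverage=CoverageScore.OK)
        bad = make_event(event_id="BAD",
                         counts_by_sample={s: (30, 10) for s in design_3v3.assignment},
                         coverage=CoverageScore.N)
        res = BetaSpliceModel([good, bad], design_3v3).fit(seed=5)
        assert res.n_input == 2
        assert res.n_filtered == 1
        assert [r.event_id for r in res.results] == ["GOOD"]
        frame = res.results_frame()
        assert list(frame["event_id"]) == ["GOOD"]
        assert set(frame.columns) >= {"delta_psi", "prob_differential", "significant"}

    def test_summary_mentions_key_quantities(self, design_3v3):
        events = [
            make_event(event_id=f"EV{i}", event_type=EventType.IR,
                       counts_by_sample={s: (40, 2) if s.startswith("kd") else (20, 20)
                                         for s in design_3v3.assignment})
            for i in range(5)
        ]
        res = BetaSpliceModel(events, design_3v3).fit(seed=2)
        text = res.summary()
        assert "events tested:     5" in text
        assert "knockdown vs control" in text
        assert "IR" in text
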