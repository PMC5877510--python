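"""WoE/MCDA scoring engine: per-LOE indices, aggregation, hazard score."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanohazard.loe import EvidenceTable, LOERecord, StudyQuality, ToxClassAssignment
from nanohazard.scoring import (
    AggregationWeights,
    ScoringError,
    ToxClassScores,
    aggregate_loe,
    default_rules,
    fit_aggregation_weights,
    hazard_score,
    normalize_weights,
    quality_weight,
    score_physchem,
    score_toxicity,
)


class TestPhyschemIndex:
    def test_elongated_aspect_ratio_scores_high_hazard(self):
        assert score_physchem({"aspect_ratio": "1:5"}, default_rules()) == 100.0

    def test_compact_aspect_ratio_scores_low_hazard(self):
        assert score_physchem({"aspect_ratio": "1:1"}, default_rules()) == 25.0

    def test_index_is_arithmetic_mean_and_skips_missing_criteria(self):
        from nanohazard.scoring import CategoricalRule, NumericRule, ScoringRuleSet

        rules = ScoringRuleSet(
            {
                "aspect_ratio": NumericRule((3.0,), (25.0, 100.0)),
                "surface_coating": CategoricalRule({"None": 100.0, "PVP": 25.0}),
            }
        )
        profile = {"aspect_ratio": 5.0, "surface_coating": "PVP",
                   "purity": "unscored-extra"}
        assert score_physchem(profile, rules) == pytest.approx(62.5)

    def test_unscorable_profile_raises_rather_than_zero(self):
        with pytest.raises(ScoringError, match="no scoreable"):
            score_physchem({"purity": "99%"}, default_rules())


class TestToxicityIndex:
    def test_convincing_causal_evidence_scores_100(self):
        assert score_toxicity(ToxClassAssignment((0, 0, 0, 0, 1))) == 100.0

    def test_all_mass_in_lowest_class_scores_zero(self):
        assert score_toxicity(ToxClassAssignment((1, 0, 0, 0, 0))) == 0.0

    def test_split_assignment_matches_published_first_row(self):
        # half C4, half C5 on the even grid -> 87.50, the printed row-1 index
        assert score_toxicity(
            ToxClassAssignment((0, 0, 0, 0.5, 0.5))
        ) == pytest.approx(87.50)

    def test_class_scores_must_be_nondecreasing_with_c5_fixed(self):
        with pytest.raises(ScoringError):
            ToxClassScores((0, 50, 25, 75, 100))
        with pytest.raises(ScoringError):
            ToxClassScores((0, 25, 50, 75, 90))


class TestAggregation:
    def test_published_first_row(self):
        assert aggregate_loe(41.67, 87.50, AggregationWeights(0.3, 0.7)) == pytest.approx(73.75, abs=0.005)

    def test_published_third_row(self):
        assert aggregate_loe(50.00, 75.00, AggregationWeights(0.3, 0.7)) == pytest.approx(67.50)

    @given(x=st.floats(0, 100), w=st.floats(0.01, 0.49))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_equal_inputs_are_a_fixed_point(self, x, w):
        assert aggregate_loe(x, x, AggregationWeights(w, 1 - w)) == pytest.approx(x)

    def test_weights_must_be_convex_with_tox_not_below_pchem(self):
        with pytest.raises(ScoringError):
            AggregationWeights(0.3, 0.6)
        with pytest.raises(ScoringError):
            AggregationWeights(0.6, 0.4)
        AggregationWeights(0.5, 0.5)  # boundary allowed for exact recovery


class TestWeightRecovery:
    def test_fixture_yields_point_three(self, tio2):
        weights, report = fit_aggregation_weights(tio2)
        assert weights.w_pchem == pytest.approx(0.30, abs=0.005)
        assert weights.w_tox == pytest.approx(0.70, abs=0.005)
        assert report["max_abs_residual"] < 0.02

    def test_exact_recovery_from_noiseless_rows(self):
        table = _index_table([(20.0, 80.0), (90.0, 10.0)], a=0.5)
        weights, _ = fit_aggregation_weights(table)
        assert weights.w_pchem == pytest.approx(0.5, abs=1e-12)

    def test_recovery_under_small_rounding_noise(self):
        rng = np.random.default_rng(42)
        sp = rng.uniform(0, 100, 30)
        st_ = rng.uniform(0, 100, 30)
        for _ in range(20):
            s = 0.35 * sp + 0.65 * st_ + rng.normal(0, 0.005, 30)
            table = _index_table(list(zip(sp, st_)), a=None, s_total=s)
            weights, _ = fit_aggregation_weights(table)
            assert weights.w_pchem == pytest.approx(0.35, abs=0.01)

    def test_degenerate_system_raises(self):
        table = _index_table([(50.0, 50.0), (60.0, 60.0)], a=0.4)
        with pytest.raises(ScoringError, match="degenerate"):
            fit_aggregation_weights(table)


def _index_table(pairs, a, s_total=None, weights=None):
    records = []
    for j, (sp, st_) in enumerate(pairs):
        s = s_total[j] if s_total is not None else a * sp + (1 - a) * st_
        records.append(
            LOERecord(
                loe_id=str(j),
                nm="X",
                precomputed={
                    "s_pchem": float(sp),
                    "s_tox": float(st_),
                    "s_total": float(s),
                    "quality_weight": float(weights[j]) if weights is not None else 1.0,
                },
            )
        )
    return EvidenceTable(nm="X", records=records)


class TestWeightNormalization:
    def test_fixture_first_weight(self, tio2):
        wn = normalize_weights(tio2.column("quality_weight"))
        assert wn[0] == pytest.approx(0.61 / 13.93, abs=1e-9)
        assert round(wn[0], 2) == 0.04  # printed value

    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=30),
           st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_sums_to_one_and_scale_invariant(self, w, k):
        wn = normalize_weights(w)
        assert wn.sum() == pytest.approx(1.0)
        assert np.allclose(normalize_weights(np.array(w) * k), wn)

    def test_simple_proportions(self):
        assert np.allclose(normalize_weights([2, 1, 1]), [0.5, 0.25, 0.25])

    def test_all_zero_raises(self):
        with pytest.raises(ScoringError):
            normalize_weights([0.0, 0.0])


class TestQualityWeight:
    def test_override_passes_through(self):
        assert quality_weight(StudyQuality(weight_override=0.94)) == 0.94

    def test_perfect_study_scores_one(self):
        q = StudyQuality({c: 1.0 for c in
                          ("adequacy", "reliability", "statistical_power",
                           "toxicological_significance")})
        assert quality_weight(q) == 1.0

    def test_default_is_arithmetic_mean(self):
        q = StudyQuality({"adequacy": 0.8, "reliability": 0.6,
                          "statistical_power": 0.4,
                          "toxicological_significance": 0.6})
        assert quality_weight(q) == pytest.approx(0.6)

    def test_missing_criterion_without_override_raises(self):
        with pytest.raises(ScoringError, match="missing"):
            quality_weight(StudyQuality({"adequacy": 0.8}))


class TestHazardScore:
    def test_single_loe_weight_normalises_to_one(self):
        table = _index_table([(60.0, 60.0)], a=0.3)
        assert hazard_score(table).v == pytest.approx(60.0)

    def test_two_equal_weight_loes_average(self):
        table = _index_table([(40.0, 40.0), (80.0, 80.0)], a=0.3)
        assert hazard_score(table).v == pytest.approx(60.0)

    def test_empty_table_raises(self):
        with pytest.raises(ScoringError, match="empty"):
            hazard_score(EvidenceTable(nm="X"))

    def test_matches_hand_composed_steps_on_small_tables(self):
        """Independent oracle: steps 1-5 composed by hand for <=5 LOEs."""
        rng = np.random.default_rng(2024)
        for _ in range(25):
            n = rng.integers(1, 6)
            sp = rng.uniform(0, 100, n)
            st_ = rng.uniform(0, 100, n)
            w = rng.uniform(0.05, 1.0, n)
            # by hand: S_j, normalised weights, weighted sum
            s = 0.3 * sp + 0.7 * st_
            expected = float(sum(s * (w / w.sum())))
            table = _index_table(list(zip(sp, st_)), a=0.3, weights=w)
            assert hazard_score(table).v == pytest.approx(expected, abs=1e-9)

    def test_v_within_convex_hull_of_loe_indices(self):
        rng = np.random.default_rng(7)
        sp = rng.uniform(0, 100, 10)
        st_ = rng.uniform(0, 100, 10)
        w = rng.uniform(0.1, 1, 10)
        table = _index_table(list(zip(sp, st_)), a=0.3, weights=w)
        result = hazard_score(table)
        s = result.breakdown["s_total"]
        assert s.min() - 1e-9 <= result.v <= s.max() + 1e-9

    def test_v_monotone_in_any_single_toxicity_index(self):
        base = [(40.0, 30.0), (60.0, 50.0), (20.0, 70.0)]
        v0 = hazard_score(_index_table(base, a=0.3, weights=[0.5, 0.7, 0.9])).v
        bumped = [(40.0, 30.0), (60.0, 90.0), (20.0, 70.0)]
        v1 = hazard_score(_index_table(bumped, a=0.3, weights=[0.5, 0.7, 0.9])).v
        assert v1 > v0

    def test_v_invariant_under_uniform_weight_rescaling(self):
        pairs = [(40.0, 30.0), (60.0, 50.0)]
        v1 = hazard_score(_index_table(pairs, a=0.3, weights=[0.4, 0.8])).v
        v2 = hazard_score(_index_table(pairs, a=0.3, weights=[0.2, 0.4])).v
        assert v1 == pytest.approx(v2)

    def test_absent_toxicity_evidence_scores_zero_not_excluded(self):
        # mirrors the published row with S_tox = 0: the row stays in
        record = LOERecord(loe_id="1", nm="X",
                           precomputed={"s_pchem": 41.67, "quality_weight": 0.63})
        other = LOERecord(loe_id="2", nm="X",
                          precomputed={"s_pchem": 50.0, "s_tox": 50.0,
                                       "quality_weight": 0.63})
        result = hazard_score(EvidenceTable(nm="X", records=[record, other]))
        assert result.breakdown["s_tox"].iloc[0] == 0.0
        assert len(result.breakdown) == 2
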