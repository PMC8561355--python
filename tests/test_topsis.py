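"""Fuzzy TOPSIS pipeline: stages, conventions, regression, properties."""

import pytest
from hypothesis import given, strategies as st

from cytomaint.fuzzy import TFN, Judgement, RATING_SCALE, WEIGHT_SCALE
from cytomaint.synthetic import ProblemGeneratorConfig, generate_problem
from cytomaint.topsis import (
    Criterion,
    DecisionProblem,
    Direction,
    FuzzyMatrix,
    IdealConvention,
    NormalisationMode,
    aggregate_ratings,
    aggregate_weights,
    apply_weights,
    closeness,
    normalise,
    reference_solutions,
    run_pipeline,
    separations,
)

from conftest import EXPECTED_NORMALISED, EXPECTED_RANKING, EXPECTED_RESULT, EXPECTED_WEIGHTED


def tiny_problem(weight_labels, rating_labels, directions=None, makers=("dm1",)):
    """Build a small fully-populated problem from label grids."""
    criteria = tuple(
        Criterion(name, directions.get(name, Direction.BENEFIT) if directions else Direction.BENEFIT)
        for name in weight_labels
    )
    alternatives = tuple(rating_labels)
    weight_judgements = {
        (dm, c): Judgement.from_label(weight_labels[c]) for dm in makers for c in weight_labels
    }
    rating_judgements = {
        (dm, alt, c): Judgement.from_label(rating_labels[alt][c])
        for dm in makers
        for alt in rating_labels
        for c in rating_labels[alt]
    }
    return DecisionProblem(
        criteria=criteria,
        alternatives=alternatives,
        decision_makers=tuple(makers),
        weight_judgements=weight_judgements,
        rating_judgements=rating_judgements,
    )


class TestAggregation:
    def test_single_maker_weight_passes_through(self):
        p = tiny_problem({"QH": "ML"}, {"A": {"QH": "VG"}})
        assert aggregate_weights(p)["QH"] == TFN(0.1, 0.3, 0.5)

    def test_identical_judgements_are_idempotent(self):
        p = tiny_problem({"C": "M"}, {"A": {"C": "G"}}, makers=("k1", "k2", "k3"))
        got_w = aggregate_weights(p)["C"]
        assert got_w.as_tuple() == pytest.approx(WEIGHT_SCALE["M"].as_tuple())
        got_r = aggregate_ratings(p)[("A", "C")]
        assert got_r.as_tuple() == pytest.approx(RATING_SCALE["G"].as_tuple())

    def test_componentwise_mean_over_makers(self):
        criteria = (Criterion("C", Direction.BENEFIT),)
        p = DecisionProblem(
            criteria=criteria,
            alternatives=("A",),
            decision_makers=("k1", "k2"),
            weight_judgements={
                ("k1", "C"): Judgement.from_tfn(TFN(0, 0, 0)),
                ("k2", "C"): Judgement.from_tfn(TFN(1, 1, 1)),
            },
            rating_judgements={
                ("k1", "A", "C"): Judgement.from_label("VP"),
                ("k2", "A", "C"): Judgement.from_label("G"),
            },
        )
        assert aggregate_weights(p)["C"] == TFN(0.5, 0.5, 0.5)
        assert aggregate_ratings(p)[("A", "C")] == TFN(3.5, 4.5, 5.5)

    def test_missing_cell_rejected_at_construction(self):
        with pytest.raises(ValueError, match="missing rating"):
            DecisionProblem(
                criteria=(Criterion("C", Direction.BENEFIT),),
                alternatives=("A",),
                decision_makers=("k1",),
                weight_judgements={("k1", "C"): Judgement.from_label("M")},
                rating_judgements={},
            )


class TestNormalisation:
    def _matrix(self, entries, alts, crits):
        return FuzzyMatrix(tuple(alts), tuple(crits), entries, stage="aggregated")

    def test_global_max_divides_by_column_max_u(self):
        m = self._matrix(
            {("A", "C"): TFN(9, 10, 10), ("B", "C"): TFN(5, 7.5, 10)}, "AB", ["C"]
        )
        out = normalise(m, [Criterion("C", Direction.BENEFIT)])
        assert out[("A", "C")].as_tuple() == pytest.approx((0.9, 1, 1))
        assert out[("B", "C")].as_tuple() == pytest.approx((0.5, 0.75, 1))

    def test_already_normalised_column_unchanged(self):
        m = self._matrix({("A", "C"): TFN(0.2, 0.5, 1.0)}, "A", ["C"])
        out = normalise(m, [Criterion("C", Direction.BENEFIT)])
        assert out[("A", "C")] == TFN(0.2, 0.5, 1.0)

    def test_global_max_treats_cost_like_benefit(self):
        m = self._matrix({("A", "C"): TFN(2, 4, 8)}, "A", ["C"])
        out = normalise(m, [Criterion("C", Direction.COST)])
        assert out[("A", "C")].as_tuple() == pytest.approx((0.25, 0.5, 1.0))

    def test_cost_inverse_inverts_through_min_lower_bound(self):
        m = self._matrix(
            {("A", "C"): TFN(2, 4, 8), ("B", "C"): TFN(1, 2, 4)}, "AB", ["C"]
        )
        out = normalise(m, [Criterion("C", Direction.COST)], NormalisationMode.COST_INVERSE)
        assert out[("A", "C")].as_tuple() == pytest.approx((0.125, 0.25, 0.5))
        assert out[("B", "C")].as_tuple() == pytest.approx((0.25, 0.5, 1.0))

    def test_cost_inverse_rejects_zero_components(self):
        m = self._matrix({("A", "C"): TFN(0, 1, 2)}, "A", ["C"])
        with pytest.raises(ValueError, match="strictly positive"):
            normalise(m, [Criterion("C", Direction.COST)], NormalisationMode.COST_INVERSE)

    def test_scale_max_uses_fixed_denominator(self):
        m = self._matrix({("A", "C"): TFN(3, 5, 7)}, "A", ["C"])
        out = normalise(
            m, [Criterion("C", Direction.BENEFIT)], NormalisationMode.SCALE_MAX, scale_max=10.0
        )
        assert out[("A", "C")].as_tuple() == pytest.approx((0.3, 0.5, 0.7))

    def test_zero_column_rejected(self):
        m = self._matrix({("A", "C"): TFN(0, 0, 0)}, "A", ["C"])
        with pytest.raises(ValueError, match="upper bounds are zero"):
            normalise(m, [Criterion("C", Direction.BENEFIT)])


class TestWeightingAndIdeals:
    def test_weighting_is_componentwise_product(self):
        norm = FuzzyMatrix(
            ("A", "B"),
            ("C",),
            {("A", "C"): TFN(0.9, 1, 1), ("B", "C"): TFN(0.3, 0.5, 0.7)},
            stage="normalised",
        )
        weighted = apply_weights(norm, {"C": TFN(0.1, 0.3, 0.5)})
        assert weighted[("A", "C")].as_tuple() == pytest.approx((0.09, 0.3, 0.5))
        assert weighted[("B", "C")].as_tuple() == pytest.approx((0.03, 0.15, 0.35))

    def test_unit_weight_is_identity(self):
        norm = FuzzyMatrix(
            ("A",), ("C",), {("A", "C"): TFN(0.2, 0.5, 0.9)}, stage="normalised"
        )
        assert apply_weights(norm, {"C": TFN(1, 1, 1)})[("A", "C")] == TFN(0.2, 0.5, 0.9)

    def test_absolute_ideals_swap_for_cost_criteria(self, hospital_problem):
        refs = reference_solutions(hospital_problem.criteria)
        assert refs.fpis["QH"] == TFN(1, 1, 1)
        assert refs.fpis["MC"] == TFN(0, 0, 0)
        assert refs.fpis["IC"] == TFN(0, 0, 0)
        for c in ("MP", "IH", "WO"):
            assert refs.fpis[c] == TFN(1, 1, 1)
        for c in ("QH", "MC", "IC", "MP", "IH", "WO"):
            swap = {TFN(1, 1, 1): TFN(0, 0, 0), TFN(0, 0, 0): TFN(1, 1, 1)}
            assert refs.fnis[c] == swap[refs.fpis[c]]

    def test_all_benefit_problem_has_unit_fpis(self):
        crits = [Criterion(f"C{i}", Direction.BENEFIT) for i in range(3)]
        refs = reference_solutions(crits)
        assert all(refs.fpis[c.name] == TFN(1, 1, 1) for c in crits)

    def test_chen_ideals_are_weighted_column_extremes(self):
        weighted = FuzzyMatrix(
            ("A", "B"),
            ("C",),
            {("A", "C"): TFN(0.1, 0.2, 0.6), ("B", "C"): TFN(0.05, 0.3, 0.4)},
            stage="weighted",
        )
        refs = reference_solutions(
            [Criterion("C", Direction.BENEFIT)], IdealConvention.CHEN, weighted=weighted
        )
        assert refs.fpis["C"] == TFN(0.6, 0.6, 0.6)
        assert refs.fnis["C"] == TFN(0.05, 0.05, 0.05)


class TestSeparationsAndCloseness:
    def test_alternative_at_the_positive_ideal(self):
        weighted = FuzzyMatrix(
            ("A",), ("C",), {("A", "C"): TFN(1, 1, 1)}, stage="weighted"
        )
        refs = reference_solutions([Criterion("C", Direction.BENEFIT)])
        d_plus, d_minus = separations(weighted, refs)
        assert d_plus["A"] == 0.0
        result = closeness(d_plus, d_minus)
        assert result.cc["A"] == 1.0

    def test_equidistant_alternative_scores_half(self):
        assert closeness({"A": 2.0}, {"A": 2.0}).cc["A"] == 0.5

    def test_degenerate_zero_distances_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            closeness({"A": 0.0}, {"A": 0.0})

    def test_ties_broken_lexicographically(self):
        result = closeness({"B": 1.0, "A": 1.0}, {"B": 1.0, "A": 1.0})
        assert result.ranking == ("A", "B")


class TestHospitalRegression:
    """The packaged consensus fixture reproduces the published tables."""

    def test_aggregated_weights(self, hospital_problem):
        weights = aggregate_weights(hospital_problem)
        assert weights["QH"] == TFN(0.1, 0.3, 0.5)
        assert weights["MC"] == TFN(0.0, 0.3, 0.5)
        assert weights["IC"] == TFN(0.0, 0.3, 0.5)
        assert weights["MP"] == TFN(0.0, 0.1, 0.3)
        assert weights["IH"] == TFN(0.0, 0.1, 0.3)
        assert weights["WO"] == TFN(0.0, 0.0, 0.1)

    def test_normalised_matrix(self, hospital_problem):
        out = run_pipeline(hospital_problem)
        for (crit, alt), expected in EXPECTED_NORMALISED.items():
            got = out.normalised[(alt, crit)]
            assert [round(x, 3) for x in got] == pytest.approx(list(expected)), (crit, alt)

    def test_weighted_matrix(self, hospital_problem):
        out = run_pipeline(hospital_problem)
        for (crit, alt), expected in EXPECTED_WEIGHTED.items():
            got = out.weighted[(alt, crit)]
            assert [round(x, 3) for x in got] == pytest.approx(list(expected)), (crit, alt)

    def test_separations_closeness_and_ranking(self, hospital_problem):
        res = run_pipeline(hospital_problem).result
        for alt, exp in EXPECTED_RESULT.items():
            assert round(res.d_plus[alt], 3) == pytest.approx(exp["d_plus"])
            assert round(res.d_minus[alt], 3) == pytest.approx(exp["d_minus"])
            assert round(res.cc[alt], 3) == pytest.approx(exp["cc"])
            assert res.rank_of(alt) == exp["rank"]
        assert res.ranking == EXPECTED_RANKING


def _add_alternative(problem, ratings_by_criterion, name="Z_new"):
    new_ratings = dict(problem.rating_judgements)
    for dm in problem.decision_makers:
        for c in problem.criteria:
            new_ratings[(dm, name, c.name)] = ratings_by_criterion[c.name]
    return DecisionProblem(
        criteria=problem.criteria,
        alternatives=problem.alternatives + (name,),
        decision_makers=problem.decision_makers,
        weight_judgements=problem.weight_judgements,
        rating_judgements=new_ratings,
    )


class TestPipelineProperties:
    @given(seed=st.integers(0, 10_000))
    def test_cc_bounded(self, seed):
        problem = generate_problem(ProblemGeneratorConfig(seed=seed))
        res = run_pipeline(problem).result
        assert all(0.0 <= cc <= 1.0 for cc in res.cc.values())

    def test_order_equivariance_under_permutation(self, hospital_problem):
        p = hospital_problem
        permuted = DecisionProblem(
            criteria=tuple(reversed(p.criteria)),
            alternatives=tuple(reversed(p.alternatives)),
            decision_makers=p.decision_makers,
            weight_judgements=p.weight_judgements,
            rating_judgements=p.rating_judgements,
        )
        r1 = run_pipeline(p).result
        r2 = run_pipeline(permuted).result
        assert r1.ranking == r2.ranking
        for alt in p.alternatives:
            assert r1.cc[alt] == pytest.approx(r2.cc[alt], abs=1e-12)

    @given(seed=st.integers(0, 2_000))
    def test_benefit_rating_improvement_never_lowers_cc(self, seed):
        problem = generate_problem(
            ProblemGeneratorConfig(n_cost_criteria=2, interval_judgement_prob=0.0, seed=seed)
        )
        benefit = next(c for c in problem.criteria if c.direction == Direction.BENEFIT)
        alt = problem.alternatives[0]
        dm = problem.decision_makers[0]
        improved = dict(problem.rating_judgements)
        improved[(dm, alt, benefit.name)] = Judgement.from_label("VG")
        problem2 = DecisionProblem(
            criteria=problem.criteria,
            alternatives=problem.alternatives,
            decision_makers=problem.decision_makers,
            weight_judgements=problem.weight_judgements,
            rating_judgements=improved,
        )
        # raising one benefit rating to the top label (componentwise >= any
        # label) must not lower the alternative's closeness under fixed ideals
        new_cc = run_pipeline(
            problem2, normalisation=NormalisationMode.SCALE_MAX
        ).result.cc[alt]
        old_cc = run_pipeline(
            problem, normalisation=NormalisationMode.SCALE_MAX
        ).result.cc[alt]
        assert new_cc >= old_cc - 1e-12

    @given(seed=st.integers(0, 2_000), label=st.sampled_from(RATING_SCALE.labels))
    def test_rank_reversal_resistance_with_fixed_denominator(self, seed, label):
        problem = generate_problem(ProblemGeneratorConfig(seed=seed))
        extended = _add_alternative(
            problem, {c.name: Judgement.from_label(label) for c in problem.criteria}
        )
        opts = {"normalisation": NormalisationMode.SCALE_MAX}
        r1 = run_pipeline(problem, **opts).result
        r2 = run_pipeline(extended, **opts).result
        for i, a in enumerate(problem.alternatives):
            for b in problem.alternatives[i + 1:]:
                assert (r1.cc[a] - r1.cc[b]) * (r2.cc[a] - r2.cc[b]) >= 0
                assert r1.cc[a] == pytest.approx(r2.cc[a], abs=1e-12)

    @given(seed=st.integers(0, 2_000))
    def test_rank_reversal_resistance_when_column_maxima_fixed(self, seed):
        # under per-column normalisation the ideals are data-independent but
        # the denominators are not; orders are preserved whenever the added
        # alternative leaves every column maximum unchanged
        problem = generate_problem(ProblemGeneratorConfig(seed=seed))
        extended = _add_alternative(
            problem, {c.name: Judgement.from_label("VP") for c in problem.criteria}
        )
        r1 = run_pipeline(problem).result
        r2 = run_pipeline(extended).result
        for i, a in enumerate(problem.alternatives):
            for b in problem.alternatives[i + 1:]:
                assert (r1.cc[a] - r1.cc[b]) * (r2.cc[a] - r2.cc[b]) >= 0

    def test_single_alternative_single_criterion_closed_form(self):
        # rating VG, weight VH: weighted row (0.81, 1, 1) against (1,1,1)/(0,0,0)
        p = tiny_problem({"C": "VH"}, {"A": {"C": "VG"}})
        res = run_pipeline(p).result
        import math

        d_plus = math.sqrt(((1 - 0.81) ** 2) / 3)
        d_minus = math.sqrt((0.81**2 + 1 + 1) / 3)
        assert res.d_plus["A"] == pytest.approx(d_plus)
        assert res.d_minus["A"] == pytest.approx(d_minus)
        assert res.cc["A"] == pytest.approx(d_minus / (d_minus + d_plus))
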