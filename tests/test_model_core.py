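"""Core semantics: expression evaluation, target levels, influence inference,
and model validation."""

import pytest

from qualm import (
    And,
    Cmp,
    EvaluationError,
    FALSE,
    FunctionTerm,
    GeneratorParams,
    LogicalModel,
    Not,
    Or,
    QualitativeSpecies,
    TRUE,
    Transition,
    TransitionInput,
    TransitionOutput,
    evaluate_expression,
    infer_regulatory_graph,
    random_model,
    target_level,
    validate_model,
)

from conftest import truth_table_sign


class TestEvaluateExpression:
    @pytest.mark.parametrize(
        "expr,state,expected",
        [
            (And((Cmp("eq", "A", 1), Not(Cmp("eq", "B", 1)))), {"A": 1, "B": 0, "C": 0}, True),
            (And((Cmp("eq", "A", 1), Not(Cmp("eq", "B", 1)))), {"A": 1, "B": 1, "C": 0}, False),
            (TRUE, {"A": 0}, True),
            (FALSE, {"A": 1}, False),
            (Cmp("geq", "X", 2), {"X": 1}, False),
            (Cmp("geq", "X", 2), {"X": 2}, True),
            (Cmp("lt", "X", 2), {"X": 1}, True),
            (Cmp("neq", "X", 0), {"X": 2}, True),
            (Or((Cmp("eq", "A", 1), Cmp("eq", "B", 1))), {"A": 0, "B": 1}, True),
        ],
    )
    def test_boolean_and_comparison_semantics(self, expr, state, expected):
        assert evaluate_expression(expr, state) is expected

    def test_unresolved_reference_names_the_species(self):
        with pytest.raises(EvaluationError, match="Missing"):
            evaluate_expression(Cmp("eq", "Missing", 1), {"A": 0})


class TestTargetLevel:
    def test_toy_activator_on_inhibitor_off_gives_one(self, toy):
        assert target_level(toy, "C", {"A": 1, "B": 0, "C": 0}) == 1

    def test_toy_default_term_applies_when_no_condition_holds(self, toy):
        assert target_level(toy, "C", {"A": 0, "B": 0, "C": 1}) == 0

    @pytest.mark.parametrize("state", [{"A": 0, "B": 1, "C": 0}, {"A": 1, "B": 1, "C": 1}])
    def test_transitionless_species_keeps_its_level(self, toy, state):
        assert target_level(toy, "A", state) == state["A"]
        assert target_level(toy, "B", state) == state["B"]

    def test_first_true_term_in_document_order_wins(self):
        sp = [QualitativeSpecies("A"), QualitativeSpecies("B", max_level=2)]
        tr = Transition(
            id="tr_B",
            inputs=(TransitionInput("A"),),
            outputs=(TransitionOutput("B"),),
            function_terms=(
                FunctionTerm(2, Cmp("eq", "A", 1)),
                FunctionTerm(1, Cmp("geq", "A", 1)),
            ),
            default_term=FunctionTerm(0),
        )
        model = LogicalModel(sp, [tr])
        assert target_level(model, "B", {"A": 1, "B": 0}) == 2

    def test_total_and_in_range_on_random_models(self, random_models):
        for model in random_models(10, n_species=5, max_level=2):
            for state in model.iter_states():
                for sid in model.species_by_id:
                    lvl = target_level(model, sid, state)
                    assert 0 <= lvl <= model.species_by_id[sid].max_level


class TestInferRegulatoryGraph:
    def test_toy_activation_and_inhibition_signs(self, toy):
        g = infer_regulatory_graph(toy)
        assert g.edges == (("A", "C", "+"), ("B", "C", "-"))

    def test_unused_declared_input_yields_no_edge(self):
        sp = [QualitativeSpecies(i) for i in "ABC"]
        tr = Transition(
            id="tr_C",
            inputs=(TransitionInput("A"), TransitionInput("B")),
            outputs=(TransitionOutput("C"),),
            function_terms=(FunctionTerm(1, Cmp("eq", "A", 1)),),
            default_term=FunctionTerm(0),
        )
        model = LogicalModel(sp, [tr])
        g = infer_regulatory_graph(model)
        assert g.sign("B", "C") is None
        assert g.sign("A", "C") == "+"

    def test_xor_table_gives_dual_edges(self):
        sp = [QualitativeSpecies(i) for i in "ABC"]
        xor = Or(
            (
                And((Cmp("eq", "A", 1), Cmp("eq", "B", 0))),
                And((Cmp("eq", "A", 0), Cmp("eq", "B", 1))),
            )
        )
        tr = Transition(
            id="tr_C",
            inputs=(TransitionInput("A"), TransitionInput("B")),
            outputs=(TransitionOutput("C"),),
            function_terms=(FunctionTerm(1, xor),),
            default_term=FunctionTerm(0),
        )
        model = LogicalModel(sp, [tr])
        g = infer_regulatory_graph(model)
        assert g.sign("A", "C") == "dual"
        assert g.sign("B", "C") == "dual"

    def test_agrees_with_truth_table_oracle_on_random_models(self, random_models):
        models = random_models(15, n_species=6, max_regulators=4)
        models += random_models(5, n_species=5, max_level=2, max_regulators=3)
        for model in models:
            g = infer_regulatory_graph(model)
            for v in model.species_order:
                for u in model.regulators(v):
                    assert g.sign(u, v) == truth_table_sign(model, u, v), (u, v, model.name)


class TestValidateModel:
    def test_toy_model_is_valid(self, toy):
        assert validate_model(toy) == []

    def test_result_level_above_max_level_is_reported(self):
        sp = [QualitativeSpecies("A"), QualitativeSpecies("B")]
        tr = Transition(
            id="tr_B",
            inputs=(TransitionInput("A"),),
            outputs=(TransitionOutput("B"),),
            function_terms=(FunctionTerm(2, Cmp("eq", "A", 1)),),
            default_term=FunctionTerm(0),
        )
        diags = validate_model(LogicalModel(sp, [tr]))
        assert any(d.code == "result-out-of-range" for d in diags)

    def test_two_transitions_sharing_an_output_are_reported(self, toy):
        extra = Transition(
            id="tr_C2",
            inputs=(TransitionInput("B"),),
            outputs=(TransitionOutput("C"),),
            function_terms=(FunctionTerm(1, Cmp("eq", "B", 1)),),
            default_term=FunctionTerm(0),
        )
        model = LogicalModel(toy.species, toy.transitions + (extra,))
        diags = validate_model(model)
        assert any(d.code == "multiple-transitions" for d in diags)

    def test_initial_level_above_max_is_reported(self):
        model = LogicalModel([QualitativeSpecies("A", max_level=1, initial_level=2)])
        assert any(d.code == "bad-initial-level" for d in validate_model(model))

    def test_constant_species_as_output_is_reported(self):
        sp = [QualitativeSpecies("A"), QualitativeSpecies("B", constant=True)]
        tr = Transition(
            id="tr_B",
            inputs=(TransitionInput("A"),),
            outputs=(TransitionOutput("B"),),
            function_terms=(FunctionTerm(1, Cmp("eq", "A", 1)),),
            default_term=FunctionTerm(0),
        )
        assert any(
            d.code == "constant-output" for d in validate_model(LogicalModel(sp, [tr]))
        )

    def test_overlapping_terms_warn_but_do_not_invalidate(self):
        sp = [QualitativeSpecies("A"), QualitativeSpecies("B")]
        tr = Transition(
            id="tr_B",
            inputs=(TransitionInput("A"),),
            outputs=(TransitionOutput("B"),),
            function_terms=(
                FunctionTerm(1, Cmp("eq", "A", 1)),
                FunctionTerm(0, Cmp("geq", "A", 1)),
            ),
            default_term=FunctionTerm(0),
        )
        diags = validate_model(LogicalModel(sp, [tr]))
        assert any(d.code == "overlapping-terms" and d.severity == "warning" for d in diags)
        assert not any(d.severity == "error" for d in diags)

    def test_condition_species_missing_from_inputs_is_reported(self):
        sp = [QualitativeSpecies("A"), QualitativeSpecies("B")]
        tr = Transition(
            id="tr_B",
            inputs=(),
            outputs=(TransitionOutput("B"),),
            function_terms=(FunctionTerm(1, Cmp("eq", "A", 1)),),
            default_term=FunctionTerm(0),
        )
        assert any(
            d.code == "undeclared-input" for d in validate_model(LogicalModel(sp, [tr]))
        )


def test_boolean_target_equals_disjunction_of_true_term_conditions(random_models):
    """For Boolean models the update is the OR of the level-1 terms' conditions."""
    for model in random_models(10, n_species=5):
        for sid, tr in model.transition_of.items():
            conds = [t.condition for t in tr.function_terms if t.result_level == 1]
            for state in model.iter_states():
                via_or = any(evaluate_expression(c, state) for c in conds)
                expected = via_or or (
                    tr.default_term.result_level == 1
                    and not any(
                        evaluate_expression(t.condition, state)
                        for t in tr.function_terms
                    )
                )
                assert target_level(model, sid, state) == int(expected)
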