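"""Kernel semantics: condition evaluation, rule application, fixpoints,
knockouts, protocols."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from nutlogic.engine import (
    And,
    Atom,
    Effect,
    InputCondition,
    Not,
    Or,
    Rule,
    SimulationConfig,
    apply_rule,
    configure_model,
    default_state,
    eval_condition,
    find_lss,
    permuted_rule_order,
    phos,
    predict,
    present,
    run_protocol,
    set_inputs,
)
from nutlogic.errors import (
    ConfigurationError,
    ModelConsistencyError,
    OscillationError,
)

from conftest import two_protein_model


# ---------------------------------------------------------------------------
# condition evaluation


def test_condition_evaluation_on_kinase_cascade(tiny_model):
    state = default_state(tiny_model)
    cond = And(present("Prt2"), present("Prt1"), phos("Prt1"))
    assert not eval_condition(state, cond)  # Prt1 not yet phosphorylated
    state["Prt1"].phosphorylation = 1
    assert eval_condition(state, cond)
    assert eval_condition(state, And())  # vacuous truth
    assert not eval_condition(state, Or())
    assert eval_condition(state, Not(phos("Prt2")))
    assert eval_condition(state, Atom("Prt2", "phosphorylation", 1, op="ne"))


def test_condition_with_dangling_reference_raises(tiny_model):
    state = default_state(tiny_model)
    with pytest.raises(ModelConsistencyError):
        eval_condition(state, present("Ghost"))


# ---------------------------------------------------------------------------
# rule application


def test_rule_fires_once_and_is_idempotent(tiny_model):
    state = default_state(tiny_model)
    state["Prt1"].phosphorylation = 1
    rule = tiny_model.rules[0]
    assert apply_rule(state, rule)
    assert state["Prt2"].phosphorylation == 1
    assert not apply_rule(state, rule)  # satisfied effect: no change


def test_rule_never_modifies_knocked_out_component(tiny_model):
    state = default_state(configure_model(tiny_model, knockouts={"Prt2"}))
    state["Prt1"].phosphorylation = 1
    rule = tiny_model.rules[0]
    assert not apply_rule(state, rule, knockouts={"Prt2"})
    assert state["Prt2"].phosphorylation == 0
    assert state["Prt2"].presence == 0


# ---------------------------------------------------------------------------
# default state


def test_default_state_all_present_except_knockouts(glucose_wt):
    state = default_state(glucose_wt, InputCondition(1))
    assert all(getattr(c, "presence", 1) == 1 for c in state.components())
    ko = default_state(configure_model(glucose_wt, knockouts={"Snf1"},
                                       crosstalk_flags=glucose_wt.crosstalk_flags))
    assert ko["Snf1"].presence == 0
    assert sum(getattr(c, "presence", 1) == 0 for c in ko.components()) == 1


def test_default_state_unknown_knockout_names_offender(glucose_wt):
    with pytest.raises(ConfigurationError, match="NotAComponent"):
        configure_model(glucose_wt, knockouts={"NotAComponent"})


# ---------------------------------------------------------------------------
# fixpoint search


def test_empty_rule_list_is_vacuous_fixpoint(tiny_model):
    empty = two_protein_model(rules=())
    state = default_state(empty)
    assert find_lss(empty, state) == state


def test_two_protein_system_reaches_lss(tiny_model):
    state = default_state(tiny_model)
    state["Prt1"].phosphorylation = 1
    lss = find_lss(tiny_model, state)
    assert lss["Prt2"].phosphorylation == 1
    # fixpoint of every rule
    assert not any(apply_rule(lss.copy(), r) for r in tiny_model.rules)


def test_contradictory_rules_raise_oscillation_error():
    flip = two_protein_model(
        rules=(
            Rule("up", "PathwayX", And(), (Effect("Prt1", "phosphorylation", 1),)),
            Rule("down", "PathwayX", phos("Prt1"), (Effect("Prt1", "phosphorylation", 0),)),
        )
    )
    with pytest.raises(OscillationError) as err:
        find_lss(flip, default_state(flip), SimulationConfig(max_passes=20))
    assert len(err.value.trace) == 2  # last two sweep traces attached


# ---------------------------------------------------------------------------
# configuration


def test_all_flags_off_leaves_base_rules(glucose_wt):
    off = configure_model(glucose_wt, crosstalk_flags={i: 0 for i in glucose_wt.crosstalk})
    assert off.active_rules() == off.rules
    on = configure_model(glucose_wt, crosstalk_flags={7: 1, 9: 1})
    extra = on.active_rules()[len(on.rules):]
    assert [r.crosstalk_id for r in extra] == [7, 9]  # ascending id order


def test_unknown_crosstalk_id_rejected(glucose_wt):
    with pytest.raises(ConfigurationError):
        configure_model(glucose_wt, crosstalk_flags={99: 1})


# ---------------------------------------------------------------------------
# protocols


def test_empty_condition_sequence_rejected(glucose_wt):
    with pytest.raises(ConfigurationError):
        run_protocol(glucose_wt, SimulationConfig(condition_sequence=()))


def test_predict_pre_equilibrates_at_opposite_condition(glucose_wt):
    target = InputCondition(1)
    cfg = SimulationConfig(condition_sequence=(target.opposite(), target))
    assert predict(glucose_wt, target) == run_protocol(glucose_wt, cfg)[-1][1]


def test_determinism_bit_identical_lss(glucose_wt):
    a = predict(glucose_wt, InputCondition(0))
    b = predict(glucose_wt, InputCondition(0))
    assert a == b and a.diff(b) == []


# ---------------------------------------------------------------------------
# properties


@settings(derandomize=True, max_examples=200)
@given(st.data())
def test_random_condition_trees_match_reference_evaluator(data):
    """Dual route: tree evaluation vs an independent recursive oracle."""
    model = two_protein_model()
    state = default_state(model)
    state["Prt1"].phosphorylation = data.draw(st.integers(0, 1))
    state["Prt2"].phosphorylation = data.draw(st.integers(0, 1))

    atoms = st.builds(
        Atom,
        st.sampled_from(["Prt1", "Prt2"]),
        st.sampled_from(["presence", "phosphorylation"]),
        st.integers(0, 1),
        st.sampled_from(["eq", "ne"]),
    )
    trees = st.recursive(
        atoms,
        lambda sub: st.one_of(
            st.builds(lambda a, b: And(a, b), sub, sub),
            st.builds(lambda a, b: Or(a, b), sub, sub),
            st.builds(Not, sub),
        ),
        max_leaves=12,
    )
    tree = data.draw(trees)

    def oracle(node):
        if isinstance(node, Atom):
            actual = getattr(state[node.component], node.field)
            return actual == node.value if node.op == "eq" else actual != node.value
        if isinstance(node, And):
            return all(oracle(c) for c in node.children)
        if isinstance(node, Or):
            return any(oracle(c) for c in node.children)
        return not oracle(node.child)

    assert eval_condition(state, tree) == oracle(tree)


def test_domain_safety_after_simulation(glucose_wt):
    from nutlogic.engine import field_domain, KIND_FIELDS

    for g in (0, 1):
        lss = predict(glucose_wt, InputCondition(g))
        for comp in lss.components():
            for f in KIND_FIELDS[comp.kind]:
                assert getattr(comp, f) in field_domain(comp.kind, f)


def test_lss_confluent_under_rule_permutations(glucose_wt):
    """The packaged rule set is order-independent: permuting the sweep
    order never changes the steady state."""
    rng = random.Random(7)
    cond = InputCondition(1)
    reference = predict(glucose_wt, cond)
    for _ in range(25):
        order = permuted_rule_order(glucose_wt, rng)
        state = default_state(glucose_wt, cond.opposite())
        mid = find_lss(glucose_wt, state, rule_order=order)
        set_inputs(mid, cond)
        assert find_lss(glucose_wt, mid, rule_order=order) == reference
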